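"""Single-sample set scoring and preranked GSEA against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senoconverge import DataError, GeneSetCollection, ParameterError
from senoconverge import simulate as sim
from senoconverge.enrich import (
    SampleSetScore,
    gsea_preranked,
    gsva_scores,
    score_signature_groups,
)


# ---------------------------------------------------------------------------
# straightforward loop-based reimplementation of the single-sample scoring
# ---------------------------------------------------------------------------

def gsva_oracle(expr: pd.DataFrame, sets: dict, kernel: str) -> pd.DataFrame:
    X = expr.to_numpy(float)
    G, N = X.shape
    z = np.zeros((G, N))
    for g in range(G):
        if kernel == "gaussian":
            sd = float(np.std(X[g], ddof=1))
            h = sd / 4.0
            for j in range(N):
                z[g, j] = np.mean([stats.norm.cdf((X[g, j] - X[g, k]) / h)
                                   for k in range(N)]) if sd > 0 else 0.5
        else:
            for j in range(N):
                z[g, j] = np.mean([X[g, k] <= X[g, j] for k in range(N)])
    genes = list(expr.index)
    out = {}
    for name, members in sets.items():
        member_idx = {genes.index(m) for m in members if m in genes}
        col = []
        for j in range(N):
            order = sorted(range(G), key=lambda g: (-z[g, j], g))
            sym = [abs(r - (G + 1) / 2) for r in range(1, G + 1)]
            denom = sum(sym[i] for i, g in enumerate(order) if g in member_idx)
            miss = 1.0 / (G - len(member_idx))
            v, walk = 0.0, []
            for i, g in enumerate(order):
                v += sym[i] / denom if g in member_idx else -miss
                walk.append(v)
            col.append(max(max(walk), 0.0) + min(min(walk), 0.0))
        out[name] = col
    return pd.DataFrame(out, index=expr.columns).T


def gsea_walk_extrema(sorted_scores, hit_mask, weight=1.0):
    """Explicit O(G) cumulative walk; returns (max, min) deviations."""
    G = len(sorted_scores)
    m = int(np.sum(hit_mask))
    w = np.abs(sorted_scores) ** weight
    denom = float(np.sum(w[hit_mask]))
    v, best_hi, best_lo = 0.0, -np.inf, np.inf
    for i in range(G):
        v += w[i] / denom if hit_mask[i] else -1.0 / (G - m)
        best_hi = max(best_hi, v)
        best_lo = min(best_lo, v)
    return best_hi, best_lo


def gsea_es_oracle(sorted_scores, hit_mask, weight=1.0):
    best_hi, best_lo = gsea_walk_extrema(sorted_scores, hit_mask, weight)
    return best_hi if best_hi > -best_lo else best_lo


def assert_es_matches_oracle(es, sorted_scores, hit_mask, tol=1e-12):
    """Signed comparison, except when the positive and negative extrema tie
    in magnitude (the sign is then arbitrary up to float noise)."""
    hi, lo = gsea_walk_extrema(sorted_scores, hit_mask)
    if abs(hi + lo) > 1e-9:
        expected = hi if hi > -lo else lo
        assert es == pytest.approx(expected, abs=tol)
    else:
        assert abs(es) == pytest.approx(hi, abs=1e-9)


class TestGsvaScores:
    @pytest.mark.parametrize("kernel", ["gaussian", "none"])
    def test_matches_loop_oracle(self, rng, kernel):
        for _ in range(5):
            G, N = int(rng.integers(8, 20)), int(rng.integers(3, 6))
            genes = [f"g{i}" for i in range(G)]
            expr = pd.DataFrame(rng.normal(size=(G, N)), index=genes,
                                columns=[f"s{j}" for j in range(N)])
            sets = {"A": genes[:4], "B": genes[3:9]}
            ours = gsva_scores(expr, GeneSetCollection("c", sets), kernel=kernel)
            ref = gsva_oracle(expr, sets, kernel)
            np.testing.assert_allclose(ours.scores.to_numpy(),
                                       ref.to_numpy(), atol=1e-12)

    def test_scores_bounded(self, rng):
        genes = [f"g{i}" for i in range(50)]
        expr = pd.DataFrame(rng.normal(size=(50, 8)), index=genes,
                            columns=[f"s{j}" for j in range(8)])
        sets = GeneSetCollection("c", {"A": genes[:10], "B": genes[10:40]})
        s = gsva_scores(expr, sets).scores.to_numpy()
        assert np.all(s >= -1.0) and np.all(s <= 1.0)

    def test_identical_samples_get_identical_scores(self, rng):
        genes = [f"g{i}" for i in range(30)]
        col = rng.normal(size=30)
        expr = pd.DataFrame({"s1": col, "s2": rng.normal(size=30), "s3": col},
                            index=genes)
        s = gsva_scores(expr, GeneSetCollection("c", {"A": genes[:8]})).scores
        np.testing.assert_allclose(s["s1"], s["s3"], atol=1e-12)

    def test_permuting_samples_permutes_columns(self, rng):
        genes = [f"g{i}" for i in range(30)]
        expr = pd.DataFrame(rng.normal(size=(30, 5)), index=genes,
                            columns=list("abcde"))
        sets = GeneSetCollection("c", {"A": genes[:8]})
        s1 = gsva_scores(expr, sets).scores
        s2 = gsva_scores(expr[list("edcba")], sets).scores
        np.testing.assert_allclose(s1[list("edcba")].to_numpy(), s2.to_numpy(),
                                   atol=1e-12)

    def test_constant_gene_row_warns(self, rng):
        genes = [f"g{i}" for i in range(10)]
        expr = pd.DataFrame(rng.normal(size=(10, 4)), index=genes)
        expr.iloc[0] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            gsva_scores(expr, GeneSetCollection("c", {"A": genes[:3]}))

    def test_single_sample_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 1)),
                            index=[f"g{i}" for i in range(10)])
        with pytest.raises(ParameterError):
            gsva_scores(expr, GeneSetCollection("c", {"A": ["g0"]}))

    def test_no_surviving_sets_is_error(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 3)),
                            index=[f"g{i}" for i in range(10)])
        with pytest.warns(UserWarning, match="dropped"), \
             pytest.raises(DataError):
            gsva_scores(expr, GeneSetCollection("c", {"A": ["nope"]}))

    def test_planted_shift_raises_group_scores(self):
        genes = [f"g{i:04d}" for i in range(1, 101)]
        sets = sim.make_random_sets(3, 12, genes, seed=31)
        name = list(sets.sets)[0]
        expr, truth = sim.simulate_expression(100, 16, sets, {name: 2.0}, seed=31)
        s = gsva_scores(expr, sets).scores
        groups = np.array(truth.extra["groups"])
        diff = (np.median(s.loc[name, groups == "B"])
                - np.median(s.loc[name, groups == "A"]))
        assert diff > 0


class TestGseaPreranked:
    def test_singleton_top_gene_gives_unit_es(self):
        ranking = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0], index=list("abcde"))
        res = gsea_preranked(ranking, GeneSetCollection("c", {"S": ["a"]}),
                             min_size=1, nperm=50, seed=0)
        assert res["es"].iloc[0] == pytest.approx(1.0)

    def test_whole_universe_set_dropped(self):
        ranking = pd.Series([3.0, 2.0, 1.0, -1.0], index=list("abcd"))
        res = gsea_preranked(ranking,
                             GeneSetCollection("c", {"S": list("abcd")}),
                             min_size=1, nperm=10, seed=0)
        assert res.empty

    def test_size_window_enforced(self, rng):
        genes = [f"g{i}" for i in range(40)]
        ranking = pd.Series(rng.normal(size=40), index=genes)
        coll = GeneSetCollection("c", {"small": genes[:2], "big": genes[:30],
                                       "ok": genes[:5]})
        res = gsea_preranked(ranking, coll, min_size=3, max_size=20,
                             nperm=20, seed=0)
        assert list(res["set"]) == ["ok"]

    def test_es_matches_brute_force_oracle(self, rng):
        for _ in range(50):
            G = int(rng.integers(15, 50))
            m = int(rng.integers(3, 10))
            genes = [f"g{i}" for i in range(G)]
            values = rng.normal(size=G)
            ranking = pd.Series(values, index=genes)
            members = list(rng.choice(genes, size=m, replace=False))
            res = gsea_preranked(ranking, GeneSetCollection("c", {"S": members}),
                                 min_size=1, nperm=10, seed=5)
            order = np.argsort(-values)  # distinct floats: no tie ambiguity
            hit = np.isin(np.array(genes)[order], members)
            assert_es_matches_oracle(res["es"].iloc[0], values[order], hit)

    def test_es_invariant_under_positive_scaling(self, rng):
        genes = [f"g{i}" for i in range(30)]
        values = rng.normal(size=30)
        coll = GeneSetCollection("c", {"S": genes[:6]})
        r1 = gsea_preranked(pd.Series(values, index=genes), coll,
                            min_size=1, nperm=10, seed=3)
        r2 = gsea_preranked(pd.Series(7.5 * values, index=genes), coll,
                            min_size=1, nperm=10, seed=3)
        assert r1["es"].iloc[0] == pytest.approx(r2["es"].iloc[0], abs=1e-12)

    def test_negating_ranking_negates_es(self, rng):
        genes = [f"g{i}" for i in range(30)]
        values = rng.normal(size=30)
        coll = GeneSetCollection("c", {"S": genes[:6], "T": genes[10:20]})
        r1 = gsea_preranked(pd.Series(values, index=genes), coll,
                            min_size=1, nperm=10, seed=3)
        r2 = gsea_preranked(pd.Series(-values, index=genes), coll,
                            min_size=1, nperm=10, seed=3)
        for s in ("S", "T"):
            e1 = float(r1.loc[r1["set"] == s, "es"].iloc[0])
            e2 = float(r2.loc[r2["set"] == s, "es"].iloc[0])
            assert e1 == pytest.approx(-e2, abs=1e-12)

    def test_permutation_p_consistent_with_larger_run(self, rng):
        genes = [f"g{i}" for i in range(40)]
        values = rng.normal(size=40)
        ranking = pd.Series(values, index=genes)
        coll = GeneSetCollection("c", {"S": genes[:8]})
        p_small = gsea_preranked(ranking, coll, min_size=1, nperm=200,
                                 seed=0)["pvalue"].iloc[0]
        p_big = gsea_preranked(ranking, coll, min_size=1, nperm=2000,
                               seed=1)["pvalue"].iloc[0]
        # binomial 95% band of the small run around the big-run estimate
        band = 1.96 * np.sqrt(p_big * (1 - p_big) / 200)
        assert abs(p_small - p_big) < band + 2 / 200

    def test_degenerate_ranking_rejected(self):
        ranking = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        with pytest.raises(DataError, match="degenerate"):
            gsea_preranked(ranking, GeneSetCollection("c", {"S": ["a"]}),
                           min_size=1)

    def test_nan_in_ranking_rejected(self):
        ranking = pd.Series([1.0, np.nan], index=list("ab"))
        with pytest.raises(DataError, match="missing"):
            gsea_preranked(ranking, GeneSetCollection("c", {"S": ["a"]}),
                           min_size=1)

    def test_nes_sign_matches_es_sign(self, rng):
        genes = [f"g{i}" for i in range(60)]
        ranking = pd.Series(rng.normal(size=60), index=genes)
        coll = GeneSetCollection(
            "c", {f"S{k}": list(rng.choice(genes, 8, replace=False))
                  for k in range(10)})
        res = gsea_preranked(ranking, coll, min_size=1, nperm=100, seed=2)
        nonzero = res[res["es"] != 0]
        assert np.all(np.sign(nonzero["nes"]) == np.sign(nonzero["es"]))


class TestScoreSignatureGroups:
    def _scores(self, a_vals, b_vals):
        cols = {f"a{i}": [v] for i, v in enumerate(a_vals)}
        cols.update({f"b{i}": [v] for i, v in enumerate(b_vals)})
        df = pd.DataFrame(cols, index=["S"])
        groups = {c: ("A" if c.startswith("a") else "B") for c in df.columns}
        return df, groups

    def test_identical_groups(self):
        df, groups = self._scores([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        res = score_signature_groups(df, groups)
        assert res.loc["S", "difference"] == pytest.approx(0.0)
        assert res.loc["S", "pvalue"] == pytest.approx(1.0)

    def test_hand_t_formula_three_vs_three(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
        df, groups = self._scores(a, b)
        res = score_signature_groups(df, groups)
        na, nb = 3, 3
        sp2 = (np.var(a, ddof=1) * (na - 1) + np.var(b, ddof=1) * (nb - 1)) / (na + nb - 2)
        t_hand = (np.mean(b) - np.mean(a)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.loc["S", "t"] == pytest.approx(t_hand)
        assert res.loc["S", "difference"] == pytest.approx(2.0)

    def test_shifted_group_detected(self, rng):
        a = rng.normal(0, 0.1, 10)
        b = rng.normal(1, 0.1, 10)
        df, groups = self._scores(a, b)
        res = score_signature_groups(df, groups)
        assert res.loc["S", "difference"] > 0.5
        assert res.loc["S", "pvalue"] < 1e-6

    def test_single_sample_group_rejected(self):
        df, groups = self._scores([0.1], [0.2, 0.3])
        with pytest.raises(ParameterError):
            score_signature_groups(df, groups)
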
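"""Gene-set scoring: single-sample (GSVA-style) and preranked GSEA.

Single-sample scoring follows the gene-set variation analysis construction:
a per-gene cross-sample kernel-CDF statistic (Gaussian kernel with bandwidth
sd/4, or the empirical CDF), a within-sample ranking of genes by that
statistic with the symmetric rank score |rank - (G+1)/2|, and a weighted
Kolmogorov-Smirnov random walk per set whose score is the sum of the maximum
positive and maximum negative deviations (the signed-difference convention,
bounded in [-1, 1]).

Preranked GSEA sorts genes by a caller-supplied ranking statistic and runs
the weighted running-sum enrichment: hits add |score|^weight normalized over
the set, misses subtract 1/(G - m).  The null is built from random gene sets
of matching size; NES divides ES by the mean |null ES| of matching sign, and
the permutation p-value is two-sided with a +1 pseudocount.  BH adjustment
is applied within a collection only, so p-values from different gene-set
databases are never pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParameterError
from .io import GeneSetCollection
from .scoring import bh_adjust


@dataclass
class SampleSetScore:
    """Sets-by-samples matrix of single-sample enrichment scores."""

    scores: pd.DataFrame
    kernel: str = "gaussian"
    tie_rule: str = "stable"


def _kernel_cdf_statistic(X: np.ndarray, kernel: str) -> np.ndarray:
    """Per-gene cross-sample CDF statistic, genes x samples in, same out."""
    n_genes, n_samples = X.shape
    diffs = X[:, :, None] - X[:, None, :]  # (G, N, N): x_gj - x_gk
    if kernel == "gaussian":
        sd = X.std(axis=1, ddof=1)
        constant = sd == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant gene row(s): statistic set to 0.5",
                stacklevel=3,
            )
        h = np.where(constant, 1.0, sd / 4.0)
        z = stats.norm.cdf(diffs / h[:, None, None]).mean(axis=2)
        z[constant, :] = 0.5
        return z
    if kernel == "none":
        return (diffs >= 0).mean(axis=2)
    raise ParameterError(f"unknown kernel '{kernel}'")


def gsva_scores(
    expr: pd.DataFrame,
    sets: GeneSetCollection,
    kernel: str = "gaussian",
) -> SampleSetScore:
    """Single-sample gene-set scores for a genes-by-samples matrix.

    Set members are intersected with the matrix genes; sets left without a
    single surviving member are dropped with a warning, and an empty
    surviving collection is an error.
    """
    if expr.shape[1] < 2:
        raise ParameterError("need >= 2 samples for cross-sample density estimation")
    genes = expr.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    surviving: dict[str, np.ndarray] = {}
    for name, members in sets.sets.items():
        idx = np.array([gene_pos[g] for g in members if g in gene_pos], dtype=int)
        if idx.size == 0:
            warnings.warn(f"gene set '{name}' has no members in the matrix; dropped",
                          stacklevel=2)
            continue
        surviving[name] = idx
    if not surviving:
        raise DataError("no gene set has members in the expression matrix")

    X = expr.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    z = _kernel_cdf_statistic(X, kernel)

    # membership matrix (genes x sets) and symmetric rank score by position
    set_names = list(surviving)
    member = np.zeros((n_genes, len(set_names)), dtype=bool)
    for s, name in enumerate(set_names):
        member[surviving[name], s] = True
    m_sizes = member.sum(axis=0)
    sym = np.abs(np.arange(1, n_genes + 1) - (n_genes + 1) / 2.0)

    out = np.empty((len(set_names), n_samples))
    miss_step = 1.0 / np.maximum(n_genes - m_sizes, 1)
    for j in range(n_samples):
        order = np.argsort(-z[:, j], kind="stable")  # ties: input gene order
        mo = member[order]  # (G, S) membership in walk order
        hits_w = mo * sym[:, None]
        denom = hits_w.sum(axis=0)
        denom = np.where(denom == 0, np.nan, denom)
        steps = hits_w / denom - (~mo) * miss_step
        walk = np.cumsum(steps, axis=0)
        es = np.maximum(walk.max(axis=0), 0.0) + np.minimum(walk.min(axis=0), 0.0)
        out[:, j] = np.nan_to_num(es)

    scores = pd.DataFrame(out, index=pd.Index(set_names, name="set"),
                          columns=expr.columns)
    return SampleSetScore(scores=scores, kernel=kernel)


def _running_es(weights: np.ndarray, hit: np.ndarray, miss_step: float) -> float:
    """Signed maximum deviation of the weighted running sum for one set."""
    hits_w = np.where(hit, weights, 0.0)
    denom = hits_w.sum()
    if denom == 0:  # all hit scores exactly zero: fall back to equal steps
        hits_w = hit.astype(float)
        denom = hits_w.sum()
    walk = np.cumsum(hits_w / denom - (~hit) * miss_step)
    lo, hi = walk.min(), walk.max()
    return float(hi if hi > -lo else lo)


def _null_es(weights: np.ndarray, m: int, nperm: int, rng: np.random.Generator) -> np.ndarray:
    """Null ES from random same-size gene sets, vectorized over permutations."""
    n = weights.size
    # sample nperm index sets of size m without replacement
    hit = np.zeros((nperm, n), dtype=bool)
    for i in range(nperm):
        hit[i, rng.choice(n, size=m, replace=False)] = True
    hits_w = hit * weights
    denom = hits_w.sum(axis=1)
    denom = np.where(denom == 0, m, denom)  # degenerate all-zero draws
    steps = hits_w / denom[:, None] - (~hit) / (n - m)
    walk = np.cumsum(steps, axis=1)
    hi = walk.max(axis=1)
    lo = walk.min(axis=1)
    return np.where(hi > -lo, hi, lo)


def gsea_preranked(
    ranking: pd.Series,
    sets: GeneSetCollection,
    weight: float = 1.0,
    nperm: int = 1000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked GSEA over one gene-set collection.

    Returns one row per retained set with columns ``set``, ``collection``,
    ``es``, ``nes``, ``pvalue``, ``padj`` (BH within this collection) and
    ``set_size``.  Sets whose intersection with the ranking universe falls
    outside [min_size, max_size] are dropped.
    """
    if ranking.isna().any():
        raise DataError("ranking contains missing values")
    values = ranking.to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise DataError("degenerate ranking: all scores tied")

    rng = np.random.default_rng(seed)
    n = values.size
    shuffle = rng.permutation(n)  # randomized, then stable: unbiased tie-break
    order = shuffle[np.argsort(-values[shuffle], kind="stable")]
    sorted_genes = ranking.index.to_numpy()[order]
    gene_rank = {g: i for i, g in enumerate(sorted_genes)}
    weights = np.abs(values[order]) ** weight

    retained: list[tuple[str, np.ndarray]] = []
    for name, members in sets.sets.items():
        pos = np.array(sorted([gene_rank[g] for g in members if g in gene_rank]), dtype=int)
        if pos.size < min_size or pos.size > max_size or pos.size >= n:
            continue
        retained.append((name, pos))
    if not retained:
        return pd.DataFrame(
            columns=["set", "collection", "es", "nes", "pvalue", "padj", "set_size"]
        )

    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name, pos in retained:
        m = pos.size
        hit = np.zeros(n, dtype=bool)
        hit[pos] = True
        es = _running_es(weights, hit, 1.0 / (n - m))
        if m not in null_cache:
            null_cache[m] = _null_es(weights, m, nperm, rng)
        null = null_cache[m]
        pvalue = (1.0 + np.count_nonzero(np.abs(null) >= abs(es))) / (nperm + 1.0)
        same_sign = null[null > 0] if es > 0 else null[null < 0]
        if es == 0 or same_sign.size == 0:
            nes = 0.0
        else:
            nes = es / float(np.mean(np.abs(same_sign)))
        rows.append({"set": name, "collection": sets.collection_id, "es": es,
                     "nes": nes, "pvalue": pvalue, "set_size": int(m)})

    result = pd.DataFrame(rows)
    result["padj"] = bh_adjust(result["pvalue"].to_numpy())
    return result[["set", "collection", "es", "nes", "pvalue", "padj", "set_size"]]


def score_signature_groups(
    scores: SampleSetScore | pd.DataFrame,
    groups,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-group comparison of per-set single-sample scores.

    ``groups`` maps sample name to a group label (exactly two labels).
    Returns per-set difference of means (second minus first label in sorted
    order) and a two-sided t-test p-value (pooled variance by default,
    Welch optional).
    """
    df = scores.scores if isinstance(scores, SampleSetScore) else scores
    labels = pd.Series({s: groups[s] for s in df.columns})
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ParameterError(f"need exactly 2 groups, got {uniq}")
    a_cols = labels.index[labels == uniq[0]]
    b_cols = labels.index[labels == uniq[1]]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ParameterError("each group needs >= 2 samples")

    A = df[a_cols].to_numpy(float)
    B = df[b_cols].to_numpy(float)
    t, p = stats.ttest_ind(B, A, axis=1, equal_var=not welch)
    return pd.DataFrame(
        {"set": df.index, "group_a": uniq[0], "group_b": uniq[1],
         "difference": B.mean(axis=1) - A.mean(axis=1), "t": t, "pvalue": p}
    ).set_index("set")
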
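"""Synthetic data with planted ground truth for every pipeline input.

Each generator is a pure function of its parameters and a seed: multi-study
differential-expression tables under a hierarchical random-effects model,
expression matrices with planted gene-set activity, regulon-driven gene
signatures, age/sex-structured marker-positive cell tallies, and coupled
transcript/protein matrices.  The accompanying :class:`SynthTruth` records
what was planted so downstream recovery can be scored blindly.

The default DE universe is 2,000 genes over 3 studies with 5% shared-signal
genes: large enough for stable false-discovery estimates, small enough for
seconds-scale runs.  A dedicated opposed-effect class (sign flips across
studies) exercises the leave-one-out robustness filter, and a study-specific
class exercises the cross-study consensus requirements.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .io import DETable, GeneSetCollection, RegulonTable
from .scoring import bh_adjust

MEMBERSHIP_CLASSES = ("shared", "opposed", "study_specific", "null")


@dataclass
class SynthTruth:
    """Planted ground truth accompanying one synthetic dataset."""

    seed: int
    gene_effects: pd.DataFrame | None = None  # gene, class, mu, tau
    set_activity: dict[str, float] = field(default_factory=dict)
    tf_activity: dict[str, float] = field(default_factory=dict)
    prevalence: pd.DataFrame | None = None
    rho: float | None = None
    extra: dict = field(default_factory=dict)

    def genes_of_class(self, cls: str) -> list[str]:
        if self.gene_effects is None:
            return []
        df = self.gene_effects
        return df.loc[df["class"] == cls, "gene"].tolist()

    def to_json(self, path: str | Path) -> None:
        payload: dict = {"seed": self.seed, "rho": self.rho,
                         "set_activity": self.set_activity,
                         "tf_activity": self.tf_activity,
                         "extra": self.extra}
        if self.gene_effects is not None:
            payload["gene_effects"] = self.gene_effects.to_dict(orient="list")
        if self.prevalence is not None:
            payload["prevalence"] = self.prevalence.to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
            fh.write("\n")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def simulate_de_studies(
    n_genes: int = 2000,
    n_studies: int = 3,
    frac_shared: float = 0.05,
    frac_opposed: float = 0.02,
    frac_specific: float = 0.03,
    mu: float = 1.0,
    tau: float = 0.2,
    se_range: tuple[float, float] = (0.1, 0.3),
    seed: int = 0,
) -> tuple[list[DETable], SynthTruth]:
    """Simulate per-study DE tables under a random-effects model.

    For a signal gene g the study-level true effect is
    theta_gi ~ Normal(mu_g, tau^2); the observed log2 fold change is
    y_gi ~ Normal(theta_gi, se_gi^2) with heteroscedastic standard errors
    drawn uniformly from ``se_range``.  Null genes have mu_g = 0.  Gene
    classes: ``shared`` (same mu_g in every study, sign drawn once),
    ``opposed`` (|mu_g| identical, sign flips between studies),
    ``study_specific`` (signal in a single random study), ``null``.
    Two-sided Wald p-values (z = y/se) and per-study BH adjustment fill the
    ``pvalue``/``padj`` columns.
    """
    if n_studies < 2:
        raise ParameterError("n_studies must be >= 2")
    for name, frac in (("frac_shared", frac_shared), ("frac_opposed", frac_opposed),
                       ("frac_specific", frac_specific)):
        if not 0.0 <= frac <= 1.0:
            raise ParameterError(f"{name}={frac} outside [0, 1]")
    if frac_shared + frac_opposed + frac_specific > 1.0:
        raise ParameterError("signal fractions sum to more than 1")
    if se_range[0] <= 0 or se_range[1] < se_range[0]:
        raise ParameterError(f"invalid se_range {se_range}")

    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    n_shared = int(round(frac_shared * n_genes))
    n_opposed = int(round(frac_opposed * n_genes))
    n_specific = int(round(frac_specific * n_genes))

    classes = np.array(["null"] * n_genes, dtype=object)
    order = rng.permutation(n_genes)
    classes[order[:n_shared]] = "shared"
    classes[order[n_shared:n_shared + n_opposed]] = "opposed"
    classes[order[n_shared + n_opposed:n_shared + n_opposed + n_specific]] = "study_specific"

    signal = classes != "null"
    mu_g = np.zeros(n_genes)
    mu_g[signal] = mu * rng.choice([-1.0, 1.0], size=signal.sum())
    tau_g = np.where(signal, tau, 0.0)
    specific_study = rng.integers(0, n_studies, size=n_genes)

    tables: list[DETable] = []
    for s in range(n_studies):
        se = rng.uniform(se_range[0], se_range[1], size=n_genes)
        mu_study = mu_g.copy()
        opp = classes == "opposed"
        # alternate the sign of opposed genes across studies
        mu_study[opp] = mu_g[opp] * np.where(s % 2 == 0, 1.0, -1.0)
        spec = classes == "study_specific"
        mu_study[spec & (specific_study != s)] = 0.0
        theta = mu_study + np.where(tau_g > 0, rng.normal(0.0, 1.0, n_genes) * tau_g, 0.0)
        y = theta + rng.normal(0.0, 1.0, n_genes) * se
        pvalue = 2.0 * stats.norm.sf(np.abs(y / se))
        df = pd.DataFrame(
            {"log2fc": y, "se": se, "pvalue": pvalue, "padj": bh_adjust(pvalue)},
            index=pd.Index(genes, name="gene"),
        )
        tables.append(DETable(study_id=f"study{s + 1}", data=df))

    truth = SynthTruth(
        seed=seed,
        gene_effects=pd.DataFrame(
            {"gene": genes, "class": classes, "mu": mu_g, "tau": tau_g,
             "specific_study": specific_study}
        ),
        extra={"n_studies": n_studies, "mu": mu, "tau": tau, "se_range": list(se_range)},
    )
    return tables, truth


def simulate_expression(
    n_genes: int = 500,
    n_samples: int = 12,
    sets: GeneSetCollection | None = None,
    active_sets: Mapping[str, float] | None = None,
    groups: Sequence[str] | None = None,
    shifted_group: str = "B",
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SynthTruth]:
    """Simulate a log-scale expression matrix with planted gene-set activity.

    Baseline expression is Gaussian per gene (gene-specific mean, shared
    ``noise_sd``).  For each entry of ``active_sets`` (set name -> shift, in
    log2 units) the member genes are shifted by that amount in the samples of
    ``shifted_group``.  ``groups`` assigns one label per sample; default is
    an A/B split in half.
    """
    if sets is None:
        sets = GeneSetCollection("synthetic", {})
    active_sets = dict(active_sets or {})
    unknown = set(active_sets) - set(sets.sets)
    if unknown:
        raise ParameterError(f"active sets not in collection: {sorted(unknown)}")
    if groups is None:
        groups = ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)
    if len(groups) != n_samples:
        raise ParameterError("groups must have one label per sample")

    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    base = rng.normal(6.0, 2.0, size=n_genes)
    X = base[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    group_arr = np.asarray(groups, dtype=object)
    for set_name, shift in active_sets.items():
        idx = [gene_pos[g] for g in sets.sets[set_name] if g in gene_pos]
        X[np.ix_(idx, np.flatnonzero(group_arr == shifted_group))] += shift

    samples = [f"s{j + 1:02d}_{g}" for j, g in enumerate(groups)]
    expr = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)
    truth = SynthTruth(seed=seed, set_activity=dict(active_sets),
                       extra={"groups": list(groups), "shifted_group": shifted_group,
                              "noise_sd": noise_sd})
    return expr, truth


def make_random_sets(
    n_sets: int,
    set_size: int,
    genes: Sequence[str],
    collection_id: str = "synthetic",
    seed: int = 0,
) -> GeneSetCollection:
    """Random disjoint-draw gene sets over a given universe (with replacement
    across sets, without within a set)."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    sets = {
        f"{collection_id}_set{i + 1:03d}": list(rng.choice(genes, size=set_size, replace=False))
        for i in range(n_sets)
    }
    return GeneSetCollection(collection_id, sets)


def simulate_cell_tallies(
    design: Sequence[tuple[str, str, float, int]],
    intercept: float = -2.2,
    age_slope: float = 0.05,
    sex_effect: float = 0.0,
    interaction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SynthTruth]:
    """Simulate marker-positive cell tallies per (tissue, sex, age) stratum.

    Prevalence follows a logistic model in age with a sex main effect and a
    sex-by-age interaction (``female`` coded 1):

        logit p = intercept + age_slope*age + sex_effect*F + interaction*F*age

    ``design`` rows are (tissue, sex, age_months, n_cells); positives are
    binomial draws.  Defaults give ~10% prevalence at 3 months rising with
    age, the order of magnitude seen for marker-positive fractions in aging
    mouse tissue atlases.
    """
    rng = np.random.default_rng(seed)
    rows = []
    prev_rows = []
    for tissue, sex, age, n_cells in design:
        if n_cells < 1:
            raise ParameterError(f"n_cells must be >= 1 (stratum {tissue}/{sex}/{age})")
        female = 1.0 if str(sex).lower() in ("f", "female") else 0.0
        eta = intercept + age_slope * age + sex_effect * female + interaction * female * age
        p = 1.0 / (1.0 + np.exp(-eta))
        if not 0.0 < p < 1.0:
            raise ParameterError(f"prevalence {p} outside (0,1) for stratum {tissue}/{sex}/{age}")
        n_pos = int(rng.binomial(n_cells, p))
        rows.append({"tissue": tissue, "sex": sex, "age_months": age,
                     "n_total": int(n_cells), "n_pos": n_pos})
        prev_rows.append({"tissue": tissue, "sex": sex, "age_months": age, "prevalence": p})
    tallies = pd.DataFrame(rows)
    truth = SynthTruth(seed=seed, prevalence=pd.DataFrame(prev_rows),
                       extra={"intercept": intercept, "age_slope": age_slope,
                              "sex_effect": sex_effect, "interaction": interaction})
    return tallies, truth


def make_random_regulons(
    n_tfs: int,
    targets_per_tf: int,
    genes: Sequence[str],
    frac_repressed: float = 0.3,
    seed: int = 0,
) -> RegulonTable:
    """Random regulons: each TF gets targets drawn without replacement and
    signed mode-of-regulation weights (+1 activating, -1 repressing)."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    records = []
    for t in range(n_tfs):
        targets = rng.choice(genes, size=targets_per_tf, replace=False)
        mor = rng.choice([1.0, -1.0], size=targets_per_tf,
                         p=[1 - frac_repressed, frac_repressed])
        conf = rng.choice(["A", "B", "C"], size=targets_per_tf)
        for g, m, c in zip(targets, mor, conf):
            records.append({"tf": f"TF{t + 1:02d}", "target": g, "mor": float(m),
                            "confidence": str(c)})
    df = pd.DataFrame(records).drop_duplicates(subset=["tf", "target"])
    return RegulonTable(df.reset_index(drop=True))


def simulate_tf_signature(
    regulons: RegulonTable,
    active: Mapping[str, float],
    n_genes: int = 1000,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.Series, SynthTruth]:
    """Simulate a per-gene signature driven by planted TF activities.

    signature_g = sum_tf activity_tf * mor(tf, g) over the TF's targets,
    plus Gaussian noise.  Genes are the union of ``g0001..`` filler ids and
    all regulon targets, so every planted TF keeps its full regulon.
    """
    tf_universe = set(regulons.tfs)
    missing = set(active) - tf_universe
    if missing:
        raise ParameterError(f"active TFs not in regulon table: {sorted(missing)}")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    genes = list(dict.fromkeys(_gene_ids(n_genes) + list(regulons.data["target"])))
    sig = pd.Series(0.0, index=pd.Index(genes, name="gene"))
    for tf, activity in active.items():
        sub = regulons.data[regulons.data["tf"] == tf]
        sig.loc[sub["target"].to_numpy()] += activity * sub["mor"].to_numpy()
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=len(sig))
    truth = SynthTruth(seed=seed, tf_activity=dict(active),
                       extra={"noise_sd": noise_sd})
    return sig, truth


def simulate_omics_pair(
    n_genes: int = 1000,
    n_samples: int = 11,
    rho: float = 0.5,
    offset_sd: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Simulate coupled log-scale transcript and protein matrices.

    Per gene, sample-wise (rna, protein) deviations are bivariate Gaussian
    with correlation ``rho``; a per-gene abundance offset (SD ``offset_sd``)
    is shared between layers, so the cross-gene abundance correlation is
    governed by the offset-to-noise variance ratio while the within-gene
    sample-wise coupling is governed by ``rho``.
    """
    if not -1.0 <= rho <= 1.0:
        raise ParameterError(f"rho={rho} outside [-1, 1]")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    samples = [f"m{j + 1:02d}" for j in range(n_samples)]
    offsets = rng.normal(0.0, offset_sd, size=n_genes)
    z1 = rng.normal(size=(n_genes, n_samples))
    z2 = rng.normal(size=(n_genes, n_samples))
    e_rna = z1
    e_prot = rho * z1 + np.sqrt(max(0.0, 1.0 - rho**2)) * z2
    rna = offsets[:, None] + noise_sd * e_rna
    prot = offsets[:, None] + noise_sd * e_prot
    idx = pd.Index(genes, name="gene")
    truth = SynthTruth(seed=seed, rho=rho,
                       extra={"offset_sd": offset_sd, "noise_sd": noise_sd})
    return (pd.DataFrame(rna, index=idx, columns=samples),
            pd.DataFrame(prot, index=idx, columns=samples), truth)
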
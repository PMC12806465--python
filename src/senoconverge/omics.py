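"""Transcript-protein concordance statistics.

Matched transcriptomic and proteomic matrices are compared three ways:
gene-wise Spearman correlations across samples (with a summary of the
fraction positive, fraction significant and median coefficient), per-sample
Pearson correlations across genes, and a global cross-gene Spearman of
sample-averaged abundances.

Gene-wise Spearman p-values use the t approximation, except for very small
sample counts (n <= 9, no ties) where the exact permutation distribution of
the rank statistic is used; matched-proteome cohorts are often on the
order of a dozen animals per study, where both paths are relevant.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParameterError

EXACT_P_MAX_N = 9


@dataclass
class OmicsPair:
    """Matched genes-by-samples RNA and protein matrices.

    The constructor aligns both layers on their shared genes and samples;
    correlations only ever see matched entries.
    """

    rna: pd.DataFrame
    protein: pd.DataFrame

    def __post_init__(self) -> None:
        genes = self.rna.index.intersection(self.protein.index)
        samples = self.rna.columns.intersection(self.protein.columns)
        if len(genes) == 0:
            raise DataError("no genes shared between the RNA and protein layers")
        if len(samples) == 0:
            raise DataError("no samples shared between the RNA and protein layers")
        self.rna = self.rna.loc[genes, samples]
        self.protein = self.protein.loc[genes, samples]

    @property
    def n_samples(self) -> int:
        return self.rna.shape[1]


@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Sorted exact null distribution of Spearman rho for n untied samples."""
    base = np.arange(1, n + 1, dtype=float)
    denom = n * (n * n - 1) / 6.0
    rhos = [1.0 - ((base - np.array(perm, dtype=float)) ** 2).sum() / denom
            for perm in itertools.permutations(range(1, n + 1))]
    return np.sort(np.asarray(rhos))


def _spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = x.size
    has_ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if n <= EXACT_P_MAX_N and not has_ties:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        denom = n * (n * n - 1) / 6.0
        rho = 1.0 - ((rx - ry) ** 2).sum() / denom
        null = _exact_spearman_null(n)
        # two-sided: fraction of the exact null at least as extreme
        count = null.size - np.searchsorted(null, abs(rho) - 1e-12, side="left")
        count += np.searchsorted(null, -abs(rho) + 1e-12, side="right")
        return float(rho), float(min(1.0, count / null.size))
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def genewise_correlation(pair: OmicsPair, min_samples: int = 3,
                         alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Per-gene Spearman correlation between the RNA and protein layers.

    Genes with fewer than ``min_samples`` matched finite values, or with all
    values tied in one layer, are excluded and counted in the summary.
    Returns the per-gene table (rho, pvalue, n) and a summary dict with
    ``fraction_positive``, ``fraction_significant``, ``median_rho``,
    ``n_genes`` and ``n_excluded``.
    """
    R = pair.rna.to_numpy(float)
    P = pair.protein.to_numpy(float)
    rows = []
    excluded = 0
    for i, gene in enumerate(pair.rna.index):
        ok = np.isfinite(R[i]) & np.isfinite(P[i])
        x, y = R[i, ok], P[i, ok]
        if ok.sum() < min_samples or np.all(x == x[0]) or np.all(y == y[0]):
            excluded += 1
            continue
        rho, p = _spearman_with_p(x, y)
        rows.append({"gene": gene, "rho": rho, "pvalue": p, "n": int(ok.sum())})
    if not rows:
        raise DataError("no gene has enough matched samples")
    table = pd.DataFrame(rows).set_index("gene")
    summary = {
        "fraction_positive": float((table["rho"] > 0).mean()),
        "fraction_significant": float((table["pvalue"] < alpha).mean()),
        "median_rho": float(table["rho"].median()),
        "n_genes": int(len(table)),
        "n_excluded": int(excluded),
    }
    return table, summary


def samplewise_correlation(pair: OmicsPair, method: str = "pearson") -> pd.Series:
    """One correlation per matched sample, computed across genes."""
    if method not in ("pearson", "spearman"):
        raise ParameterError(f"unknown method '{method}'")
    if pair.rna.shape[0] < 3:
        raise ParameterError("need >= 3 matched genes")
    out = {}
    for sample in pair.rna.columns:
        x = pair.rna[sample].to_numpy(float)
        y = pair.protein[sample].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if ok.sum() < 3 or np.all(x == x[0]) or np.all(y == y[0]):
            warnings.warn(f"sample {sample}: constant or insufficient profile; "
                          "correlation set to missing", stacklevel=2)
            out[sample] = np.nan
            continue
        if method == "pearson":
            out[sample] = float(stats.pearsonr(x, y).statistic)
        else:
            out[sample] = float(stats.spearmanr(x, y).statistic)
    return pd.Series(out, name=f"{method}_r")


def global_abundance_correlation(pair: OmicsPair, logged: bool = True) -> tuple[float, float]:
    """Cross-gene Spearman of sample-averaged abundances in the two layers.

    With ``logged=False`` the inputs are linear-scale abundances and are
    log10-transformed after averaging; all values must then be strictly
    positive.  Pre-logged inputs (the default) are averaged as-is.
    """
    rna_mean = pair.rna.mean(axis=1)
    prot_mean = pair.protein.mean(axis=1)
    if not logged:
        for name, v in (("rna", rna_mean), ("protein", prot_mean)):
            bad = v[v <= 0]
            if len(bad):
                raise DataError(
                    f"nonpositive {name} abundance for gene '{bad.index[0]}'; "
                    "cannot log10-transform"
                )
        rna_mean = np.log10(rna_mean)
        prot_mean = np.log10(prot_mean)
    res = stats.spearmanr(rna_mean, prot_mean)
    return float(res.statistic), float(res.pvalue)
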
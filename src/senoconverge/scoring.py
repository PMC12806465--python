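"""Signed differential-expression scoring across conditions.

The per-gene, per-condition score combines significance and direction:

    S = -log10(padj) * sgn(log2FC)

Genes shared by every input table form the score matrix; an informative-gene
filter keeps rows whose absolute score exceeds a cut in at least one
condition (strictly), mirroring the convention of ranking conditions by
their strongest transcriptional responses before similarity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, ParameterError

PADJ_FLOOR = 1e-300  # caps |S| near 300; adjusted p of exactly 0 would diverge


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1, restore input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ParameterError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise DataError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_score(padj, log2fc) -> np.ndarray | float:
    """-log10(adjusted p) times the sign of the fold change (sgn(0) = 0).

    Adjusted p-values of exactly 0 (underflow in upstream DE tables) are
    clamped to ``PADJ_FLOOR`` with a warning.
    """
    padj_arr = np.asarray(padj, dtype=float)
    lfc_arr = np.asarray(log2fc, dtype=float)
    if np.any(padj_arr < 0) or np.any(padj_arr > 1):
        raise DataError("padj outside [0, 1]")
    if np.any(padj_arr == 0):
        warnings.warn("padj of 0 clamped to floor 1e-300", stacklevel=2)
    clamped = np.maximum(padj_arr, PADJ_FLOOR)
    score = -np.log10(clamped) * np.sign(lfc_arr)
    # -log10(1) = 0 multiplied by sign -> force +0.0 to avoid -0.0 artifacts
    score = score + 0.0
    if np.isscalar(padj) and np.isscalar(log2fc):
        return float(score)
    return score


@dataclass
class SignedScoreMatrix:
    """Genes-by-conditions matrix of signed DE scores.

    ``scores`` rows are exactly the genes shared (with finite padj) across
    all contributing tables; ``provenance`` maps condition label to the
    source study id.
    """

    scores: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.scores.index

    @property
    def conditions(self) -> list[str]:
        return list(self.scores.columns)


def build_score_matrix(tables, recompute_padj: bool = False) -> SignedScoreMatrix:
    """Assemble the signed score matrix over the gene intersection.

    Tables lacking a ``padj`` column get it recomputed by BH adjustment of
    their raw p-values (as do all tables when ``recompute_padj`` is set).
    Genes with missing padj in any condition are dropped (intersection
    semantics), not imputed.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ParameterError("need >= 2 conditions to build a score matrix")

    columns = {}
    provenance = {}
    common: pd.Index | None = None
    for table in tables:
        df = table.data
        if recompute_padj or "padj" not in df.columns:
            padj = pd.Series(bh_adjust(df["pvalue"].to_numpy()), index=df.index)
        else:
            padj = df["padj"]
        keep = padj.notna() & df["log2fc"].notna()
        col = pd.Series(
            signed_score(padj[keep].to_numpy(), df.loc[keep, "log2fc"].to_numpy()),
            index=df.index[keep],
        )
        condition = table.study_id
        columns[condition] = col
        provenance[condition] = table.study_id
        common = col.index if common is None else common.intersection(col.index)

    if common is None or len(common) == 0:
        raise DataError("empty gene intersection across tables")
    scores = pd.DataFrame({c: columns[c].loc[common] for c in columns})
    scores.index.name = "gene"
    return SignedScoreMatrix(scores=scores, provenance=provenance)


def filter_informative(matrix: SignedScoreMatrix, cut: float = 2.0) -> SignedScoreMatrix:
    """Keep genes with |score| strictly greater than ``cut`` in >= 1 condition."""
    if cut < 0:
        raise ParameterError("cut must be >= 0")
    mask = (matrix.scores.abs() > cut).any(axis=1)
    return SignedScoreMatrix(scores=matrix.scores.loc[mask],
                             provenance=dict(matrix.provenance))
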
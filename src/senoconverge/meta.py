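"""Gene-wise random-effects meta-analysis with leave-one-out robustness.

Per gene, study-level log2 fold changes y_i with standard errors se_i are
pooled under the random-effects model y_i ~ Normal(mu, se_i^2 + tau^2).
The between-study variance tau^2 is the Paule-Mandel estimate: the solution
of the generalized Cochran equation

    Q(tau^2) = sum_i w_i(tau^2) (y_i - mu(tau^2))^2 = k - 1,
    w_i = 1 / (se_i^2 + tau^2),  mu = sum w y / sum w,

with tau^2 = 0 whenever Q(0) <= k - 1 (no continuity correction at the
boundary).  Inference on the pooled effect is Wald-normal.  Heterogeneity is
summarized by tau^2, the estimator-based I^2 = 100 tau^2/(tau^2 + s^2) with
s^2 = (k-1) sum w0 / ((sum w0)^2 - sum w0^2), w0 = 1/se^2, and Q = Q(0).

The robust signature applies two nested criteria with strict inequalities:
meta-analysis p < 0.01, and a leave-one-out sensitivity pass requiring the
maximum p over all single-study exclusions (tau^2 re-estimated each time)
below 0.1.  Genes whose signal rests on a single study, or whose effect
sign opposes between studies, fail the second criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParameterError
from .scoring import bh_adjust

_TAU2_TOL = 1e-10


@dataclass
class MetaGeneResult:
    """Pooled-effect results for one gene."""

    gene_id: str
    k: int
    mu_hat: float
    se_mu: float
    z: float
    pvalue: float
    tau2: float
    I2: float
    Q: float
    loo_pvalues: np.ndarray | None = None
    robust: bool | None = None


def _check_inputs(effects: np.ndarray, ses: np.ndarray) -> None:
    if effects.shape != ses.shape or effects.ndim != 1:
        raise ParameterError("effects and ses must be 1-d arrays of equal length")
    if effects.size < 2:
        raise ParameterError("need k >= 2 studies")
    if not (np.all(np.isfinite(effects)) and np.all(np.isfinite(ses))):
        raise DataError("non-finite effect or SE")
    if np.any(ses <= 0):
        raise DataError("standard errors must be positive")


def _q_gen(tau2: np.ndarray, Y: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Generalized Cochran statistic, rows = genes; tau2 is per-row."""
    w = 1.0 / (V + tau2[:, None])
    mu = (w * Y).sum(axis=1) / w.sum(axis=1)
    return (w * (Y - mu[:, None]) ** 2).sum(axis=1)


def _pm_tau2_rows(Y: np.ndarray, V: np.ndarray, tol: float = _TAU2_TOL) -> np.ndarray:
    """Vectorized Paule-Mandel tau^2 for many genes at once.

    Q(tau^2) is monotone decreasing, so the root is bracketed by doubling
    the upper bound until Q < k - 1, then bisected to |delta tau^2| < tol.
    """
    n_genes, k = Y.shape
    tau2 = np.zeros(n_genes)
    q0 = _q_gen(tau2, Y, V)
    need = q0 > (k - 1)
    if not need.any():
        return tau2

    Yn, Vn = Y[need], V[need]
    lo = np.zeros(Yn.shape[0])
    hi = np.ones(Yn.shape[0])
    for _ in range(200):
        open_above = _q_gen(hi, Yn, Vn) > (k - 1)
        if not open_above.any():
            break
        hi[open_above] *= 2.0
    while np.max(hi - lo) > tol:
        mid = 0.5 * (lo + hi)
        below_root = _q_gen(mid, Yn, Vn) > (k - 1)  # root lies above mid
        lo = np.where(below_root, mid, lo)
        hi = np.where(below_root, hi, mid)
    tau2[need] = 0.5 * (lo + hi)
    return tau2


def pm_tau2(effects, ses) -> float:
    """Paule-Mandel between-study variance for a single gene."""
    y = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    _check_inputs(y, se)
    return float(_pm_tau2_rows(y[None, :], se[None, :] ** 2)[0])


def _meta_rows(Y: np.ndarray, V: np.ndarray) -> dict[str, np.ndarray]:
    """Random-effects pooling for many genes; returns column arrays."""
    k = Y.shape[1]
    tau2 = _pm_tau2_rows(Y, V)
    w = 1.0 / (V + tau2[:, None])
    sw = w.sum(axis=1)
    mu = (w * Y).sum(axis=1) / sw
    se_mu = sw ** -0.5
    z = mu / se_mu
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    w0 = 1.0 / V
    sw0 = w0.sum(axis=1)
    s2 = (k - 1) * sw0 / (sw0 ** 2 - (w0 ** 2).sum(axis=1))
    I2 = 100.0 * tau2 / (tau2 + s2)
    Q = _q_gen(np.zeros(Y.shape[0]), Y, V)
    return {"mu_hat": mu, "se_mu": se_mu, "z": z, "pvalue": pvalue,
            "tau2": tau2, "I2": I2, "Q": Q}


def re_meta(effects, ses, gene_id: str = "?") -> MetaGeneResult:
    """Random-effects meta-analysis of one gene (Wald-normal inference)."""
    y = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    _check_inputs(y, se)
    cols = _meta_rows(y[None, :], se[None, :] ** 2)
    return MetaGeneResult(
        gene_id=gene_id, k=y.size,
        **{name: float(arr[0]) for name, arr in cols.items()},
    )


def loo_meta(effects, ses) -> np.ndarray:
    """Leave-one-out p-values: entry i excludes study i (tau^2 refit)."""
    y = np.asarray(effects, dtype=float)
    se = np.asarray(ses, dtype=float)
    _check_inputs(y, se)
    k = y.size
    if k < 3:
        raise ParameterError("LOO requires >= 3 studies")
    out = np.empty(k)
    for i in range(k):
        keep = np.arange(k) != i
        out[i] = re_meta(y[keep], se[keep]).pvalue
    return out


@dataclass
class RobustSignatureResult:
    """Full meta table plus the nested significant and robust gene lists."""

    meta: pd.DataFrame        # all genes, one row each, sorted by p
    significant: pd.DataFrame
    robust: pd.DataFrame
    per_study: pd.DataFrame   # long format: gene, study, log2fc, se (heatmap export)


def robust_signature(
    tables,
    p_meta: float = 0.01,
    p_loo_max: float = 0.1,
    adjust: str = "none",
) -> RobustSignatureResult:
    """Meta-analyze DE tables and extract the robust gene signature.

    The gene universe is the intersection of all tables (genes with finite
    effect and SE everywhere; partial pooling is not attempted).  A gene is
    *significant* when its meta p-value is strictly below ``p_meta`` (on the
    raw scale by default; ``adjust='bh'`` applies BH first) and *robust*
    when additionally the maximum leave-one-out p-value is strictly below
    ``p_loo_max``.
    """
    if adjust not in ("none", "bh"):
        raise ParameterError("adjust must be 'none' or 'bh'")
    tables = list(tables)
    if len(tables) < 2:
        raise ParameterError("need >= 2 studies")

    common: pd.Index | None = None
    for t in tables:
        ok = t.data["log2fc"].notna() & t.data["se"].notna()
        idx = t.data.index[ok]
        common = idx if common is None else common.intersection(idx)
    if common is None or len(common) == 0:
        raise DataError("empty gene intersection across studies")
    genes = common
    k = len(tables)

    Y = np.column_stack([t.data.loc[genes, "log2fc"].to_numpy(float) for t in tables])
    SE = np.column_stack([t.data.loc[genes, "se"].to_numpy(float) for t in tables])
    if np.any(SE <= 0):
        raise DataError("standard errors must be positive")
    V = SE ** 2

    cols = _meta_rows(Y, V)
    meta = pd.DataFrame({"gene": genes, "k": k, **cols})

    if k >= 3:
        loo = np.empty((len(genes), k))
        for i in range(k):
            keep = np.arange(k) != i
            loo[:, i] = _meta_rows(Y[:, keep], V[:, keep])["pvalue"]
        meta["loo_max_p"] = loo.max(axis=1)
        for i, t in enumerate(tables):
            meta[f"loo_p_excl_{t.study_id}"] = loo[:, i]
    else:
        meta["loo_max_p"] = np.nan

    crit_p = bh_adjust(meta["pvalue"].to_numpy()) if adjust == "bh" else meta["pvalue"].to_numpy()
    meta["significant"] = crit_p < p_meta
    meta["robust"] = meta["significant"] & (meta["loo_max_p"] < p_loo_max)
    meta = meta.sort_values("pvalue", kind="stable").reset_index(drop=True)

    per_study = pd.concat(
        [pd.DataFrame({"gene": genes, "study": t.study_id,
                       "log2fc": t.data.loc[genes, "log2fc"].to_numpy(float),
                       "se": t.data.loc[genes, "se"].to_numpy(float)})
         for t in tables],
        ignore_index=True,
    )
    return RobustSignatureResult(
        meta=meta,
        significant=meta[meta["significant"]].reset_index(drop=True),
        robust=meta[meta["robust"]].reset_index(drop=True),
        per_study=per_study,
    )
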
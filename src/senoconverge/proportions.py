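"""Marker-positive cell-proportion analysis.

Cells with marker expression above a threshold (default: any nonzero value)
are classified positive; tallies aggregate positives per tissue/sex/age
stratum by pooling cells.  Group differences use Pearson's chi-squared test
on the 2x2 positive/negative table, with Yates' continuity correction by
default, and effect sizes are odds ratios with Wald log-odds confidence
intervals (Haldane-Anscombe 0.5 correction when a cell count is zero, never
applied inside the chi-squared test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParameterError


@dataclass
class CellTally:
    """Marker-positive counts for one stratum."""

    tissue: str
    sex: str
    age_months: float
    n_total: int
    n_pos: int

    def __post_init__(self) -> None:
        if self.n_total < 0 or self.n_pos < 0:
            raise DataError("counts must be non-negative")
        if self.n_pos > self.n_total:
            raise DataError(f"n_pos {self.n_pos} exceeds n_total {self.n_total}")

    @property
    def n_neg(self) -> int:
        return self.n_total - self.n_pos

    @property
    def proportion(self) -> float:
        return self.n_pos / self.n_total if self.n_total else float("nan")


def classify_positive(
    expr,
    tissue: str = "pooled",
    sex: str = "pooled",
    age_months: float = float("nan"),
    threshold: float = 0.0,
) -> tuple[np.ndarray, CellTally]:
    """Classify cells as marker-positive (value strictly above threshold).

    Returns the per-cell boolean vector and the stratum tally.
    """
    values = np.asarray(expr, dtype=float)
    if np.any(values < 0):
        raise DataError("marker expression values must be >= 0")
    positive = values > threshold
    tally = CellTally(tissue=tissue, sex=sex, age_months=age_months,
                      n_total=int(values.size), n_pos=int(positive.sum()))
    return positive, tally


def aggregate(tallies, by=("sex", "age_months")) -> list[CellTally]:
    """Sum counts within each combination of the requested stratum keys.

    Pools cells across the collapsed strata (e.g. tissues); keys absent from
    ``by`` are reported as ``pooled``.
    """
    tallies = list(tallies)
    if not tallies:
        raise ParameterError("no tallies to aggregate")
    valid = {"tissue", "sex", "age_months"}
    bad = set(by) - valid
    if bad:
        raise KeyError(f"unknown stratum keys: {sorted(bad)}")

    buckets: dict[tuple, list[CellTally]] = {}
    for t in tallies:
        key = tuple(getattr(t, k) for k in by)
        buckets.setdefault(key, []).append(t)
    out = []
    for key, group in buckets.items():
        fields = dict(zip(by, key))
        out.append(CellTally(
            tissue=fields.get("tissue", "pooled"),
            sex=fields.get("sex", "pooled"),
            age_months=fields.get("age_months", float("nan")),
            n_total=sum(t.n_total for t in group),
            n_pos=sum(t.n_pos for t in group),
        ))
    return out


def _table(a: CellTally, b: CellTally) -> np.ndarray:
    return np.array([[a.n_pos, a.n_neg], [b.n_pos, b.n_neg]], dtype=float)


def proportion_test(a: CellTally, b: CellTally, yates: bool = True) -> tuple[float, float]:
    """Two-sided Pearson chi-squared test of equal positive proportions.

    With Yates' continuity correction (default),
    chi2 = N (|ad - bc| - N/2)^2 / (r1 r2 c1 c2), clamped at 0 when
    |ad - bc| <= N/2; without it, the plain Pearson formula.
    """
    t = _table(a, b)
    r1, r2 = t.sum(axis=1)
    c1, c2 = t.sum(axis=0)
    if min(r1, r2, c1, c2) == 0:
        raise DataError("degenerate table: a margin is zero")
    n = t.sum()
    cross = abs(t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0])
    if yates:
        cross = max(cross - n / 2.0, 0.0)
    chi2 = n * cross ** 2 / (r1 * r2 * c1 * c2)
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def odds_fold_change(a: CellTally, b: CellTally, z: float = 1.959963984540054
                     ) -> dict[str, float | bool]:
    """Odds ratio (a vs b) with log-odds SE and Wald confidence interval.

    Any zero among the four cell counts triggers the Haldane-Anscombe 0.5
    correction (flagged in the result as ``corrected``).
    """
    counts = np.array([a.n_pos, a.n_neg, b.n_pos, b.n_neg], dtype=float)
    corrected = bool(np.any(counts == 0))
    if corrected:
        counts = counts + 0.5
    ap, an, bp, bn = counts
    log_or = np.log(ap * bn) - np.log(an * bp)
    se = float(np.sqrt((1.0 / counts).sum()))
    return {
        "odds_ratio": float(np.exp(log_or)),
        "log_or": float(log_or),
        "se_log_or": se,
        "ci_low": float(np.exp(log_or - z * se)),
        "ci_high": float(np.exp(log_or + z * se)),
        "corrected": corrected,
    }


def tallies_from_frame(df: pd.DataFrame) -> list[CellTally]:
    """Build tallies from a data frame with the standard tally columns."""
    required = {"tissue", "sex", "age_months", "n_total", "n_pos"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"tally table missing columns: {sorted(missing)}")
    return [CellTally(tissue=str(r.tissue), sex=str(r.sex),
                      age_months=float(r.age_months),
                      n_total=int(r.n_total), n_pos=int(r.n_pos))
            for r in df.itertuples()]
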
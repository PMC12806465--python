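"""Regulon-based transcription-factor activity and cross-study consensus.

Activity is inferred with a univariate linear model (ULM): for each TF a
predictor vector over the whole signature universe carries the signed
mode-of-regulation weight on the TF's targets and zero elsewhere; the
signature is regressed on it (OLS with intercept) and the slope
t-statistic is the activity, with a two-sided p from the t distribution
on G - 2 degrees of freedom.  Regulons are restricted to curation
confidence classes A-C by default.

A TF is a *consensus* hit when its activity is significant (p below the
cut) in every study and its sign agrees across all of them; consensus TFs
split into activated and repressed by that common sign.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, ParameterError
from .io import RegulonTable


def ulm_activity(
    signature: pd.Series,
    regulons: RegulonTable,
    min_targets: int = 5,
    confidence=("A", "B", "C"),
) -> pd.DataFrame:
    """Univariate-linear-model TF activities for one gene-level signature.

    ``signature`` maps gene id to a statistic (signed DE score, Wald t, ...).
    Returns one row per retained TF: ``activity`` (slope t-statistic),
    ``pvalue``, ``n_targets`` (targets present in the signature universe).
    TFs with fewer than ``min_targets`` surviving targets, or a zero-variance
    predictor, are dropped with a warning.
    """
    if signature.isna().any():
        raise DataError("signature contains missing values")
    reg = regulons.filter_confidence(confidence).data
    genes = signature.index
    gene_pos = {g: i for i, g in enumerate(genes)}
    y = signature.to_numpy(dtype=float)
    G = y.size
    if G < 3:
        raise ParameterError("signature universe too small")

    yc = y - y.mean()
    ss_y = float(yc @ yc)
    rows = []
    dropped = []
    for tf, sub in reg.groupby("tf", sort=True):
        idx = [gene_pos[t] for t in sub["target"] if t in gene_pos]
        if len(idx) < min_targets:
            dropped.append(tf)
            continue
        x = np.zeros(G)
        mor = sub["mor"].to_numpy(float)[[t in gene_pos for t in sub["target"]]]
        x[idx] = mor
        xc = x - x.mean()
        ss_x = float(xc @ xc)
        if ss_x == 0 or ss_y == 0:
            dropped.append(tf)
            continue
        r = float(xc @ yc) / np.sqrt(ss_x * ss_y)
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) == 1.0:
            t_stat = np.inf * np.sign(r)
            p = 0.0
        else:
            t_stat = r * np.sqrt((G - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t_stat), df=G - 2)
        rows.append({"tf": tf, "activity": float(t_stat), "pvalue": float(p),
                     "n_targets": len(idx)})
    if dropped:
        warnings.warn(f"dropped TFs (too few targets or degenerate predictor): "
                      f"{dropped[:10]}{'...' if len(dropped) > 10 else ''}",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["tf", "activity", "pvalue", "n_targets"])


def consensus_tfs(
    activities: dict[str, pd.DataFrame],
    p_tf: float = 0.05,
    require_sign: bool = True,
) -> dict:
    """Cross-study consensus TF classification.

    ``activities`` maps study id to a :func:`ulm_activity` result.  Returns
    a dict with ``activated`` / ``repressed`` TF lists, a ``consensus``
    table (per-study activities of consensus TFs), and ``venn``: the
    membership partition of per-study significant TFs keyed by the sorted
    combination of study ids.
    """
    studies = list(activities)
    if len(studies) < 2:
        raise ParameterError("need >= 2 studies for consensus")
    frames = {s: df.set_index("tf") for s, df in activities.items()}
    universes = [set(f.index) for f in frames.values()]
    common = set.intersection(*universes)
    if any(u - common for u in universes):
        warnings.warn("studies have unequal TF universes; consensus restricted "
                      "to the intersection", stacklevel=2)

    sig_sets = {s: set(f.index[f["pvalue"] < p_tf]) for s, f in frames.items()}

    # Venn partition over per-study significant TFs
    venn: dict[str, list[str]] = {}
    all_sig = set().union(*sig_sets.values())
    for r in range(1, len(studies) + 1):
        for combo in itertools.combinations(studies, r):
            inside = set(combo)
            region = [tf for tf in sorted(all_sig)
                      if {s for s in studies if tf in sig_sets[s]} == inside]
            venn["&".join(combo)] = region

    activated, repressed, rows = [], [], []
    for tf in sorted(common):
        if not all(tf in sig_sets[s] for s in studies):
            continue
        signs = {np.sign(frames[s].loc[tf, "activity"]) for s in studies}
        if require_sign and len(signs) != 1:
            continue
        direction = signs.pop() if len(signs) == 1 else 0.0
        if direction > 0:
            activated.append(tf)
        elif direction < 0:
            repressed.append(tf)
        label = "activated" if direction > 0 else ("repressed" if direction < 0 else "mixed")
        row = {"tf": tf, "direction": label}
        for s in studies:
            row[f"activity_{s}"] = float(frames[s].loc[tf, "activity"])
            row[f"pvalue_{s}"] = float(frames[s].loc[tf, "pvalue"])
        rows.append(row)

    return {
        "activated": activated,
        "repressed": repressed,
        "consensus": pd.DataFrame(rows),
        "venn": venn,
    }
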
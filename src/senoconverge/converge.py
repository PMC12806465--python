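"""Cross-condition similarity: Spearman matrices, clustering, DEG overlap.

Conditions (studies, interventions, aging contrasts) are compared by the
Spearman correlation of their per-gene signed scores or per-set normalized
enrichment scores.  Agglomerative clustering on the distance 1 - rho (not
1 - |rho|, so aging-versus-intervention sign structure is preserved) yields
the condition dendrogram, and the correlation matrix doubles as an edge
list for network export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .exceptions import DataError, ParameterError


@dataclass
class ConditionSimilarity:
    """Pairwise condition similarity with optional clustering results.

    ``rho`` is symmetric with unit diagonal; ``n_features`` counts the
    complete observations behind each pairwise coefficient.  After
    :func:`hcluster`, ``linkage_matrix`` holds the scipy merge encoding and
    ``leaf_order`` the dendrogram leaf sequence.
    """

    rho: pd.DataFrame
    n_features: pd.DataFrame
    linkage_matrix: np.ndarray | None = None
    leaf_order: list[str] | None = None

    @property
    def conditions(self) -> list[str]:
        return list(self.rho.columns)

    def edges(self) -> pd.DataFrame:
        """Upper-triangle edge list (source, target, rho) for graph export."""
        conds = self.conditions
        rows = [
            {"source": conds[i], "target": conds[j], "rho": self.rho.iloc[i, j]}
            for i in range(len(conds))
            for j in range(i + 1, len(conds))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho"])


def spearman_matrix(M: pd.DataFrame) -> ConditionSimilarity:
    """Pairwise Spearman correlation of the columns of a features-by-conditions
    matrix, with average ranks for ties and pairwise-complete observations.

    Constant columns yield undefined correlations for their pairs; those
    entries are flagged as missing with a warning and later excluded from
    clustering.
    """
    if M.shape[0] < 3:
        raise ParameterError("need >= 3 features for rank correlation")
    conds = list(M.columns)
    k = len(conds)
    rho = np.eye(k)
    nf = np.full((k, k), M.shape[0], dtype=int)
    X = M.to_numpy(dtype=float)
    undefined = []
    for i in range(k):
        for j in range(i + 1, k):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            nf[i, j] = nf[j, i] = int(ok.sum())
            xi, xj = X[ok, i], X[ok, j]
            if ok.sum() < 3 or np.all(xi == xi[0]) or np.all(xj == xj[0]):
                rho[i, j] = rho[j, i] = np.nan
                undefined.append((conds[i], conds[j]))
                continue
            r = stats.spearmanr(xi, xj).statistic
            rho[i, j] = rho[j, i] = r
    if undefined:
        warnings.warn(f"undefined correlations (constant column): {undefined}",
                      stacklevel=2)
    return ConditionSimilarity(
        rho=pd.DataFrame(rho, index=conds, columns=conds),
        n_features=pd.DataFrame(nf, index=conds, columns=conds),
    )


def nes_similarity(enrichments: dict[str, pd.DataFrame], padj_cut: float = 0.1) -> ConditionSimilarity:
    """Condition similarity at the gene-set level.

    ``enrichments`` maps condition label to a preranked-GSEA result table
    (columns ``set``, ``nes``, ``padj``).  The feature universe is the union
    of sets reaching adjusted p below ``padj_cut`` in at least one condition;
    the per-condition NES of those sets feed :func:`spearman_matrix`.
    """
    keep: set[str] = set()
    for cond, table in enrichments.items():
        keep.update(table.loc[table["padj"] < padj_cut, "set"])
    if not keep:
        raise DataError(f"no sets pass the padj < {padj_cut} filter")
    universe = sorted(keep)
    cols = {}
    for cond, table in enrichments.items():
        cols[cond] = table.set_index("set")["nes"].reindex(universe)
    return spearman_matrix(pd.DataFrame(cols, index=universe))


def hcluster(sim: ConditionSimilarity, method: str = "average") -> ConditionSimilarity:
    """Agglomerative clustering of conditions on the distance 1 - rho.

    Returns a new similarity object carrying the linkage matrix and leaf
    order.  Conditions with any undefined correlation cannot be clustered.
    """
    if method not in ("single", "complete", "average"):
        raise ParameterError(f"unknown linkage method '{method}'")
    conds = sim.conditions
    if len(conds) < 2:
        raise ParameterError("need >= 2 conditions to cluster")
    R = sim.rho.to_numpy(dtype=float)
    if np.isnan(R).any():
        raise DataError("missing correlations: drop affected conditions before clustering")
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method=method)
    leaves = [conds[i] for i in hierarchy.leaves_list(Z)]
    return ConditionSimilarity(rho=sim.rho, n_features=sim.n_features,
                               linkage_matrix=Z, leaf_order=leaves)


def top_split(sim: ConditionSimilarity) -> tuple[set[str], set[str]]:
    """The two condition groups separated by the final (root) merge."""
    if sim.linkage_matrix is None:
        raise ParameterError("run hcluster first")
    conds = sim.conditions
    n = len(conds)
    members: dict[int, set[str]] = {i: {conds[i]} for i in range(n)}
    for step, (a, b, _, _) in enumerate(sim.linkage_matrix):
        members[n + step] = members[int(a)] | members[int(b)]
    a, b = int(sim.linkage_matrix[-1, 0]), int(sim.linkage_matrix[-1, 1])
    return members[a], members[b]


def deg_overlap(tables, padj_cut: float = 0.05) -> pd.DataFrame:
    """Partition significant genes by study-membership pattern.

    A gene is significant in a study when its BH-adjusted p falls strictly
    below ``padj_cut``.  Returns one row per gene significant anywhere, with
    a boolean column per study, the membership ``pattern`` string, and for
    multi-study genes a ``concordant`` flag (identical log2fc sign in every
    study where significant).
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ParameterError("need >= 2 tables")
    sig: dict[str, pd.Index] = {}
    signs: dict[str, pd.Series] = {}
    for t in tables:
        if not t.has_padj:
            raise DataError(f"study {t.study_id} lacks padj")
        mask = t.data["padj"] < padj_cut
        sig[t.study_id] = t.data.index[mask]
        signs[t.study_id] = np.sign(t.data["log2fc"])

    studies = list(sig)
    all_genes = sorted(set().union(*[set(ix) for ix in sig.values()]))
    rows = []
    for g in all_genes:
        membership = {s: g in sig[s] for s in studies}
        present = [s for s in studies if membership[s]]
        gene_signs = {s: signs[s].get(g) for s in present}
        concordant = len({v for v in gene_signs.values()}) == 1 if len(present) > 1 else None
        rows.append({"gene": g, **membership,
                     "pattern": "&".join(present), "n_studies": len(present),
                     "concordant": concordant})
    return pd.DataFrame(rows, columns=["gene", *studies, "pattern", "n_studies", "concordant"])
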
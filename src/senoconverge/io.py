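"""Tabular input/output: DE tables, GMT gene sets, regulons, matrices, config.

All readers validate their invariants on load and raise
:class:`~senoconverge.exceptions.FormatError` /
:class:`~senoconverge.exceptions.DataError` with enough context (column name,
row number, offending id) to locate the problem in the source file.

Conventions
-----------
* Delimited text is TSV by default; a ``sep`` argument selects comma.
* Missing values may be encoded as empty fields or ``NA``.
* Gene identifiers are opaque, case-sensitive strings; no symbol mapping.
* Every writer has a matching reader and the pair round-trips values to
  full float precision (``repr``-style formatting).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError, FormatError, ParameterError

# Candidate header names per logical field, tried in order.  The first group
# is the DESeq2 dialect, the second the package's own canonical short names.
DEFAULT_COLUMN_CANDIDATES: dict[str, tuple[str, ...]] = {
    "gene": ("gene", "gene_id", "Gene"),
    "log2fc": ("log2FoldChange", "log2fc", "logFC"),
    "se": ("lfcSE", "se", "SE"),
    "pvalue": ("pvalue", "p_value", "PValue"),
    "padj": ("padj", "p_adj", "adj.P.Val", "qvalue"),
}

_REQUIRED_FIELDS = ("gene", "log2fc", "se", "pvalue")


@dataclass
class DETable:
    """Per-gene differential-expression estimates for one study/contrast.

    ``data`` is indexed by gene id with float columns ``log2fc``, ``se``,
    ``pvalue`` and optionally ``padj`` (BH-adjusted p).  Effects are log2
    fold changes with their standard errors, the atoms of all downstream
    scoring and meta-analysis.
    """

    study_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        validate_de_table(self.data, self.study_id)

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def has_padj(self) -> bool:
        return "padj" in self.data.columns

    def __len__(self) -> int:
        return len(self.data)


def validate_de_table(df: pd.DataFrame, study_id: str = "?") -> None:
    """Check DETable invariants, raising :class:`DataError` on violation."""
    for col in ("log2fc", "se", "pvalue"):
        if col not in df.columns:
            raise FormatError(f"study {study_id}: missing column '{col}'")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"study {study_id}: duplicate gene ids: {dups[:10]}")
    se = df["se"].to_numpy(float)
    if np.any(se[np.isfinite(se)] <= 0):
        raise DataError(f"study {study_id}: non-positive standard errors")
    p = df["pvalue"].to_numpy(float)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise DataError(f"study {study_id}: p-values outside [0, 1]")
    if "padj" in df.columns:
        q = df["padj"].to_numpy(float)
        ok = np.isfinite(q)
        if np.any((q[ok] < 0) | (q[ok] > 1)):
            raise DataError(f"study {study_id}: padj outside [0, 1]")


def read_de_table(
    path: str | Path,
    study_id: str | None = None,
    columns: Mapping[str, str] | None = None,
    sep: str = "\t",
) -> DETable:
    """Read a differential-expression table from delimited text.

    Parameters
    ----------
    path
        Delimited file with a header row.
    study_id
        Label for the study; defaults to the file stem.
    columns
        Optional explicit mapping from logical field (``gene``, ``log2fc``,
        ``se``, ``pvalue``, ``padj``) to the header name in the file.
        Fields not mapped fall back to the default candidate names.
    sep
        Field separator.
    """
    path = Path(path)
    if study_id is None:
        study_id = path.stem
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]

    resolved: dict[str, str] = {}
    for fieldname, candidates in DEFAULT_COLUMN_CANDIDATES.items():
        if columns and fieldname in columns:
            cand: tuple[str, ...] = (columns[fieldname],)
        else:
            cand = candidates
        hit = next((c for c in cand if c in raw.columns), None)
        if hit is None:
            if fieldname in _REQUIRED_FIELDS:
                raise FormatError(
                    f"{path.name}: missing required column '{cand[0]}' "
                    f"(accepted names: {', '.join(cand)})"
                )
            continue  # padj is optional
        resolved[fieldname] = hit

    out = pd.DataFrame(index=raw[resolved["gene"]].astype(str))
    out.index.name = "gene"
    for fieldname in ("log2fc", "se", "pvalue", "padj"):
        if fieldname not in resolved:
            continue
        col = raw[resolved[fieldname]].mask(raw[resolved[fieldname]].isin(["", "NA"]))
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() & col.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise FormatError(
                f"{path.name}: non-numeric value '{col[bad].iloc[0]}' in "
                f"column '{resolved[fieldname]}' at line {row}"
            )
        out[fieldname] = numeric.to_numpy()
    return DETable(study_id=study_id, data=out)


def write_de_table(table: DETable, path: str | Path, sep: str = "\t") -> None:
    df = table.data.reset_index()
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


@dataclass
class GeneSetCollection:
    """Named gene sets from one database collection (e.g. one MSigDB source).

    Invariants: no empty set; members deduplicated (first occurrence kept).
    """

    collection_id: str
    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            deduped = list(dict.fromkeys(members))
            if not deduped:
                raise DataError(f"gene set '{name}' is empty")
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(self.collection_id, {n: list(self.sets[n]) for n in names})


def read_gmt(path: str | Path, collection_id: str | None = None) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, members...)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}: line {lineno} has {len(fields)} fields, "
                    "expected at least 3 (name, description, members...)"
                )
            name = fields[0]
            members = [g for g in fields[2:] if g]
            sets[name] = members
    if not sets:
        raise FormatError(f"{path.name}: no sets")
    return GeneSetCollection(collection_id or path.stem, sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


VALID_CONFIDENCE = frozenset("ABCDE")


@dataclass
class RegulonTable:
    """TF-target interactions with signed mode-of-regulation weights.

    ``data`` has columns ``tf``, ``target``, ``mor`` (signed weight) and
    ``confidence`` (curation class A-E).  (tf, target) pairs are unique and
    weights are finite and nonzero.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("tf", "target", "mor", "confidence"):
            if col not in df.columns:
                raise FormatError(f"regulon table missing column '{col}'")
        if df.duplicated(subset=["tf", "target"]).any():
            pair = df[df.duplicated(subset=["tf", "target"])].iloc[0]
            raise DataError(f"duplicate regulon edge ({pair['tf']}, {pair['target']})")
        mor = df["mor"].to_numpy(float)
        if not np.all(np.isfinite(mor)) or np.any(mor == 0):
            raise DataError("mode-of-regulation weights must be finite and nonzero")
        bad = set(df["confidence"]) - VALID_CONFIDENCE
        if bad:
            raise DataError(f"unknown confidence classes: {sorted(bad)}")

    def filter_confidence(self, keep: Sequence[str] = ("A", "B", "C")) -> "RegulonTable":
        return RegulonTable(self.data[self.data["confidence"].isin(keep)].reset_index(drop=True))

    @property
    def tfs(self) -> list[str]:
        return list(dict.fromkeys(self.data["tf"]))


def read_regulons(path: str | Path, sep: str = "\t") -> RegulonTable:
    df = pd.read_csv(path, sep=sep, dtype={"tf": str, "target": str, "confidence": str})
    return RegulonTable(df)


def write_regulons(table: RegulonTable, path: str | Path, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a genes-by-samples matrix (first column = gene ids)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, float_format="%.17g")


_THRESHOLD_RANGES = {
    "score_cut": (0.0, np.inf),
    "padj_de": (0.0, 1.0),
    "padj_gsea": (0.0, 1.0),
    "p_meta": (0.0, 1.0),
    "p_loo_max": (0.0, 1.0),
    "p_tf": (0.0, 1.0),
}


@dataclass
class RunConfig:
    """Pipeline thresholds and reproducibility settings.

    Defaults mirror the analysis conventions of the senescent-cell-clearance
    convergence workflow: informative-gene score cut 2, DE significance at
    BH-adjusted p < 0.05, gene-set filter at adjusted p < 0.1, meta-analysis
    p < 0.01, leave-one-out max p < 0.1, TF significance p < 0.05.
    """

    seed: int = 0
    score_cut: float = 2.0
    padj_de: float = 0.05
    padj_gsea: float = 0.1
    p_meta: float = 0.01
    p_loo_max: float = 0.1
    p_tf: float = 0.05
    nperm: int = 1000
    linkage: str = "average"

    def __post_init__(self) -> None:
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            value = getattr(self, name)
            if not (lo <= value <= hi):
                raise ParameterError(f"{name}={value} outside [{lo}, {hi}]")
        if self.nperm < 1:
            raise ParameterError("nperm must be >= 1")
        if self.linkage not in ("single", "complete", "average"):
            raise ParameterError(f"unknown linkage '{self.linkage}'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_metadata(path: str | Path, config: RunConfig | None = None, **extra) -> None:
    """Write a JSON run-metadata sidecar next to an output file."""
    from . import __version__

    payload: dict = {"package": "senoconverge", "version": __version__}
    if config is not None:
        payload["config"] = config.to_dict()
    payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
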
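"""Containers and readers/writers for the formats the pipeline touches.

Expression matrices are genes x samples on a log scale (the pipeline never
normalizes; inputs are assumed pre-processed).  Gene-set collections follow
the GMT convention; clinical tables are plain TSV with required columns
``sample_id``, ``os_time``, ``os_event`` and the optional columns ``stage``,
``tissue_class``, ``timepoint``, ``patient_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from ._utils import DataFormatError, DegsigError, logger

CLINICAL_REQUIRED = ("sample_id", "os_time", "os_event")
CLINICAL_OPTIONAL = ("stage", "tissue_class", "timepoint", "patient_id")


@dataclass
class ExpressionMatrix:
    """Log-scale expression, genes in rows, samples in columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise DegsigError(f"duplicate gene ids: {dupes[:5]}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise DegsigError(f"duplicate sample ids: {dupes[:5]}")
        values = df.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise DegsigError("expression matrix contains non-finite values")
        self.data = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def row(self, gene_id: str) -> pd.Series:
        if gene_id not in self.data.index:
            raise DegsigError(f"gene {gene_id!r} not in expression matrix")
        return self.data.loc[gene_id]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise DegsigError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[gene_ids])

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DegsigError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[sample_ids])


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (hallmark signature or a constructed DEG set)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise DegsigError("gene set name must be non-empty")
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise DegsigError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dup = next(n for n in names if n in seen or seen.add(n))  # type: ignore[func-returns-value]
            raise DegsigError(f"duplicate gene-set name {dup!r}")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


@dataclass
class ClinicalTable:
    """Per-sample survival and optional grouping annotations."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise DegsigError("duplicate sample ids in clinical table")
        for col in ("os_time", "os_event"):
            if col not in df.columns:
                raise DegsigError(f"clinical table missing required column {col!r}")
        times = df["os_time"].to_numpy(dtype=float)
        if not (np.isfinite(times).all() and (times > 0).all()):
            raise DegsigError("os_time must be positive and finite")
        events = df["os_event"].to_numpy(dtype=float)
        if not np.isin(events, (0.0, 1.0)).all():
            raise DegsigError("os_event must be 0 or 1")
        df = df.copy()
        df.index = df.index.astype(str)
        df["os_event"] = df["os_event"].astype(int)
        if "stage" in df.columns:
            stages = df["stage"].dropna()
            if len(stages) and not stages.astype(float).isin([1.0, 2.0, 3.0, 4.0]).all():
                raise DegsigError("stage must be an ordinal in 1..4 where present")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        sample_ids = list(sample_ids)
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise DegsigError(f"samples not in clinical table: {missing[:5]}")
        return ClinicalTable(self.data.loc[sample_ids])


# ---------------------------------------------------------------------------
# expression I/O


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    """Keep, per duplicated gene id, the row with the highest mean."""
    if not df.index.has_duplicates:
        return df
    n_dup = int(df.index.duplicated().sum())
    means = df.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    keep = ~df.index[order].duplicated()
    kept = df.iloc[order[keep]]
    kept = kept.loc[df.index.unique()]  # restore first-appearance order
    logger.info("collapsed %d duplicate gene rows (kept highest mean)", n_dup)
    return kept


def _to_numeric(df: pd.DataFrame, path: str | Path) -> pd.DataFrame:
    out = df.apply(pd.to_numeric, errors="coerce")
    bad = out.isna() & ~df.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if out.isna().to_numpy().any():
        r, c = np.argwhere(out.isna().to_numpy())[0]
        raise DataFormatError(f"{path}: missing value at gene {out.index[r]!r}, sample {out.columns[c]!r}")
    return out


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes x samples expression matrix from TSV or GCT v1.2."""
    path = Path(path)
    if not path.exists():
        raise DegsigError(f"no such file: {path}")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
        if df.columns.size == 0:
            raise DataFormatError(f"{path}: no sample columns in header")
        df.index = df.index.astype(str)
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise DataFormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().strip().split("\t")
            if len(dims) < 2:
                raise DataFormatError(f"{path}: malformed GCT dimension line")
            try:
                n_genes, n_samples = int(dims[0]), int(dims[1])
            except ValueError as exc:
                raise DataFormatError(f"{path}: non-integer GCT dimensions {dims[:2]}") from exc
            body = pd.read_csv(fh, sep="\t", dtype=str)
        if list(body.columns[:2]) != ["Name", "Description"]:
            raise DataFormatError(f"{path}: GCT header must start with Name\\tDescription")
        if len(body) != n_genes or body.shape[1] - 2 != n_samples:
            raise DataFormatError(
                f"{path}: GCT dimension line says {n_genes} genes x {n_samples} samples, "
                f"found {len(body)} x {body.shape[1] - 2}"
            )
        df = body.set_index("Name").drop(columns=["Description"])
        df.index = df.index.astype(str)
    else:
        raise DegsigError(f"unknown expression format {format!r}")
    df = _to_numeric(df, path)
    df = _collapse_duplicate_genes(df)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        expr.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    elif format == "gct":
        n_genes, n_samples = expr.shape
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{n_genes}\t{n_samples}\n")
        body = expr.data.copy()
        body.insert(0, "Description", "na")
        body.to_csv(path, sep="\t", index_label="Name", float_format="%.10g", mode="a")
    else:
        raise DegsigError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name TAB description TAB members."""
    path = Path(path)
    if not path.exists():
        raise DegsigError(f"no such file: {path}")
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(f"{path}:{lineno}: fewer than 3 fields")
            name, description = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning("%s:%d: %d duplicate members in set %r deduplicated",
                               path, lineno, len(members) - len(unique), name)
            sets.append(GeneSet(name=name, description=description, members=frozenset(unique)))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            desc = gs.description or "na"
            fh.write("\t".join([gs.name, desc, *gs.sorted_members()]) + "\n")


# ---------------------------------------------------------------------------
# clinical I/O


def read_clinical(path: str | Path) -> ClinicalTable:
    path = Path(path)
    if not path.exists():
        raise DegsigError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "patient_id": str})
    for col in CLINICAL_REQUIRED:
        if col not in df.columns:
            raise DataFormatError(f"{path}: missing required column {col!r}")
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.data.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


# ---------------------------------------------------------------------------
# alignment


def align_samples(expr: ExpressionMatrix, clin: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both tables to their shared samples, in expression order."""
    shared = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    if not shared:
        raise DegsigError("expression and clinical tables share no samples")
    logger.info("aligned on %d shared samples (%d expr, %d clinical)",
                len(shared), len(expr.sample_ids), len(clin.sample_ids))
    return expr.subset_samples(shared), clin.subset(shared)
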
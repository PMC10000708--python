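"""Readers, writers and deterministic input transforms.

This module owns the data containers the pipeline passes around — a
gene-by-sample :class:`ExpressionMatrix`, a :class:`GeneSetCollection`
(GMT-style), a :class:`ClinicalTable` with overall-survival fields, and
copy-number segments — plus the unit conversion from FPKM/RPKM to TPM and
the standard copy-number segment filter.

Conventions
-----------
* Expression tables are delimited text with gene identifiers in the first
  column and sample identifiers in the header row.
* Duplicate gene rows are collapsed by the per-sample maximum (the common
  convention when multiple probes/transcripts map to one symbol); a warning
  is logged.
* RPKM is treated identically to FPKM for the TPM transform: the
  single-end/paired-end distinction does not enter the formula.
* Copy-number coordinates are 1-based inclusive (SEG-file convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_UNITS = ("FPKM", "TPM", "LOG2")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a declared unit.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows, samples in columns. Index and columns must be unique,
        values numeric and complete.
    unit : str
        One of ``FPKM``, ``TPM`` or ``LOG2``. Non-negativity is enforced for
        the two linear units.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown expression unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.shape[0] == 0 or self.values.shape[1] == 0:
            raise ValueError("expression matrix is empty")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        if self.values.isna().any().any():
            gene, sample = next(
                (g, s)
                for g, row in self.values.iterrows()
                for s, v in row.items()
                if pd.isna(v)
            )
            raise ValueError(f"missing expression value for gene {gene!r} in sample {sample!r}")
        if self.unit in ("FPKM", "TPM") and (self.values.values < 0).any():
            raise ValueError(f"negative values are not allowed for unit {self.unit}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """Return log2(x + pseudocount); identity if unit is already LOG2."""
        if self.unit == "LOG2":
            return self.values.copy()
        return np.log2(self.values + pseudocount)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        if not present:
            raise ValueError("none of the requested genes are in the matrix")
        return ExpressionMatrix(self.values.loc[present], self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)], self.unit)


def read_expression_matrix(
    path: str | Path,
    unit: str,
    sep: str | None = None,
    impute_missing: bool = False,
) -> ExpressionMatrix:
    """Read a delimited gene-by-sample table.

    First column = gene IDs, header row = sample IDs. Duplicate gene rows are
    collapsed by per-sample max (logged). Missing cells are an error unless
    ``impute_missing`` is set, in which case per-gene medians are imputed.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    seen: set[str] = set()
    dupes = [h for h in header if h in seen or seen.add(h)]
    if dupes:
        raise ValueError(f"{path}: duplicate sample IDs {sorted(set(dupes))[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric value for gene {bad[0]!r} in sample {col!r}"
                )
            df[col] = coerced
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by per-sample max", n_dup)
        order = df.index.drop_duplicates()
        df = df.groupby(level=0, sort=False).max().loc[order]
    if df.isna().any().any():
        if impute_missing:
            df = df.apply(lambda row: row.fillna(row.median()), axis=1)
            if df.isna().any().any():
                raise ValueError(f"{path}: gene(s) with all values missing cannot be imputed")
            logger.warning("imputed missing expression values with per-gene medians")
        else:
            mask = df.isna()
            gene = mask.any(axis=1).idxmax()
            sample = mask.loc[gene].idxmax()
            raise ValueError(
                f"{path}: missing value for gene {gene!r} in sample {sample!r} "
                "(pass impute_missing=True to impute per-gene medians)"
            )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, unit)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    m.values.to_csv(path, sep=sep, index_label="gene_id")


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale FPKM/RPKM columns so each sample sums to one million (TPM).

    TPM_ij = FPKM_ij / sum_i FPKM_ij * 1e6.
    """
    if m.unit != "FPKM":
        raise ValueError(f"fpkm_to_tpm expects unit FPKM, got {m.unit}")
    colsum = m.values.sum(axis=0)
    zero = colsum.index[colsum <= 0]
    if len(zero):
        raise ValueError(f"sample(s) with all-zero expression: {list(zero[:5])}")
    tpm = m.values.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(tpm, "TPM")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("gene-set collection is empty")
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets and all(
            self.descriptions.get(n, "") == other.descriptions.get(n, "") for n in self.sets
        )

    def restrict_to(self, universe: Sequence[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; empty results are dropped with a warning."""
        uni = set(universe)
        kept: dict[str, list[str]] = {}
        for name, genes in self.sets.items():
            inter = [g for g in genes if g in uni]
            if inter:
                kept[name] = inter
            else:
                logger.warning("gene set %r has no genes in the expression matrix; dropped", name)
        if not kept:
            raise ValueError("no gene set intersects the gene universe")
        return GeneSetCollection(kept, {n: self.descriptions.get(n, "") for n in kept})


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene [<tab> gene ...]."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning("gene set %r: removed %d duplicate gene(s)", name, len(genes) - len(deduped))
            if not deduped:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection.names:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *collection[name]]) + "\n")


# ---------------------------------------------------------------------------
# Clinical
# ---------------------------------------------------------------------------

RESPONSE_LEVELS = ("responder", "non-responder")


@dataclass
class ClinicalTable:
    """Per-sample survival data plus optional covariates and response label.

    ``data`` is indexed by sample ID and must contain ``os_time`` (positive)
    and ``os_event`` (0/1). A ``response`` column, when present, uses the
    levels ``responder`` / ``non-responder``.
    """

    data: pd.DataFrame
    time_unit: str = "months"

    def __post_init__(self) -> None:
        for col in ("os_time", "os_event"):
            if col not in self.data.columns:
                raise ValueError(f"clinical table lacks required column {col!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample IDs in clinical table")
        if (self.data["os_time"] <= 0).any():
            bad = self.data.index[self.data["os_time"] <= 0].tolist()
            raise ValueError(f"non-positive os_time for sample(s) {bad[:5]}")
        if not self.data["os_event"].isin([0, 1]).all():
            raise ValueError("os_event must be 0 or 1")
        if "response" in self.data.columns:
            resp = self.data["response"].dropna()
            bad = set(resp.unique()) - set(RESPONSE_LEVELS)
            if bad:
                raise ValueError(f"unknown response labels {sorted(bad)}; expected {RESPONSE_LEVELS}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def os_time(self) -> pd.Series:
        return self.data["os_time"]

    @property
    def os_event(self) -> pd.Series:
        return self.data["os_event"]

    @property
    def response(self) -> pd.Series | None:
        return self.data["response"] if "response" in self.data.columns else None

    def subset(self, samples: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.data.loc[list(samples)].copy(), self.time_unit)


def read_clinical(path: str | Path, sep: str = "\t", time_unit: str = "months") -> ClinicalTable:
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: clinical table lacks a sample_id column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return ClinicalTable(df, time_unit)


def write_clinical(table: ClinicalTable, path: str | Path, sep: str = "\t") -> None:
    table.data.to_csv(path, sep=sep, index_label="sample_id")


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CopyNumberSegment:
    """One SEG-file row; 1-based inclusive coordinates."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_probes: int
    seg_mean: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")


def read_segments(path: str | Path, sep: str = "\t") -> list[CopyNumberSegment]:
    df = pd.read_csv(path, sep=sep)
    required = ["sample", "chrom", "start", "end", "num_probes", "seg_mean"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: segment table lacks column(s) {missing}")
    return [
        CopyNumberSegment(
            str(r["sample"]), str(r["chrom"]), int(r["start"]), int(r["end"]),
            int(r["num_probes"]), float(r["seg_mean"]),
        )
        for _, r in df.iterrows()
    ]


def filter_copy_number_segments(
    segments: Sequence[CopyNumberSegment],
    min_probes: int = 10,
    amp_thr: float = 0.2,
    del_thr: float = -0.2,
) -> list[tuple[CopyNumberSegment, str]]:
    """Retain supported amplification/deletion calls.

    A segment is kept when it has at least ``min_probes`` supporting probes
    and its log2 segment mean is strictly above ``amp_thr`` (label
    ``"amplification"``) or strictly below ``del_thr`` (``"deletion"``).
    """
    if not (del_thr < 0 < amp_thr):
        raise ValueError("thresholds must satisfy del_thr < 0 < amp_thr")
    out: list[tuple[CopyNumberSegment, str]] = []
    for seg in segments:
        if seg.n_probes < min_probes:
            continue
        if seg.seg_mean > amp_thr:
            out.append((seg, "amplification"))
        elif seg.seg_mean < del_thr:
            out.append((seg, "deletion"))
    return out
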
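"""Readers and writers for the pipeline's external artifacts.

Expression matrices arrive either dense (TSV/CSV, genes in rows, first
column ``gene_id``) or as MatrixMarket coordinate triplets with ``genes.tsv``
and ``samples.tsv`` sidecars. Gene sets use the GMT dialect. Clinical tables
are TSV with ``patient_id``, ``time``, ``event`` and one column per score
gene. All identifiers are matched case-sensitively, with no alias
resolution.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "SurvivalCohort",
    "read_expression",
    "read_gmt",
    "read_cohort",
    "write_table",
]


class ValidationError(ValueError):
    """An input violated a structural invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
        if seen[i] == 2:
            dups.append(i)
    if dups:
        raise ValidationError(f"duplicate {what}: {sorted(dups)}")


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples expression values.

    ``scale`` records whether values are raw counts ("counts", all
    non-negative) or already log-transformed ("log", may be negative).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.scale not in ("counts", "log"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value grid shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.scale == "counts" and (self.values < 0).any():
            bad = int((self.values < 0).sum())
            raise ValidationError(f"{bad} negative values in a counts-scale matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        try:
            idx = self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None
        return self.values[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets: term_id -> (term_name, member gene ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclasses.dataclass
class SurvivalCohort:
    """Per-patient follow-up time, event indicator and score-gene expression."""

    patient_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    expr: pd.DataFrame  # patients x score genes, aligned with patient_ids

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        _check_unique(self.patient_ids, "patient ids")
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        n = len(self.patient_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValidationError("time/event length does not match patient ids")
        if (self.time < 0).any() or not np.all(np.isfinite(self.time)):
            raise ValidationError("follow-up times must be finite and >= 0")
        if not np.isin(self.event, [0, 1]).all():
            bad = sorted(set(np.asarray(self.event).tolist()) - {0, 1})
            raise ValidationError(f"event indicator must be 0 or 1, found {bad}")
        self.event = self.event.astype(int)
        if len(self.expr) != n:
            raise ValidationError("expression table length does not match patients")
        if self.expr.isna().any().any():
            raise ValidationError("expression table contains missing values")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


def _dense_expression(path: Path, sep: str, scale: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep=sep, header=0, dtype={0: str})
    if df.shape[1] < 2:
        raise ParseError(f"{path}: line 1: expected gene_id column plus samples")
    gene_col = df.columns[0]
    genes = df[gene_col].astype(str).tolist()
    samples = [str(c) for c in df.columns[1:]]
    try:
        values = df.iloc[:, 1:].to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    return ExpressionMatrix(genes, samples, values, scale=scale)


def _mtx_expression(path: Path, scale: str) -> ExpressionMatrix:
    genes_file = path.parent / "genes.tsv"
    samples_file = path.parent / "samples.tsv"
    for sidecar in (genes_file, samples_file):
        if not sidecar.exists():
            raise FileNotFoundError(f"missing sidecar {sidecar} next to {path}")
    mat = scipy.io.mmread(path)
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    genes = [l.split("\t")[0] for l in genes_file.read_text().splitlines() if l.strip()]
    samples = [l.split("\t")[0] for l in samples_file.read_text().splitlines() if l.strip()]
    if dense.shape != (len(genes), len(samples)):
        raise ValidationError(
            f"MTX shape {dense.shape} does not match sidecars "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    return ExpressionMatrix(genes, samples, dense, scale=scale)


def read_expression(path: str | Path, format: str = "tsv", scale: str = "counts") -> ExpressionMatrix:
    """Read a genes x samples expression matrix.

    ``format`` is one of ``tsv``, ``csv`` (dense, first column gene_id) or
    ``mtx`` (MatrixMarket coordinate triplet with ``genes.tsv`` /
    ``samples.tsv`` sidecars). Duplicate gene or sample ids are an error,
    never silently collapsed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _dense_expression(path, "\t", scale)
    if format == "csv":
        return _dense_expression(path, ",", scale)
    if format == "mtx":
        return _mtx_expression(path, scale)
    raise ValueError(f"unknown expression format {format!r}")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: term_id TAB description TAB member..."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs term, description "
                    f"and at least one member (got {len(fields)} fields)"
                )
            term, desc = fields[0], fields[1]
            if term in sets:
                raise ValidationError(f"{path}: line {lineno}: duplicate term {term!r}")
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise ParseError(f"{path}: line {lineno}: gene set {term!r} has no members")
            sets[term] = (desc, members)
    return GeneSetCollection(sets)


def read_cohort(path: str | Path, score_genes: Sequence[str]) -> SurvivalCohort:
    """Read a clinical TSV into a complete-case SurvivalCohort.

    Rows with missing time, event or expression are dropped (the count is
    logged); stratification must run on complete cases, never on imputed
    values. Event values are coerced strictly from {0, 1}.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    for col in ("patient_id", "time", "event"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    for gene in score_genes:
        if gene not in df.columns:
            raise ValidationError(f"{path}: requested gene column {gene!r} absent")
    cols = ["patient_id", "time", "event", *score_genes]
    sub = df[cols]
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        logger.info("read_cohort: dropped %d incomplete rows from %s", dropped, path)
    event = complete["event"].to_numpy()
    if not np.isin(event, [0, 1]).all():
        bad = sorted(set(event.tolist()) - {0, 1})
        raise ValidationError(f"{path}: event values outside {{0,1}}: {bad}")
    time = complete["time"].to_numpy(dtype=float)
    if (time < 0).any():
        raise ValidationError(f"{path}: negative follow-up time")
    expr = complete[list(score_genes)].reset_index(drop=True).astype(float)
    return SurvivalCohort(
        patient_ids=complete["patient_id"].tolist(),
        time=time,
        event=event.astype(int),
        expr=expr,
    )


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    records = list(records)
    if records and dataclasses.is_dataclass(records[0]):
        return pd.DataFrame([dataclasses.asdict(r) for r in records])
    return pd.DataFrame(records)


def write_table(records, path: str | Path) -> None:
    """Write any result table as TSV with reals at 6 significant digits.

    Column order is the table's own (deterministic for dataclass records);
    re-reading reproduces values to the rendered precision. An empty table
    yields a header-only file.
    """
    if records is None:
        raise ValueError("records must not be None")
    df = _as_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
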
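"""Tabular I/O and core data containers.

Expression data are genes x samples, real-valued, tab-delimited, with
empty fields or ``NA`` marking missing measurements.  Genotype data are
markers x samples with binary calls (the two parental alleles of a
haploid biparental cross, e.g. BY = 1 and RM = 0 in a yeast segregant
panel); every marker carries a chromosomal interval (1-based inclusive
base pairs).  Missing genotype calls are not supported: segregant panels
are genotyped completely and a missing call is treated as a data error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GenotypeMatrix",
    "read_expression_table",
    "write_expression_table",
    "read_genotype_table",
    "write_genotype_table",
    "align_samples",
]


class ValidationError(ValueError):
    """Raised when an input table violates the format contract."""


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit missing mask.

    ``values`` stores missing entries as NaN; ``missing`` exposes the
    boolean mask.  Any two rows form one 2D-trait for the scan.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, condition_label: str = "") -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            condition_label=condition_label,
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, list(sample_ids), self.values[:, idx], self.condition_label)

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.sample_ids, self.values[idx], self.condition_label)


@dataclass
class GenotypeMatrix:
    """Markers x samples binary genotype calls plus marker intervals.

    ``intervals`` is a DataFrame indexed by marker id with columns
    ``chromosome``, ``start``, ``end`` (1-based inclusive bp).  Markers
    are kept sorted by (chromosome, start).
    """

    marker_ids: list[str]
    sample_ids: list[str]
    calls: np.ndarray
    intervals: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls)
        self.marker_ids = list(self.marker_ids)
        self.sample_ids = list(self.sample_ids)
        if self.calls.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValidationError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.sample_ids)} samples"
            )
        _check_unique(self.marker_ids, "marker ids")
        _check_unique(self.sample_ids, "sample ids")
        if np.isnan(self.calls.astype(float)).any():
            raise ValidationError("missing genotype calls are not supported")
        self.calls = self.calls.astype(np.int8)
        bad = ~np.isin(self.calls, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"genotype call outside {{0,1}} for marker {self.marker_ids[i]}, "
                f"sample {self.sample_ids[j]}"
            )
        missing_iv = [m for m in self.marker_ids if m not in self.intervals.index]
        if missing_iv:
            raise ValidationError(f"markers without interval metadata: {missing_iv[:5]}")
        self.intervals = self.intervals.loc[self.marker_ids, ["chromosome", "start", "end"]].copy()
        self.intervals["start"] = self.intervals["start"].astype(int)
        self.intervals["end"] = self.intervals["end"].astype(int)
        degen = self.intervals["start"] > self.intervals["end"]
        if degen.any():
            raise ValidationError(
                f"degenerate interval (start > end) for marker(s) "
                f"{self.intervals.index[degen].tolist()[:5]}"
            )
        order = self.intervals.sort_values(["chromosome", "start"], kind="stable").index
        if list(order) != self.marker_ids:
            pos = {m: k for k, m in enumerate(self.marker_ids)}
            idx = [pos[m] for m in order]
            self.calls = self.calls[idx]
            self.marker_ids = list(order)
            self.intervals = self.intervals.loc[self.marker_ids]

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def marker(self, marker_id: str) -> np.ndarray:
        return self.calls[self.marker_ids.index(marker_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.marker_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(self.marker_ids, list(sample_ids), self.calls[:, idx], self.intervals)

    def interval_of(self, marker_id: str) -> tuple[str, int, int]:
        row = self.intervals.loc[marker_id]
        return str(row["chromosome"]), int(row["start"]), int(row["end"])


def _read_strict_tsv(path) -> pd.DataFrame:
    """Tab-delimited read that rejects ragged rows with a line number."""
    try:
        frame = pd.read_csv(
            path, sep="\t", index_col=0, na_values=["NA"],
            keep_default_na=False, dtype=str, engine="c",
        )
    except pd.errors.ParserError as exc:  # pandas message carries the line
        raise ValidationError(f"malformed table {path}: {exc}") from exc
    # pandas silently NaN-fills short rows; catch rows that ended early
    if frame.index.isna().any():
        raise ValidationError(f"malformed table {path}: empty row label")
    return frame


def read_expression_table(path, condition_label: str = "") -> ExpressionMatrix:
    """Read a genes x samples expression TSV (``NA``/empty = missing)."""
    frame = _read_strict_tsv(path)
    try:
        values = frame.apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric expression value in {path}: {exc}") from exc
    return ExpressionMatrix(
        gene_ids=[str(g) for g in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        values=values,
        condition_label=condition_label,
    )


def write_expression_table(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="gene")


def read_genotype_table(path, interval_path) -> GenotypeMatrix:
    """Read a markers x samples calls TSV plus a marker-interval TSV.

    The interval file has columns ``marker_id``, ``chromosome``,
    ``start``, ``end``.  Calls must all lie in {0, 1}.
    """
    frame = _read_strict_tsv(path)
    if frame.isna().any().any():
        raise ValidationError(f"missing genotype call in {path}")
    try:
        calls = frame.apply(pd.to_numeric, errors="raise").to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric genotype call in {path}: {exc}") from exc
    iv = pd.read_csv(interval_path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    required = {"marker_id", "chromosome", "start", "end"}
    if not required.issubset(iv.columns):
        raise ValidationError(f"interval file {interval_path} lacks columns {sorted(required - set(iv.columns))}")
    iv = iv.set_index("marker_id")
    return GenotypeMatrix(
        marker_ids=[str(m) for m in frame.index],
        sample_ids=[str(s) for s in frame.columns],
        calls=calls,
        intervals=iv,
    )


def write_genotype_table(geno: GenotypeMatrix, path, interval_path) -> None:
    geno.to_frame().to_csv(path, sep="\t", index_label="marker")
    iv = geno.intervals.copy()
    iv.index.name = "marker_id"
    iv.to_csv(interval_path, sep="\t")


def align_samples(expr: ExpressionMatrix, geno: GenotypeMatrix) -> tuple[ExpressionMatrix, GenotypeMatrix]:
    """Restrict both matrices to their shared samples, in one order.

    The order follows the expression matrix.  Dropped samples are logged.
    Idempotent; raises on an empty intersection.
    """
    shared = [s for s in expr.sample_ids if s in set(geno.sample_ids)]
    if not shared:
        raise ValidationError("expression and genotype matrices share no samples")
    dropped = sorted((set(expr.sample_ids) | set(geno.sample_ids)) - set(shared))
    if dropped:
        logger.warning("align_samples dropped %d sample(s): %s", len(dropped), dropped)
    return expr.subset_samples(shared), geno.subset_samples(shared)
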
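"""Expression and genotype preprocessing for the two-locus scan.

Three steps prepare a segregant panel: genes with too many missing
measurements are dropped; each gene's remaining values are replaced by
normal quantiles of their ranks so the fixed-mean, fixed-SD bivariate
model applies; and runs of nearly identical neighbouring markers are
collapsed to single merged markers, after which only marker pairs with
adequately filled joint-genotype classes enter the scan.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .io import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMergeMap",
    "filter_genes_by_missing",
    "normal_quantile_transform",
    "merge_markers",
    "eligible_marker_pairs",
]


@dataclass
class MarkerMergeMap:
    """Mapping from merged markers back to their source markers."""

    groups: dict[str, list[str]]
    intervals: dict[str, tuple[str, int, int]]

    def source_to_merged(self) -> dict[str, str]:
        return {src: merged for merged, srcs in self.groups.items() for src in srcs}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for merged, srcs in self.groups.items():
            chrom, start, end = self.intervals[merged]
            rows.append({"merged_id": merged, "chromosome": chrom, "start": start,
                         "end": end, "source_ids": ",".join(srcs)})
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_genes_by_missing(expr, max_missing: int):
    """Drop genes with more than ``max_missing`` missing values.

    ``expr`` may be one :class:`ExpressionMatrix` or a sequence of them
    (one per condition); with several conditions a gene is dropped if it
    exceeds the cap in *any* condition, and all matrices are filtered to
    the common surviving gene set.
    """
    if max_missing < 0:
        raise ValueError("max_missing must be non-negative")
    single = isinstance(expr, ExpressionMatrix)
    mats = [expr] if single else list(expr)
    genes = mats[0].gene_ids
    for m in mats[1:]:
        if m.gene_ids != genes:
            raise ValueError("all conditions must carry the same gene ids")
    keep_mask = np.ones(len(genes), dtype=bool)
    for m in mats:
        keep_mask &= m.missing.sum(axis=1) <= max_missing
    kept = [g for g, k in zip(genes, keep_mask) if k]
    if not kept:
        logger.warning("filter_genes_by_missing removed every gene")
    dropped = int((~keep_mask).sum())
    if dropped:
        logger.info("filter_genes_by_missing removed %d gene(s)", dropped)
    out = [m.subset_genes(kept) for m in mats]
    return out[0] if single else tuple(out)


def normal_quantile_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each gene's values by normal quantiles of their ranks.

    A value with (average, for ties) rank r among that gene's n
    non-missing values becomes ``ndtri(r / (n + 1))``.  Missing entries
    stay missing.  The transform is invariant to any strictly monotone
    rescaling of the input, gives every gene mean exactly zero, and at
    n = 109 leaves sample SD ~ 0.97 — the fixed SD the correlation model
    assumes downstream.
    """
    values = expr.values.copy()
    for i, gene in enumerate(expr.gene_ids):
        row = values[i]
        obs = ~np.isnan(row)
        n = int(obs.sum())
        if n < 3:
            raise ValueError(f"gene {gene} has fewer than 3 non-missing values")
        ranks = stats.rankdata(row[obs], method="average")
        row[obs] = ndtri(ranks / (n + 1))
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids, values, expr.condition_label)


def _majority_calls(block: np.ndarray) -> np.ndarray:
    """Per-sample majority vote over group members; ties take the first row."""
    frac = block.mean(axis=0)
    rep = (frac > 0.5).astype(np.int8)
    tie = frac == 0.5
    rep[tie] = block[0, tie]
    return rep


def merge_markers(geno: GenotypeMatrix, max_discordant: int) -> tuple[GenotypeMatrix, MarkerMergeMap]:
    """Greedily merge runs of nearly identical neighbouring markers.

    Walking each chromosome left to right, a marker joins the current
    group when its calls differ from the group's representative calls in
    fewer than ``max_discordant`` samples ("fewer than": a discordance
    equal to the threshold starts a new group); bit-identical neighbours
    always merge, even at threshold 0.  The representative is
    the per-sample majority vote over members; the merged interval spans
    the group and the merged id is the left-most member's id.
    """
    merged_ids: list[str] = []
    merged_calls: list[np.ndarray] = []
    groups: dict[str, list[str]] = {}
    intervals: dict[str, tuple[str, int, int]] = {}

    def close(members: list[int]) -> None:
        ids = [geno.marker_ids[i] for i in members]
        block = geno.calls[members]
        rep = _majority_calls(block)
        chroms = geno.intervals.iloc[members]
        merged_id = ids[0]
        merged_ids.append(merged_id)
        merged_calls.append(rep)
        groups[merged_id] = ids
        intervals[merged_id] = (
            str(chroms["chromosome"].iloc[0]),
            int(chroms["start"].min()),
            int(chroms["end"].max()),
        )

    current: list[int] = []
    current_rep: np.ndarray | None = None
    current_chrom: str | None = None
    for i, _marker in enumerate(geno.marker_ids):
        chrom = str(geno.intervals["chromosome"].iloc[i])
        calls = geno.calls[i]
        discord = int(np.sum(calls != current_rep)) if current else -1
        if current and chrom == current_chrom and (discord == 0 or discord < max_discordant):
            current.append(i)
            current_rep = _majority_calls(geno.calls[current])
        else:
            if current:
                close(current)
            current = [i]
            current_rep = calls
            current_chrom = chrom
    if current:
        close(current)

    iv_frame = pd.DataFrame(
        [(m, *intervals[m]) for m in merged_ids],
        columns=["marker_id", "chromosome", "start", "end"],
    ).set_index("marker_id")
    merged = GenotypeMatrix(merged_ids, geno.sample_ids, np.vstack(merged_calls), iv_frame)
    logger.info("merge_markers: %d markers -> %d merged markers", geno.n_markers, merged.n_markers)
    return merged, MarkerMergeMap(groups=groups, intervals=intervals)


def eligible_marker_pairs(geno: GenotypeMatrix, min_class_size: int
                          ) -> list[tuple[str, str, dict[tuple[int, int], int]]]:
    """Unordered marker pairs with every joint-genotype class filled.

    Returns (marker1, marker2, class counts) for every pair whose four
    joint-genotype counts are all at least ``min_class_size``.
    """
    g = geno.calls.astype(np.int64)
    n11 = g @ g.T
    n10 = g @ (1 - g).T
    n01 = (1 - g) @ g.T
    n00 = (1 - g) @ (1 - g).T
    ok = (
        (n00 >= min_class_size) & (n01 >= min_class_size)
        & (n10 >= min_class_size) & (n11 >= min_class_size)
    )
    out = []
    for i, j in itertools.combinations(range(geno.n_markers), 2):
        if ok[i, j]:
            counts = {(0, 0): int(n00[i, j]), (0, 1): int(n01[i, j]),
                      (1, 0): int(n10[i, j]), (1, 1): int(n11[i, j])}
            out.append((geno.marker_ids[i], geno.marker_ids[j], counts))
    logger.info("eligible_marker_pairs: %d of %d pairs eligible (min class %d)",
                len(out), geno.n_markers * (geno.n_markers - 1) // 2, min_class_size)
    return out
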
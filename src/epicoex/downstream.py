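"""Post-scan analyses: epistasis map, clustering, enrichment tests.

Significant modules on neighbouring markers are first collapsed onto
merged loci (same greedy rule as the pre-scan merge, looser threshold),
then summarized as a symmetric locus x locus *epistasis map* counting
the modules that link each locus pair.  Hierarchical clustering of the
map's interaction profiles exposes groups of densely interacting loci.
Two hypergeometric enrichment tests interpret results functionally: one
asks whether particular (unordered) function pairs are over-represented
among the module gene pairs, the other whether a function is
over-represented among genes inside a set of chromosomal intervals
(computed by exact convolution of per-interval hypergeometric draws,
which reduces to the ordinary one-interval test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import GenotypeMatrix
from .model import ModuleResult
from .preprocess import merge_markers

logger = logging.getLogger(__name__)

__all__ = [
    "EpistasisMap", "PairEnrichmentInput", "IntervalEnrichmentInput",
    "merge_module_markers", "build_epistasis_map", "cluster_epistasis_map",
    "pair_function_enrichment", "interval_function_enrichment",
    "read_gmt", "linkage_to_newick",
]


# ---------------------------------------------------------------------------
# module merging and the epistasis map


def merge_module_markers(results: list[ModuleResult], geno: GenotypeMatrix,
                         max_discordant: int = 15
                         ) -> tuple[list[ModuleResult], "object"]:
    """Re-map module markers onto coarser merged loci and collapse duplicates.

    Markers are merged with the same greedy neighbour rule as the
    pre-scan merge but at a looser threshold; modules that share a gene
    pair and land on the same merged locus pair collapse to the one with
    the smallest p-value.  Returns the collapsed results and the merge
    map.
    """
    merged_geno, mmap = merge_markers(geno, max_discordant)
    to_merged = mmap.source_to_merged()
    best: dict[tuple, ModuleResult] = {}
    for r in results:
        c = r.candidate
        la = to_merged.get(c.marker1, c.marker1)
        lb = to_merged.get(c.marker2, c.marker2)
        if la > lb:
            la, lb = lb, la
        key = (c.gene1, c.gene2, la, lb)
        prev = best.get(key)
        if prev is None or (np.nan_to_num(r.p_value, nan=1.0)
                            < np.nan_to_num(prev.p_value, nan=1.0)):
            remapped = ModuleResult(
                candidate=type(c)(c.gene1, c.gene2, la, lb,
                                  class_counts=dict(c.class_counts)),
                pa=r.pa, selected_partition=r.selected_partition,
                rho_hat=dict(r.rho_hat), loglik_alt=r.loglik_alt,
                loglik_null=r.loglik_null, lr=r.lr, df=r.df, p_value=r.p_value,
                p_marginal1=r.p_marginal1, p_marginal2=r.p_marginal2,
                epistasis_p=r.epistasis_p, flags=set(r.flags),
            )
            best[key] = remapped
    out = [best[k] for k in sorted(best)]
    logger.info("merge_module_markers: %d modules -> %d after collapsing "
                "(%d merged loci)", len(results), len(out), merged_geno.n_markers)
    return out, mmap


@dataclass
class EpistasisMap:
    """Symmetric locus x locus matrix of significant-module counts."""

    locus_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if not np.array_equal(self.counts, self.counts.T):
            raise ValueError("epistasis map must be symmetric")
        if np.diag(self.counts).any():
            raise ValueError("epistasis map diagonal must be zero")
        if (self.counts < 0).any():
            raise ValueError("epistasis map counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.locus_ids, columns=self.locus_ids)

    @property
    def n_modules(self) -> int:
        return int(self.counts.sum() // 2)


def build_epistasis_map(results: list[ModuleResult]) -> EpistasisMap:
    """Count significant modules per (merged) locus pair."""
    sig = [r for r in results if r.significant]
    loci = sorted({m for r in sig for m in r.candidate.marker_pair})
    idx = {m: i for i, m in enumerate(loci)}
    counts = np.zeros((len(loci), len(loci)), dtype=int)
    for r in sig:
        a, b = (idx[m] for m in r.candidate.marker_pair)
        counts[a, b] += 1
        counts[b, a] += 1
    return EpistasisMap(locus_ids=loci, counts=counts)


def cluster_epistasis_map(emap: EpistasisMap, linkage: str = "average",
                          metric: str = "jaccard", n_clusters: int | None = None):
    """Agglomerative clustering of locus interaction profiles.

    Profiles are binarized (locus interacts with locus, yes/no) and
    clustered with the given linkage over the given distance (Jaccard by
    default, which groups loci interacting with the same partners).
    Returns (linkage matrix, flat cluster labels aligned with
    ``emap.locus_ids``).
    """
    if not emap.locus_ids:
        raise ValueError("cannot cluster an empty epistasis map")
    if len(emap.locus_ids) == 1:
        return np.empty((0, 4)), np.array([1])
    profiles = (emap.counts > 0).astype(float)
    dist = pdist(profiles, metric=metric)
    z = hierarchy.linkage(dist, method=linkage)
    labels = hierarchy.fcluster(z, t=n_clusters or 2, criterion="maxclust")
    return z, labels


def linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Export a scipy linkage matrix as a Newick string."""
    if len(leaf_names) == 1:
        return f"{leaf_names[0]};"
    tree = hierarchy.to_tree(z)

    def walk(node, parent_dist):
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{parent_dist - node.dist:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_dist - node.dist:.6g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


# ---------------------------------------------------------------------------
# enrichment


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT annotation file into gene -> set of terms."""
    gene_terms: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term = parts[0]
            for gene in parts[2:]:
                if gene:
                    gene_terms.setdefault(gene, set()).add(term)
    return gene_terms


@dataclass
class PairEnrichmentInput:
    """Hypergeometric counts for one function pair among gene pairs."""

    N: int  # total gene pairs in the universe
    M: int  # universe pairs bearing the function pair
    n: int  # module gene pairs
    k: int  # module pairs bearing the function pair

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.M)):
            raise ValueError("need 0 <= k <= min(n, M)")
        if self.M > self.N or self.n > self.N:
            raise ValueError("M and n cannot exceed N")


def _pair_terms(pair: tuple[str, str], annotation: dict[str, set[str]]) -> set[frozenset]:
    t1 = annotation.get(pair[0]) or {"unknown"}
    t2 = annotation.get(pair[1]) or {"unknown"}
    return {frozenset((a, b)) for a in t1 for b in t2}


def pair_function_enrichment(module_pairs, universe_pairs,
                             annotation: dict[str, set[str]]) -> pd.DataFrame:
    """Hypergeometric over-representation of function pairs in modules.

    Each gene contributes all its annotation terms ("unknown" if it has
    none); a gene pair is labelled by every unordered term pair it
    spans, contributing once per label.  For each label with counts
    (N, M, n, k) the upper-tail hypergeometric p-value is Bonferroni-
    corrected over the number of labels tested (those observed in the
    module pairs).
    """
    universe_pairs = [tuple(sorted(p)) for p in universe_pairs]
    module_pairs = [tuple(sorted(p)) for p in module_pairs]
    n_universe = len(universe_pairs)
    n_module = len(module_pairs)
    universe_counts: dict[frozenset, int] = {}
    for pair in universe_pairs:
        for label in _pair_terms(pair, annotation):
            universe_counts[label] = universe_counts.get(label, 0) + 1
    module_counts: dict[frozenset, int] = {}
    for pair in module_pairs:
        for label in _pair_terms(pair, annotation):
            module_counts[label] = module_counts.get(label, 0) + 1
    n_tests = len(module_counts)
    rows = []
    for label, k in sorted(module_counts.items(), key=lambda kv: sorted(kv[0])):
        M = universe_counts.get(label, 0)
        inp = PairEnrichmentInput(N=n_universe, M=M, n=n_module, k=k)
        p_raw = float(stats.hypergeom.sf(inp.k - 1, inp.N, inp.M, inp.n))
        rows.append({
            "function_pair": " | ".join(sorted(label)),
            "k": k, "M": M, "n": n_module, "N": n_universe,
            "p_raw": p_raw, "p_bonferroni": min(1.0, p_raw * n_tests),
        })
    return pd.DataFrame(rows).sort_values("p_raw", ignore_index=True)


@dataclass
class IntervalEnrichmentInput:
    """Counts for interval enrichment: per-interval gene and hit numbers."""

    N: int            # total annotated genes
    M: int            # genes with the function
    m: list[int]      # genes per interval
    k: list[int]      # genes with the function per interval

    def __post_init__(self) -> None:
        if len(self.m) != len(self.k):
            raise ValueError("m and k must align per interval")
        if not self.m:
            raise ValueError("need at least one interval")
        if sum(self.m) > self.N:
            raise ValueError("interval genes exceed the annotated universe")
        if self.M > self.N:
            raise ValueError("M cannot exceed N")
        for mi, ki in zip(self.m, self.k):
            if not (0 <= ki <= min(mi, self.M)):
                raise ValueError("need 0 <= k_i <= min(m_i, M)")

    @property
    def n(self) -> int:
        return len(self.m)


def interval_function_enrichment(inp: IntervalEnrichmentInput) -> float:
    """Tail probability that intervals jointly hold >= the observed hits.

    Models the hit count of interval i as an independent hypergeometric
    draw of m_i genes from (N, M) and convolves the per-interval pmfs
    exactly; the p-value is P(sum K_i >= sum k_i).  With one interval
    this is the standard hypergeometric upper tail.
    """
    dist = np.array([1.0])
    for mi in inp.m:
        kmax = min(mi, inp.M)
        pmf = stats.hypergeom.pmf(np.arange(kmax + 1), inp.N, inp.M, mi)
        dist = np.convolve(dist, pmf)
    observed = sum(inp.k)
    p = float(dist[observed:].sum())
    return min(1.0, max(p, float(dist[-1])))  # clamp numerical noise, keep p > 0


def genes_in_intervals(intervals: list[tuple[str, int, int]],
                       gene_positions: pd.DataFrame) -> list[list[str]]:
    """Genes whose (chromosome, start, end) overlap each query interval.

    ``gene_positions`` needs columns chromosome/start/end indexed by
    gene id; coordinates are 1-based inclusive.
    """
    out = []
    for chrom, start, end in intervals:
        sel = gene_positions[
            (gene_positions["chromosome"] == chrom)
            & (gene_positions["end"] >= start)
            & (gene_positions["start"] <= end)
        ]
        out.append(sorted(sel.index))
    return out
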
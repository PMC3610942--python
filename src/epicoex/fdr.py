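"""Permutation-based false-discovery-rate estimation.

The null is built by permuting the sample columns of the expression
matrix jointly across all genes: gene-gene correlations (the
co-expression structure) are preserved while every genotype-expression
link is destroyed.  The full pipeline — same PA cutoff, same 1D filter,
same model selection and thresholds — is re-run on each permuted panel
and, per permutation, the number of *unique gene pairs* among
significant modules is counted (a gene pair mapped by several
neighbouring marker pairs counts once, since linked markers make such
duplicates common).  The FDR estimate is the mean null count divided by
the observed unique-gene-pair count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScanConfig
from .io import ExpressionMatrix, GenotypeMatrix
from .model import ModuleResult
from .scan import exhaustive_scan

logger = logging.getLogger(__name__)

__all__ = ["permute_expression", "unique_gene_pairs", "estimate_fdr", "FdrReport"]


def permute_expression(expr: ExpressionMatrix, seed: int,
                       per_gene: bool = False) -> ExpressionMatrix:
    """Randomly permute sample columns (jointly across genes by default).

    ``per_gene=True`` instead permutes each gene's values independently,
    which additionally destroys the co-expression structure.
    """
    rng = np.random.default_rng(seed)
    if per_gene:
        values = expr.values.copy()
        for i in range(values.shape[0]):
            values[i] = values[i, rng.permutation(values.shape[1])]
    else:
        perm = rng.permutation(expr.n_samples)
        values = expr.values[:, perm]
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids, values, expr.condition_label)


def unique_gene_pairs(results: list[ModuleResult], significant_only: bool = True) -> set:
    """Unique 2D-traits (gene pairs) among (significant) modules."""
    return {
        r.candidate.gene_pair
        for r in results
        if (not significant_only) or r.significant
    }


@dataclass
class FdrReport:
    fdr: float | None
    observed_unique: int
    null_counts: list[int]
    seeds: list[int]

    @property
    def mean_null(self) -> float:
        return float(np.mean(self.null_counts))

    @property
    def sd_null(self) -> float:
        return float(np.std(self.null_counts, ddof=1)) if len(self.null_counts) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"permutation": i + 1, "seed": s, "null_unique_2d_traits": c}
            for i, (s, c) in enumerate(zip(self.seeds, self.null_counts))
        ]
        rows.append({"permutation": "summary", "seed": "",
                     "null_unique_2d_traits": f"mean={self.mean_null:.2f};"
                     f"sd={self.sd_null:.2f};observed={self.observed_unique};"
                     f"fdr={'NA' if self.fdr is None else f'{self.fdr:.4f}'}"})
        return pd.DataFrame(rows)


def estimate_fdr(observed: list[ModuleResult], expr: ExpressionMatrix,
                 geno: GenotypeMatrix, config: ScanConfig | None = None) -> FdrReport:
    """Re-run the pipeline on permuted expression to estimate the FDR.

    Permutation seeds derive from ``config.rng_seed`` by a fixed counter
    scheme (seed + permutation index) so the runs are reproducible and
    mutually independent.  With zero observed significant 2D-traits the
    FDR is undefined and reported as None.
    """
    config = config or ScanConfig()
    if config.n_permutations < 1:
        raise ValueError("need at least one permutation")
    observed_unique = len(unique_gene_pairs(observed))
    null_counts, seeds = [], []
    for i in range(config.n_permutations):
        seed = (config.rng_seed + 1_000_003 * (i + 1)) % (2**31)
        seeds.append(seed)
        permuted = permute_expression(expr, seed)
        null_results = exhaustive_scan(permuted, geno, config)
        null_counts.append(len(unique_gene_pairs(null_results)))
        logger.info("permutation %d (seed %d): %d null unique 2D-traits",
                    i + 1, seed, null_counts[-1])
    fdr = None if observed_unique == 0 else float(np.mean(null_counts)) / observed_unique
    return FdrReport(fdr=fdr, observed_unique=observed_unique,
                     null_counts=null_counts, seeds=seeds)
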
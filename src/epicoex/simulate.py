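"""Synthetic segregant panels with planted co-expression epistasis.

The generator emulates a haploid biparental cross: each chromosome is a
two-state Markov chain along its markers (first marker Bernoulli(0.5),
each subsequent call flipping with the inter-marker recombination
probability), which reproduces the linkage structure that makes
neighbouring-marker merging and duplicate-module collapsing meaningful.
Expression consists of background genes with an exchangeable
correlation and no genotype dependence, plus planted module gene pairs
drawn, sample by sample, from the bivariate normal whose correlation
(and optionally mean and SD, for the power-study variants) depends on
the sample's joint genotype at the module's marker pair.

Default trait SD is 0.97 so generated data directly match the fixed-SD
fitting assumption of the correlation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenotypeMatrix
from .partitions import JOINT_GENOTYPES

__all__ = ["ModuleSpec", "SimSpec", "simulate_genotypes", "simulate_module",
           "make_benchmark_dataset", "demo_spec"]


@dataclass
class ModuleSpec:
    """One planted module: a marker pair plus per-joint-genotype parameters."""

    marker1: str
    marker2: str
    #: correlation per joint genotype, e.g. {(0,0): 0.7, ...}
    rho: dict[tuple[int, int], float]
    gene1: str = ""
    gene2: str = ""
    #: per-genotype (mean_x, mean_y); None = all zero (genotype-independent)
    mean: dict[tuple[int, int], tuple[float, float]] | None = None
    #: per-genotype SD; None = the panel default (genotype-independent)
    sd: dict[tuple[int, int], float] | None = None

    def __post_init__(self) -> None:
        if set(self.rho) != set(JOINT_GENOTYPES):
            raise ValueError("rho must cover all four joint genotypes")
        if any(abs(r) >= 1 for r in self.rho.values()):
            raise ValueError("|rho| must be < 1")
        if self.sd is not None and any(s <= 0 for s in self.sd.values()):
            raise ValueError("per-class SDs must be positive")


@dataclass
class SimSpec:
    """Full panel specification (the study conditions of every simulation)."""

    n_samples: int = 150
    #: per chromosome: (number of markers, inter-marker recombination prob.)
    chromosomes: list[tuple[int, float]] = field(default_factory=lambda: [(3, 0.1)] * 4)
    modules: list[ModuleSpec] = field(default_factory=list)
    n_background_genes: int = 14
    background_rho: float = 0.2
    sd: float = 0.97
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for n_mark, rec in self.chromosomes:
            if not (0.0 < rec <= 0.5):
                raise ValueError("recombination probability must lie in (0, 0.5]")
            if n_mark < 1:
                raise ValueError("each chromosome needs at least one marker")
        if not abs(self.background_rho) < 1:
            raise ValueError("|background_rho| must be < 1")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


def simulate_genotypes(spec: SimSpec, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Markov-chain genotypes for a haploid biparental panel.

    Marker ids are ``c<chrom>m<index>``; intervals place markers 20 kb
    apart (1-based inclusive) on chromosomes ``chr1``, ``chr2``, ...
    """
    rng = rng if rng is not None else np.random.default_rng(spec.rng_seed)
    ids, rows, iv = [], [], []
    for ci, (n_mark, rec) in enumerate(spec.chromosomes, start=1):
        calls = np.empty((n_mark, spec.n_samples), dtype=np.int8)
        calls[0] = rng.random(spec.n_samples) < 0.5
        for k in range(1, n_mark):
            flip = rng.random(spec.n_samples) < rec
            calls[k] = np.where(flip, 1 - calls[k - 1], calls[k - 1])
        for k in range(n_mark):
            ids.append(f"c{ci}m{k + 1}")
            start = 1 + 20_000 * k
            iv.append((f"chr{ci}", start, start + 9_999))
            rows.append(calls[k])
    intervals = pd.DataFrame(iv, columns=["chromosome", "start", "end"],
                             index=pd.Index(ids, name="marker_id"))
    sample_ids = [f"s{i + 1:03d}" for i in range(spec.n_samples)]
    return GenotypeMatrix(ids, sample_ids, np.vstack(rows), intervals)


def simulate_module(entry: ModuleSpec, geno: GenotypeMatrix, sd_default: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw one planted gene pair conditionally on the joint genotype."""
    g1 = geno.marker(entry.marker1)
    g2 = geno.marker(entry.marker2)
    n = geno.n_samples
    x = np.empty(n)
    y = np.empty(n)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    for gt in JOINT_GENOTYPES:
        m = (g1 == gt[0]) & (g2 == gt[1])
        rho = entry.rho[gt]
        sd = entry.sd[gt] if entry.sd is not None else sd_default
        mx, my = entry.mean[gt] if entry.mean is not None else (0.0, 0.0)
        x[m] = mx + sd * z1[m]
        y[m] = my + sd * (rho * z1[m] + np.sqrt(1.0 - rho * rho) * z2[m])
    return x, y


def make_benchmark_dataset(spec: SimSpec
                           ) -> tuple[ExpressionMatrix, GenotypeMatrix, pd.DataFrame]:
    """Genotypes, expression and a truth table for one synthetic panel.

    Background genes share an exchangeable correlation (one latent
    factor) and carry no genotype dependence; planted modules are
    appended as named gene pairs.  The truth table lists one row per
    planted module with its gene pair, marker pair and per-genotype
    correlations, and round-trips through TSV.
    """
    rng = np.random.default_rng(spec.rng_seed)
    geno = simulate_genotypes(spec, rng)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    a = np.sqrt(abs(spec.background_rho))
    b = np.sqrt(1.0 - abs(spec.background_rho))
    factor = rng.standard_normal(spec.n_samples)
    for i in range(spec.n_background_genes):
        noise = rng.standard_normal(spec.n_samples)
        gene_ids.append(f"bg{i + 1:03d}")
        rows.append(spec.sd * (a * factor + b * noise))
    truth_rows = []
    for k, entry in enumerate(spec.modules, start=1):
        gene1 = entry.gene1 or f"mod{k}_ga"
        gene2 = entry.gene2 or f"mod{k}_gb"
        x, y = simulate_module(entry, geno, spec.sd, rng)
        gene_ids += [gene1, gene2]
        rows += [x, y]
        rec = {"gene1": min(gene1, gene2), "gene2": max(gene1, gene2),
               "marker1": min(entry.marker1, entry.marker2),
               "marker2": max(entry.marker1, entry.marker2)}
        swap = entry.marker1 > entry.marker2
        for gt in JOINT_GENOTYPES:
            src = (gt[1], gt[0]) if swap else gt
            rec[f"rho_{gt[0]}{gt[1]}"] = entry.rho[src]
        truth_rows.append(rec)
    expr = ExpressionMatrix(gene_ids, geno.sample_ids, np.vstack(rows),
                            condition_label="synthetic")
    truth = pd.DataFrame(truth_rows, columns=["gene1", "gene2", "marker1", "marker2",
                                              "rho_00", "rho_01", "rho_10", "rho_11"])
    return expr, geno, truth


def demo_spec(rng_seed: int = 0) -> SimSpec:
    """The bundled demo panel: 20 genes, 12 markers, 3 planted modules.

    150 segregants over four 3-marker chromosomes (recombination 0.1
    between neighbours).  The planted modules exercise the three
    qualitative epistasis patterns: a sign-switching (XOR-like) module
    with no marginal correlation signal, a single-class module where
    only genotype (1,1) differs, and a graded 3-class module.
    """
    xor = {gt: (0.75 if gt[0] == gt[1] else -0.75) for gt in JOINT_GENOTYPES}
    one_vs_rest = {gt: (0.9 if gt == (1, 1) else -0.3) for gt in JOINT_GENOTYPES}
    graded = {(0, 0): -0.8, (0, 1): 0.0, (1, 0): 0.0, (1, 1): 0.8}
    return SimSpec(
        n_samples=150,
        chromosomes=[(3, 0.1)] * 4,
        modules=[
            ModuleSpec("c1m1", "c2m1", xor),
            ModuleSpec("c3m1", "c4m1", one_vs_rest),
            ModuleSpec("c1m3", "c3m3", graded),
        ],
        n_background_genes=14,
        background_rho=0.2,
        sd=0.97,
        rng_seed=rng_seed,
    )
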
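"""Genome-wide exhaustive two-locus scan and its comparators.

The scan walks every gene pair against every eligible marker pair
through a filter cascade: the closed-form PA screen, a single-trait
(1D) linkage filter that discards modules explainable by genotype
effects on individual expression levels, likelihood-ratio model
selection over the epistatic genotype partitions, and a final
epistasis-versus-marginal test.  Every evaluated module is emitted with
its filter flags so attrition at each stage is auditable.

Two comparator analyses are included: per-gene Wilcoxon rank-sum eQTL
mapping (the 1D analysis), and a forward search that first finds the
single marker most associated with a pair's co-expression and only then
scans for an interacting partner — the strategy that misses modules
whose loci have weak marginal effects.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .config import ScanConfig
from .io import ExpressionMatrix, GenotypeMatrix
from .model import (
    GenotypeCorrelationModel,
    ModuleCandidate,
    ModuleResult,
    lr_test,
)
from .partitions import JOINT_GENOTYPES, marginal_partitions, null_partition
from .preprocess import eligible_marker_pairs

logger = logging.getLogger(__name__)

__all__ = ["one_d_linkage", "one_d_filter", "exhaustive_scan",
           "forward_search_scan", "results_to_frame", "ScanCounts"]


def one_d_linkage(expr: ExpressionMatrix, geno: GenotypeMatrix) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum p-value of each gene split by each marker.

    Returns a genes x markers DataFrame.  A marker leaving one genotype
    class empty for a gene yields p = 1 with a warning.
    """
    pmat = np.ones((expr.n_genes, geno.n_markers))
    for j in range(geno.n_markers):
        split = geno.calls[j] == 1
        for i in range(expr.n_genes):
            row = expr.values[i]
            obs = ~np.isnan(row)
            a = row[obs & split]
            b = row[obs & ~split]
            if a.size == 0 or b.size == 0:
                logger.warning("marker %s leaves one genotype class empty for gene %s",
                               geno.marker_ids[j], expr.gene_ids[i])
                continue
            # exact tail for small tie-free splits, normal approximation otherwise
            method = "exact" if max(a.size, b.size) <= 25 and \
                np.unique(np.concatenate([a, b])).size == a.size + b.size else "asymptotic"
            pmat[i, j] = stats.mannwhitneyu(a, b, alternative="two-sided",
                                            method=method).pvalue
    return pd.DataFrame(pmat, index=expr.gene_ids, columns=geno.marker_ids)


def one_d_filter(results: list[ModuleResult], pmat: pd.DataFrame,
                 threshold: float) -> list[ModuleResult]:
    """Drop modules in which either gene is linked to either module marker."""
    kept = []
    for res in results:
        c = res.candidate
        ps = [pmat.at[g, m] for g in c.gene_pair for m in c.marker_pair]
        if min(ps) >= threshold:
            res.flags.add("passed_1d")
            kept.append(res)
    return kept


def _pa_fast(x, y, joint, mask):
    """PA score from sufficient statistics; NaN for degenerate modules.

    Matches :func:`epicoex.pa.pa_score` exactly (tested) but runs on
    precomputed joint-genotype indices via bincount, which is what makes
    screening every candidate of the exhaustive scan cheap.
    """
    j = joint[mask]
    xv = x[mask]
    yv = y[mask]
    n = np.bincount(j, minlength=4).astype(float)
    if (n < 2).any():
        return np.nan
    sx = np.bincount(j, weights=xv, minlength=4)
    sy = np.bincount(j, weights=yv, minlength=4)
    sxx = np.bincount(j, weights=xv * xv, minlength=4)
    syy = np.bincount(j, weights=yv * yv, minlength=4)
    sxy = np.bincount(j, weights=xv * yv, minlength=4)
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    if (vx <= 0).any() or (vy <= 0).any():
        return np.nan
    r = (sxy - sx * sy / n) / np.sqrt(vx * vy)
    if (np.abs(r) >= 1).any():
        return np.nan
    nt = n.sum()
    vxa = sxx.sum() - sx.sum() ** 2 / nt
    vya = syy.sum() - sy.sum() ** 2 / nt
    if vxa <= 0 or vya <= 0:
        return np.nan
    r_all = (sxy.sum() - sx.sum() * sy.sum() / nt) / np.sqrt(vxa * vya)
    if abs(r_all) >= 1:
        return np.nan
    return float(np.sum(n * (np.log1p(-r_all * r_all) - np.log1p(-r * r))))


class ScanCounts(dict):
    """Stage-by-stage candidate counts of one scan (a plain dict)."""

    STAGES = ("formed", "scored_pa", "passed_pa", "passed_1d",
              "passed_lr", "passed_epistasis", "significant")

    def __init__(self):
        super().__init__({s: 0 for s in self.STAGES})


def exhaustive_scan(expr: ExpressionMatrix, geno: GenotypeMatrix,
                    config: ScanConfig | None = None,
                    counts_out: ScanCounts | None = None) -> list[ModuleResult]:
    """Scan every gene pair x eligible marker pair through the cascade.

    Inputs are assumed preprocessed (rank-normalized expression, merged
    markers).  Deterministic given the config; results are invariant to
    gene and marker input order because module identities are
    canonicalized.  Emits one :class:`ModuleResult` per evaluated
    module; modules that fail a stage carry the flags of the stages they
    passed, so the attrition at each stage can be audited.
    """
    config = config or ScanConfig()
    counts = counts_out if counts_out is not None else ScanCounts()
    pairs = eligible_marker_pairs(geno, config.min_class_size)
    if not pairs:
        raise ValueError("no eligible marker pairs at the configured class size")

    # canonical (lexicographic) marker order fixes the joint-genotype axes
    pair_info = []
    for ma, mb, _counts in pairs:
        if ma > mb:
            ma, mb = mb, ma
        g1 = geno.marker(ma)
        g2 = geno.marker(mb)
        pair_info.append((ma, mb, g1, g2, 2 * g1.astype(int) + g2.astype(int)))

    pmat = one_d_linkage(expr, geno)
    gene_order = sorted(range(expr.n_genes), key=lambda i: expr.gene_ids[i])

    results: list[ModuleResult] = []
    for gi, gj in itertools.combinations(gene_order, 2):
        x = expr.values[gi]
        y = expr.values[gj]
        mask = ~(np.isnan(x) | np.isnan(y))
        gene1, gene2 = expr.gene_ids[gi], expr.gene_ids[gj]
        for ma, mb, g1, g2, joint in pair_info:
            counts["formed"] += 1
            jm = joint[mask]
            class_counts = {gt: int(np.sum(jm == 2 * gt[0] + gt[1])) for gt in JOINT_GENOTYPES}
            if min(class_counts.values()) < config.min_class_size:
                continue
            cand = ModuleCandidate(gene1, gene2, ma, mb, class_counts=class_counts)
            pa = _pa_fast(x, y, joint, mask)
            if np.isnan(pa):
                logger.info("dropping degenerate module %s", cand.key)
                continue
            counts["scored_pa"] += 1
            res = ModuleResult(candidate=cand, pa=pa)
            results.append(res)
            if pa < config.pa_cutoff:
                continue
            res.flags.add("passed_pa")
            counts["passed_pa"] += 1
            ps = [pmat.at[g, m] for g in (gene1, gene2) for m in (ma, mb)]
            if min(ps) < config.oned_p_threshold:
                continue
            res.flags.add("passed_1d")
            counts["passed_1d"] += 1
            model = GenotypeCorrelationModel(x[mask], y[mask], g1[mask], g2[mask],
                                             sd=config.sd_fixed)
            fit = model.fit()
            res.selected_partition = fit.partition.id
            res.rho_hat = dict(fit.rho_hat)
            res.loglik_alt = fit.llf
            res.loglik_null = fit.llnull
            res.lr = fit.lr
            res.df = fit.df
            res.p_value = fit.p_value
            res.p_marginal1 = fit.p_marginal1
            res.p_marginal2 = fit.p_marginal2
            res.epistasis_p = fit.epistasis_p
            if res.p_value >= config.p_threshold:
                continue
            res.flags.add("passed_lr")
            counts["passed_lr"] += 1
            if res.epistasis_p >= config.epistasis_p_threshold:
                continue
            res.flags.add("passed_epistasis")
            counts["passed_epistasis"] += 1
            res.flags.add("significant")
            counts["significant"] += 1
    logger.info("scan counts: %s", dict(counts))
    return results


def forward_search_scan(x, y, geno: GenotypeMatrix,
                        config: ScanConfig | None = None,
                        gene1: str = "gene_x", gene2: str = "gene_y") -> ModuleResult | None:
    """Two-stage forward search for one gene pair.

    Stage 1 finds the single marker whose 2-class (marker-split)
    correlation model is most significant against the constant-
    correlation null; if no marker clears the significance threshold the
    pair is abandoned — which is exactly how modules whose loci have
    weak marginal effects are missed.  Stage 2 holds that marker fixed
    and scans every second marker with full model selection, returning
    the best two-locus module.
    """
    config = config or ScanConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    xv, yv = x[mask], y[mask]

    best_first, best_p = None, np.inf
    for idx, marker in enumerate(geno.marker_ids):
        g = geno.calls[idx][mask]
        n1 = int(g.sum())
        if min(n1, g.size - n1) < config.min_class_size:
            continue
        # 2-class marker split vs constant correlation, df = 1
        model = GenotypeCorrelationModel(xv, yv, g, np.zeros_like(g), sd=config.sd_fixed)
        null_fit = model.fit_partition(null_partition())
        marg = model.fit_partition(marginal_partitions()[0])
        p = lr_test(marg, null_fit).p_value
        if p < best_p:
            best_p, best_first = p, marker
    if best_first is None or best_p >= config.p_threshold:
        return None

    g1_full = geno.marker(best_first)
    best_res = None
    for marker in geno.marker_ids:
        if marker == best_first:
            continue
        g2_full = geno.marker(marker)
        jm = 2 * g1_full[mask].astype(int) + g2_full[mask].astype(int)
        if np.bincount(jm, minlength=4).min() < config.min_class_size:
            continue
        cand = ModuleCandidate(gene1, gene2, *sorted([best_first, marker]))
        ga, gb = (g1_full, g2_full) if cand.marker1 == best_first else (g2_full, g1_full)
        model = GenotypeCorrelationModel(xv, yv, ga[mask], gb[mask], sd=config.sd_fixed)
        fit = model.fit()
        res = ModuleResult(
            candidate=ModuleCandidate(gene1, gene2, cand.marker1, cand.marker2,
                                      class_counts=model.class_counts()),
            selected_partition=fit.partition.id, rho_hat=dict(fit.rho_hat),
            loglik_alt=fit.llf, loglik_null=fit.llnull, lr=fit.lr, df=fit.df,
            p_value=fit.p_value, p_marginal1=fit.p_marginal1,
            p_marginal2=fit.p_marginal2, epistasis_p=fit.epistasis_p,
        )
        if best_res is None or res.p_value < best_res.p_value:
            best_res = res
    return best_res


def results_to_frame(results: list[ModuleResult],
                     geno: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Flatten scan results to one row per module (the results TSV)."""
    rows = []
    for r in results:
        c = r.candidate
        row = {
            "gene1": c.gene1, "gene2": c.gene2,
            "marker1": c.marker1, "marker2": c.marker2,
        }
        if geno is not None:
            for tag, m in (("1", c.marker1), ("2", c.marker2)):
                chrom, start, end = geno.interval_of(m)
                row[f"interval{tag}"] = f"{chrom}:{start}-{end}"
        for gt in JOINT_GENOTYPES:
            row[f"n_{gt[0]}{gt[1]}"] = c.class_counts.get(gt, 0)
        row.update(
            pa=r.pa, partition_id=r.selected_partition,
            rho=";".join(f"{cl}:{v:+.4f}" for cl, v in sorted(r.rho_hat.items())),
            lr=r.lr, df=r.df, p_value=r.p_value,
            p_marginal1=r.p_marginal1, p_marginal2=r.p_marginal2,
            epistasis_p=r.epistasis_p, flags=",".join(sorted(r.flags)),
        )
        rows.append(row)
    return pd.DataFrame(rows)
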
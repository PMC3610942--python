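"""Conditional bivariate-normal model with genotype-dependent correlation.

For one candidate module — a pair of expression traits (x, y) and a pair
of binary markers (g1, g2) — the traits are modelled, conditionally on
the joint genotype, as bivariate normal with means fixed at zero and
both standard deviations fixed at a common value (0.97 by default, the
SD of normal-quantile-transformed expression at the yeast panel's sample
size).  Only the correlation varies: a genotype partition assigns each
of the four joint genotypes to a correlation class, and each class
carries one correlation parameter.

Model selection fits the twelve epistatic partitions against the
one-class null by likelihood-ratio tests (chi-square, df = difference in
class counts) and keeps the partition with the smallest p-value.  The
min-over-partitions selection is deliberately not multiplicity-adjusted
analytically; the permutation FDR of the full scan absorbs it.  A final
generalized LR test against the better of the two marginal (single
marker) models removes modules whose correlation pattern one marker
explains alone.

:class:`GenotypeCorrelationModel` / :class:`GenotypeCorrelationResults`
expose this in the usual model/results idiom; the functional wrappers
(:func:`fit_correlations`, :func:`lr_test`, :func:`select_best_model`,
:func:`epistasis_vs_marginal`) serve the genome-wide scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .partitions import (
    JOINT_GENOTYPES,
    GenotypePartition,
    enumerate_partitions,
    epistatic_partitions,
    marginal_partitions,
    null_partition,
)

__all__ = [
    "RHO_BOUND_EPS",
    "ModuleCandidate",
    "ModuleResult",
    "CorrelationFit",
    "TestResult",
    "GenotypeCorrelationModel",
    "GenotypeCorrelationResults",
    "log_likelihood",
    "fit_correlations",
    "lr_test",
    "select_best_model",
    "epistasis_vs_marginal",
    "fit_variance_dependent",
]

#: correlations are constrained to (-1 + eps, 1 - eps)
RHO_BOUND_EPS = 1e-6

_LN_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# containers


@dataclass
class ModuleCandidate:
    """One (gene pair, marker pair) candidate, canonically ordered."""

    gene1: str
    gene2: str
    marker1: str
    marker2: str
    class_counts: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gene1 == self.gene2:
            raise ValueError("a module needs two distinct genes")
        if self.marker1 == self.marker2:
            raise ValueError("a module needs two distinct markers")
        if self.gene1 > self.gene2:
            self.gene1, self.gene2 = self.gene2, self.gene1
        if self.marker1 > self.marker2:
            self.marker1, self.marker2 = self.marker2, self.marker1
            if self.class_counts:
                self.class_counts = {(j, i): c for (i, j), c in self.class_counts.items()}

    @property
    def gene_pair(self) -> tuple[str, str]:
        return (self.gene1, self.gene2)

    @property
    def marker_pair(self) -> tuple[str, str]:
        return (self.marker1, self.marker2)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.gene1, self.gene2, self.marker1, self.marker2)


@dataclass
class ModuleResult:
    """Scored module: PA, selected partition, LR statistics and filter flags."""

    candidate: ModuleCandidate
    pa: float = np.nan
    selected_partition: str | None = None
    rho_hat: dict[int, float] = field(default_factory=dict)
    loglik_alt: float = np.nan
    loglik_null: float = np.nan
    lr: float = np.nan
    df: int = 0
    p_value: float = np.nan
    p_marginal1: float = np.nan
    p_marginal2: float = np.nan
    epistasis_p: float = np.nan
    flags: set[str] = field(default_factory=set)

    @property
    def significant(self) -> bool:
        return "significant" in self.flags


@dataclass
class CorrelationFit:
    """Per-class correlation MLEs under one genotype partition."""

    partition: GenotypePartition
    rho_hat: dict[int, float]
    loglik: float
    sd_fixed: float
    n_per_class: dict[int, int]
    #: per-class SD / mean estimates, populated by the variance/mean-dependent variants
    sd_hat: dict[int, float] | None = None
    mean_hat: dict[int, tuple[float, float]] | None = None


@dataclass
class TestResult:
    lr: float
    df: int
    p_value: float


# ---------------------------------------------------------------------------
# per-class likelihood machinery

def _class_labels(g1: np.ndarray, g2: np.ndarray, partition: GenotypePartition) -> np.ndarray:
    """Correlation class (1..k) of every sample."""
    lab = np.asarray(partition.class_labels())  # indexed by 2*g1 + g2
    return lab[2 * np.asarray(g1, dtype=int) + np.asarray(g2, dtype=int)]


def _suffstats(x, y, labels, k):
    """Per-class (n, S = Sxx+Syy, P = Sxy)."""
    idx = np.asarray(labels, dtype=int) - 1
    n = np.bincount(idx, minlength=k).astype(float)
    s = np.bincount(idx, weights=x * x + y * y, minlength=k)
    p = np.bincount(idx, weights=x * y, minlength=k)
    return n, s, p


def _class_loglik(rho: float, n: float, s: float, p: float, sd: float) -> float:
    """Log-likelihood of one class at correlation ``rho`` (means 0, SDs ``sd``)."""
    om = 1.0 - rho * rho
    return (
        -n * (_LN_2PI + 2.0 * np.log(sd))
        - 0.5 * n * np.log(om)
        - (s - 2.0 * rho * p) / (2.0 * sd * sd * om)
    )


def _mle_rho(n: float, s: float, p: float, sd: float) -> float:
    """Maximizer of the fixed-mean fixed-SD class likelihood over rho.

    The stationary condition is the cubic

        n sd^2 rho^3 - P rho^2 + (S - n sd^2) rho - P = 0,

    which reduces to rho = Pearson r when the empirical second moments
    match sd^2.  The real roots inside the open interval plus the
    interval endpoints are compared on the likelihood.
    """
    lo, hi = -1.0 + RHO_BOUND_EPS, 1.0 - RHO_BOUND_EPS
    nsd2 = n * sd * sd
    roots = np.roots([nsd2, -p, s - nsd2, -p])
    cands = [lo, hi]
    for r in roots:
        if abs(r.imag) < 1e-9:
            cands.append(float(np.clip(r.real, lo, hi)))
    vals = [_class_loglik(r, n, s, p, sd) for r in cands]
    return cands[int(np.argmax(vals))]


def log_likelihood(x, y, partition: GenotypePartition, rho: dict[int, float],
                   sd: float, class_of_sample) -> float:
    """Joint log-likelihood of paired traits under per-class correlations.

    ``class_of_sample`` gives each sample's correlation class (1..k).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if sd <= 0:
        raise ValueError("sd must be positive")
    labels = np.asarray(class_of_sample, dtype=int)
    if labels.shape != x.shape:
        raise ValueError("class_of_sample must match the sample count")
    total = 0.0
    for c in range(1, partition.k + 1):
        rc = rho[c]
        if not abs(rc) < 1.0:
            raise ValueError(f"correlation for class {c} must lie in (-1, 1)")
        m = labels == c
        n = float(m.sum())
        s = float(np.sum(x[m] ** 2 + y[m] ** 2))
        pxy = float(np.sum(x[m] * y[m]))
        total += _class_loglik(rc, n, s, pxy, sd)
    return float(total)


# ---------------------------------------------------------------------------
# model / results objects


class GenotypeCorrelationModel:
    """Conditional bivariate-normal correlation model for one module.

    Parameters
    ----------
    x, y
        Expression of the two genes (same samples; NaNs in either trait
        drop the sample).
    g1, g2
        Binary genotype calls at the two markers for the same samples.
    sd
        Fixed standard deviation of both traits (default 0.97).

    Examples
    --------
    >>> model = GenotypeCorrelationModel(x, y, g1, g2)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, x, y, g1, g2, sd: float = 0.97):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        g1 = np.asarray(g1, dtype=int)
        g2 = np.asarray(g2, dtype=int)
        if not (x.shape == y.shape == g1.shape == g2.shape):
            raise ValueError("x, y, g1, g2 must share one length")
        if sd <= 0:
            raise ValueError("sd must be positive")
        keep = ~(np.isnan(x) | np.isnan(y))
        self.x = x[keep]
        self.y = y[keep]
        self.g1 = g1[keep]
        self.g2 = g2[keep]
        self.sd = float(sd)
        self.nobs = int(keep.sum())
        if not np.isfinite(self.x).all() or not np.isfinite(self.y).all():
            raise ValueError("expression values must be finite")

    def class_counts(self) -> dict[tuple[int, int], int]:
        counts = {}
        for gt in JOINT_GENOTYPES:
            counts[gt] = int(np.sum((self.g1 == gt[0]) & (self.g2 == gt[1])))
        return counts

    def loglike(self, partition: GenotypePartition, rho: dict[int, float]) -> float:
        labels = _class_labels(self.g1, self.g2, partition)
        return log_likelihood(self.x, self.y, partition, rho, self.sd, labels)

    def fit_partition(self, partition: GenotypePartition) -> CorrelationFit:
        """Per-class correlation MLE under one partition (fixed means/SDs)."""
        labels = _class_labels(self.g1, self.g2, partition)
        n, s, p = _suffstats(self.x, self.y, labels, partition.k)
        if (n < 2).any():
            empty = [c + 1 for c in range(partition.k) if n[c] < 2]
            raise ValueError(f"class(es) {empty} hold fewer than 2 samples")
        rho_hat, loglik = {}, 0.0
        for c in range(partition.k):
            r = _mle_rho(n[c], s[c], p[c], self.sd)
            rho_hat[c + 1] = r
            loglik += _class_loglik(r, n[c], s[c], p[c], self.sd)
        return CorrelationFit(
            partition=partition, rho_hat=rho_hat, loglik=float(loglik),
            sd_fixed=self.sd,
            n_per_class={c + 1: int(n[c]) for c in range(partition.k)},
        )

    def fit_variance_dependent(self, partition: GenotypePartition,
                               variant: str = "model6") -> CorrelationFit:
        """Richer per-class fits used only for power comparisons.

        ``model6`` frees a common per-class SD for both traits (means
        stay 0); ``model20`` additionally frees per-class means.  With a
        free common SD the per-class correlation MLE is 2*Sxy/(Sxx+Syy)
        and the SD follows in closed form.
        """
        if variant not in ("model6", "model20"):
            raise ValueError("variant must be 'model6' or 'model20'")
        labels = _class_labels(self.g1, self.g2, partition)
        rho_hat, sd_hat, mean_hat, loglik = {}, {}, {}, 0.0
        for c in range(1, partition.k + 1):
            m = labels == c
            n = int(m.sum())
            if n < 4:
                raise ValueError(f"class {c} holds fewer than 4 samples")
            xc, yc = self.x[m], self.y[m]
            if variant == "model20":
                mx, my = float(xc.mean()), float(yc.mean())
                xc, yc = xc - mx, yc - my
                mean_hat[c] = (mx, my)
            s = float(np.sum(xc * xc + yc * yc))
            p = float(np.sum(xc * yc))
            r = float(np.clip(2.0 * p / s, -1.0 + RHO_BOUND_EPS, 1.0 - RHO_BOUND_EPS))
            sig2 = (s - 2.0 * r * p) / (2.0 * n * (1.0 - r * r))
            rho_hat[c] = r
            sd_hat[c] = float(np.sqrt(sig2))
            loglik += _class_loglik(r, n, s, p, float(np.sqrt(sig2)))
        return CorrelationFit(
            partition=partition, rho_hat=rho_hat, loglik=float(loglik),
            sd_fixed=np.nan,
            n_per_class={c: int(np.sum(labels == c)) for c in range(1, partition.k + 1)},
            sd_hat=sd_hat, mean_hat=mean_hat if variant == "model20" else None,
        )

    def fit(self, min_class_size: int = 0) -> "GenotypeCorrelationResults":
        """Model selection over the twelve epistatic partitions.

        Fits the one-class null and every epistatic partition, takes the
        partition with the smallest chi-square LR p-value (ties broken
        by fewer classes, then catalogue order), then tests it against
        the better marginal model.
        """
        counts = self.class_counts()
        if min_class_size and min(counts.values()) < min_class_size:
            raise ValueError(
                f"joint-genotype class counts {counts} below min_class_size={min_class_size}"
            )
        fit_null = self.fit_partition(null_partition())
        per_partition = []
        for part in epistatic_partitions():
            fit_alt = self.fit_partition(part)
            test = lr_test(fit_alt, fit_null)
            per_partition.append((fit_alt, test))
        best_fit, best_test = min(
            per_partition,
            key=lambda ft: (ft[1].p_value, ft[0].partition.k, ft[0].partition.id),
        )
        m1_fit = self.fit_partition(marginal_partitions()[0])
        m2_fit = self.fit_partition(marginal_partitions()[1])
        p_m1 = lr_test(m1_fit, fit_null).p_value
        p_m2 = lr_test(m2_fit, fit_null).p_value
        best_marg_ll = max(m1_fit.loglik, m2_fit.loglik)
        epi_lr = max(0.0, 2.0 * (best_fit.loglik - best_marg_ll))
        epi_df = max(best_fit.partition.k - 2, 1)
        epi_p = float(stats.chi2.sf(epi_lr, epi_df))
        return GenotypeCorrelationResults(
            model=self, fit_null=fit_null, best_fit=best_fit, best_test=best_test,
            per_partition=per_partition, p_marginal1=p_m1, p_marginal2=p_m2,
            epistasis_p=epi_p,
        )


class GenotypeCorrelationResults:
    """Fit results for one module: selected partition, LR tests, diagnostics."""

    def __init__(self, model, fit_null, best_fit, best_test, per_partition,
                 p_marginal1, p_marginal2, epistasis_p):
        self.model = model
        self.fit_null = fit_null
        self.best_fit = best_fit
        self.best_test = best_test
        self.per_partition = per_partition
        self.p_marginal1 = p_marginal1
        self.p_marginal2 = p_marginal2
        self.epistasis_p = epistasis_p

    @property
    def partition(self) -> GenotypePartition:
        return self.best_fit.partition

    @property
    def rho_hat(self) -> dict[int, float]:
        return self.best_fit.rho_hat

    @property
    def llf(self) -> float:
        return self.best_fit.loglik

    @property
    def llnull(self) -> float:
        return self.fit_null.loglik

    @property
    def lr(self) -> float:
        return self.best_test.lr

    @property
    def df(self) -> int:
        return self.best_test.df

    @property
    def p_value(self) -> float:
        return self.best_test.p_value

    def rho_by_genotype(self) -> dict[tuple[int, int], float]:
        return {g: self.rho_hat[c] for g, c in self.partition.class_of.items()}

    def summary(self) -> str:
        lines = [
            "Genotype-dependent correlation model",
            "=" * 52,
            f"No. observations: {self.model.nobs:>6d}    fixed SD: {self.model.sd:.4f}",
            f"Null correlation: {self.fit_null.rho_hat[1]:+.4f}"
            f"    loglik(null): {self.llnull:.3f}",
            f"Selected partition: {self.partition.id}  (k={self.partition.k})",
            f"loglik(best): {self.llf:.3f}   LR: {self.lr:.3f}"
            f"   df: {self.df}   p: {self.p_value:.3e}",
            "-" * 52,
            "joint genotype   class   n      rho_hat",
        ]
        counts = self.model.class_counts()
        for g in JOINT_GENOTYPES:
            c = self.partition.class_of[g]
            lines.append(
                f"  ({g[0]},{g[1]})          {c}     {counts[g]:>4d}   {self.rho_hat[c]:+.4f}"
            )
        lines += [
            "-" * 52,
            f"marginal p (marker 1 / marker 2): {self.p_marginal1:.3e} / {self.p_marginal2:.3e}",
            f"epistasis vs best marginal: p = {self.epistasis_p:.3e}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of the two traits coloured by correlation class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        labels = _class_labels(self.model.g1, self.model.g2, self.partition)
        for c in range(1, self.partition.k + 1):
            m = labels == c
            ax.scatter(self.model.x[m], self.model.y[m], s=12,
                       label=f"class {c} (rho={self.rho_hat[c]:+.2f})")
        ax.set_xlabel("trait x")
        ax.set_ylabel("trait y")
        ax.legend(fontsize=8)
        return ax


# ---------------------------------------------------------------------------
# functional interface used by the scan


def fit_correlations(x, y, g1, g2, partition: GenotypePartition,
                     sd: float = 0.97) -> CorrelationFit:
    """Per-class correlation MLE for one partition (functional form)."""
    return GenotypeCorrelationModel(x, y, g1, g2, sd=sd).fit_partition(partition)


def lr_test(fit_alt: CorrelationFit, fit_null: CorrelationFit) -> TestResult:
    """Chi-square LR test of a finer partition against a nested coarser one."""
    if not fit_alt.partition.refines(fit_null.partition):
        raise ValueError(
            f"partition {fit_alt.partition.id} is not nested in "
            f"{fit_null.partition.id}; use epistasis_vs_marginal for "
            "non-nested comparisons"
        )
    lr = max(0.0, 2.0 * (fit_alt.loglik - fit_null.loglik))
    df = fit_alt.partition.k - fit_null.partition.k
    p = float(stats.chi2.sf(lr, df)) if df > 0 else 1.0
    return TestResult(lr=lr, df=df, p_value=p)


def select_best_model(x, y, g1, g2, config=None, sd: float | None = None,
                      candidate: ModuleCandidate | None = None) -> ModuleResult:
    """Fit all epistatic partitions and report the most significant one."""
    from .config import ScanConfig

    config = config or ScanConfig()
    model = GenotypeCorrelationModel(x, y, g1, g2, sd=sd or config.sd_fixed)
    res = model.fit()
    cand = candidate or ModuleCandidate("geneA", "geneB", "mkr1", "mkr2",
                                        class_counts=model.class_counts())
    if not cand.class_counts:
        cand.class_counts = model.class_counts()
    return ModuleResult(
        candidate=cand,
        selected_partition=res.partition.id,
        rho_hat=dict(res.rho_hat),
        loglik_alt=res.llf,
        loglik_null=res.llnull,
        lr=res.lr,
        df=res.df,
        p_value=res.p_value,
        p_marginal1=res.p_marginal1,
        p_marginal2=res.p_marginal2,
        epistasis_p=res.epistasis_p,
    )


def epistasis_vs_marginal(x, y, g1, g2, best: ModuleResult,
                          config=None) -> tuple[float, float, float]:
    """Test the selected model against the better single-marker model.

    Returns (p_marginal1, p_marginal2, epistasis_p) where the marginal
    p-values test each 2-class marker split against the null and the
    epistasis p-value is the generalized LR of the selected partition
    against the better marginal fit at df = max(k - 2, 1).
    """
    from .config import ScanConfig

    config = config or ScanConfig()
    model = GenotypeCorrelationModel(x, y, g1, g2, sd=config.sd_fixed)
    fit_null = model.fit_partition(null_partition())
    m1_fit, m2_fit = (model.fit_partition(p) for p in marginal_partitions())
    p_m1 = lr_test(m1_fit, fit_null).p_value
    p_m2 = lr_test(m2_fit, fit_null).p_value
    best_part = next(p for p in enumerate_partitions() if p.id == best.selected_partition)
    best_fit = model.fit_partition(best_part)
    epi_lr = max(0.0, 2.0 * (best_fit.loglik - max(m1_fit.loglik, m2_fit.loglik)))
    epi_df = max(best_part.k - 2, 1)
    epi_p = float(stats.chi2.sf(epi_lr, epi_df))
    best.p_marginal1, best.p_marginal2, best.epistasis_p = p_m1, p_m2, epi_p
    if epi_p < config.epistasis_p_threshold:
        best.flags.add("passed_epistasis")
    return p_m1, p_m2, epi_p


def fit_variance_dependent(x, y, g1, g2, partition: GenotypePartition,
                           variant: str = "model6") -> CorrelationFit:
    """Functional wrapper for the variance/mean-dependent model variants."""
    return GenotypeCorrelationModel(x, y, g1, g2).fit_variance_dependent(partition, variant)
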
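# Methods

## Model

A module is a pair of expression traits (X, Y) plus a pair of biallelic
markers (m₁, m₂) in a haploid cross, genotypes coded 0/1.  Conditional
on the joint genotype, (X, Y) is bivariate normal with means fixed at 0,
both SDs fixed at a common σ, and a correlation that is constant within
each class of a *genotype partition* — an assignment of the four joint
genotypes {(0,0),(0,1),(1,0),(1,1)} to correlation classes.  The 15 set
partitions of four genotypes decompose into 1 null (k = 1 class), 2
marginal (classes determined by one marker), and 12 epistatic
partitions; the scan's alternative hypothesis space is the 12 epistatic
partitions.

Fixing means and SDs is deliberate.  Expression is first rank-normalized
per gene (Φ⁻¹(rank/(n+1)), average ranks for ties), which forces every
trait to mean 0 exactly and to a deterministic SD that depends only on
the non-missing count (≈ 0.9676 at n = 109; the conventional rounded
value 0.97 is used as the model σ).  Mean effects of genotype on single
traits are deliberately excluded from the model and actively filtered
out (the 1D filter below), because the target signal is co-expression
change, not expression change.  The cost of this restriction is that
modules whose correlation signal is entangled with genotype-dependent
means or variances lose power or are filtered; the variance- and
mean-freeing variants (`fit_variance_dependent`, "model6"/"model20")
exist to quantify that trade-off and show that on
constant-mean/variance data the fixed-parameter model has the better
power, which is why it is the scan's default.

## Estimation and testing

Per class with statistics n, S = Σ(x²+y²), P = Σxy, the log-likelihood
at correlation ρ is

  ℓ(ρ) = −n·ln(2πσ²) − (n/2)·ln(1−ρ²) − (S − 2ρP) / (2σ²(1−ρ²)),

maximized where n σ² ρ³ − P ρ² + (S − nσ²) ρ − P = 0.  The real roots of
this cubic inside (−1+ε, 1−ε), ε = 10⁻⁶, plus the interval endpoints are
compared on ℓ and the best is taken; when the empirical second moments
equal σ² the solution reduces to the Pearson correlation.  This
root-based route is deterministic, iteration-free, and is verified in
the tests against a grid-search oracle (step 10⁻⁴) to 10⁻³ in ρ and
10⁻⁵ in log-likelihood.

Each epistatic partition is tested against the null partition by the LR
statistic 2·(ℓ_alt − ℓ_null), clipped at 0, referred to χ² with
df = k_alt − k_null.  The partition with the smallest p-value is
selected; ties break toward fewer classes, then catalogue order.  The
min-over-12 selection is *not* analytically multiplicity-adjusted — the
permutation FDR of the full scan absorbs the selection, which mirrors
how the method is meant to be used (one nominal cutoff plus permutation
calibration).  Finally the selected model is compared against the better
of the two marginal models by a generalized LR at df = max(k − 2, 1); a
module is kept only if this epistasis test rejects.  When the selected
model fits no better than a marginal model the statistic clips at 0 and
p = 1 by construction, so the comparison reduces to the standard nested
test whenever the selected partition refines a marginal one.

**Known calibration property.**  At the panel sizes this method targets
(n ≈ 110–150, i.e. ~30 samples per joint-genotype class) the full
4-class LR against the null is slightly anti-conservative under the χ²(3)
reference: simulations at n = 120, common ρ = 0.3, σ = 0.97 give an
empirical rejection rate of ≈ 0.065 at nominal 0.05, decaying toward
0.05 with growing n (≈ 0.047 at n = 480).  This is a finite-sample
(Bartlett-type) property of the fixed-parameter homogeneity LR, verified
with an implementation-independent grid maximizer; it is precisely the
kind of miscalibration the permutation-based FDR absorbs, and it is why
the pipeline reports permutation FDR rather than trusting nominal χ²
levels.

## PA screen

Fitting ~10⁹ candidate modules is infeasible, so candidates are first
screened with the closed-form statistic

  PA = Σᵢⱼ nᵢⱼ · [ln(1 − r²) − ln(1 − rᵢⱼ²)],

where rᵢⱼ is the within-class and r the all-sample Pearson correlation —
the plug-in LR for correlation heterogeneity.  PA needs no iteration, is
symmetric in the traits, invariant to class relabelling, zero when every
class correlation equals the overall one, and sits on the same scale as
the model LR, which it exceeds for all but a calibrated tail of
candidates.  The cutoff is chosen from paired (PA, LR) values on
simulated modules as lr_threshold + q, with q the 0.005 empirical
quantile of PA − LR, bounding the screen's false-removal rate at 0.5%.
The default cutoff 45 corresponds to the stringent genome-wide LR
threshold of the yeast-scale analysis; a scan run at a laxer p-threshold
should re-calibrate (`epicoex calibrate-pa`).  The formula lives behind
a single function so an alternative screen can be swapped in.

## Pipeline defaults (units: samples, base pairs, probabilities)

| parameter | default | role |
|---|---|---|
| `sd_fixed` | 0.97 | model σ after rank-normalization at n ≈ 109 |
| `pa_cutoff` | 45 | PA screen, calibrated to the genome-wide LR threshold |
| `min_class_size` | 15 | minimum samples per joint-genotype class |
| `max_missing_per_gene` | 10 | gene filter (per condition) |
| `marker_merge_discordance` | 5 | pre-scan merge: "fewer than 5 discordant calls" |
| `module_merge_discordance` | 15 | post-scan locus merge for the epistasis map |
| `p_threshold` | 10⁻⁶ | LR significance cutoff (genome-wide scale) |
| `oned_p_threshold` | 10⁻⁵ | Wilcoxon single-trait linkage filter |
| `epistasis_p_threshold` | 0.05 | epistasis-vs-marginal test |
| `n_permutations` | 10 | permutation FDR replicates |

Marker merging walks each chromosome left to right, joining a marker to
the current group when its calls differ from the group's majority-vote
representative in fewer than the threshold number of samples
(bit-identical neighbours always merge, so threshold 0 collapses exact
duplicates only; majority ties take the left-most member's call).  The
1D linkage test uses the exact Wilcoxon distribution for tie-free splits
of ≤ 25 per side and the normal approximation otherwise.  Per module,
samples are those with both traits observed; class counts are recomputed
per module because up to 10 missing values per gene are allowed through.
Degenerate candidates (a class with zero expression variance or |r| = 1)
are dropped with a logged reason — the likelihood fit would equally
fail.  FDR counts *unique gene pairs* because linkage makes one 2D-trait
map to several neighbouring marker pairs; permutation seeds derive from
the config seed by a fixed counter so the replicates are reproducible.

## Synthetic data

The generator emulates a haploid biparental segregant panel: per
chromosome, the first marker is Bernoulli(0.5) and each subsequent
marker flips with the inter-marker recombination probability (a Markov
chain), giving the linkage that makes marker merging and
duplicate-module collapsing meaningful.  Background genes share an
exchangeable correlation via one latent factor and carry no genotype
dependence; planted modules draw (x, y) per sample from the class
bivariate normal, with optional per-class means/SDs for the power-study
variants (means-and-variances-independent, variance-dependent,
mean-dependent regimes).  Default trait SD is 0.97 so generated data
match the fitting assumption directly; rank-normalizing first changes
nothing material.

The bundled demo panel (150 segregants; four 3-marker chromosomes at
recombination 0.1; 14 background genes at ρ = 0.2; three planted
modules) covers the three qualitative epistasis patterns: a sign-
switching XOR module (ρ = ±0.75, no marginal signal at all — the case a
marginal-first forward search structurally misses), a single-class
module ((1,1): 0.9 vs −0.3 elsewhere), and a graded 3-class module
(−0.8 / 0 / +0.8).  Contrasts are set so the planted modules are
unambiguous at the default PA cutoff (Fisher-z contrasts ≈ 1.6–1.9,
expected PA ≈ 70–120 against the cutoff 45): the demo demonstrates the
cascade, not threshold luck.  What the demo does *not* emulate:
microarray noise, polygenic mean structure, hotspots, crossover
interference, or realistic gene-gene correlation topology — passing on
it shows the pipeline's plumbing and statistics are right at yeast-like
sample sizes, not that real-data power equals the simulated power.

Simulation sizes used by the acceptance script (10⁴ null modules for LR
calibration, 200 recovery replicates, 10⁴ mixed modules for the PA
bound, a 20-permutation demo null) balance Monte-Carlo error against
desk-scale runtime; each reported quantity carries its problem size.

## Downstream analyses

Significant modules are re-mapped onto loci merged at the looser
post-scan threshold, duplicates (same gene pair, same merged locus pair)
collapse keeping the smallest p.  The epistasis map counts modules per
locus pair; interaction profiles are binarized and clustered with
average-linkage Jaccard distance (both configurable — binarized-profile
clustering is what exposes groups of loci that co-target the same
modules).  Function-pair enrichment is an upper-tail hypergeometric test
over unordered annotation-term pairs (a gene contributes all its terms,
unannotated genes the term "unknown"; a pair with several term
combinations counts once per combination), Bonferroni-corrected over
the tested pairs.  Interval enrichment models per-interval hit counts as
independent hypergeometric draws from the annotated universe and
convolves the exact pmfs; with one interval this is exactly the standard
hypergeometric tail.  Independence across intervals is an approximation
(draws actually compete for the same universe) that errs conservative
for small intervals and is exact in the single-interval case.

## Design choices made where the design was open

* Expression missing values are representable; missing genotype calls
  are a validation error (segregant panels are completely genotyped, and
  this keeps class counting unambiguous).
* Merged-marker representative = per-sample majority vote (symmetric in
  the group, reproduces a run's consensus) rather than the first
  member's calls.
* The 1D filter tests each module gene against each of the two module
  markers only, not genome-wide: the scan must not discard a module for
  linkage to an unrelated locus.
* The forward-search comparator's stage-1 statistic is the marginal
  2-class LR from the same likelihood (df = 1), keeping both search
  strategies on one scale.
* The scan emits *every* evaluated module with stage flags, so filter
  attrition is auditable from the results table alone.
* Coordinates are 1-based inclusive base pairs; module identity is
  canonicalized by sorting gene ids and marker ids lexicographically so
  duplicate candidates collapse.

## Limitations

Two alleles, haploid; no covariates; no genotype-dependent means in the
main scan (an estimated ~13% of true modules carry mean effects and are
intentionally ceded to the 1D analysis); the χ² reference is mildly
anti-conservative at ~30 samples/class (see above), so nominal p-values
near a threshold should be read through the permutation FDR; interval
enrichment assumes independent intervals; clustering of small epistasis
maps is descriptive, not inferential.
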
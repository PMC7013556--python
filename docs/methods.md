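# Methods

This note documents the statistical models, the synthetic data they are
validated on, and the design choices made where the underlying study left
the procedure open.

## Differential expression

The design is a differentiation time course: log2 intensities for 8 days
(0–7), nominally 3 replicates per day. Fold changes are differences of
day-mean log2 values ("mean expression compared"), against two baselines:
day 0 and the previous day.

Per comparison, a moderated t-statistic shrinks the pooled per-gene
residual variance s²_g (df = n_a + n_b − 2) toward a prior:
s̃²_g = (d0·s0² + df·s²_g)/(d0 + df), t̃ = Δmean / (s̃·√(1/n_a + 1/n_b)),
with p from a t distribution on d0 + df degrees of freedom (normal when d0
is infinite). The hyperparameters (d0, s0²) are fitted by method of
moments on log s²_g: under s²_g ~ s0²·F(df, d0), the mean and variance of
log s² identify both parameters through digamma/trigamma functions
(trigamma inverted by Newton iteration). **Guard:** when the observed
spread of log s² does not exceed its expected sampling spread, the prior
is degenerate and d0 is set infinite with s0² = exp(mean). Forcing d0 = 0
recovers the ordinary pooled t exactly; forcing d0 = ∞ gives the
fixed-denominator normal test — both limits are asserted to 1e−12 in the
tests. With fewer than two replicates in a group the statistics are
reported unavailable (warning) and DE calling degrades to the fold-change
criterion alone.

BH adjustment is applied within one comparison family per day and
baseline. The DE rule — |log2FC| ≥ log2(2) **and** q < 0.1 — is read as
both conditions holding *in the same comparison*: a significance value
belongs to the comparison it was computed for, so pairing a day-3 fold
change with a day-5 q-value would be meaningless. The rule is monotone in
both thresholds (property-tested).

The constitutive-expression flag marks genes whose smallest day-mean
*linear* intensity (2^mean-log2, a geometric mean across replicates) stays
at or above `ratio` × background (default 4×), boundary inclusive.

The PPE-versus-rest fold-change contrast reports group means of the linear
maximal fold change and a Welch t-test on the log2 values; the exact test
used for this contrast in the motivating study is unstated, and Welch on
the log scale is the conventional choice.

## Fisher enrichment machinery

All enrichment questions reduce to a 2×2 table. The odds ratio is the raw
cross product ad/bc — undefined (NaN) when a margin is empty, and with the
Haldane–Anscombe +0.5 correction (flagged) when a single cell is zero.
The correction affects display only, never the p-value.

The exact p-value is computed from first principles: with both margins
fixed, the pmf numerators C(r1, x)·C(n−r1, c1−x) are integers, so the
two-sided point-probability rule (sum all tables whose probability does
not exceed the observed table's) involves only exact integer comparisons —
no floating-point tie ambiguity. The test suite checks agreement with an
independent Fraction-arithmetic enumeration to 1e−12 for every table with
n ≤ 30, and spot-checks scipy. Gene-set (GMT) enrichment defaults to the
one-sided enrichment tail and reports coverage (percent of the query set
annotated to the term); terms are intersected with the universe first and
dropped with a warning when disjoint. BH families are per call — per
chromosome set, per GMT collection, per module table — matching how such
analyses are reported.

## Co-expression modules

Profiles are the 8 day-mean log2 values per gene. Adjacency is unsigned by
default, a_ij = |r_ij|^β; a signed variant ((1+r_ij)/2)^β is provided.
**Why both:** temporal programmes come in mirror pairs (an up-regulated
and a down-regulated version of the same kinetics). Mirror-pair profiles
are perfectly anticorrelated, so under unsigned adjacency they are
mathematically indistinguishable from co-members and merge; the unsigned
default reflects the absolute-correlation convention used elsewhere in
this workflow, while the signed variant is the right tool whenever up and
down programmes must be kept apart. The module-recovery benchmark uses
the signed variant for exactly this reason; the noise-free exactness test
uses unsigned adjacency with three non-mirror archetypes.

The soft power β is the smallest integer in 1..20 whose connectivity
distribution fits a power law with R² ≥ 0.8 (log10 p(k) against log10 k
over ≥ 5 occupied degree bins); when no power qualifies — common with only
8 time points, where correlations are coarse — the conventional β = 9 is
used with a warning. TOM follows the standard unsigned formula
TOM_ij = (Σ_u a_iu·a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij), unit diagonal.

Clustering is average linkage on 1−TOM with a **static quantile cut**
(default: the 0.99 quantile of merge heights) instead of the dynamic
hybrid tree cut: deterministic, order-invariant, and sufficient for the
recovery tests. Clusters below `min_size` (30) are unassigned (grey).
Modules are numbered M1.. by decreasing size with the conventional module
color series. A module is *placental* when its one-sided Fisher enrichment
p for PPE genes is < 0.05 with OR > 1. With only 8 observations per
correlation, module claims rest on recovery benchmarks, not on inference
from the correlations themselves.

## HEC threshold and temporal clusters

The curve OR(t) crosses (max |log2FC| ≥ t) with the PPE flag on a grid
t = 0.1..4.0 (step 0.1) over all measured genes (a flag restricts the
universe to DE genes if desired). The automatic breakpoint is the first
grid step across which the OR grows ≥ `slope_factor`-fold (default 3);
the top of the jump is returned. A relative rule is used deliberately:
as the background stratum thins, OR curves climb geometrically, so
absolute increments grow steadily along the climb and an
absolute-difference criterion fires well before any breakpoint; a sudden
*multiplicative* jump is what singles the breakpoint out. Grid points
where more than 95% of genes lie above the cutoff are excluded from the
search: below the replicate-noise floor "above threshold" describes
essentially everyone and the OR is not an enrichment signal. A manual
override (default 2.5, the study's published threshold, ≈ 5.7-fold) always
wins; the automatic choice is logged beside it.

HEC trajectories (log2FC vs day 0, anchored with the day-0 zero so
flat-after-day-1 shapes keep a defined shape correlation) are clustered
with correlation distance (1 − r; scale-free, so amplitude does not move a
gene between clusters) and average linkage, cut to k = 5, and renumbered
C1..C5 by the time the cluster-mean |trajectory| first reaches half its
maximum — earliest response first.

## Regulatory networks

The TR co-expression network links every DE TR gene to every DE gene with
|Pearson r| ≥ 0.9 over the 8-day profiles (absolute value: inhibition is
as informative as activation); connectivity is the neighbour count. TR
timing splits DE TR genes by whether the DE rule first holds on day 1.

Footprint edges require a motif instance (BED name = TF) to overlap a
DNaseI footprint by ≥ 1 bp *and* to lie entirely inside the target's
promoter window, default −5000..+1000 relative to the TSS in transcription
direction (0-based half-open, reflected on the minus strand); the window
is a convention, exposed in the config. Multiple footprint files combine
by union (default) or intersection — how the motivating study merged its
two footprint sources is unknown, so both modes exist. Edges are then
annotated with the TF–target expression correlation and kept at |r| > 0.6
(strictly); TFs with no expression profile are counted and listed, never
silently dropped. Coverage reports give, per TF, the fraction of
placental-group and non-placental-group genes among its targets with flags
at ≥ 4% (both groups), ≥ 5% and ≥ 10% (per group).

The disease overlay takes a (gene, log2FC, FDR) table from a second
condition. The differentiation fold change of a gene is the signed log2FC
at its day of maximum |log2FC|. TR genes DE in both contexts are
discordant iff the two fold changes disagree in sign. Tightness of the
discordant set is its mean pairwise |r|, compared against `B` random
equal-size subsets of the DE TR genes; p = (#{null ≥ obs} + 1)/(B + 1).

## Pathway impact

Pathways are signed directed graphs (+1 activation, −1 inhibition;
compound edge types must be collapsed to ±1 upstream). The perturbation
factor solves PF = ΔE + B·PF with B[g,u] = β_ug/N_ds(u) (downstream-edge
normalisation), i.e. PF = (I−B)⁻¹ΔE; a condition number above 1e12 marks
the pathway non-evaluable — reported, never skipped. Accumulation
tA = Σ(PF − ΔE) is linear in ΔE, so the bootstrap uses the precomputed
weight vector w = 1ᵀ((I−B)⁻¹ − I): each null round places n_DE draws from
the observed DE fold-change pool on uniformly chosen pathway genes. The
null is median-centred (standard practice for this class of methods; the
centring is immaterial for symmetric nulls and guards against topology-
induced offset otherwise) and pAcc is two-sided with the +1 count
correction. pORA is the hypergeometric upper tail. The combination
pG = c − c·ln c (c = pORA·pAcc) is the exact tail of the product of two
independent uniforms (Fisher's method for two p-values); uniformity under
the null is Monte-Carlo-verified, and the full pipeline's type-I rate at
pG < 0.05 is checked to land in [0.03, 0.07] over 2000 simulated pathway
tests.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design: 8 integer days × 3 replicates,
log2 baselines uniform in [6, 12], and additive Gaussian replicate noise
(default SD 0.25 log2 units). Planted modules follow four archetypes —
flat; immediate-transient (full response day 1, half day 2, gone from day
3); immediate-persistent (step at day 1); slow-persistent (linear rise
over days 0–5, then held) — each in up and down versions, scaled by
log-normal amplitudes (default mean 1.5 log2 units, log-SD 0.5). PPE
labels are drawn per module (placental-style slow modules get 10–20×
higher fractions) with amplitudes from a distribution of twice the mean,
so PPE genes have larger fold changes by construction; PPE genes are also
biased 4:1 toward one designated chromosome ("chr19"). TR labels are
uniform at 12%. The disease table gives planted flip genes (a subset of
TR genes with solidly detectable amplitude) a fold change of opposite
sign at low FDR, a fraction of the remaining DE TR genes concordant
changes, and everything else non-significant values.

The **breakpoint mode** (`ppe_breakpoint`) is a purpose-built
parameter-recovery benchmark rather than a portrait of real data: module
amplitudes follow an exponential truncated at the breakpoint, so the
enrichment OR grows at a steady geometric rate up to a sharp cliff, and
half of the PPE genes carry a slowly decaying boost above it. The
benchmark runs at replicate SD 0.05 because the per-gene maximum of seven
noisy fold changes is upward-biased by roughly 1.35 standard errors, which
at the default noise level would shift the apparent cliff by about two
grid steps — the benchmark measures the selector, not that bias.

Passing these tests shows the machinery recovers what was planted under
the stated noise; it does not certify performance on real arrays, which
add probe-level artifacts, normalisation residuals, batch structure,
correlated noise and non-archetypal kinetics that the generator
deliberately omits.

## Problem sizes and numerical conventions

The test suite simulates 1 000–3 000 genes (module recovery: 2 000 genes,
5 modules, 20 seeds; FDR calibration: 20 × 400 null genes; impact
calibration: 2 000 pathway tests at 400 bootstrap rounds), sizes at which
every stage's behaviour is already asymptotically stable while the whole
suite runs in well under a minute. Other conventions: correlations are
clipped to [−1, 1]; constant profiles are dropped from correlation-based
steps with warnings; BED intervals are 0-based half-open; all randomness
flows through explicitly passed seeds or `numpy` Generators, and reruns
with equal seeds are byte-identical.

## Known limitations

* The nine-module, five-cluster structure of the motivating study depends
  on its real dataset; the pipeline reproduces the *procedures* and their
  parameter defaults, not those dataset-specific counts.
* Correlations over 8 day-means carry little sampling information; module
  and network edges should be read as descriptive structure.
* The static tree cut can split one planted module at high noise instead
  of shaving stragglers, which the dynamic hybrid cut handles better.
* The moderated-t moments fit assumes a common replicate design across
  genes (no per-gene missingness).
* Footprint edge mapping is interval arithmetic only; it does not score
  motif affinity or footprint depth.
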
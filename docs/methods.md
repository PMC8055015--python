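# Methods

This note records the statistical models the package implements, the
defaults that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Site identity and coordinates

All coordinates are 0-based, half-open; a splice site is identified by
`(chrom, pos, strand, kind)` where `pos` is the exon/intron boundary on
the intron side. Shifts are signed distances from maSS to miSS in
transcript orientation (genomic difference, negated on the minus strand),
so a `+4` donor shift means the minor donor sits 4 nt into the intron. A
donor miSS downstream of its maSS, or an acceptor miSS upstream, is
intronic (an insertion at the protein level); otherwise exonic (a
deletion).

## Catalogue rules

A site is *expressed* when at least 3 split reads support it in each of
two or more samples from at least two distinct tissues, counting only
junction records with offset entropy ≥ 1.5 bit (low-entropy stacks are
characteristic of mis-alignment). When no entropy is provided the filter
passes everything and warns — entropy is a property of the upstream
junction caller, not recomputable here. A site whose expressing samples
are a non-empty subset of the samples carrying a germline variant within
the site or 35 nt of adjacent exon is removed as an alignment artifact.
Clusters are maximal chains of same-kind, same-strand sites with
successive gaps ≤ 30 nt (`|Δpos| ≤ 30`, endpoints inclusive); clusters
larger than 5 sites or with no expressed member are flagged rather than
deleted, so pre- and post-filter counts are both reportable. Ranking uses
pooled read counts; ties go to the transcript-upstream site, a
deterministic choice consistent with upstream sites being the stronger
ones on average. Aggregated phi is computed from summed counts, not
averaged per-sample phi, matching the count-level models downstream.

## Zero-inflated Poisson significance model

Per tissue, `r_miSS | r_maSS ~ ZIP(lambda, pi)` with
`log lambda = log a0 + a1 log r_maSS` and `logit pi = b0 + b1 r_maSS`.
The fit is direct maximum likelihood (statsmodels'
`ZeroInflatedPoisson`), started from a Poisson log-log regression for
`(a0, a1)` and the excess-zero fraction for `(b0, b1)`, with BFGS →
L-BFGS → Nelder-Mead fallback; non-convergence flags the tissue and
suppresses its calls. Pairs with `r_maSS = 0` are excluded (the log
covariate is singular there) and receive no P-value.

The P-value is implemented in two tail conventions. The default
evaluates the CDF at the observed count, `P = P(X > r)`; this is the
printed form of the model but is anti-conservative for discrete counts
(for small lambda, a single stray read yields `P ≈ lambda²/2`).
`inclusive_tail=True` evaluates at `r − 1`, giving the standard
super-uniform `P(X ≥ r)`; null-calibration checks use this convention,
because only it makes "FDR below nominal under the fitted null" a
meaningful property. With it, resimulating from a fitted null yields
essentially zero significant calls at q < 0.05 ∧ phi > 0.05.

At n = 5000 pairs the maximum-likelihood estimates of `a0, a1, b0` carry
relative standard errors of roughly 5%, 1% and 5%; `b1` (the inflation
slope, ~5e-4) carries ~20% — a power fact worth knowing before
interpreting small fitted `b1` values.

## Storey q-values

`tasscat.qvalue` implements Storey's procedure with the cubic-smoother
pi0 estimate over a lambda grid (0.05…0.90). Two adjustments handle
discrete, range-bounded p-values such as the ZIP tail probabilities,
whose maximum attainable value can sit well below 1: lambda points at or
beyond the largest observed p-value are dropped (their empty tails would
drag the smoother to zero and make every test significant), and the tail
width is measured relative to the attainable range `[0, max(p)]`. Both
reduce to the classic estimator when p-values span [0, 1]. With fewer
than four usable lambda points the median-of-grid estimate replaces the
smoother. `pi0 = 1` reproduces Benjamini-Hochberg exactly.

## Tissue-specificity model

A single joint model with one dummy slope per tissue is perfectly
collinear (`Σ_t D_t·r_maSS = r_maSS`), so the package fits one
one-vs-rest regression per tissue: ordinary least squares of `r_miSS` on
`{r_maSS, D_t·r_maSS}` through the origin, two-tailed t-test on the
deviation slope `a_t`. Heteroscedasticity of counts is acknowledged and
not modelled — the estimator stays faithful to the stated model. The
effect size is `dphi_t = a_t / ((1+a0+a_t)(1+a0))`, algebraically equal
to `phi_t − phi_bar`; both denominators must be positive, otherwise the
record is flagged undefined. One consequence of one-vs-rest fitting worth
knowing: a strong deviation in one tissue contaminates the "rest"
baseline of the other fits for the same miSS, so a truly brain-up miSS
can echo as weakly-down calls in other tissues. Cell-type and
tissue-of-origin analyses reuse the same code path with the grouping
label swapped. Sample-level phi profiles zero out entries where neither
count exceeds 20 reads before Pearson-correlation comparisons; q-values
for specificity are computed over the supplied (already
significance-filtered) miSS × tissue table.

## Regulatory triples

Knockdown responses must be significant (q < 0.05), substantial
(|dphi_KD| > 0.05) and sign-concordant in both K562 and HepG2 to count;
the discordant fraction is reported. RBP tissue specificity requires
q < 0.05 and |log2FC| > 0.5. Triples are the inner join of
(miSS, tissue), (RBP, tissue) and (RBP, miSS) keys; a triple is
co-directed iff `sign(dphi_t)·sign(dRBP_t)·sign(dphi_KD) = −1`, and a
zero in any delta (unreachable after thresholds) excludes the triple.
The excess of co-directed triples is a one-tailed exact binomial test at
p = 1/2. eCLIP peaks are kept at log2FC ≥ 3 and P < 0.001, unioned
across replicates and cell lines by interval merge per (RBP,
chromosome), and a miSS is supported when `[pos − 20, pos + 20]` overlaps
a same-RBP peak (closed-interval overlap); co-enrichment among supported
triples is a one-tailed Fisher test. Overexpression-vs-knockdown
contrasts keep events passing q and |dphi| thresholds in either arm,
report both Pearson and Spearman correlations (the choice is genuinely
open), and split proximal/distal at |shift| < 5 nt.

## Selection statistic

Donor windows are the intronic positions +1..+6 (GT obligate, +3..+6
analysed); acceptor windows are −24..−1 (AG obligate, −24..−3 analysed),
all in transcript orientation. A base is consensus (Cn) at a position iff
its frequency among constitutive sites is ≥ 0.35 (configurable; the
window between "single most frequent base" and "any common base" is a
genuinely open definition, and 0.35 keeps near-ties like a 0.60/0.34
split classified asymmetrically, which the threshold makes explicit).
Maps built from fewer than 100 sequences are refused.

Ancestral states come from parsimony over (human, marmoset, galago):
ingroup agreement wins, otherwise the outgroup resolves, otherwise the
position is excluded. Substitutions are counted on the marmoset lineage
by default (counting on the human lineage, available via `lineage=`,
ascertains towards the human state and distorts both tails). Only sites
with canonical GT/AG in all three genomes are counted. Each unambiguous
ancestral base at an analysed position is one opportunity of its class;
a lineage substitution landing in the opposite class is one observed
event; the expected count is the sum over opportunities of background
substitution rates into the opposite class.

Background rates can be pooled per ancestral base or stratified per
(window position, ancestral base) (`per_position=True`). Stratification
matters: parsimony misreconstruction (convergent substitutions on the
human and outgroup branches) inflates apparent rates in proportion to
the local abundance of the competing base, so pooling across positions
mixes that inflation with position-dependent class membership and biases
O/E downward by 2–3% under neutrality — enough to break interval
coverage at realistic set sizes. With a position-stratified background
of matching composition, neutral simulations give mean O/E 1.002 and
95%-CI coverage of 96% over 200 replicates of 20,000 sites, and an
injected selection intensity of 0.5 is recovered as O/E ≈ 0.52.

The confidence interval inverts the score statistic for a ratio of two
binomial proportions (Koopman-type), with the constrained MLE obtained
from the closed-form quadratic and the bounds found by bracketed root
finding; zero numerators give a zero lower limit, zero background counts
an infinite upper limit, and non-integer (effective) counts are valid
input since the statistic is algebraic. The background side enters as an
effective binomial sample size computed by the delta method over the
(position, base) strata, so the interval reflects the true information
content of a stratified rate estimate.

Strength matching samples, for each target site, one control uniformly
among unused pool sites within 0.01 of its PWM log-odds strength,
visiting targets in random order; unmatched targets are reported, not
silently dropped.

## Mixture model for the noisy fraction

A category of k sites is modelled as `alpha·k` sites drawn from the
negative set (cryptic-like, neutral) plus `(1−alpha)·k` from the positive
set (constitutive-like, selected). For every alpha on a grid (default
step 0.0033) the package draws B (default 300) subsamples — without
replacement when the source sets allow, otherwise with replacement and a
warning — and records their O/E, building the joint (alpha, O/E)
distribution. Conditional 2.5/50/97.5% quantiles of alpha within a margin
eps of the observed O/E are computed over the margin grid
(0.025…0.5, step 0.005) and extrapolated to eps → 0 by a least-squares
line, clamped to [0, 1].

Two guards stabilise the extrapolation when the O/E spread of the mixture
is small relative to the margin grid (the desk-scale regime: pure-set O/E
differ by ~0.76 and resample O/E scatter is ~0.05). Margins whose window
captures more than half of all resampled points are no longer selective —
their quantiles drift towards the unconditional alpha distribution and
drag the fitted intercept inward — and are excluded from the fit. And
because the quantile-vs-margin curves flatten as eps → 0, a linear
intercept systematically overshoots the narrowing, so the reported
interval is never narrower than the quantiles at the smallest informative
margin. Measured on 51 seeded mixtures at true alpha ∈ {0.2, 0.5, 0.8}
(k = 2000, B = 100, grid 0.01), interval coverage is 80% without the
guards and ~94% with them.

## Synthetic generators

`SimConfig` holds the study conditions: ZIP parameters
(0.05, 0.9, −1, 5e-4), log-normal maSS counts (mu = 4, sigma = 1.5 on the
log scale — the heavy right tail junction pools actually show; the model
needs several orders of magnitude of `r_maSS` to identify `a1` and `b1`),
8 tissues × 10 samples, shift distributions concentrated at ±4 (donor)
and ±3 (acceptor), a 163/256 co-directed fraction for regulatory truth
tables, and a substitution process with per-branch rate 0.06, a 2×
outgroup branch, and a selection multiplier `s` applied to
consensus-breaking changes at analysis positions. Each generator draws
from its own RNG stream derived from `(seed, stream tag)`, so outputs are
reproducible and mutually independent.

What the generators do *not* emulate: read-level artifacts (mapping bias,
duplicate stacks), donor-level covariance between samples, correlated
substitution processes along a window, gene-structure realism beyond what
the filters exercise, and real eCLIP peak shapes. Passing tests therefore
demonstrate that the estimators recover the effects they model, at the
stated sizes — not that those models capture every property of GTEx- or
ENCODE-scale data.

## Problem sizes used in the checks

The shipped acceptance checks run the neutrality calibration at 200
replicates of 20,000 sites with 30,000-site backgrounds, the mixture
coverage at k = 2000 with B = 100 and grid step 0.01 over ~50 seeded
repetitions, and the ZIP recovery at n = 5000 — sizes chosen so the full
suite completes on a single CPU in minutes while keeping Monte-Carlo
error well inside the asserted tolerances.
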
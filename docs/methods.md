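# Methods

This note documents the models, conventions and numerical choices behind
each `flymeio` component, what the synthetic-data generators do and do
not emulate, and the known limitations.

## Crossover scoring

A backcross progeny is a single recovered chromatid phenotyped at an
ordered set of recessive markers. Calls are abstracted to binary
parental (`P`) / recombinant (`R`) at ingest; dominance relationships of
the actual markers are out of scope. A crossover is a phase switch
between consecutive **non-missing** calls. Conventions:

- An interval is flagged recombinant only when the switch's flanking
  non-missing calls sit at the interval's own endpoints. A switch that
  spans two or more intervals because of a missing call is counted once
  in the chromatid's crossover count but assigned to no interval
  (conservative: class tallies are preserved, interval tallies are not
  inflated by guesses).
- Male progeny are rejected with a logged warning by default (in the
  standard cross only females are informative); `allow_male=True`
  overrides for other designs.
- Two crossovers inside one interval are undetectable by flanking-marker
  phenotyping. This is a known downward bias of the method itself, not
  of the implementation, and the simulator reproduces it (below).
- Map lengths are 100 × recombinants / N per interval (cM); the total is
  the arithmetic interval sum. When no calls are missing this equals
  100 × mean crossovers per chromatid. Tables display one decimal; full
  precision is carried internally.

Between-genotype interval comparisons use Fisher's exact test (two-sided,
point-probability-sum convention; `scipy.stats.fisher_exact`).

## Weinstein tetrad analysis

Model: tetrads carry *n* exchanges with frequency *E<sub>n</sub>*; with
no chromatid interference each exchange involves the single recovered
chromatid independently with probability ½, so
f<sub>k</sub> = Σ<sub>n≥k</sub> E<sub>n</sub> C(n,k)/2<sup>n</sup>.
The no-chromatid-interference assumption is the classical one and is the
load-bearing assumption of everything in this module.

Two estimators:

1. **Direct inversion** — back-substitution of the upper-triangular
   system, highest rank first. It is exact on exact fractions but may
   produce negative E values on sampled data; the result carries a
   `valid` flag and is never silently clipped.
2. **Constrained MLE** — EM with the latent tetrad rank: responsibilities
   P(n|k) ∝ E<sub>n</sub>C(n,k)/2<sup>n</sup>, update
   E<sub>n</sub> = (1/N)Σ<sub>k</sub> c<sub>k</sub> P(n|k). The
   log-likelihood is non-decreasing at every step. When the inversion is
   non-negative the MLE equals it (interior optimum); otherwise the MLE
   lies on the simplex boundary.

Numerical choices: uniform initialisation over ranks 0..max_rank;
convergence when the log-likelihood improves < 1e-12 **and** parameters
move < 1e-10 (max-norm); iteration cap 10⁵ (the problem is tiny, tight
tolerances cost nothing). EM approaches a boundary optimum only
sublinearly, so after the loop any E<sub>n</sub> < 1e-4 is snapped to
zero and renormalised **iff** that does not decrease the likelihood; an
EM fixed-point check at the snapped vector then certifies convergence.
Boundary fits (any E<sub>n</sub> = 0) raise a warning because boundary
mixtures can be non-identifiable (e.g. all-SCO data); the reported fit
is EM's limit point from the uniform start, with no further tie-break.
`max_rank` defaults to the highest observed crossover class. Reported E
values display four decimals; full precision is retained.

Uncertainty: nonparametric bootstrap (multinomial resampling of the N
chromatids, percentile intervals per rank), vectorised across replicates
and deterministic under a fixed seed. Single-class data collapse the
intervals to a point and are flagged.

Total map length from classes is 100 × Σ k·c<sub>k</sub>/N. Note that on
real tables the interval-sum total and the class-count total can
disagree when records with missing calls contribute switches that no
interval receives; both numbers are reported and not reconciled.

## Nondisjunction assay

Diplo-X and nullo-X exceptional progeny each represent two exceptional
meioses because the reciprocal products die; hence
adjusted = regular + 2×exceptions, NDJ % = 100·2X/adjusted, and
progeny-per-female = adjusted / parent females (the adjusted total is an
unbiased count of scored meioses under the model).

The significance test is a declared Monte-Carlo test under that
generative model: each of the adjusted-total meioses is exceptional with
the pooled rate, exceptional meioses are recovered with probability ½,
and the statistic is the difference of estimated rates. Two-sidedness
doubles the smaller MC tail (capped at 1, with the +1 finite-sample
correction). The two simulation streams are assigned after canonically
ordering the tallies, making the p-value symmetric in its arguments; the
default is 10⁵ replicates with a mandatory seed in the CLI. An analytic
Wald test (delta-method variance of 2X/(2X+R) under the trinomial
meiosis outcome) is provided as a secondary approximation. Measured
type-I error of the MC test at α = 0.05, n ≈ 1000 meioses per group and
a 1 % true rate is ≈ 0.06 (the discrete pooled-null plug-in is slightly
anti-conservative at these counts).

## Germarium screen and foci statistics

Defect labels are assigned per category when the defective fraction over
germaria with a non-missing flag is **≥ 0.5** ("at least 50 %" is read
inclusively), with a hard minimum of 10 scorable germaria. Missing flags
are excluded from that category's denominator rather than imputed —
visual scoring routinely skips obstructed nuclei. Rules: SC assembly
defect = no robust full-length SC in region 2A; SC maintenance defect =
full-length SC not retained at the region-3 nucleus; DSB initiation
defect = no γH2Av foci in 2A; DSB repair defect = γH2Av foci persisting
in region 3; underdeveloped per its own flag.

Mann–Whitney U uses the exact permutation distribution (midranks for
ties) when n₁+n₂ ≤ 16, else the normal approximation with tie and
continuity corrections; results use the min-U convention and two-sided
p, with `*`/`**` annotations at 0.05/0.01. The normal approximation is
within 0.02 of the exact p for groups of ≥ 5 without heavy ties; below
that it can deviate by ~0.03, which is why the exact path exists.
Foci summaries are sample mean, SD (n−1) and N, displayed as
`mean (+/-sd) N=n` at one decimal.

## Proximity enrichment (dNSAF)

Distributed counts d<sub>i</sub> = u<sub>i</sub> + Σ<sub>g</sub>
s<sub>g</sub>·u<sub>i</sub>/Σ<sub>j∈g</sub>u<sub>j</sub> (a group's share
is dropped in samples where every member has zero unique counts), then
dNSAF<sub>i</sub> = (d<sub>i</sub>/L<sub>i</sub>)/Σ<sub>j</sub>(d<sub>j</sub>/L<sub>j</sub>).
Each sample's dNSAF sums to 1 and is invariant to rescaling that
sample's counts.

Enrichment calls use the dual strict threshold log₂FC > 2 **and** Z > 5.
The Z statistic is a deliberately simple moderated two-sample statistic
on log₂(dNSAF + ε): pseudocount ε = half the smallest nonzero dNSAF
across the supplied samples; per-protein pooled variance floored at the
10th percentile of positive pooled variances (with only two replicates
per condition, raw variance estimates are far too noisy to divide by).
This is **not** a re-implementation of QPROT's Bayesian model and will
not reproduce its Z values; it is a transparent substitute sharing the
thresholds' intent. Proteins absent from a condition get dNSAF 0 (then
ε); no imputation. Replicate dNSAFs are averaged on the raw scale for
the fold-change and on the log scale for Z. Upstream FDR filtering of
the search results is assumed done.

## Synthetic-data generators

All generators are bit-reproducible given (config, seed); a single
global seed fans out to named substreams via
`SeedSequence([seed, stream_id])` with frozen stream ids, so stages
never share a stream.

- **Progeny** — rank n ~ E; Binomial(n, ½) exchanges transmitted;
  transmitted exchanges assigned to intervals ∝ interval weights,
  independently (no interference, matching the estimator's assumption);
  an even number of exchanges in one interval cancels in the phenotype,
  reproducing the scoring method's undetectability. The starting phase
  is random. Because of the cancellation rule, observed class fractions
  sit slightly below the forward model when weights are concentrated
  (with the chr-2 control weights the shift is ≈ 1.3 % of mass from DCO
  to NCO); with evenly spread weights the bias is well under 1 %.
  Defaults follow the study conditions: N = 1721, control-like E and
  interval weights proportional to the control cM values.
- **NDJ** — Poisson broods per female (`mean_brood` = expected scored
  meioses per female), exceptional meioses with probability `p_ndj`,
  recovery of exceptions with probability ½ split evenly diplo/nullo.
- **Foci** — negative-binomial counts moment-matched to the configured
  (mean, SD), falling back to Poisson with a warning when SD² ≤ mean;
  the packaged calibration carries the published per-region means/SDs
  for both γH2Av foci and CID clusters. The published tables' raw
  per-nucleus counts are not available, so these moments serve as
  generator calibration, not as reproduction targets.
- **Spectral counts** — Poisson counts with rate ∝ protein length ×
  gamma-distributed abundance × condition fold-change; defaults of 500
  background + 20 spiked proteins at 8-fold, two replicates per
  condition, ~50 expected counts per background protein, and 5 % shared
  pair-groups give a realistic desk-scale table on which the published
  thresholds recover ≥ 18/20 spiked proteins with ≤ 2 false calls.

What the generators do **not** emulate: crossover interference, viability
differences among marker classes, region-dependent brood structure,
peptide-level identification noise, or correlated protein abundances.
Tests passing on these simulators therefore validate the estimators
under their own assumptions, not the assays' robustness to violations of
those assumptions on real data.

## Problem sizes

The test suite runs the heavier consistency checks at deliberately
desk-scale sizes chosen to keep Monte-Carlo error well inside each
assertion band: 200 simulated datasets of N = 1721 chromatids for tetrad
recovery, 1000 null tally pairs × 10⁴ MC replicates for the NDJ test's
type-I error, 10⁵ progeny for the forward-model convergence check, and a
520-protein spectral table for spiked recovery.

## Known limitations

- The tetrad model is wrong in the presence of chromatid interference;
  no interference diagnostics are provided.
- Interval-level double crossovers are invisible to the scoring method;
  reported interval cM therefore underestimate long intervals.
- The NDJ MC test's pooled-null plug-in is mildly anti-conservative at
  small exception counts (see above).
- The enrichment Z is a simplified statistic; absolute Z values are not
  comparable to QPROT's, only the threshold semantics are analogous.
- The packaged NDJ tallies reconstruct unpublished diplo/nullo and
  female/male splits evenly (file and loader are labelled synthetic);
  the published adjusted totals and one-decimal NDJ percentages are
  reproduced exactly.
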
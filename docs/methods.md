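# Methods

## The problem

Tumor genomes accumulate somatic copy-number alterations (CNAs). Most are
*sporadic* passengers private to single samples; the interesting ones are
*recurrent* — hitting the same locus in many tumors — because recurrence
beyond chance marks candidate driver loci. Given a cohort's segmented copy
number profiles (an N samples x M probes matrix of log2 ratios versus the
diploid baseline), the package identifies Significant Copy Number
Aberrations (SCAs): loci whose cross-sample aberration burden exceeds what
a positional-permutation null of sporadic CNAs explains. Upstream
normalization and single-sample segmentation (e.g. CBS) are out of scope;
the input is their output.

## Model and procedure

**Thresholding.** The matrix is split by an indicator into an
amplification matrix (entries >= theta_amp > 0, else 0) and a deletion
matrix (entries <= theta_del < 0, else 0). The two tails are analysed
completely independently; no cross-tail multiplicity correction is
applied.

**CNA units.** A probe altered in at least one sample is a CNA probe.
Maximal runs of consecutive CNA probes (never crossing a chromosome
boundary) form CNA regions. Within a region, a breakpoint is declared
between adjacent probes whose cross-sample Pearson correlation (sample
s.d., divisor N-1) falls below theta_rho, or is undefined (zero variance);
the region is cut at every breakpoint. The resulting CNA units u(k, L) —
start k, length L — partition the CNA probes and are the elements that get
scored and tested. Correlation is computed on the thresholded values,
zeros included, because the zeros of unaltered samples carry the
recurrence-frequency signal.

**U score.** U_{k,L} is the grand mean of the unit's N x L thresholded
block. It rises with both the amplitude of the alterations and the
fraction of samples carrying them.

**Permutation null.** The null hypothesis is that CNA placement is
positionally random within each sample. T permuted datasets are drawn by
relocating each sample's CNA segments — the maximal contiguous nonzero
runs of that sample's row — to uniformly random start positions, rows
independently, within the permitted span (the segment's own chromosome
under `scope="chromosome"`, any chromosome it fits in under `"genome"`).
A row's segments are placed at mutually disjoint positions (sequential
rejection in random placement order), so every relocated segment, and
therefore every observed unit, survives intact in every permuted dataset.
For each permuted dataset and each observed unit length L, the maximum
(amplification) or minimum (deletion) U score over *all* L-wide windows in
the scope is recorded. The observed unit's empirical P-value is

    P = (1 + #{t : extremum_t beats U_obs}) / (T + 1),

right tail for amplifications, left tail for deletions, ties counted as
beats. Taking the extremum over window positions adjusts the P-value for
the genome-wide multiplicity of locations at that length; the per-length
nulls adapt to the different background rates of short and long units.

**Iterative re-estimation.** True SCAs participate in the permutations and
inflate the null, hiding weaker recurrent signal. The iterative procedure
calls units with P <= alpha' = alpha/(1+alpha), masks the called units'
columns to zero, and repeats on the masked matrix (units are re-used, not
re-defined) until an iteration produces no new call. Because iteration r's
calls are conditional on iteration r-1 having called something, the
procedure-wide false-positive rate is the geometric series
sum_r alpha'^r = alpha'/(1-alpha') = alpha — alpha' is exactly the
per-iteration level that makes the cascade hit the targeted alpha.
Finally, every call's P-value is re-computed under the *truth-converging*
null: fresh permutations of the fully masked matrix, in which only
presumed-sporadic signal remains. The call set is not re-thresholded after
this re-computation (calls are conditional by design); the re-computed
P-values are the reported ones and are mutually comparable because they
share one null.

## Parameters

| name | meaning | default | notes |
| --- | --- | --- | --- |
| theta_amp / theta_del | log2-ratio thresholds defining altered probes | 0.263 / -0.322 (2.4 and 1.6 copies) | focal analyses of noisier cohorts; simulation runs use +/-0.1 (`simulation_params`) |
| theta_rho | adjacent-probe correlation needed for unit coherence | 0.95 (real data), 0.75 (simulations) | segmented data has within-segment correlations near 1; 0.7–0.95 is the useful range |
| permutations (T) | permutation count per null estimate | 1000 | P-value floor is 1/(T+1) |
| alpha | targeted family-wise false-positive rate | 0.05 | per-iteration threshold is alpha/(1+alpha) |
| scope | relocation span and window-extremum span | chromosome | genome-wide available; identical on single-chromosome data |
| collision | segment collision handling during placement | reject | `overwrite` lets later placements clobber earlier ones; it loses segment mass at high CNA density and makes the null anti-conservative, so it exists for comparison only |
| atoms | relocation atoms | runs | `units` relocates per-(unit, row) blocks instead; measured nearly identical in power but with worse null-data error control (see below) |
| max_iterations | safety cap on the masking loop | 50 | the unit set strictly shrinks, so this is a guard, not a tuning knob |

X and Y probes are analysed separately from autosomes by the pipeline
(`split_sex`), reflecting their distinct CNA background.

## Synthetic data

Three generator families provide ground truth; all use the tumor/normal
mixture c = 2 lambda + (1 - lambda) copy, reported as log2(c/2), with
lambda the per-sample normal-cell fraction and c floored at 0.05 copies so
homozygous deletions stay finite.

* **Null model** (`NullSimConfig`): each of N samples carries
  Uniform{2..10} sporadic units, lengths Uniform{10..50}, placed
  disjointly and uniformly within the sample; half deletions (copies
  {0,1}), half amplifications (copies {3..8}); lambda ~ U(0.2, 0.8).
  Defaults are N=20, M=1000. `clump_fraction` confines that fraction of a
  sample's units to one random window — sized max(10% of the span, 1.3x
  the clumped mass) so disjoint packing stays feasible — inducing
  within-sample positional clustering with no cross-sample enrichment. The
  generator emulates *segmented* input and is therefore piecewise constant
  with no per-probe noise: segmentation removes probe-level noise upstream,
  and adding it back would fragment the defined units far below the
  generative segment lengths.
* **Power model** (`PowerSimConfig`): M=5000; per sample one sporadic
  deletion and one sporadic amplification (lengths Uniform{150..250},
  disjoint, avoiding the recurrent intervals); per dataset one recurrent
  deletion and one recurrent amplification interval, fixed position,
  carried by a Bernoulli(omega) subset of samples with per-carrier copy
  draws; lambda ~ N(mu_lambda, sigma_lambda) truncated to [0, 1]. No extra
  probe noise (segmented input).
* **ROC model** (`RocSimConfig`): N=50, M=5000; truth SCAs of lengths
  {30, 20, 10} (amplification, copies 3, 4, 5) and 20 (deletion, copies
  {0, 1}) at frequency omega * beta_omega with lengths scaled by
  beta_length; per sample 2–10 background CNAs (lengths 10–50, disjoint);
  lambda ~ U(0.2, 0.8); zero-mean Gaussian probe noise with a per-sample
  s.d. drawn from one of the tiers U(0.2,0.4), U(0.4,0.6), U(0.6,0.8).
  This family deliberately violates the segmented-input assumption to
  stress probe-level ranking; it is evaluated by probe-level TPR/FPR, not
  by calibrated error control.

What passing tests on these generators do *not* show about real data:
real segmented profiles have chromosome-specific background rates,
wave/GC artefacts, arm-level events spanning whole chromosomes, and
correlated breakpoints across samples at fragile sites — none of which the
generators emulate.

## Evaluation metrics

FWER is the fraction of null datasets with at least one call at the given
alpha. Power counts a truth interval as detected when a call of the
matching tail overlaps it by at least one probe; per-tail rates are
reported together with their mean, and boundary accuracy (mean absolute
start/end error of the merged overlapping calls, in probes) is reported
but not thresholded. Detection-rate comparisons against the reference
power table use the amplification rate: under the mixture model deletion
log-ratios are bounded (c >= 2 lambda, so with copies in {0,1} the signal
cannot exceed ~|log2 lambda|) and high-contamination carriers are censored
at theta_del entirely, which makes deletion detection systematically
weaker than amplification detection at the same omega; the reference
table's values are only consistent with the amplification rate. ROC
curves are probe-level: a probe's score is the final P-value of the unit
covering it, swept over all achievable P levels; the internal baseline
scores each probe by the fraction of samples beyond the threshold
(frequency only, no amplitude, no significance model).

## Numerical choices

* Window sums use prefix sums over column sums; the compiled scan and the
  numpy reference agree to 1e-12 and both are validated against direct
  window enumeration.
* Eq.-style tie counting (`>=`) uses a 1e-9 relative guard band so the
  structural tie — a relocated segment exactly reproducing its own window
  sum — cannot be flipped by summation-order round-off.
* Per-permutation placement draws come from one 32-bit seed per
  permutation (an independent substream), the seed vector being a prefix-
  stable draw from the build-level generator: increasing T extends the
  stream without reshuffling earlier permutations.
* The two tails share per-iteration seed streams and the deletion branch
  runs the amplification code path on the negated matrix, so deletion
  analysis of -X reproduces amplification analysis of X exactly.
* Non-overlap placement retries up to 100 draws per segment and then falls
  back to an additive placement (no mass is ever lost); the fallback is
  unreachable in practice below ~60% per-row CNA coverage.
* Zero-variance probe pairs have undefined correlation and are treated as
  breakpoints (an undefined correlation cannot certify coherence), giving
  length-1 units.
* Degenerate inputs: an all-zero tail yields no units, no calls and an
  empty null; a unit longer than every permitted span is a configuration
  error.

## Open design choices and their resolutions

* **Relocation atoms.** Relocating per-(unit, row) blocks tears a sample's
  contiguous segment wherever cross-sample breakpoints cut through it,
  which contradicts the requirement that the permutation preserve
  within-sample correlation structure, and measurably thins the null's
  upper tail. The default therefore relocates each sample's maximal
  contiguous runs; the block variant remains available (`atoms="units"`).
  Head-to-head at matched seeds the two differ by 2–4 points of power,
  while null-data FWER is 0.10–0.13 (runs) versus 0.19–0.21 (units) at
  alpha = 0.05.
* **Collision handling.** Disjoint (rejection) placement is the default
  because overwriting loses relocated mass whenever units are dense,
  biasing P-values anti-conservatively.
* **Final re-thresholding.** Units called during the iterations keep their
  calls even if the re-computed truth-converging P-value exceeds alpha';
  the re-computed value is reported so users can apply their own cut.

## Known limitations

* **Cross-length multiplicity.** Each unit length is tested against its
  own window-extremum null, which adjusts for location multiplicity within
  that length but not across lengths. On null data whose unit decomposition
  yields many distinct lengths (the sporadic-segment null model above
  produces ~25 per tail), the union of per-length tests inflates the
  realized FWER to roughly 2–3x the nominal alpha even though each
  per-length test is individually conservative (per-length rejection
  ~0.002 at alpha' = 0.048). The per-length marginals are
  exchangeability-valid — on data drawn from the relocation distribution
  itself the union FWER is ~0.08 — so the inflation is a property of the
  length-adaptive testing scheme, not of the permutation machinery.
  Datasets with few distinct unit lengths (e.g. marker-level data) do not
  show it.
* **Deletion saturation.** Under normal-cell contamination the deletion
  signal is bounded and partially censored (see above); deletion power is
  intrinsically below amplification power in the mixture simulations.
* Permutation cost grows with T x (segments + distinct lengths x M); the
  compiled kernel handles the defaults (T = 1000, M ~ 10^5 per chromosome)
  comfortably, but genome-wide scope over very dense unit sets is the slow
  path.

## Problem sizes used in the shipped validation

The test suite and `scripts/acceptance.py` run the simulation studies at
desk scale, chosen to keep the full validation in the tens of minutes:
FWER on 500 null datasets per clumping setting (N=20, M=1000, T=200);
power on 50 replicates per setting (M=5000, T=500); the iterative-gain
property on 100 two-region replicates (M=800, T=100); ROC dominance on 20
replicates (N=50, M=5000, T=200). The reference study used 10,000 null
repeats and 100 replicates per power setting with T=1000.
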
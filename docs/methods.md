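# Methods

## The TF–nucleosome competition model

A regulatory element is modeled as a DNA segment that is either wrapped in a
nucleosome or open, carrying binding sites for a TF at effective
concentration α (concentration divided by a site's dissociation constant
K_D; only ratios α/K_D are identifiable from curve shape). The grand
partition function has an open branch Z_open = ∏_i (1 + α/K_D,i) and a
nucleosome branch Z_nuc = L·∏_i (1 + c·α/K_D,i); accessibility is
Acc = Z_open/(Z_open + Z_nuc). Assumptions: thermodynamic equilibrium, a
single nucleosome per element, no direct TF–TF interactions (all
cooperativity is emergent through the shared nucleosome), and a single
competition parameter c shared by all sites. The c factor is applied to
*every* site class in the nucleosome branch, including low-affinity sites in
the mixed high/low model — with c on the high-affinity sites only, the
low-affinity factor cancels between numerator and denominator and the
low-affinity site count and K_D ratio become unidentifiable, which would
contradict the fact that these parameters are recoverable from curve shape
(see the noiseless self-consistency tests).

Parameters and defaults:

| symbol | meaning | default | why |
|---|---|---|---|
| L | nucleosome/open equilibrium constant (dimensionless) | 10³ | a closed, nucleosome-favored baseline: Acc(0) = 1/(1+L) ≈ 10⁻³ |
| c | TF binding suppression on nucleosomal DNA, ∈ [0,1] | fit (starts 10⁻³–10⁻¹) | c=0 forbids binding in the wrapped state; c=1 makes the nucleosome invisible |
| a₁₀₀ | α at 100% TF dosage in units of K_D,HA | fit (bounds (0,10⁶]) | dosage→concentration is assumed linear, α(d) = (d/100)·a₁₀₀, with the proportionality constant absorbed here |
| r | K_D ratio of low- to high-affinity sites, ≥ 1 | fit (bounds [1,10⁶]) | r < 1 would make the "low-affinity" site the stronger one |

All partition-function evaluation is in log space (`log1p` sums), so
saturating concentrations cannot overflow.

**Theoretical ED50.** The ED50 of an accessibility titration is the α at
half of the curve's rise over the titration window [10⁻⁵, 10⁵]:
Acc(α\*) = Acc(0) + ½·(Acc(10⁵) − Acc(0)), located by a 400-point log-grid
bracket plus Brent bisection (relative tolerance 10⁻⁶). Using the top-of-range
value rather than the α→∞ limit changes single-site ED50s by under 3% at
L = 10³ (the baseline is ~10⁻³) and avoids an arbitrary extrapolation.
Curves with no rise (c = 1, or an empty site set) raise an error rather than
returning a pseudo-ED50.

**Buffering→sensitizing crossover.** For one high-affinity site plus a
second site at K_D ratio r, the crossover r\* is the smallest r at which the
two-site ED50 exceeds the single-site ED50. The excess is negative at r = 1
(identical sites always buffer: both stabilize the same open state), tends
to zero from one side as r → ∞ (the second site vanishes), and for c > 0
changes sign exactly once in between; r\* is found by a 240-point log-grid
scan over [1, 10⁴] followed by bisection. With c = 0 the excess is negative
for every finite r and the function returns "none". Computed values:
r\* ≈ 4.60 at c = 0.01 and r\* ≈ 247 at c = 0.001 (L = 10³).

**Fitting.** Empirical curves normalized to response(100%) = 1 are fitted by
`scipy.optimize.least_squares` (trust-region reflective) on the model
response M(d) = [Acc(α(d)) − Acc(0)] / [Acc(a₁₀₀) − Acc(0)], with c linear
in [0,1] and a₁₀₀, r on log₁₀ scale. Multi-start over
c ∈ {10⁻³,10⁻²,10⁻¹} × a₁₀₀ ∈ {3,30,300} (× r ∈ {3,30,300} for mixed
models); best mse wins. A fit is accepted iff mse ≤ 10⁻³ and c ≥ 0. The
effective number of high-affinity sites is chosen by scanning n = 1..7 and
taking the smallest n whose median mse across curves is within 5% of the
minimum — parsimony among statistically equivalent fits; on curves generated
with n = 3 the scan selects 3.

## Hill dose-response fitting

Counts are TMM-normalized (trimmed mean of M-values: reference = sample
whose 75th-percentile count fraction is closest to the mean; trim 0.30 on M
and 0.05 on A by ranks; inverse-asymptotic-variance weights; factors
rescaled to geometric mean 1) to CPM. Per RE, batch is regressed out of
log₂(CPM + 0.5) as a categorical covariate (residuals plus grand mean,
back-transformed) — the log scale makes an exact multiplicative batch effect
exactly removable; values are then scaled by the maximum absolute value and
samples with |z| > 3 (computed on the scaled values, i.e. after correction)
are masked. Series with fewer than 4 usable samples spanning 3 dosages are
flagged unfittable.

The two-parameter Hill model f(d) = min + (max−min)·d^h/(d^h+e^h) anchors
min and max at the mean value at full and no depletion; the three-parameter
model frees the maximum and is reported when AIC improves by more than 2
(AIC = n·ln(RSS/n) + 2k; the additive Gaussian constant cancels in the
comparison). Because the anchored maximum is the observed value at d = 100
rather than the Hill plateau, data generated with a genuine plateau are
recovered exactly through the three-parameter branch — this is the intended
route, not a defect. The Hill ratio d^h/(d^h+e^h) is evaluated as a
logistic in log-dose, which is exact and stable for arbitrarily large h.
REs that gain accessibility on depletion are fitted on the negated response
with the direction recorded. Multi-start over e ∈ {10,30,60,90} ×
h ∈ {1,2,4}; RSS ties break toward smaller h.

**Modified ED50** — the smallest d ∈ (0,100] with f(d) = ½·f(100) on the
fitted curve, by grid bracketing plus Brent bisection. If the curve never
reaches the half level below 100% the function returns 100 (the cap); if the
fitted baseline already exceeds it (a shallow responder whose full-depletion
value stays above half of its unperturbed value), it returns 0 — such REs
are maximally buffered under this definition.

## CWM instance calling

Contribution tracks hold a signed per-base attribution value at the observed
base of each position (length × 4, zero elsewhere). A CWM slides over both
strands; each window is scored by continuous Jaccard similarity
Σ sgn·min(|x|,|y|) / Σ max(|x|,|y|) after L1 normalization of both matrices
(sgn = −1 where signs disagree), so magnitude-matched, sign-consistent
windows score near 1 and anti-correlated windows near −1.

Thresholds are percentile-based against a per-CWM reference distribution
standing in for a discovered seqlet set: windows whose total absolute
contribution exceeds the robust background level (median + 8×MAD over all
windows, strictly). Against that reference the permissive defaults apply —
Jaccard ≥ 10th percentile and total |contribution| ≥ 0.5th percentile —
keeping degenerate low-affinity occurrences. The MAD rule adapts to the
track's noise floor instead of assuming a fixed fraction of motif-bearing
windows; on noiseless tracks it reduces to "any nonzero contribution".
Overlapping candidates (any base-pair overlap) are resolved greedily by
Jaccard × CWM length — longer motifs win over their own sub-motifs — then by
higher Jaccard, then leftmost; coincident forward/reverse calls of a
palindromic CWM keep the + strand.

**PWM matching.** Log-odds scores (log₂ p/background) are discretized to
0.01-bit bins; the null distribution of the total score under the background
model is built by exact dynamic-programming convolution, and the p-value
threshold is the largest achievable score t with P(score ≥ t) ≥ p. Scoring
uses the same bins, so pass decisions are exact (verified against 4^L
enumeration for L ≤ 8). Non-ACGT bases score 0 (background). The default
p = 0.01 is a permissive scanning cutoff.

**Conservation contrast.** Instances are summarized by the mean of their
per-base scores (missing bases skipped); the control consists of same-length
intervals placed uniformly at random within the scored regions, rejected on
any overlap with a true instance (seeded, reproducible).

## Synthetic data

The generators emulate the study design, not raw sequencing:

* **Dose counts** — 5 dosages {100, 60, 30, 12, 0}% (the realized dosages of
  a dTAG titration are instrument-specific; this spacing covers the dynamic
  range), 4 replicates per dosage, 2 differentiation batches balanced across
  dosages. Expected CPM follows CPM₀·[1 + (2^lfc − 1)·(1 − d^h/(d^h+e^h))]
  with per-RE ED50 ∈ [5,95], Hill exponent ∈ [0.8,4], full-depletion log₂FC
  ∈ [−4,−1]; 30% of REs lose accessibility on depletion, 5% gain, 65% are
  null — a realistic responsive fraction that also keeps
  composition-sensitive TMM normalization well behaved (a simulation where
  every RE responds makes CPM renormalization visibly distort the curves,
  which is faithful to how normalization behaves, not a bug). Counts are
  gamma-Poisson (negative binomial) with dispersion 0.05; batch effects are
  per-(RE, batch) log₂-normal with sd 0.1; library sizes uniform in
  [8,12]×10⁶.
* **Contribution tracks** — 400-bp regions, central summit; a strong
  "buffering" PWM (85% consensus, amplitude 1.0) planted at N(summit, 30 bp)
  and a degenerate "sensitizing" PWM (60% consensus, amplitude 0.5) at
  N(summit, 120 bp); 1–3 instances per region, overlaps resampled away so
  truth stays unambiguous. Planted letters are drawn from the PWM
  (strand-aware); the planted contribution is amplitude × per-base log-odds
  of the sampled letter; i.i.d. Gaussian noise (sd 0.05) is added at every
  observed base.
* **Competition curves** — normalized model responses on a 0–100% grid
  (step 5) with Gaussian noise sd 0.01, truncated to [0,1]; default truth
  nHA = 3, c = 0.022. Degenerate draws (c = 1, identically flat) are flagged.

What the generators do *not* emulate — and hence what passing tests do not
establish about real data: Tn5 insertion bias and fragment structure,
attribution-model artifacts (DeepLIFT noise is not i.i.d. Gaussian),
motif grammar beyond independent planted instances, genuine evolutionary
conservation, and any nonlinearity in the dTAG dosage→concentration map.

## Pipeline and reproducibility

All randomness descends from one global seed; each stage derives its own
seed as (seed·1000003 + CRC32(stage name)) mod 2³¹, so disabling one stage
does not shift another's stream. Every table carries a one-line versioned
schema comment; a run writes a manifest of SHA256 hashes over all data
artifacts plus the resolved config. Reruns with the same config and seed are
byte-identical for every manifested artifact; the run log carries wall-clock
timestamps and is deliberately excluded from the manifest. Coordinates are
0-based half-open throughout (BED convention). The demo conservation track
written by the pipeline's motif stage is a synthetic stand-in (elevated
inside planted instances) used to exercise the contrast machinery.

## Problem sizes

The shipped analyses use 200 REs / 200 regions / 200 curves with the noise
levels above; parameter-recovery checks use the same sizes (the
dose-response regression benchmark compares a 4-replicate run against a
20-replicate, 60-RE run). These sizes give stable medians for every
reported contrast while keeping each driver in the minutes range on one CPU.

## Known limitations

* The competition model is single-nucleosome and at equilibrium; multi-
  nucleosome arrays, remodeler kinetics and out-of-equilibrium effects are
  out of scope.
* c is shared across sites within an element; site-specific competition
  (e.g. position-dependent unwrapping cost) is not modeled.
* In mixed-site fits c and r are partially confounded at this noise level
  (medians recover the truth's order of magnitude, individual fits less so).
* The dosage→concentration map is assumed linear; only the product with
  1/K_D,HA (a₁₀₀) is identifiable.
* TMM assumes most features are unchanged; designs where most REs respond
  violate this and bias normalization (demonstrably, in the generator).
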
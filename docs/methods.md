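# Methods

## Cumulative-labeling model

The estimator assumes an asynchronous population in steady state: every
cycling cell's position is uniform on its cycle of length T_C, a
fraction G of the population cycles, and phase order is G1 → S → G2 →
M.  Under continuous label availability a cell is labeled by time t iff
it is in S at some point during [0, t]; for a uniform cohort the
labeled fraction is G·(t + T_S)/T_C, capped at G.  All durations are in
hours; fractions are kept in [0, 1] internally and converted to percent
only at I/O.

**Fitting.**  Points with observed labeling index within 2% of the
plateau G are excluded and the rest fit by weighted least squares with
binomial variance weights n/(li(1−li)+ε), ε = 1/(4n), which keeps
weights finite at indices of exactly 0 or 1.  `g="auto"` takes the
plateau from the data only when at least two points lie within 2% of
the maximum observed index — a single high point is not evidence of a
plateau — and otherwise assumes G = 1, appropriate for perinatal OP
populations in which essentially all cells cycle.  Standard errors of
T_C = G/m and T_S = y₀G/m come from the delta method on the WLS
covariance of (y₀, m).  A fitted slope ≤ 0 raises a non-identifiability
error rather than returning a negative cycle time.

**Mixture corrections.**  When a fraction f of the population is
recombined and the remainder cycles with a known T_C′, two corrections
are offered.  The arithmetic form treats the fitted average cycle time
as a weighted arithmetic mean: T_C = (T̄_C − (1−f)·T_C′)/f.  The
harmonic form notes that the linear model's pre-plateau slope is the
weighted sum of subpopulation slopes (rates add, not periods), so the
fitted T̄_C is a harmonic-type mean: T_C = fG/(m̄ − (1−f)G/T_C′).  With
T̄_C = 179 h, f = 0.8, T_C′ = 77 h the arithmetic correction gives
204.5 h (reported 205 h) and the harmonic correction applied to the
equivalent average slope gives a substantially smaller implied average
for the same subpopulation T_C (inverting: a true subpopulation T_C of
204.5 h yields a fitted average of only ≈154 h).  Which mean a given
report intends is ambiguous in general; both are computed and labeled.

**G2 estimator.**  t_G2 = t_chase − f_pH3·T_S, the labeled-mitoses
reconstruction: labeled cells occupy the last f_pH3·T_S hours of S at
pulse time if they are to be in M after the chase.  The estimator is
exact (simulator bias < 1 h at 10⁴ cells) while t_chase ≤ T_G2 + T_M,
and biased upward once labeled cells have divided out of M
(t_chase > T_G2 + T_M) — the simulator demonstrates both regimes.
f_pH3 = 0 marks the result as a lower bound on G2 (no labeled mitoses
yet); f_pH3·T_S > t_chase clips to zero with a flag.  The ratio used is
pH3+ cells among EdU+ cells.

**G1.**  T_G1 = T_C − T_S − T_G2 − T_M with T_M defaulting to 0, making
the result an upper bound.  Report strings round durations to one
decimal below 10 h and to the nearest hour above, half-up.

## Population simulator

`simulate_cohort` draws subpopulation membership, cycling status
(probability G per subpopulation) and a uniform cycle position per
cycling cell.  Labeling and chase protocols are then deterministic
given the cohort: all sampling noise enters through the random
positions, which makes the per-timepoint counts exactly binomial around
the analytic index.  On division one daughter is retained, with label,
at cycle position 0 — a modelling assumption (not biology) that keeps
the counted population stationary, which is precisely the condition
under which the linear labeling model is valid.  Real perinatal cortex
adds population growth, EdU dilution over repeated divisions, and
non-uniform age structure; passing tests here validate the estimators
under the model's own assumptions, not against those violations.  The
EdU pulse in the pulse-chase protocol defaults to instantaneous
(`pulse_window = 0`) since in-vivo bioavailability after one injection
is short but not precisely known; a window parameter exists to probe
sensitivity.  pH3 positivity spans exactly M-phase.

Sampling designs used by the drivers and the reproduction script — 8
timepoints at 3–24 h, 500 scored cells per timepoint, 20 replicate
seeds; 10⁴ cells for pulse-chase — mirror a realistic perinatal
labeling experiment (hundreds of scored cells per litter, one litter
per timepoint).

All stochastic steps derive child seeds from one integer seed via a
CRC-based mix (`child_seed`), logged in sidecar JSON files next to
every written dataset.

## Photobleaching traces and fits

The generator plants a mobile fraction F and exchange rate k.  FRAP:
pre-bleach plateau at 1, instantaneous drop to the bleach depth b, then
recovery b + F(1−b)(1−e^(−kt)).  FLIP: distal-region decay
(1−F) + F·e^(−kt).  Both the bleached ROI and the reference decay by a
shared acquisition-bleaching exponential, and additive Gaussian noise
is applied — at full amplitude to the small bleach ROI and at a quarter
amplitude to the reference and background ROIs, which average many more
pixels.  At zero noise the traces equal their closed forms to 1e-12.

**Normalization.**  Double normalization (background subtraction,
division by the reference, scaling to a pre-bleach mean of 1) cancels
shared acquisition bleaching exactly.  `normalize_frap` then applies
full-scale normalization — subtract the first post-bleach value, divide
by (1 − that value) — so a complete recovery spans 0 to 1 and the
fitted plateau is the mobile fraction directly.

**Fitting.**  Single-exponential models throughout (no
diffusion-reaction kinetics): the assays report only mobile fraction,
T½ and R², which a one-rate model fully parameterizes.  `fit_recovery`
fits A(1−e^(−kt)) on a full-scale-normalized series.  The pipeline
entry point `analyze_frap` instead fits the bleach floor jointly,
b + (1−b)·F·(1−e^(−kt)), on the double-normalized series: anchoring the
full scale on the single first post-bleach frame propagates that one
frame's noise multiplicatively into the amplitude, and the joint fit
removes this sensitivity (identical results at zero noise).
Initialization: amplitude from the last-decile mean, rate from the
half-rise time, with a 3-point multi-start over the rate (÷10, ×1, ×10)
because noisy traces have a shallow degenerate minimum at (A → bound,
k → 0).  Bounds A ∈ [0, 1.2] (small overshoot tolerated, clipped for
reporting), k > 0; tolerances 1e-10, at most 10⁴ evaluations;
non-convergence is flagged in the result, never raised.  Flat series
return mobile fraction 0 with the rate marked unidentifiable.

Bleach-frame auto-detection distinguishes an abrupt FRAP drop (one
frame-to-frame step far above the noise floor, located exactly) from a
gradual FLIP onset (windowed step statistic, first half-peak crossing).
FLIP onset detection is accurate to a few frames under noise; when the
acquisition protocol is known, pass `bleach_index` explicitly, as the
analysis drivers do.

## Enrichment statistics

Fold enrichment is (k_fg/n_fg)/(k_bg/n_bg) with a one-sided Fisher
exact test for enrichment on the 2×2 table (the direction the analyses
report) and a 95% CI from the delta-method SE of the log ratio,
√(1/k_fg − 1/n_fg + 1/k_bg − 1/n_bg).  Folds are reported to one
decimal in text output; machine output keeps full precision.
Benjamini–Hochberg correction is applied across the motif list (the
choice of correction is a package decision).  The background set
defaults to all non-foreground peaks and is configurable.  Gene-set
overlap uses the hypergeometric tail P(X ≥ observed), expected overlap
n_a·n_b/N, and the Jaccard index.  Exact-test p-values are validated in
the test suite against independent brute-force enumeration of all
fixed-margin tables up to total size 30.

The peak-universe generator draws BED intervals (0-based, half-open)
with independent Bernoulli motif indicators at planted per-set
frequencies — sufficient for validating the counting statistics; it
does not model peak width variation, genomic clustering, or correlated
motif co-occurrence.

## Known limitations

- The cell-cycle machinery assumes fixed phase durations per
  subpopulation; inter-cell variability in T_C (which flattens the
  plateau shoulder) is not modeled.
- The mixture corrections assume the unrecombined subpopulation cycles
  exactly at the reference rate.
- FLIP fitting assumes the distal region is far enough from the bleach
  spot that its loss is exchange-limited; no spatial diffusion model.
- Enrichment treats peaks as exchangeable units; no GC, width, or
  distance-to-TSS covariate matching of the background.
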
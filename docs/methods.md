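# Methods

## Model and procedure

The pipeline asks whether a single blood sample, drawn at ZT6, carries
enough information to reconstruct an individual mouse's recent locomotor
activity (LA) — a proxy for its position in an infradian (~10–20 day) cycle
of mood-related activity.

**Targets.** For each mouse, the 24 h LA is the distance traveled in the
absolute interval `[sampling − 30 h, sampling − 6 h)` (ZT0 of the day
before sampling to ZT0 of the sampling day), and the 3 h LAs are the 24
half-open windows `[sampling − 3w, sampling − 3(w−1))`, w = 1..24, tiling
the 72 h lookback. Intervals are half-open so no bin is counted twice, and
window sums require bin edges to align with window edges — bins coarser
than 3 h are rejected rather than interpolated, and gaps are refused rather
than imputed.

**Predictor.** The target y (an LA value or a log2 expression value) is
regressed on metabolite concentrations by nested leave-one-out
cross-validation (LOOCV):

1. outer loop: hold out mouse *i*;
2. inner loop, entirely within the n−1 training mice: for each candidate
   model size k, run LOOCV where each inner split re-ranks all metabolites
   by |Pearson r| with y on the inner-training rows and fits OLS on the
   top-k (features z-scored with inner-training statistics, intercept
   included); choose the k with smallest inner mean squared error, ties to
   the smallest k;
3. rank features on the full training set, fit the top-k* OLS model, and
   predict mouse *i*.

The n out-of-fold pairs (yᵢ, ŷᵢ) are scored by the sample Pearson r with
the two-sided p-value from t = r√(n−2)/√(1−r²) on n−2 df. The fraction of
outer folds in which a metabolite entered the model ("feature preference")
profiles the signal carriers. The procedure is fully deterministic.

Design points that were genuinely open and how they were fixed:

* **Ranking statistic** = |Pearson r| on the training split, ties broken by
  input column order; zero-variance columns rank last. Univariate
  correlation ranking is the minimal selector consistent with reporting
  per-metabolite correlations alongside preference profiles.
* **Model size** by inner-LOOCV MSE with ties to the smallest k:
  parsimonious and deterministic. Default grid 1..min(20, n_train − 2), so
  OLS stays overdetermined.
* **OLS, not ridge/lasso**: k ≪ n keeps the problem well posed, and the
  linear map is the model being claimed. Collinear columns are dropped
  keeping the earlier-ranked one (logged), rather than falling back to a
  pseudo-inverse — reproducible and explainable.
* **Standardization leakage:** z-scoring uses training-fold statistics
  only; the metabolome module deliberately does *not* offer global scaling.
* **Sidedness:** the two-sided Pearson p matches the t-transform of
  reported correlation/p pairs at n = 35; one-sided would halve them.
* **Exact interpolation** is allowed at n = k + 1 (two points define the
  line); the safety margin n_train − 2 is enforced in the k-grid instead.

**Multiplicity.** The window scan corrects its 24 p-values by
Benjamini–Hochberg (step-up; q-values = min-over-tail of p·m/rank) and
flags q < 0.1; the per-metabolite screen applies BH over all tested
metabolites; the gene scan uses Bonferroni α/m (0.05/7 ≈ 0.00714 for the
default seven-gene panel). These defaults are config-overridable and are
recorded in every run manifest.

## Synthetic cohorts

The simulator emulates the study design the analysis assumes — it is the
test bed, not a model of any particular real dataset. Per mouse:

    distance(bin) = B · (1 + A sin(2πt/24T + φ)) · circ(ZT) · ε(bin)

with period T ~ U(10, 20) days, phase φ ~ U(0, 2π), circadian factor
`circ` = 3 for dark bins (nocturnal mice) and 1 for light bins, baseline
B = 1500 cm/h, multiplicative lognormal bin noise (σ = 0.3,
mean-corrected), truncation at zero, 75 days of 1 h bins, sampling at ZT6
of the last day. A coupled metabolite j with lag window [a, b) h before
sampling is

    x_j = baseline_j + β_j (W − W̄) + ε_j,   W = LA in [sampling−b, sampling−a),

with random sign β_j, and Var(ε_j) set so the population R² between x_j and
W equals `coupling_strength` exactly (sample R² is then calibrated to ±0.1
at the study scale — verified by test). Defaults: 35 mice, 106 metabolites,
10 coupled to the 24 h-LA window (6–30 h before sampling) at R² = 0.5.
Uncoupled metabolites are iid noise; baseline offsets keep concentrations
positive (≈ 8 SD above zero, so truncation is negligible). The raw table is
multiplied per mouse by a lognormal measurement efficiency that also
appears as the internal-standard column, so normalization has real work to
do. Gene expression couples the same way to the latent infradian state
sin(phase at sampling); the default panel is the seven circadian genes, two
coupled. At `coupling_strength = 0` the coupled sets are forced empty and
every feature is independent of LA. All randomness flows from one seed
through a single generator; identical configs are bit-identical.

Amplitude (0.6), noise scale (0.3), dark/light ratio (3) and baseline are
calibration choices — the motivating literature gives period and design,
not amplitude or noise statistics.

What the simulator does **not** emulate: metabolite–metabolite correlation
structure (real metabolomes are strongly intercorrelated, which would
spread feature preference across pathway members), nonlinear or saturating
coupling, batch effects, missingness mechanisms, and selection of mice for
extreme activity. Passing tests therefore demonstrate correctness and
calibration of the *procedure* under its own assumptions, not expected
performance on real cohorts.

`empirical_period` is simulator QC: daily totals are Hann-windowed,
zero-padded (2¹⁴ points) and the periodogram peak strictly below 1
cycle/day is reported; constant traces return NaN, traces under 2 days are
refused, and estimates are reliable only when the record is at least twice
the period.

## Monte-Carlo problem sizes

Calibration and recovery suites run at the study scale (n = 35, p = 106):
200 null cohorts for the type-I measurement (reduced k-grid 1..5, which
leaves the selection semantics intact while keeping the inner loops cheap),
100 leaky-control cohorts, 100 signal cohorts at R² = 0.5 for power and
preference recovery (default k-grid, so models can grow to cover the
10-metabolite truth set), 20 cohorts for the null metabolite screen, and
reduced replicate counts (5–15) for the window/gene recovery and
p-value-uniformity checks in the unit suite.

## Known limitations

**The pooled cross-validated correlation test is miscalibrated under the
null.** The out-of-fold pairs are not independent draws from a bivariate
distribution: every prediction shares training data with every other, and
each leans on a training mean that *excludes* its own target, which makes
null predictions anti-correlated with the actuals. Measured at n = 35 over
200 null cohorts, the out-of-fold r has mean ≈ −0.1 and SD ≈ 0.30 (iid
theory: 0.17), so the two-sided test rejects ≈ 35–40% of the time at
nominal 0.05 — almost entirely with *negative* r. The positively
significant fraction (p < 0.05 and r > 0), which is what a claim of
successful prediction rests on, is calibrated at ≈ 0.05–0.14 depending on
target skewness, and the deliberately leaky variant (features ranked once
on all mice) rejects positively at > 0.9, which is what an actual leak
looks like. Practical reading: treat positive significant correlations as
evidence, treat "significant" negative out-of-fold correlations as the
artifact they are, and prefer the leaky-vs-nested contrast — reproduced in
the test suite — as the leakage diagnostic. A permutation test of the whole
pipeline would be exactly calibrated but is outside the analysis being
reproduced.

Window-scan FDR inherits the same caveat: BH assumes valid p-values, so
under the null a few anti-correlated windows can be flagged at q < 0.1;
with a genuinely coupled lag window, that window is recovered as the top
positive correlation essentially always (recovery tests), while distant
windows rarely show significant *positive* correlations.

Other limitations: whole-mouse exclusion discards mice with a single
missing metabolite (correct mirror of the upstream QC, wasteful for
high-missingness data); the activity module refuses trace gaps; feature
preference is interpretable only relative to the correlation structure of
the features (with correlated real metabolites it spreads over pathway
members); and the infradian waveform is a pure sinusoid — real oscillations
are neither stationary nor sinusoidal, so `empirical_period` on real traces
should be read as a dominant-scale summary, not a rhythm estimate.
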
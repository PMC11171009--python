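# Methods

This note documents the models, numerical choices and limitations of
the `rtstress` pipeline in the order data flows through it.

## Signal model and synthetic generators

**Tachogram synthesis** (`synth.generate_nn_series`). RR-interval
series are built spectrally: two unit-variance Gaussian components are
generated by frequency-domain masking of white noise, confined
slightly inside the LF (0.05–0.14 Hz) and HF (0.16–0.38 Hz) bands to
limit leakage across band edges, and combined as

    RR(t) = RR̄ + a_LF·x_LF(t) + a_HF·x_HF(t),
    a_HF = SDNN/√(1+r),  a_LF = SDNN·√(r/(1+r)),  r = target LF/HF.

Beat times are obtained by walking `t_{k+1} = t_k + RR(t_k)/1000`.
The components are then re-sampled at the realized beat times,
mean-removed, orthogonalized in-sample and rescaled, so the *sample*
SDNN equals the target exactly and the in-sample LF:HF variance split
equals `r`; what remains stochastic is only the spectral-estimation
error of the measuring code. Specs whose mean RR ± 5·SDNN would leave
the physiological 300–2000 ms range are rejected. An ODE heart model
was deliberately avoided: filtered Gaussian noise is the simplest
structure whose band powers are controllable analytically.

**PPG synthesis** (`synth.synthesize_ppg`). Each beat stamps a
two-Gaussian pulse (systolic wave σ = 0.11 s peaking exactly at the
beat time; diastolic wave 0.35× amplitude at +0.35 s), plus white
noise (relative sd 0.02 by default) and, optionally, motion bursts
modelled as additive high-amplitude (8× pulse height) 0.5 Hz
oscillations over given spans — an amplitude/frequency signature, not
a physical model of movement. Ground-truth beat times ride along in
trace metadata solely for testing.

**Breathing synthesis** (`synth.generate_resp_trace`). Cycle-by-cycle
peak-to-peak periods ~ N(mean, period_sd) and extremum magnitudes
~ N(amp_mean, amp_sd); valleys sit midway between peaks; the
alternating knots are joined by a monotone cubic (PCHIP) so the
rendered extrema coincide exactly with the drawn knots; the knot
sequence extends beyond the rendered window so interpolation endpoint
effects never appear in the signal. Because valleys are midpoints,
valley-to-valley periods average adjacent peak periods, so the phase
irregularity of a generated trace is ≈ 0.85·period_sd rather than
period_sd — tolerances in tests account for this geometry.

**Cohorts** (`synth.generate_cohort`). Patient covariates are drawn
per the study composition (41 patients, 1–5 days, ~66 % male, ages
47–80). Baseline features come from normal/log-normal ranges typical
of resting adults; each of the seven features then moves in its
stressful direction with probability `p_stress` (default 0.5, which
puts ~47 % of cases above the 50 % threshold — the reported share) and
in the opposite direction otherwise, by a strictly positive relative
magnitude (20 % × |N(1, 0.3)|, capped at 90 %). Ties therefore never
occur by construction and the number of stressful shifts is exactly
Binomial(7, p). Respiratory irregularity is linearly coupled to the
realized score:

    phase_irr = 10.0 + 0.286·(score/10) + b_i + ε,
    b_i ~ N(0, 2.0²) per patient,  ε ~ N(0, 1.5²),

with an amplitude analogue (intercept 0.143, slope 0.003 per 10 %,
patient sd 0.05, noise 0.035) dispersed enough that the amplitude
association sits at the edge of detectability, as observed in the
study this emulates. What the generator does **not** reproduce: the
bimodal shape of the observed score distribution (iid Bernoulli shifts
give a unimodal binomial), respiratory sinus-arrhythmia coupling
between the PPG and breathing signals, realistic pulse morphology, and
any true dependence of during-treatment labels on before-treatment
features — so passing prediction tests demonstrate correct machinery
(chance on shuffled/null data, convergence when dependence is
injected), not clinical predictability. Units of irregularity are
configuration, not assumption: the original recordings' units are
unstated, so only the statistical structure (slope recovery, CI
coverage) is reproduced, never absolute magnitudes.

## PPG processing

Artifact masking never alters samples, only a validity mask, with
three rules: flatline (rolling 2 s sd below 10⁻⁴× the robust IQR-based
signal sd), clipping (≥ 3 consecutive samples pinned at the trace
extrema), amplitude outliers (robust |z| > 5 against the global
median/IQR baseline). Outlier spans are morphologically closed over
1 s and padded by 0.3 s so an oscillating motion burst is masked
through its zero crossings. A fully masked trace raises an
"unusable segment" error, mirroring the exclusion of recordings with
sensor malfunction.

Phase windows are exactly 300 s starting 120 s after each phase mark
(half-open, seconds from recording start); a phase shorter than 420 s
is an error naming the phase.

Beat detection band-passes 0.5–8 Hz (3rd-order Butterworth,
forward-backward), differentiates twice with a Savitzky–Golay filter
(0.13 s window, cubic), and takes local maxima of the *negative*
second derivative: the point of strongest downward curvature is the
systolic apex, whereas the classical positive-curvature 'a' wave
precedes the apex by tens of milliseconds and would bias beat times.
Candidates must clear an adaptive prominence threshold — 2.5× the
rolling 10 s inter-quartile range of the curvature, with a scale-free
floor at 25 % of the 90th-percentile prominence (absolute thresholds
fail across sensor gains; the floor suppresses filter ripple on sparse
traces) — and respect a 0.3 s refractory period (caps detection at
200 bpm). Surviving beats are refined to the sub-sample apex of the
band-passed pulse by parabolic interpolation; beats inside masked
spans are discarded. On the default clean synthetic PPG the detector
recovers ≥ 99 % of ground-truth beats within 20 ms with ≥ 99 %
precision, and degrades monotonically with noise.

NN cleaning removes intervals outside 300–2000 ms, then intervals
deviating > 20 % from the 11-interval centred rolling median —
standard HRV practice where the underlying method states only that
artifacts were removed. Fewer than 30 surviving intervals in a window
triggers a warning (the pipeline then excludes the case); the feature
computation itself refuses series shorter than 30 intervals.

## HRV features

Time domain: HR = 60000/mean(NN); SDNN with the sample (n−1)
denominator (the dominant convention in HRV software — it makes the
alternating-series oracle exact); RMSSD; pNN50.

Frequency domain: the tachogram (NN value at its ending beat time) is
resampled at 4 Hz with a cubic spline, mean-removed, and analysed with
a single full-length rectangular-window segment capped at 300 s (50 %
overlap beyond). The rectangular window keeps the discrete Parseval
identity exact, so TP tracks the tachogram variance within a few
percent; a Hann taper re-weights the realization and inflates
band-power variance enough to break the 20 % LF/HF round-trip on
5-minute records. Band powers integrate the one-sided PSD over
LF 0.04–0.15 Hz, HF 0.15–0.4 Hz, TP 0.004–0.4 Hz; with 300 s windows
the 0.004 Hz edge is below the resolution limit, so TP effectively
starts at the first positive bin (0.0033 Hz). The LF band follows the
standard convention since the ratio's definition leaves it implicit.
LF/HF is *undefined* (None, never infinity) when HF is zero to
machine precision, e.g. for a constant series. A Lomb–Scargle
estimator on the uneven series (normalized so its band integral equals
the series variance) is available via `estimator="lomb"` and serves as
the independent cross-route in tests — on concentrated (multi-tone)
spectra the two routes agree within 15 %; on stochastic tachograms two
unbiased estimators legitimately disagree per-realization, which is an
estimator-variance fact, not an implementation defect.

## Scoring

A feature's label is True iff it *strictly* moved in its stressful
direction. Ties count as not stressful: conservative, measure-zero for
continuous features, and it makes the all-equal case score 0. An
undefined LF/HF in either phase yields a False label plus a
`lf_hf_undefined` data-quality flag rather than a guessed direction.
The score is 100·k/7 rounded half-up to two decimals so emitted bins
string-match the published table; exactly 50 is unattainable from
seven labels (asserted), so the > 50 % yes-call is exhaustive. Feature
weighting is deliberately out of scope.

## Prediction

Eight dataset types append subsets of {age, sex, day} to the seven
before-treatment features in a fixed column order (sex M=1/F=0, day as
integer). Models: multi-output decision tree and 200-tree random
forest (raw inputs); per-label RBF SVMs; and two compact numpy
sequence models — an Elman-style tanh recurrent network and a
single-head scaled dot-product self-attention encoder with learned
positional embeddings — that read the z-scored feature vector as an
ordered univariate sequence (the tabular-to-sequence mapping is a
design choice; no canonical mapping exists). The sequence models are
trained full-batch with Adam (300 epochs, lr 0.02, 16 hidden units /
8 dims) and their manual gradients are verified against numerical
differentiation in the test-suite. A label column that is single-class
in training short-circuits to a constant prediction with a warning.
Inputs are z-scored per training fold for margin and neural models,
raw for trees.

Cross-validation defaults to patient-grouped 10-fold splits (no
patient contributes to both train and test); plain shuffled K-fold is
available for parity with analyses that do not state grouping — the
10-fold split of 123 cases into folds of 12–13 arises in that mode.
Evaluation reports EMR (all seven labels right) and example-based
metrics: per-case Jaccard accuracy |Y∩Z|/|Y∪Z|, precision |Y∩Z|/|Z|,
recall |Y∩Z|/|Y|, F1, averaged over cases (a case with no true and no
predicted positives counts 1.0; an empty denominator against a
non-empty counterpart counts 0); micro-averaged values are emitted
alongside because the averaging mode of the original analysis is not
verifiable. EMR ≤ example-based accuracy always. The binary stress
call is *derived* from predicted labels through the scoring rule,
never trained separately, with precision defined as 0 (plus warning)
when positives exist but none are predicted.

## Respiratory irregularity and association

Breathing extrema come from a 0.5 s moving-average-smoothed trace
(odd-length kernel, edge-replicating, so the statistic is invariant to
constant offsets), with ≥ 1.5 s separation (breathing < 40
cycles/min), prominence ≥ 10 % of the smoothed peak-to-peak range,
strict peak/valley alternation enforced by keeping the more extreme of
same-sign neighbours, parabolic sub-sample refinement, and a
smoothing-window margin trimmed at both trace edges. Irregularity is
the mean of the two dispersions — sd of peak values and of valley
values (amplitude, signal units), sd of peak-to-peak and of
valley-to-valley periods (phase, seconds) — using sample sd
throughout, consistent with SDNN. Amplitude uses raw extremum values
rather than peak-to-valley excursions ("dispersion of the peaks and of
the valleys" reads as value dispersion); an excursion-based variant is
a config switch. Consequences: amplitude irregularity is invariant to
adding a constant to the trace and scales linearly with the trace;
phase irregularity is invariant to both.

The stress–irregularity association is a marginal linear model fitted
by GEE with patient clusters, exchangeable working correlation and
robust (sandwich) standard errors — the standard default where the
working structure is unstated. Predictors: score/10 (so the
coefficient is the irregularity change per 10 % score increment) or
the binary call. A single cluster falls back to OLS with
heteroskedasticity-robust errors and a warning. On 200 synthetic
replicates (40 patients × 3 cases, true slope 0.3) the 95 % CI covers
the truth at nominal rate (90–98 %), and the null is retained at
nominal rate when the slope is 0.

## Reporting and reproducibility

`report.summarize_distribution` emits one row per occupied score bin
with counts and percentages to two decimals; day/sex comparisons use
two-sided Mann–Whitney U tests (exact on small tie-free samples) per
day and Friedman tests across days for patients with complete data,
reporting "no-variation" when scores are constant. One YAML config
governs every stage; all randomness flows from per-call
`numpy.random.Generator` seeds, and `report.run_pipeline` is
byte-identical across reruns of the same config. Regenerating reports
from the saved case table reproduces identical downstream numbers.

Problem sizes used by the test-suite and acceptance checks — 300 s
windows at 100 Hz PPG, cohorts of 40–120 patients, 200 association
replicates — were chosen as the smallest sizes at which the targeted
tolerances are statistically meaningful.
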
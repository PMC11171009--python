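"""Respiratory irregularity and its association with stress.

First computes the irregularity statistic — the mean of the standard
deviations of breathing peaks and valleys, in amplitude (extremum
heights) and phase (cycle periods) — on one synthetic trace, then
recovers the stress-coupling slope on a full cohort with a GEE
(patient clusters, exchangeable working correlation).
"""

from rtstress import resp, synth

trace = synth.generate_resp_trace(period_mean=4.0, period_sd=0.4,
                                  amp_mean=1.0, amp_sd=0.15,
                                  duration=180, seed=2)
extrema = resp.detect_extrema(trace)
irr = resp.irregularity(extrema)
print(f"breathing cycles    : {extrema.peak_times.size}")
print(f"amplitude irregularity: {irr.amplitude_irr:.3f} (generator sd 0.15)")
print(f"phase irregularity    : {irr.phase_irr:.3f} s (generator sd 0.4)")
print()

cases = synth.generate_cohort(
    synth.CohortConfig(n_patients=41, days_per_patient=(1, 5),
                       resp_slope=0.286, seed=17)
)
r = resp.associate(cases, predictor_kind="score10", outcome="phase")
print(f"GEE slope per 10% stress score: {r.beta:.3f} "
      f"[{r.lcl:.3f}, {r.ucl:.3f}], p = {r.p_value:.4f}")
print("(the cohort was generated with a true slope of 0.286; the CI "
      "should usually cover it)")
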
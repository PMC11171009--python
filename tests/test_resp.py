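"""Breathing extrema, irregularity statistic and GEE association."""

import numpy as np
import pytest

from rtstress import resp, synth
from rtstress.types import ExtremaSeries, SignalTrace


class TestDetectExtrema:
    def test_sinusoid_counts_and_phase(self):
        fs = 25.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * t / 4.0)  # 4 s period
        ex = resp.detect_extrema(SignalTrace(samples=x, fs=fs))
        # peaks at 1, 5, ..., 57 -> 15 inside the trimmed window
        assert ex.peak_times.size == 15
        assert ex.valley_times.size >= 14
        expected = 1.0 + 4.0 * np.arange(15)
        assert np.max(np.abs(ex.peak_times - expected)) < 0.1

    def test_monotone_ramp_rejected(self):
        with pytest.raises(ValueError, match="cycles|flat"):
            resp.detect_extrema(
                SignalTrace(samples=np.linspace(0, 1, 2000), fs=25)
            )

    def test_same_sign_neighbors_collapse_to_extreme(self):
        # a notch splits one crest into two candidate peaks; the
        # detector must keep a single (higher) one
        fs = 25.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * t / 4.0)
        notch = np.exp(-0.5 * ((t - 29.0) / 0.15) ** 2)
        ex = resp.detect_extrema(SignalTrace(samples=x - 0.4 * notch, fs=fs))
        crest = (ex.peak_times > 27.0) & (ex.peak_times < 31.0)
        assert crest.sum() == 1
        kinds = []
        for pt in ex.peak_times:
            kinds.append(("p", pt))
        for vt in ex.valley_times:
            kinds.append(("v", vt))
        kinds.sort(key=lambda kv: kv[1])
        assert all(a[0] != b[0] for a, b in zip(kinds, kinds[1:]))

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="30 s"):
            resp.detect_extrema(SignalTrace(samples=np.zeros(100), fs=25))


class TestIrregularity:
    def test_constant_extrema_zero(self):
        ex = ExtremaSeries(
            peak_times=[2, 6, 10, 14], peak_values=[1, 1, 1, 1],
            valley_times=[0, 4, 8, 12], valley_values=[-1, -1, -1, -1],
        )
        r = resp.irregularity(ex)
        assert r.amplitude_irr == 0.0
        assert r.phase_irr == 0.0

    def test_hand_worked_triples(self):
        # sd of [10,12,14] = 2 and of [0,2,4] = 2 (n-1 denominator)
        ex = ExtremaSeries(
            peak_times=[1, 5, 9], peak_values=[10, 12, 14],
            valley_times=[3, 7, 11], valley_values=[0, 2, 4],
        )
        r = resp.irregularity(ex)
        assert r.amplitude_irr == pytest.approx(2.0)
        assert r.phase_irr == pytest.approx(0.0)

    def test_brute_force_oracle_random_extrema(self):
        rng = np.random.default_rng(2)
        pt = np.cumsum(rng.uniform(3, 5, 10))
        vt = pt - rng.uniform(1.4, 2.4, 10)
        pv = rng.normal(1, 0.3, 10)
        vv = rng.normal(-1, 0.3, 10)
        r = resp.irregularity(ExtremaSeries(pt, pv, vt, vv))

        def sd(v):
            m = sum(v) / len(v)
            return (sum((x - m) ** 2 for x in v) / (len(v) - 1)) ** 0.5

        assert r.amplitude_irr == pytest.approx(
            (sd(list(pv)) + sd(list(vv))) / 2, rel=1e-12
        )
        periods_p = [b - a for a, b in zip(pt, pt[1:])]
        periods_v = [b - a for a, b in zip(vt, vt[1:])]
        assert r.phase_irr == pytest.approx(
            (sd(periods_p) + sd(periods_v)) / 2, rel=1e-12
        )

    def test_period_dispersion_recovered_from_trace(self):
        tr = synth.generate_resp_trace(
            period_mean=4, period_sd=0.5, amp_mean=2, amp_sd=0.1,
            fs=25, duration=250, seed=2,
        )
        r = resp.irregularity(resp.detect_extrema(tr))
        assert 0.4 <= r.phase_irr <= 0.6

    def test_offset_invariance_and_scale_equivariance(self):
        tr = synth.generate_resp_trace(
            period_mean=4, period_sd=0.3, amp_mean=2, amp_sd=0.4,
            fs=25, duration=200, seed=3,
        )
        base = resp.irregularity(resp.detect_extrema(tr))
        shift = resp.irregularity(resp.detect_extrema(
            SignalTrace(samples=tr.samples + 50.0, fs=tr.fs)
        ))
        scale = resp.irregularity(resp.detect_extrema(
            SignalTrace(samples=tr.samples * 3.0, fs=tr.fs)
        ))
        assert shift.amplitude_irr == pytest.approx(base.amplitude_irr, rel=1e-6)
        assert shift.phase_irr == pytest.approx(base.phase_irr, rel=1e-6)
        assert scale.amplitude_irr == pytest.approx(3 * base.amplitude_irr,
                                                    rel=1e-2)
        assert scale.phase_irr == pytest.approx(base.phase_irr, rel=1e-2)

    def test_excursion_mode_drift_insensitive(self):
        # constant peak-to-valley swing with a drifting baseline:
        # excursion dispersion is 0, value dispersion is not
        drift = np.linspace(0, 2, 5)
        ex = ExtremaSeries(
            peak_times=[1, 5, 9, 13, 17], peak_values=1.0 + drift,
            valley_times=[3, 7, 11, 15, 19], valley_values=-1.0 + drift[:5],
        )
        values = resp.irregularity(ex)
        excursions = resp.irregularity(ex, amplitude_mode="excursions")
        assert excursions.amplitude_irr < values.amplitude_irr / 2

    def test_insufficient_extrema_rejected(self):
        with pytest.raises(ValueError):
            resp.irregularity(ExtremaSeries([1, 2], [1, 1], [0.5, 1.5], [0, 0]))


def _scored_case(pid, day, k_true):
    from rtstress import score as score_mod
    from rtstress.types import CaseRecord, FEATURE_ORDER, StressAssessment

    labels = dict(zip(FEATURE_ORDER, [True] * k_true + [False] * (7 - k_true)))
    s = score_mod.stress_score(labels)
    return CaseRecord(
        patient_id=pid, sex="M", age=65.0, day=day,
        assessment=StressAssessment(labels=labels, score=s,
                                    stressed=score_mod.classify_stress(s)),
    )


class TestNormalizeScores:
    def test_ratio_to_patient_max(self):
        cases = [_scored_case("P1", 1, 3), _scored_case("P1", 2, 6)]
        out = resp.normalize_scores_per_patient(cases)
        assert out.iloc[0] == pytest.approx(42.86 / 85.71)
        assert out.iloc[1] == pytest.approx(1.0)

    def test_all_zero_patient_gets_zero(self):
        cases = [_scored_case("P1", d, 0) for d in (1, 2, 3)]
        out = resp.normalize_scores_per_patient(cases)
        assert (out == 0.0).all()

    def test_single_case_is_one(self):
        out = resp.normalize_scores_per_patient([_scored_case("P1", 1, 5)])
        assert out.iloc[0] == 1.0


class TestAssociate:
    def test_slope_recovered(self, small_cohort):
        # small_cohort uses the default resp_slope 0.286
        r = resp.associate(small_cohort, "score10", "phase")
        assert r.lcl <= 0.286 <= r.ucl or abs(r.beta - 0.286) < 0.25

    def test_binary_predictor_positive_effect(self, small_cohort):
        r = resp.associate(small_cohort, "binary", "phase")
        assert r.beta > 0

    def test_ci_brackets_estimate(self, small_cohort):
        r = resp.associate(small_cohort, "score10", "amplitude")
        assert r.lcl <= r.beta <= r.ucl

    def test_single_cluster_falls_back_with_warning(self):
        cases = synth.generate_cohort(
            synth.CohortConfig(n_patients=1, days_per_patient=(5, 5), seed=3)
        )
        with pytest.warns(UserWarning, match="single"):
            r = resp.associate(cases, "score10", "phase")
        assert np.isfinite(r.beta)

    def test_noise_widens_ci(self):
        widths = []
        for noise in (0.5, 4.0):
            w = []
            for i in range(20):
                cfg = synth.CohortConfig(
                    n_patients=30, days_per_patient=(3, 3), noise_sd=noise,
                    patient_sd=0.5, seed=3000 + i,
                )
                r = resp.associate(synth.generate_cohort(cfg), "score10",
                                   "phase")
                w.append(r.ucl - r.lcl)
            widths.append(np.mean(w))
        assert widths[1] > widths[0]

    def test_bad_arguments_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            resp.associate(small_cohort, "nope")
        with pytest.raises(ValueError):
            resp.associate(small_cohort, "score10", "nope")
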
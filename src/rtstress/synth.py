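"""Synthetic PPG, breathing traces and patient cohorts.

The study design this package analyses — waiting-room vs in-treatment
PPG windows, seven directional HRV stress features, and breathing
traces whose irregularity grows with stress — involves patient
recordings that are not publicly deposited.  This module generates
signals and cohorts with the same statistical structure so that every
downstream stage is testable end-to-end without any download:

* ``generate_nn_series`` — spectrally constructed RR tachograms with
  controllable mean HR, SDNN and LF/HF ratio (band-limited Gaussian
  components in the LF 0.04-0.15 Hz and HF 0.15-0.4 Hz bands).
* ``synthesize_ppg`` — a two-Gaussian pulse template placed at each
  beat, plus noise and optional motion-burst artifacts; ground-truth
  beat times travel as side-channel metadata.
* ``generate_resp_trace`` — cycle-by-cycle breathing with configurable
  period and amplitude dispersion.
* ``generate_cohort`` — full patient-day case tables in which each
  feature moves in its stressful direction with probability
  ``p_stress`` and respiratory phase irregularity is linearly coupled
  to the realized stress score with patient-level random effects.

All randomness flows from one ``numpy.random.Generator`` seeded per
call; identical config + seed gives bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import hrv, score as score_mod
from .types import (
    FEATURE_ORDER,
    CaseRecord,
    HRVFeatures,
    IrregularityResult,
    NNSeries,
    SignalTrace,
)

__all__ = [
    "TachogramSpec",
    "ArtifactSpec",
    "CohortConfig",
    "generate_nn_series",
    "synthesize_ppg",
    "generate_resp_trace",
    "generate_cohort",
    "case_table",
]


@dataclass
class TachogramSpec:
    """Targets for one synthetic RR tachogram.

    mean_hr in bpm (30-180), sdnn_target in ms, lf_hf_target a
    non-negative ratio, duration in seconds.
    """

    mean_hr: float = 60.0
    sdnn_target: float = 40.0
    lf_hf_target: float = 1.5
    duration: float = 300.0

    def __post_init__(self) -> None:
        if not (30.0 <= self.mean_hr <= 180.0):
            raise ValueError("mean_hr must be within [30, 180] bpm")
        if self.sdnn_target < 0:
            raise ValueError("sdnn_target must be non-negative")
        if self.lf_hf_target < 0:
            raise ValueError("lf_hf_target must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class ArtifactSpec:
    """Motion-burst description: additive high-amplitude low-frequency
    oscillations over the listed ``(start_s, stop_s)`` spans."""

    bursts: Sequence[tuple[float, float]] = ()
    amplitude: float = 8.0
    freq_hz: float = 0.5


@dataclass
class CohortConfig:
    """Study-condition parameters for a synthetic cohort.

    Defaults emulate the reported study conditions: 41 patients, 1-5
    measurement days each, about two thirds male, ages 47-80, a
    per-feature stressful-shift probability of 0.5 (which puts ~47% of
    cases above the 50% score threshold, the observed share), and
    respiratory phase irregularity rising ~0.29 units per 10% of
    stress score around an intercept near 10 with patient-level random
    effects.  Amplitude irregularity carries the reported small slope
    with dispersion large enough that its association sits at the edge
    of detectability, as observed.
    """

    n_patients: int = 41
    days_per_patient: tuple[int, int] = (1, 5)
    sex_ratio: float = 0.66        # fraction male
    age_range: tuple[float, float] = (47.0, 80.0)
    p_stress: float = 0.5          # per-feature stressful-shift probability
    shift_magnitude: float = 0.2   # relative effect size per feature
    resp_slope: float = 0.286      # phase-irregularity increase per 10% score
    resp_intercept: float = 10.0
    patient_sd: float = 2.0        # between-patient random effect (phase irr)
    noise_sd: float = 1.5          # residual phase-irregularity noise
    amp_slope: float = 0.003       # amplitude-irregularity analogue
    amp_intercept: float = 0.143
    amp_patient_sd: float = 0.05
    amp_noise_sd: float = 0.035
    p_stress_sex_gap: float = 0.0  # male p = p + gap/2, female p - gap/2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sex_ratio", "p_stress"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        lo, hi = self.days_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("days_per_patient must be a positive range")
        if self.shift_magnitude <= 0:
            raise ValueError("shift_magnitude must be positive")


# ---------------------------------------------------------------------------
# Tachogram synthesis
# ---------------------------------------------------------------------------

def _band_limited_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance Gaussian noise whose spectrum is confined to
    [lo, hi] Hz (by frequency-domain masking of white noise)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def generate_nn_series(spec: TachogramSpec, seed: int = 0) -> NNSeries:
    """Synthesize an NN-interval series hitting the spec's targets.

    The RR modulation is the sum of two band-limited Gaussian
    components generated slightly inside the LF and HF bands (to limit
    spectral leakage across band edges), sampled at the beat times,
    orthogonalized and rescaled so the realized sample SDNN equals
    ``sdnn_target`` exactly and the in-sample LF:HF variance split
    equals ``lf_hf_target``.

    Raises ``ValueError`` when the spec would force intervals outside
    the physiological 300-2000 ms range.
    """
    rng = np.random.default_rng(seed)
    rr_mean = 60000.0 / spec.mean_hr
    s = spec.sdnn_target
    if rr_mean - 5 * s < 300.0 or rr_mean + 5 * s > 2000.0:
        raise ValueError(
            "unattainable tachogram spec: mean RR "
            f"{rr_mean:.0f} ms with SDNN {s:.0f} ms would push intervals "
            "outside the 300-2000 ms range"
        )

    if s == 0.0:
        n_beats = int(np.floor(spec.duration / (rr_mean / 1000.0))) + 1
        beat_times = np.arange(n_beats) * (rr_mean / 1000.0)
        nn = np.full(n_beats - 1, rr_mean)
        return NNSeries(beat_times=beat_times, nn_ms=nn)

    # continuous modulation on a 4 Hz grid, then walk the beat times
    fs_grid = 4.0
    n_grid = int(np.ceil((spec.duration + 4 * rr_mean / 1000.0) * fs_grid))
    x_lf = _band_limited_noise(rng, n_grid, fs_grid, 0.05, 0.14)
    x_hf = _band_limited_noise(rng, n_grid, fs_grid, 0.16, 0.38)
    r = spec.lf_hf_target
    a_hf = s / np.sqrt(1.0 + r)
    a_lf = s * np.sqrt(r / (1.0 + r))
    grid_t = np.arange(n_grid) / fs_grid
    rr_of_t = rr_mean + a_lf * x_lf + a_hf * x_hf

    t, beats = 0.0, [0.0]
    while t < spec.duration:
        rr = float(np.interp(t, grid_t, rr_of_t))
        t += rr / 1000.0
        beats.append(t)
    beat_times = np.array(beats)

    # re-evaluate components at beat times and normalize in-sample so
    # the realized SDNN and band-variance ratio are exact
    tb = beat_times[1:]
    xl = np.interp(tb, grid_t, x_lf)
    xh = np.interp(tb, grid_t, x_hf)
    xl = xl - xl.mean()
    xh = xh - xh.mean()
    sd_l = np.std(xl, ddof=1)
    if sd_l > 0:
        xl /= sd_l
        xh = xh - (xh @ xl) / (xl @ xl) * xl  # in-sample orthogonality
    sd_h = np.std(xh, ddof=1)
    if sd_h > 0:
        xh /= sd_h
    nn = rr_mean + a_lf * xl + a_hf * xh
    nn = np.clip(nn, 300.0, 2000.0)  # 5-sigma feasibility already enforced
    beat_times = np.concatenate([[0.0], np.cumsum(nn) / 1000.0])
    return NNSeries(beat_times=beat_times, nn_ms=nn)


# ---------------------------------------------------------------------------
# PPG synthesis
# ---------------------------------------------------------------------------

def _pulse_template(t: np.ndarray) -> np.ndarray:
    """Two-Gaussian pulse: systolic wave peaking at t=0, smaller
    diastolic wave 0.35 s later."""
    return np.exp(-0.5 * (t / 0.11) ** 2) + 0.35 * np.exp(
        -0.5 * ((t - 0.35) / 0.18) ** 2
    )


def synthesize_ppg(
    nn: NNSeries,
    fs: float = 100.0,
    noise_sd: float = 0.02,
    artifact_spec: Optional[ArtifactSpec] = None,
    seed: int = 0,
) -> SignalTrace:
    """Render an NN series as a PPG-like trace.

    One pulse template per beat, centered at the beat time; additive
    white noise of relative sd ``noise_sd``; optional motion bursts.
    Ground-truth beat times are stored in ``trace.meta["true_beats"]``.
    """
    if fs < 50.0:
        raise ValueError("fs must be at least 50 Hz for PPG synthesis")
    rng = np.random.default_rng(seed)
    duration = float(nn.beat_times[-1]) + 1.0
    n = int(np.ceil(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for bt in nn.beat_times:
        lo = max(0, int((bt - 0.7) * fs))
        hi = min(n, int((bt + 1.3) * fs))
        x[lo:hi] += _pulse_template(t[lo:hi] - bt)
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, n)
    meta = {"true_beats": nn.beat_times.copy(), "kind": "ppg"}
    if artifact_spec is not None and artifact_spec.bursts:
        spans = []
        for start, stop in artifact_spec.bursts:
            m = (t >= start) & (t < stop)
            x[m] += artifact_spec.amplitude * np.sin(
                2 * np.pi * artifact_spec.freq_hz * t[m]
            )
            spans.append((float(start), float(stop)))
        meta["artifact_spans"] = spans
    return SignalTrace(samples=x, fs=fs, meta=meta)


# ---------------------------------------------------------------------------
# Breathing synthesis
# ---------------------------------------------------------------------------

def generate_resp_trace(
    period_mean: float = 4.0,
    period_sd: float = 0.3,
    amp_mean: float = 1.0,
    amp_sd: float = 0.1,
    fs: float = 25.0,
    duration: float = 120.0,
    seed: int = 0,
) -> SignalTrace:
    """Breathing displacement with per-cycle period and amplitude draws.

    Cycle-by-cycle peak-to-peak periods are N(period_mean, period_sd)
    (truncated at half the mean) and extremum magnitudes
    N(amp_mean, amp_sd) (truncated at 5% of the mean); peaks and
    valleys alternate, joined by a monotone cubic so the extrema of the
    rendered trace sit exactly at the drawn knots.  Ground truth is
    kept in ``meta`` for testing.
    """
    if period_mean <= 0:
        raise ValueError("period_mean must be positive")
    if duration < 10 * period_mean:
        raise ValueError("duration must cover at least 10 breathing cycles")
    rng = np.random.default_rng(seed)
    n_cycles = int(np.ceil(duration / period_mean)) + 3

    periods = rng.normal(period_mean, period_sd, n_cycles)
    periods = np.maximum(periods, 0.5 * period_mean)
    peak_amps = np.maximum(rng.normal(amp_mean, amp_sd, n_cycles), 0.05 * amp_mean)
    valley_amps = np.maximum(
        rng.normal(amp_mean, amp_sd, n_cycles), 0.05 * amp_mean
    )

    # first peak sits one full cycle before t=0 so the rendered window is
    # interior to the knot sequence (PCHIP endpoint slopes never show)
    peak_times = -period_mean / 2 + np.concatenate(
        [[0.0], np.cumsum(periods[:-1])]
    )
    # valleys midway between consecutive peaks, plus one before the first
    valley_times = (peak_times[:-1] + peak_times[1:]) / 2.0
    valley_times = np.concatenate(
        [[peak_times[0] - period_mean / 2], valley_times]
    )

    knot_t = np.empty(peak_times.size + valley_times.size)
    knot_v = np.empty_like(knot_t)
    knot_t[0::2] = valley_times
    knot_t[1::2] = peak_times
    knot_v[0::2] = -valley_amps[: valley_times.size]
    knot_v[1::2] = peak_amps

    from scipy.interpolate import PchipInterpolator

    tgrid = np.arange(int(duration * fs)) / fs
    interp = PchipInterpolator(knot_t, knot_v, extrapolate=True)
    x = interp(tgrid)
    keep_p = (peak_times > 0) & (peak_times < duration)
    keep_v = (valley_times > 0) & (valley_times < duration)
    meta = {
        "kind": "resp",
        "true_peak_times": peak_times[keep_p],
        "true_peak_values": peak_amps[: peak_times.size][keep_p],
        "true_valley_times": valley_times[keep_v],
        "true_valley_values": -valley_amps[: valley_times.size][keep_v],
    }
    return SignalTrace(samples=x, fs=fs, meta=meta)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

_BASELINES = {
    "hr": (72.0, 8.0, 50.0, 110.0),       # normal: mean, sd, lo, hi
    "pnn50": (20.0, 8.0, 5.0, 60.0),
}
_LOG_BASELINES = {
    "sdnn": (3.55, 0.35, 12.0, 150.0),    # lognormal: mu, sigma, lo, hi
    "rmssd": (3.3, 0.4, 8.0, 120.0),
    "hf": (5.7, 0.6, 50.0, 2500.0),
    "lf_hf": (0.4, 0.45, 0.3, 6.0),
}


def _draw_baseline_features(rng: np.random.Generator) -> HRVFeatures:
    vals: dict[str, float] = {}
    for k, (m, s, lo, hi) in _BASELINES.items():
        vals[k] = float(np.clip(rng.normal(m, s), lo, hi))
    for k, (mu, sg, lo, hi) in _LOG_BASELINES.items():
        vals[k] = float(np.clip(rng.lognormal(mu, sg), lo, hi))
    hf = vals["hf"]
    lf = hf * vals["lf_hf"]
    tp = (lf + hf) * float(rng.uniform(1.1, 1.6))  # VLF remainder
    return HRVFeatures(
        hr=vals["hr"], sdnn=vals["sdnn"], rmssd=vals["rmssd"],
        pnn50=vals["pnn50"], lf=lf, hf=hf, lf_hf=vals["lf_hf"], tp=tp,
    )


def _shift_features(
    before: HRVFeatures,
    rng: np.random.Generator,
    p_stress: float,
    shift_magnitude: float,
) -> HRVFeatures:
    """Move each of the seven features in its stressful direction with
    probability ``p_stress`` (otherwise the opposite way), by a strictly
    positive relative magnitude."""
    d = before.as_dict()
    out = dict(d)
    for name in FEATURE_ORDER:
        stressful = rng.random() < p_stress
        direction = score_mod.STRESS_DIRECTIONS[name]  # +1 increase, -1 decrease
        sign = direction if stressful else -direction
        rel = shift_magnitude * float(np.clip(abs(rng.normal(1.0, 0.3)), 0.1, 4.0))
        rel = min(rel, 0.9)
        out[name] = d[name] * (1.0 + sign * rel)
    out["pnn50"] = float(np.clip(out["pnn50"], 0.0, 100.0))
    out["lf"] = out["hf"] * out["lf_hf"]
    return HRVFeatures(**out)


def generate_cohort(
    config: CohortConfig, with_traces: bool = False
) -> list[CaseRecord]:
    """Generate a full synthetic cohort of patient-day cases.

    Each case carries before/during features, the resulting stress
    assessment, and respiratory irregularity following

        phase_irr = intercept + resp_slope * score/10 + b_patient + eps

    with b_patient ~ N(0, patient_sd^2) and eps ~ N(0, noise_sd^2)
    (amplitude irregularity analogously, on its own scale).  With
    ``with_traces=True`` each case additionally carries raw synthetic
    PPG and breathing traces in ``case._traces`` keyed by phase.
    """
    rng = np.random.default_rng(config.seed)
    cases: list[CaseRecord] = []
    lo_d, hi_d = config.days_per_patient
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        male = rng.random() < config.sex_ratio
        sex = "M" if male else "F"
        age = float(rng.uniform(*config.age_range))
        n_days = int(rng.integers(lo_d, hi_d + 1))
        b_phase = rng.normal(0.0, config.patient_sd)
        b_amp = rng.normal(0.0, config.amp_patient_sd)
        p = config.p_stress + (0.5 if male else -0.5) * config.p_stress_sex_gap
        p = float(np.clip(p, 0.0, 1.0))
        for day in range(1, n_days + 1):
            before = _draw_baseline_features(rng)
            during = _shift_features(before, rng, p, config.shift_magnitude)
            assessment = score_mod.assess(before, during)
            phase_irr = (
                config.resp_intercept
                + config.resp_slope * assessment.score / 10.0
                + b_phase
                + rng.normal(0.0, config.noise_sd)
            )
            amp_irr = (
                config.amp_intercept
                + config.amp_slope * assessment.score / 10.0
                + b_amp
                + rng.normal(0.0, config.amp_noise_sd)
            )
            irr = IrregularityResult(
                amplitude_irr=max(amp_irr, 0.0), phase_irr=max(phase_irr, 0.0)
            )
            case = CaseRecord(
                patient_id=pid, sex=sex, age=age, day=day,
                before=before, during=during,
                assessment=assessment, irregularity=irr,
            )
            if with_traces:
                case._traces = _case_traces(case, config, rng)  # type: ignore[attr-defined]
            cases.append(case)
    return cases


def _case_traces(
    case: CaseRecord, config: CohortConfig, rng: np.random.Generator
) -> dict:
    """Raw before/during PPG plus a breathing trace consistent with the
    case's controllable feature targets (HR, SDNN, LF/HF)."""
    traces = {}
    for phase in ("before", "during"):
        feats: HRVFeatures = getattr(case, phase)
        spec = TachogramSpec(
            mean_hr=float(np.clip(feats.hr, 40.0, 150.0)),
            sdnn_target=float(np.clip(feats.sdnn, 5.0, 120.0)),
            lf_hf_target=feats.lf_hf if feats.lf_hf is not None else 1.0,
            duration=300.0,
        )
        nn = generate_nn_series(spec, seed=int(rng.integers(2**31)))
        traces[phase] = synthesize_ppg(nn, seed=int(rng.integers(2**31)))
    traces["resp"] = generate_resp_trace(
        period_sd=max(case.irregularity.phase_irr / 10.0, 0.01),
        amp_sd=max(case.irregularity.amplitude_irr, 0.01),
        seed=int(rng.integers(2**31)),
    )
    return traces


def case_table(cases: list[CaseRecord]):
    """Flatten cases into a pandas DataFrame (one row per patient-day)."""
    import pandas as pd

    rows = []
    for c in cases:
        row: dict = {
            "patient_id": c.patient_id, "sex": c.sex,
            "age": c.age, "day": c.day,
        }
        for phase in ("before", "during"):
            f: Optional[HRVFeatures] = getattr(c, phase)
            if f is not None:
                for k, v in f.as_dict().items():
                    row[f"{phase}_{k}"] = np.nan if v is None else v
        if c.assessment is not None:
            for k in FEATURE_ORDER:
                row[f"l_{k}"] = bool(c.assessment.labels[k])
            row["score"] = c.assessment.score
            row["stressed"] = bool(c.assessment.stressed)
        if c.irregularity is not None:
            row["phase_irr"] = c.irregularity.phase_irr
            row["amplitude_irr"] = c.irregularity.amplitude_irr
        rows.append(row)
    return pd.DataFrame(rows)
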
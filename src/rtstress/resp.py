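"""Respiratory irregularity and its association with stress.

Gated radiotherapy delivery depends on a regular breathing cycle, so
the dispersion of the breathing trace's extrema is the clinically
relevant summary.  Irregularity is defined as the mean of the standard
deviations of the peaks and of the valleys:

    irregularity = (STD(peaks) + STD(valleys)) / 2

computed over extremum *values* for amplitude irregularity and over
successive same-type extremum-to-extremum *periods* for phase
irregularity (sample sd, n-1 denominator, consistent with SDNN).

The association between stress and irregularity across repeated
patient-days is estimated with generalized estimating equations (GEE):
a marginal linear model with patient clusters, exchangeable working
correlation and robust (sandwich) standard errors.  The predictor is
either the stress score per 10% increment or the binary stressed
yes/no call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    AssociationResult,
    CaseRecord,
    ExtremaSeries,
    IrregularityResult,
    SignalTrace,
)

__all__ = [
    "ExtremaConfig",
    "detect_extrema",
    "irregularity",
    "normalize_scores_per_patient",
    "associate",
]


@dataclass
class ExtremaConfig:
    """Breathing-extremum detector knobs: 0.5 s moving-average
    smoothing, 1.5 s minimum extremum separation (breathing stays
    below 40 cycles/min), prominence as a fraction of the smoothed
    signal's peak-to-peak range."""

    smooth_s: float = 0.5
    min_separation_s: float = 1.5
    prominence_frac: float = 0.1


def detect_extrema(
    trace: SignalTrace, config: ExtremaConfig | None = None
) -> ExtremaSeries:
    """Detect alternating breathing peaks and valleys.

    The trace is smoothed with a moving average, maxima/minima are
    found with minimum-separation and prominence constraints, strict
    alternation is enforced by keeping the more extreme of same-sign
    neighbours, and each extremum is refined to sub-sample precision
    by parabolic interpolation.
    """
    from scipy import signal as sps

    cfg = config or ExtremaConfig()
    if trace.duration < 30.0:
        raise ValueError("need at least 30 s of breathing signal")
    x = trace.samples
    fs = trace.fs
    from scipy.ndimage import uniform_filter1d

    w = max(int(cfg.smooth_s * fs), 1) | 1  # odd: no half-sample lag
    xs = uniform_filter1d(x, w, mode="nearest")

    rng_amp = np.ptp(xs)
    if rng_amp == 0:
        raise ValueError("too few breathing cycles: flat signal")
    dist = max(int(cfg.min_separation_s * fs), 1)
    prom = cfg.prominence_frac * rng_amp
    p_idx, _ = sps.find_peaks(xs, distance=dist, prominence=prom)
    v_idx, _ = sps.find_peaks(-xs, distance=dist, prominence=prom)
    if p_idx.size < 3 or v_idx.size < 3:
        raise ValueError(
            f"too few breathing cycles: {p_idx.size} peaks, "
            f"{v_idx.size} valleys"
        )

    # enforce strict alternation: among consecutive same-type extrema
    # keep the more extreme one
    events = sorted(
        [(i, +1) for i in p_idx] + [(i, -1) for i in v_idx]
    )
    kept: list[tuple[int, int]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            better = (
                xs[idx] > xs[prev] if kind == +1 else xs[idx] < xs[prev]
            )
            if better:
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))

    def refine(i: int) -> tuple[float, float]:
        if 0 < i < xs.size - 1:
            y0, y1, y2 = xs[i - 1], xs[i], xs[i + 1]
            denom = y0 - 2 * y1 + y2
            d = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            d = float(np.clip(d, -1, 1))
            return (i + d) / fs, float(y1 - 0.25 * (y0 - y2) * d)
        return i / fs, float(xs[i])

    # extrema within a smoothing window of the trace edges are boundary
    # artifacts of the moving average / truncated cycles; drop them
    margin = cfg.smooth_s
    pt, pv, vt, vv = [], [], [], []
    for idx, kind in kept:
        t, val = refine(idx)
        if not (margin <= t <= trace.duration - margin):
            continue
        if kind == +1:
            pt.append(t)
            pv.append(val)
        else:
            vt.append(t)
            vv.append(val)
    return ExtremaSeries(
        peak_times=pt, peak_values=pv, valley_times=vt, valley_values=vv
    )


def irregularity(
    extrema: ExtremaSeries, amplitude_mode: str = "values"
) -> IrregularityResult:
    """Mean-of-dispersions irregularity in amplitude and phase.

    amplitude = [sd(peak values) + sd(valley values)] / 2 (signal
    units); phase = [sd(peak-to-peak periods) + sd(valley-to-valley
    periods)] / 2 (seconds).  Sample sd throughout.

    ``amplitude_mode="excursions"`` instead takes the sd of successive
    extremum-to-extremum excursions (peak-to-valley swings), which is
    insensitive to slow baseline drift of the whole trace.
    """
    if extrema.peak_times.size < 3 or extrema.valley_times.size < 3:
        raise ValueError("need at least 3 peaks and 3 valleys")
    if amplitude_mode == "values":
        amp = (
            np.std(extrema.peak_values, ddof=1)
            + np.std(extrema.valley_values, ddof=1)
        ) / 2.0
    elif amplitude_mode == "excursions":
        order = np.argsort(
            np.concatenate([extrema.peak_times, extrema.valley_times])
        )
        vals = np.concatenate(
            [extrema.peak_values, extrema.valley_values]
        )[order]
        amp = np.std(np.abs(np.diff(vals)), ddof=1)
    else:
        raise ValueError("amplitude_mode must be 'values' or 'excursions'")
    phase = (
        np.std(np.diff(extrema.peak_times), ddof=1)
        + np.std(np.diff(extrema.valley_times), ddof=1)
    ) / 2.0
    return IrregularityResult(amplitude_irr=float(amp), phase_irr=float(phase))


def normalize_scores_per_patient(cases: list[CaseRecord]) -> pd.Series:
    """Each case's score divided by its patient's maximum score.

    Patients whose every score is zero get 0 by convention.  Returns a
    Series aligned with the input order.
    """
    scores = pd.Series(
        [c.assessment.score for c in cases], dtype=float, name="norm_score"
    )
    pids = pd.Series([c.patient_id for c in cases])
    pmax = scores.groupby(pids).transform("max")
    out = scores.where(pmax == 0, scores / pmax.replace(0, np.nan))
    return out.fillna(0.0)


def associate(
    cases: list[CaseRecord],
    predictor_kind: str = "score10",
    outcome: str = "phase",
) -> AssociationResult:
    """GEE association between stress and respiratory irregularity.

    ``predictor_kind`` is ``"score10"`` (stress score / 10, so the
    coefficient is the irregularity change per 10% score increment) or
    ``"binary"`` (stressed yes=1 / no=0).  ``outcome`` selects phase or
    amplitude irregularity.  Patient clusters use an exchangeable
    working correlation with robust standard errors; with a single
    cluster the fit falls back to ordinary least squares with
    heteroskedasticity-robust errors and a warning.
    """
    import statsmodels.api as sm

    rows = [
        c for c in cases if c.irregularity is not None and c.assessment is not None
    ]
    if predictor_kind == "score10":
        x = np.array([c.assessment.score / 10.0 for c in rows])
    elif predictor_kind == "binary":
        x = np.array([1.0 if c.assessment.stressed else 0.0 for c in rows])
    else:
        raise ValueError("predictor_kind must be 'score10' or 'binary'")
    if outcome == "phase":
        y = np.array([c.irregularity.phase_irr for c in rows])
    elif outcome == "amplitude":
        y = np.array([c.irregularity.amplitude_irr for c in rows])
    else:
        raise ValueError("outcome must be 'phase' or 'amplitude'")
    groups = np.array([c.patient_id for c in rows])
    n_patients = np.unique(groups).size
    if n_patients < 1 or y.size < 3:
        raise ValueError("need at least 2 patients with irregularity data")

    exog = sm.add_constant(x)
    if n_patients == 1:
        warnings.warn(
            "single patient cluster: falling back to ordinary robust "
            "regression",
            UserWarning,
        )
        res = sm.OLS(y, exog).fit(cov_type="HC1")
    else:
        model = sm.GEE(
            y, exog, groups=groups,
            cov_struct=sm.cov_struct.Exchangeable(),
            family=sm.families.Gaussian(),
        )
        res = model.fit()
    ci = res.conf_int()
    ci = np.asarray(ci)
    return AssociationResult(
        beta=float(res.params[1]),
        lcl=float(ci[1, 0]),
        ucl=float(ci[1, 1]),
        p_value=float(res.pvalues[1]),
        predictor_kind=predictor_kind,
        outcome=outcome,
        n_cases=int(y.size),
        n_patients=int(n_patients),
    )
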
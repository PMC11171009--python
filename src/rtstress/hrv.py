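"""Heart-rate-variability features from a cleaned NN-interval series.

Seven features are computed per 5-minute analysis window: mean heart
rate (HR), SDNN, RMSSD, pNN50 in the time domain, and HF power, LF/HF
ratio and total power (TP) in the frequency domain (LF power is kept as
the intermediate required by the ratio).

Frequency-domain powers follow the conventional band definitions:
LF 0.04-0.15 Hz, HF 0.15-0.4 Hz, TP 0.004-0.4 Hz.  The tachogram is
resampled to an even grid with a cubic spline, mean-removed, and a
Welch estimate is integrated over each band.  With 300 s windows the
0.004 Hz lower TP edge sits at the resolution limit, so TP integration
effectively starts at the first positive frequency bin.  A Lomb-Scargle
estimator on the uneven series is available as a config alternative and
serves as an independent cross-check in the test-suite.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .types import HRVFeatures, NNSeries

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "TP_BAND",
    "time_domain",
    "frequency_domain",
    "compute_features",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
TP_BAND = (0.004, 0.4)

#: HF power (ms^2) below this floor makes the LF/HF ratio undefined.
_HF_FLOOR = 1e-12

#: Minimum NN intervals for time-domain features (5-min windows carry
#: hundreds; fewer than this means the window is unusable).
MIN_INTERVALS = 30


def time_domain(nn: NNSeries) -> tuple[float, float, float, float]:
    """Return ``(hr, sdnn, rmssd, pnn50)`` for a cleaned NN series.

    hr = 60000 / mean(nn_ms); sdnn uses the sample (n-1) denominator;
    rmssd is the root-mean-square of successive differences; pnn50 the
    percentage of successive differences exceeding 50 ms in magnitude.
    """
    x = np.asarray(nn.nn_ms, dtype=float)
    if x.size < MIN_INTERVALS:
        raise ValueError(
            f"too few NN intervals for HRV ({x.size} < {MIN_INTERVALS})"
        )
    hr = 60000.0 / float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    d = np.diff(x)
    rmssd = float(np.sqrt(np.mean(d**2)))
    pnn50 = 100.0 * float(np.mean(np.abs(d) > 50.0))
    return hr, sdnn, rmssd, pnn50


def _resample_tachogram(
    nn: NNSeries, fs_resample: float
) -> tuple[np.ndarray, float]:
    """Evenly resample the tachogram (NN value at its ending beat time)."""
    t = nn.beat_times
    x = nn.nn_ms
    if x.size == t.size - 1:
        # interval i ends at beat i+1
        tx = t[1:]
    elif x.size == t.size:
        tx = t
    else:
        # cleaned series: reconstruct times from cumulative intervals
        tx = np.cumsum(x) / 1000.0
    grid = np.arange(tx[0], tx[-1], 1.0 / fs_resample)
    if np.unique(tx).size < 4:
        return np.full(grid.size, float(np.mean(x))), fs_resample
    spline = CubicSpline(tx, x)
    return spline(grid), fs_resample


def frequency_domain(
    nn: NNSeries,
    *,
    fs_resample: float = 4.0,
    estimator: str = "welch",
    lf_band: tuple[float, float] = LF_BAND,
    hf_band: tuple[float, float] = HF_BAND,
    tp_band: tuple[float, float] = TP_BAND,
) -> tuple[float, float, float, float | None]:
    """Return ``(lf, hf, tp, lf_hf)`` band powers in ms^2.

    The mean-removed, cubic-resampled tachogram is analysed with a
    Welch estimator whose window is the full segment capped at 300 s
    (50% overlap when the record is longer).  ``estimator="lomb"``
    instead evaluates a normalized Lomb-Scargle periodogram on the
    uneven series.  ``lf_hf`` is ``None`` (undefined) when HF power is
    zero to machine precision; callers must not substitute infinity.
    """
    total_s = float(np.sum(nn.nn_ms)) / 1000.0
    if total_s < 120.0:
        raise ValueError("need at least 2 min of NN data for band powers")

    if estimator == "welch":
        x, fsr = _resample_tachogram(nn, fs_resample)
        x = x - np.mean(x)
        # longest window that fits the record, capped at 300 s (50%
        # overlap beyond that); rectangular window so the discrete
        # Parseval identity holds exactly — tapering re-weights the
        # realization and inflates band-power variance on 5-min records
        nperseg = min(x.size, int(300 * fsr))
        f, psd = sps.welch(
            x, fs=fsr, nperseg=nperseg, noverlap=nperseg // 2,
            window="boxcar", detrend=False,
        )
    elif estimator == "lomb":
        f, psd = _lomb_psd(nn)
    else:
        raise ValueError(f"unknown spectral estimator: {estimator!r}")

    df = f[1] - f[0] if f.size > 1 else 1.0

    def band_power(lo: float, hi: float) -> float:
        m = (f >= lo) & (f < hi) & (f > 0)
        return float(np.sum(psd[m]) * df)

    lf = band_power(*lf_band)
    hf = band_power(*hf_band)
    tp = band_power(*tp_band)
    lf_hf = None if hf <= _HF_FLOOR else lf / hf
    return lf, hf, tp, lf_hf


def _lomb_psd(nn: NNSeries, n_freq: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Lomb-Scargle PSD of the uneven tachogram, normalized so the
    integral over the analysed band equals the series variance
    (Parseval; valid because HRV tachograms are band-limited)."""
    t = nn.beat_times
    x = nn.nn_ms
    tx = t[1:] if x.size == t.size - 1 else np.cumsum(x) / 1000.0
    x = x - np.mean(x)
    f = np.linspace(0.004, 0.4, n_freq)
    if np.allclose(x, 0.0):
        return f, np.zeros_like(f)
    pgram = sps.lombscargle(tx, x, 2 * np.pi * f)
    df = f[1] - f[0]
    total = np.sum(pgram) * df
    psd = pgram * (np.var(x) / total) if total > 0 else pgram
    return f, psd


def compute_features(nn: NNSeries, **freq_kwargs) -> HRVFeatures:
    """Compose time- and frequency-domain features into one record."""
    hr, sdnn, rmssd, pnn50 = time_domain(nn)
    lf, hf, tp, lf_hf = frequency_domain(nn, **freq_kwargs)
    return HRVFeatures(
        hr=hr, sdnn=sdnn, rmssd=rmssd, pnn50=pnn50,
        lf=lf, hf=hf, lf_hf=lf_hf, tp=tp,
    )
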
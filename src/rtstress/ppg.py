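"""PPG cleaning, phase segmentation, beat detection and NN extraction.

The raw finger-PPG recording covers the waiting room and the treatment
session.  Processing follows four steps:

1. ``remove_artifacts`` masks motion bursts, sensor flatlines and
   clipping without touching sample values.
2. ``segment_phases`` cuts, for each phase, exactly 5 minutes of data
   starting 2 minutes after the phase mark (the stabilization period
   that absorbs heart-rate elevation due to walking / lying down).
3. ``detect_beats`` band-passes the signal (0.5-8 Hz), takes a
   smoothed (Savitzky-Golay) second derivative and places beats where
   the pulse curvature is most negative — the apex of each systolic
   wave — subject to an adaptive prominence threshold and a 0.3 s
   refractory period (caps detection at 200 bpm).
4. ``beats_to_nn`` converts beats to normal-to-normal intervals and
   drops physiologically impossible (outside 300-2000 ms) or ectopic
   (>20% off the 11-beat rolling median) intervals.

Times are seconds from recording start; windows are half-open
``[start, stop)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

from .types import (
    InsufficientNNWarning,
    InsufficientRecordingError,
    NNSeries,
    SignalTrace,
    TooFewBeatsWarning,
    UnusableSignalError,
)

__all__ = [
    "ArtifactConfig",
    "BeatConfig",
    "remove_artifacts",
    "segment_phases",
    "detect_beats",
    "beats_to_nn",
]


@dataclass
class ArtifactConfig:
    """Thresholds for the three artifact rules.

    flatline: rolling std over ``flatline_window_s`` below
    ``flatline_rel_floor`` x the robust (IQR-based) signal sd.
    clipping: >= ``clip_run`` consecutive samples pinned at the trace
    extrema.  outlier: robust |z| > ``z_max``.  Outlier spans are
    morphologically closed over ``bridge_s`` and dilated by ``pad_s``
    so an oscillating motion burst is masked through its zero
    crossings.
    """

    flatline_window_s: float = 2.0
    flatline_rel_floor: float = 1e-4
    clip_run: int = 3
    z_max: float = 5.0
    outlier_window_s: float = 10.0
    bridge_s: float = 1.0
    pad_s: float = 0.3


@dataclass
class BeatConfig:
    band: tuple[float, float] = (0.5, 8.0)
    sg_window_s: float = 0.13     # Savitzky-Golay differentiation window
    refractory_s: float = 0.3
    prominence_frac: float = 2.5  # of the rolling IQR of the curvature
    min_beats: int = 30


def _robust_sd(x: np.ndarray) -> float:
    q75, q25 = np.percentile(x, [75, 25])
    return (q75 - q25) / 1.349


def remove_artifacts(
    trace: SignalTrace, config: ArtifactConfig | None = None
) -> SignalTrace:
    """Mask flatline, clipping and amplitude-outlier spans.

    Returns a new trace with an updated ``valid_mask`` (samples
    untouched) and per-reason masked spans in
    ``meta["artifact_report"]``.  Raises :class:`UnusableSignalError`
    when nothing valid remains, mirroring the exclusion of recordings
    with sensor malfunction.
    """
    cfg = config or ArtifactConfig()
    x = trace.samples
    if x.size == 0:
        raise ValueError("empty trace")
    fs = trace.fs
    bad = {}

    # flatline: rolling std below a floor tied to the robust global sd
    w = max(int(cfg.flatline_window_s * fs), 2)
    mean = ndimage.uniform_filter1d(x, w, mode="nearest")
    sq = ndimage.uniform_filter1d(x**2, w, mode="nearest")
    roll_sd = np.sqrt(np.maximum(sq - mean**2, 0.0))
    gsd = _robust_sd(x)
    floor = cfg.flatline_rel_floor * gsd
    bad["flatline"] = roll_sd <= floor  # catches exactly-constant traces

    # clipping: runs of >= clip_run samples at the trace extrema
    clip = np.zeros(x.size, dtype=bool)
    for extreme in (x.max(), x.min()):
        at = x == extreme
        lbl, n = ndimage.label(at)
        for sl in ndimage.find_objects(lbl):
            if sl[0].stop - sl[0].start >= cfg.clip_run:
                clip[sl[0]] = True
    bad["clipping"] = clip

    # amplitude outliers: robust z against the global baseline,
    # evaluated over short windows, closed+padded over burst spans
    med = np.median(x)
    z = np.abs(x - med) / gsd if gsd > 0 else np.zeros_like(x)
    out = z > cfg.z_max
    if out.any():
        bridge = max(int(cfg.bridge_s * fs), 1)
        out = ndimage.binary_closing(out, structure=np.ones(bridge))
        pad = max(int(cfg.pad_s * fs), 1)
        out = ndimage.binary_dilation(out, structure=np.ones(pad))
    bad["outlier"] = out

    mask = trace.valid_mask.copy()
    report = []
    for reason, b in bad.items():
        mask &= ~b
        for sl in ndimage.find_objects(ndimage.label(b)[0]):
            report.append(
                {
                    "reason": reason,
                    "start_s": sl[0].start / fs,
                    "stop_s": sl[0].stop / fs,
                }
            )
    if not mask.any():
        raise UnusableSignalError(
            "unusable segment: entire trace masked by artifact rules"
        )
    meta = dict(trace.meta)
    meta["artifact_report"] = report
    return SignalTrace(
        samples=x.copy(), fs=fs, valid_mask=mask,
        phase_marks=dict(trace.phase_marks), meta=meta,
    )


STABILIZATION_S = 120.0
WINDOW_S = 300.0


def segment_phases(trace: SignalTrace) -> tuple[SignalTrace, SignalTrace]:
    """Cut the before/during analysis windows.

    Each window is exactly 300 s starting 120 s after its phase mark
    (half-open).  Requires both ``"before"`` and ``"during"`` phase
    marks and at least 420 s of recording in each phase; the validity
    mask propagates into the windows.
    """
    for key in ("before", "during"):
        if key not in trace.phase_marks:
            raise ValueError(f"missing phase mark: {key!r}")
    need = STABILIZATION_S + WINDOW_S
    bounds = {
        "before": (trace.phase_marks["before"], trace.phase_marks["during"]),
        "during": (trace.phase_marks["during"], trace.duration),
    }
    out = []
    for phase, (mark, end) in bounds.items():
        if end - mark < need:
            raise InsufficientRecordingError(
                f"insufficient recording in {phase!r} phase: "
                f"{end - mark:.0f} s < {need:.0f} s"
            )
        i0 = int(np.ceil((mark + STABILIZATION_S) * trace.fs))
        i1 = i0 + int(WINDOW_S * trace.fs)
        out.append(
            SignalTrace(
                samples=trace.samples[i0:i1].copy(),
                fs=trace.fs,
                valid_mask=trace.valid_mask[i0:i1].copy(),
                phase_marks={phase: 0.0},
                meta={**trace.meta, "window_start_s": i0 / trace.fs,
                      "phase": phase},
            )
        )
    return out[0], out[1]


def detect_beats(
    trace: SignalTrace, config: BeatConfig | None = None
) -> np.ndarray:
    """Detect beat times from the curvature of the band-passed PPG.

    The signal is band-passed 0.5-8 Hz, differentiated twice with a
    Savitzky-Golay filter (raw double differencing amplifies noise),
    and candidate beats are local maxima of the negative second
    derivative — the point of strongest downward curvature, i.e. the
    systolic apex.  Candidates need prominence above
    ``prominence_frac`` of the rolling inter-quartile curvature range
    (adaptive, so absolute sensor gain does not matter) and are
    separated by the refractory period.  Beats inside masked spans are
    discarded and each survivor is refined to the sub-sample apex of
    the band-passed pulse by parabolic interpolation.
    """
    cfg = config or BeatConfig()
    fs = trace.fs
    if fs < 50.0:
        raise ValueError("sampling rate too low for beat detection (fs < 50 Hz)")
    x = trace.samples
    sos = sps.butter(3, cfg.band, btype="band", fs=fs, output="sos")
    xb = sps.sosfiltfilt(sos, x)

    win = int(cfg.sg_window_s * fs) | 1  # odd
    win = max(win, 5)
    d2 = sps.savgol_filter(xb, win, polyorder=3, deriv=2)
    curv = -d2

    def _finish(times: np.ndarray) -> np.ndarray:
        if trace.duration >= WINDOW_S and times.size < cfg.min_beats:
            warnings.warn(
                f"too few beats: {times.size} in a "
                f"{trace.duration:.0f} s window",
                TooFewBeatsWarning,
            )
        return times

    # adaptive prominence: fraction of the rolling IQR of the curvature
    iqr_global = np.subtract(*np.percentile(curv, [75, 25]))
    if iqr_global == 0:
        return _finish(np.array([]))
    peaks, _ = sps.find_peaks(
        curv,
        distance=max(int(cfg.refractory_s * fs), 1),
        prominence=1e-12,
    )
    if peaks.size == 0:
        return _finish(np.array([]))
    prom = sps.peak_prominences(curv, peaks)[0]
    # rolling IQR on ~10 s windows, interpolated at peak positions
    seg = int(10 * fs)
    centers, iqrs = [], []
    for start in range(0, curv.size, seg):
        chunk = curv[start:start + seg]
        if chunk.size < 10:
            continue
        centers.append(start + chunk.size / 2)
        iqrs.append(np.subtract(*np.percentile(chunk, [75, 25])))
    if centers:
        local_iqr = np.interp(peaks, centers, iqrs)
    else:
        local_iqr = np.full(peaks.size, iqr_global)
    local_iqr = np.maximum(local_iqr, 0.1 * iqr_global)
    # second, scale-free floor: a real systolic peak is never far below
    # the upper prominence envelope; kills filter ripple on sparse traces
    floor = 0.25 * np.percentile(prom, 90)
    keep = prom >= np.maximum(cfg.prominence_frac * local_iqr, floor)
    peaks = peaks[keep]

    # discard beats in masked spans
    peaks = peaks[trace.valid_mask[peaks]]

    # refine to the sub-sample apex of the band-passed pulse
    times = np.empty(peaks.size)
    half = max(int(0.1 * fs), 2)
    for j, p in enumerate(peaks):
        lo, hi = max(p - half, 0), min(p + half + 1, xb.size)
        k = lo + int(np.argmax(xb[lo:hi]))
        if 0 < k < xb.size - 1:
            y0, y1, y2 = xb[k - 1], xb[k], xb[k + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -1.0, 1.0))
        else:
            delta = 0.0
        times[j] = (k + delta) / fs
    return _finish(np.unique(times))


NN_RANGE_MS = (300.0, 2000.0)
NN_MEDIAN_WINDOW = 11
NN_MEDIAN_TOL = 0.2
MIN_NN = 30


def beats_to_nn(beat_times: np.ndarray) -> NNSeries:
    """Convert beat times to a cleaned NN-interval series.

    Successive differences in ms; intervals outside 300-2000 ms are
    removed, then intervals deviating more than 20% from the 11-beat
    centered rolling median.  Removal counts are kept on the result;
    fewer than 30 survivors triggers an :class:`InsufficientNNWarning`.
    """
    bt = np.asarray(beat_times, dtype=float)
    if bt.size < 2:
        raise ValueError("need at least 2 beats for NN intervals")
    nn = np.diff(bt) * 1000.0
    in_range = (nn >= NN_RANGE_MS[0]) & (nn <= NN_RANGE_MS[1])
    nn1 = nn[in_range]
    removed = int(nn.size - nn1.size)

    if nn1.size:
        import pandas as pd

        med = (
            pd.Series(nn1)
            .rolling(NN_MEDIAN_WINDOW, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
        ok = np.abs(nn1 - med) <= NN_MEDIAN_TOL * med
        removed += int(nn1.size - ok.sum())
        nn2 = nn1[ok]
    else:
        nn2 = nn1

    if nn2.size < MIN_NN:
        warnings.warn(
            f"insufficient NN data: {nn2.size} surviving intervals",
            InsufficientNNWarning,
        )
    return NNSeries(beat_times=bt, nn_ms=nn2, n_removed=removed)
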
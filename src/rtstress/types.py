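"""Core domain containers shared by every stage of the pipeline.

The pipeline moves through a small set of value objects: a raw sensor
trace (:class:`SignalTrace`), the cleaned beat/interval series
(:class:`NNSeries`), the seven heart-rate-variability features
(:class:`HRVFeatures`), the directional stress assessment
(:class:`StressAssessment`) and one patient-day record
(:class:`CaseRecord`).  All containers are plain frozen-ish dataclasses
holding numpy arrays or floats; they carry no behaviour beyond
validation so that every stage can be tested in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "SignalTrace",
    "NNSeries",
    "HRVFeatures",
    "StressAssessment",
    "CaseRecord",
    "ExtremaSeries",
    "IrregularityResult",
    "AssociationResult",
    "UnusableSignalError",
    "InsufficientRecordingError",
    "TooFewBeatsWarning",
    "InsufficientNNWarning",
    "FEATURE_ORDER",
]

#: Canonical order of the seven stress features used everywhere a
#: feature vector is flattened (scoring labels, prediction inputs,
#: serialized case tables).
FEATURE_ORDER = ("hr", "sdnn", "rmssd", "pnn50", "hf", "lf_hf", "tp")


class UnusableSignalError(ValueError):
    """A trace is entirely masked (sensor malfunction / flatline)."""


class InsufficientRecordingError(ValueError):
    """A phase is too short to cut the stabilization + analysis window."""


class TooFewBeatsWarning(UserWarning):
    """Fewer than the minimum expected beats were found in a window."""


class InsufficientNNWarning(UserWarning):
    """Fewer than the minimum NN intervals survive cleaning."""


@dataclass
class SignalTrace:
    """Uniformly sampled sensor signal (PPG or respiratory displacement).

    Parameters
    ----------
    samples : ndarray
        Signal values in sensor units.
    fs : float
        Sampling rate in Hz (> 0).
    valid_mask : ndarray of bool, optional
        Per-sample validity; defaults to all-valid.  Artifact removal
        only ever clears bits here, never touches ``samples``.
    phase_marks : dict
        Labeled timestamps in seconds from recording start, e.g.
        ``{"before": 0.0, "during": 900.0}`` for waiting-room entry and
        treatment-couch start.
    meta : dict
        Free-form side-channel (synthetic ground truth, units, source).
    """

    samples: np.ndarray
    fs: float
    valid_mask: Optional[np.ndarray] = None
    phase_marks: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.samples.size, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.size != self.samples.size:
            raise ValueError("valid_mask length must equal sample length")

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds from recording start."""
        return np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class NNSeries:
    """Beat times (s) and cleaned normal-to-normal intervals (ms).

    ``nn_ms[i]`` is the interval ending at ``beat_times[i + 1]`` before
    cleaning; after cleaning ``nn_ms`` may be shorter than
    ``len(beat_times) - 1`` and ``n_removed`` records how many intervals
    the range and rolling-median rules discarded.
    """

    beat_times: np.ndarray
    nn_ms: np.ndarray
    n_removed: int = 0

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.nn_ms = np.asarray(self.nn_ms, dtype=float)
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.nn_ms.size)


@dataclass
class HRVFeatures:
    """The seven stress features plus LF as an intermediate.

    Units: ``hr`` bpm, ``sdnn``/``rmssd`` ms, ``pnn50`` percent,
    ``lf``/``hf``/``tp`` ms^2, ``lf_hf`` dimensionless.  ``lf_hf`` is
    ``None`` when HF power is exactly zero (undefined ratio) — callers
    must handle the undefined case explicitly.
    """

    hr: float
    sdnn: float
    rmssd: float
    pnn50: float
    lf: float
    hf: float
    lf_hf: Optional[float]
    tp: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def vector(self) -> np.ndarray:
        """The seven features in canonical order (undefined lf_hf -> nan)."""
        d = self.as_dict()
        return np.array(
            [np.nan if d[k] is None else float(d[k]) for k in FEATURE_ORDER]
        )


@dataclass
class StressAssessment:
    """Directional labels, quantized stress score and binary call.

    ``labels`` maps feature name -> True when the during-treatment value
    moved in the stressful direction.  ``score`` is ``100 * k / 7``
    rounded half-up to two decimals (k = number of true labels), so it
    lies in {0, 14.29, 28.57, 42.86, 57.14, 71.43, 85.71, 100}.
    ``stressed`` is the binary call ``score > 50``.
    """

    labels: dict
    score: float
    stressed: bool
    flags: tuple = ()

    @property
    def n_stressful(self) -> int:
        return sum(bool(v) for v in self.labels.values())


@dataclass
class CaseRecord:
    """One patient-day: covariates, feature pair, assessment, breathing."""

    patient_id: str
    sex: str  # "M" / "F"
    age: float
    day: int
    before: Optional[HRVFeatures] = None
    during: Optional[HRVFeatures] = None
    assessment: Optional[StressAssessment] = None
    irregularity: Optional["IrregularityResult"] = None

    def __post_init__(self) -> None:
        if self.day < 1:
            raise ValueError("treatment day index must be >= 1")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")


@dataclass
class ExtremaSeries:
    """Alternating breathing peaks and valleys (times s, values units)."""

    peak_times: np.ndarray
    peak_values: np.ndarray
    valley_times: np.ndarray
    valley_values: np.ndarray

    def __post_init__(self) -> None:
        for name in ("peak_times", "peak_values", "valley_times", "valley_values"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.peak_times.size != self.peak_values.size:
            raise ValueError("peak times/values length mismatch")
        if self.valley_times.size != self.valley_values.size:
            raise ValueError("valley times/values length mismatch")


@dataclass
class IrregularityResult:
    """Respiratory irregularity: mean of peak and valley dispersions.

    ``amplitude_irr`` is in signal units (dispersion of extremum
    heights), ``phase_irr`` in seconds (dispersion of same-type
    extremum-to-extremum periods).
    """

    amplitude_irr: float
    phase_irr: float

    def __post_init__(self) -> None:
        if self.amplitude_irr < 0 or self.phase_irr < 0:
            raise ValueError("irregularity values must be non-negative")


@dataclass
class AssociationResult:
    """Marginal-regression effect of stress on irregularity.

    ``beta`` is the change in irregularity per 10% stress-score
    increment (predictor_kind="score10") or between the stressed and
    non-stressed groups (predictor_kind="binary"), with robust 95%
    confidence bounds from a clustered repeated-measures fit.
    """

    beta: float
    lcl: float
    ucl: float
    p_value: float
    predictor_kind: str
    outcome: str = "phase"
    n_cases: int = 0
    n_patients: int = 0

    def __post_init__(self) -> None:
        if not (self.lcl <= self.beta <= self.ucl):
            raise ValueError("confidence bounds must bracket the estimate")
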
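"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: The eight independent leads of the 12-lead ECG, in storage order.
#: The remaining four limb leads are linear combinations of I and II.
LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Waves of the synthetic beat template, in temporal order.
WAVES: tuple[str, ...] = ("Ppos", "Pneg", "Q", "R", "S", "T")

#: Landmark names carried by :class:`FiducialSet` (per lead).
LANDMARKS: tuple[str, ...] = (
    "p_onset",
    "p_pos_peak",
    "p_pos_end",
    "p_neg_peak",
    "p_offset",
    "qrs_onset",
    "q_peak",
    "q_end",
    "r_peak",
    "s_peak",
    "qrs_offset",
    "t_onset",
    "t_peak",
    "t_end",
)


class QualityError(RuntimeError):
    """A record failed a signal-quality gate (too few beats, pure noise...)."""


class ConfigurationError(ValueError):
    """Invalid generation or processing configuration."""


@dataclass
class EcgRecord:
    """One participant's resting multichannel ECG.

    Parameters
    ----------
    signal : ndarray, shape (n_samples, 8)
        Voltages in mV, one column per lead in :data:`LEADS` order.
    fs : float
        Sampling rate in Hz.
    """

    signal: np.ndarray
    fs: float
    lead_names: tuple[str, ...] = LEADS
    record_id: str = "rec0"
    centre: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[1] != len(self.lead_names):
            raise ConfigurationError(
                f"signal must be (n_samples, {len(self.lead_names)}), "
                f"got {self.signal.shape}"
            )
        if np.isnan(self.signal).any():
            raise ConfigurationError("signal contains NaNs")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        return self.signal[:, self.lead_names.index(name)]


@dataclass
class MedianBeat:
    """Signal-averaged representative beat for one lead.

    ``beat`` spans ``pre_ms`` before to ``post_ms`` after the aligned R peak;
    ``r_index`` is the sample of the alignment point within the beat.
    ``isoelectric_level`` is the PR-segment baseline reference in mV.
    """

    beat: np.ndarray
    fs: float
    r_index: int
    pre_ms: float
    post_ms: float
    n_beats_used: int
    isoelectric_level: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.beat.shape[0]

    def ms_to_samples(self, ms: float) -> int:
        return int(round(ms * self.fs / 1000.0))


@dataclass
class LeadFiducials:
    """Landmark sample indices for one lead's median beat.

    ``None`` marks an explicitly absent landmark (e.g. no Q wave); it is
    never conflated with index 0.
    """

    p_onset: Optional[int] = None
    p_pos_peak: Optional[int] = None
    p_pos_end: Optional[int] = None
    p_neg_peak: Optional[int] = None
    p_offset: Optional[int] = None
    qrs_onset: Optional[int] = None
    q_peak: Optional[int] = None
    q_end: Optional[int] = None
    r_peak: Optional[int] = None
    s_peak: Optional[int] = None
    qrs_offset: Optional[int] = None
    t_onset: Optional[int] = None
    t_peak: Optional[int] = None
    t_end: Optional[int] = None

    def as_dict(self) -> dict[str, Optional[int]]:
        return {k: getattr(self, k) for k in LANDMARKS}


@dataclass
class FiducialSet:
    """Per-lead landmark indices for one record, with sampling metadata."""

    leads: dict[str, LeadFiducials] = field(default_factory=dict)
    fs: float = 500.0

    def samples_to_ms(self, idx: Optional[int]) -> Optional[float]:
        if idx is None:
            return None
        return 1000.0 * idx / self.fs


@dataclass
class FiducialTruth:
    """Analytic ground truth implied by a synthetic beat template.

    ``beat_ms[lead][landmark]`` gives the landmark time in ms from the beat
    origin (``None`` = absent in that lead); ``amplitudes_mv[lead][wave]``
    the per-lead scaled wave amplitudes; ``r_times_s`` the absolute R-peak
    times of every simulated beat.
    """

    beat_ms: dict[str, dict[str, Optional[float]]]
    amplitudes_mv: dict[str, dict[str, float]]
    r_times_s: np.ndarray
    rr_interval_ms: float

    def landmark_ms(self, lead: str, landmark: str) -> Optional[float]:
        return self.beat_ms[lead].get(landmark)
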
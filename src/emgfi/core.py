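"""Domain model for multichannel anorectal surface-EMG recordings.

The probe is an intra-anal cylinder carrying three rings of 16 silver bar
electrodes; each ring sits at a fixed depth along the anal canal (ring 1
closest to the anal verge).  A measurement session records the external anal
sphincter at every ring, in the relaxed (``R``) and maximally contracted
(``C``) state, twice, giving 12 ten-second epochs sampled at 2048 Hz.

Amplitudes are millivolts throughout the package.  The acquisition hardware's
ADC gain is not part of this model; mV is the documented working unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Etiology classes in canonical order.  This order also breaks majority ties
#: in tree leaves and fixes confusion-matrix layout.
CLASSES: tuple[str, ...] = ("control", "neurogenic", "myogenic", "idiopathic")

UNKNOWN_LABEL = "unknown"

RINGS: tuple[int, ...] = (1, 2, 3)
STATES: tuple[str, ...] = ("R", "C")
REPETITIONS: tuple[int, ...] = (1, 2)

SAMPLE_RATE_HZ = 2048
EPOCH_DURATION_S = 10.0
N_ELECTRODES = 16

#: Canonical 12-parameter feature names: per-ring mean RMS (mV) and median
#: frequency (Hz) in each sphincter state, e.g. ``RMS1C`` = ring 1, contracted.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{modality}{ring}{state}"
    for modality in ("RMS", "MF")
    for ring in RINGS
    for state in STATES
)


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class FormatError(ValueError):
    """A file does not follow the documented on-disk layout."""


class SessionRejectedError(RuntimeError):
    """A session failed quality control; carries the per-epoch QC reports."""

    def __init__(self, message: str, reports=None):
        super().__init__(message)
        self.reports = reports or {}


@dataclass(frozen=True)
class ProbeGeometry:
    """Geometry of the 3x16 anorectal probe (dimensions in mm)."""

    n_rings: int = 3
    electrodes_per_ring: int = N_ELECTRODES
    ring_depths_mm: tuple[tuple[float, float], ...] = ((0.0, 9.0), (18.0, 27.0), (35.0, 44.0))
    electrode_size_mm: tuple[float, float] = (1.0, 9.0)
    inter_ring_gap_mm: float = 8.0

    def __post_init__(self):
        if self.n_rings != 3 or self.electrodes_per_ring != 16:
            raise ValidationError("probe geometry is fixed at 3 rings of 16 electrodes")
        depths = self.ring_depths_mm
        if len(depths) != self.n_rings:
            raise ValidationError("one depth interval per ring required")
        for (a, b) in depths:
            if not a < b:
                raise ValidationError(f"degenerate depth interval ({a}, {b})")
        for (_, b), (a2, _) in zip(depths, depths[1:]):
            if not b < a2:
                raise ValidationError("ring depth intervals must be disjoint and increasing")


@dataclass
class Recording:
    """One 10-s multichannel epoch at a given ring depth, state and repetition.

    ``samples`` holds the 16 monopolar electrode traces (rows) in mV.
    """

    subject_id: str
    ring: int
    state: str
    repetition: int
    samples: np.ndarray
    sample_rate_hz: int = SAMPLE_RATE_HZ
    duration_s: float = EPOCH_DURATION_S

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.ring not in RINGS:
            raise ValidationError(f"ring must be one of {RINGS}, got {self.ring!r}")
        if self.state not in STATES:
            raise ValidationError(f"state must be 'R' or 'C', got {self.state!r}")
        if self.repetition not in REPETITIONS:
            raise ValidationError(f"repetition must be 1 or 2, got {self.repetition!r}")
        if self.sample_rate_hz != SAMPLE_RATE_HZ:
            raise ValidationError(
                f"sample rate must be {SAMPLE_RATE_HZ} Hz, got {self.sample_rate_hz}"
            )
        if self.samples.ndim != 2 or self.samples.shape[0] != N_ELECTRODES:
            raise ValidationError(
                f"expected {N_ELECTRODES} channels, got shape {self.samples.shape}"
            )
        n_expected = int(round(self.sample_rate_hz * self.duration_s))
        if self.samples.shape[1] != n_expected:
            raise ValidationError(
                f"expected {n_expected} samples per channel, got {self.samples.shape[1]}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def key(self) -> tuple[int, str, int]:
        return (self.ring, self.state, self.repetition)


@dataclass
class SubjectMeta:
    """Per-subject clinical metadata."""

    subject_id: str
    age: float | None = None
    sex: str | None = None
    fisi_score: int | None = None
    etiology_label: str = UNKNOWN_LABEL

    def __post_init__(self):
        if self.fisi_score is not None and self.fisi_score < 0:
            raise ValidationError("FISI score must be non-negative")
        if self.etiology_label not in CLASSES + (UNKNOWN_LABEL,):
            raise ValidationError(
                f"etiology label {self.etiology_label!r} not in {CLASSES + (UNKNOWN_LABEL,)}"
            )
        if self.sex not in (None, "F", "M"):
            raise ValidationError(f"sex must be 'F' or 'M', got {self.sex!r}")


@dataclass
class FeatureVector:
    """The 12 RMS/MF parameters of one subject, plus label."""

    subject_id: str
    values: Mapping[str, float]
    label: str = UNKNOWN_LABEL

    def __post_init__(self):
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        if missing:
            raise ValidationError(f"missing feature values: {missing}")
        extra = [n for n in self.values if n not in FEATURE_NAMES]
        if extra:
            raise ValidationError(f"unknown feature names: {extra}")
        if self.label not in CLASSES + (UNKNOWN_LABEL,):
            raise ValidationError(f"unknown label {self.label!r}")
        for name in FEATURE_NAMES:
            v = self.values[name]
            if not np.isfinite(v):
                raise ValidationError(f"{name} is non-finite")
            if name.startswith("RMS") and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
            if name.startswith("MF") and not (10.0 <= v <= 500.0):
                raise ValidationError(f"{name} must lie in [10, 500] Hz, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)


def validate_labels(labels: Sequence[str], allow_unknown: bool = False) -> None:
    allowed = set(CLASSES) | ({UNKNOWN_LABEL} if allow_unknown else set())
    bad = sorted(set(labels) - allowed)
    if bad:
        raise ValidationError(f"labels outside the class set: {bad}")
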
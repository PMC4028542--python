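"""From raw epochs to the 12-parameter RMS / median-frequency feature vector.

Pipeline per epoch: derive the 16 circumferential bipolar pairs, band-limit
each pair to 10-500 Hz (zero-phase 4th-order Butterworth), compute the RMS
amplitude and the spectral median frequency per pair, and average across the
16 pairs.  Per (ring, state) slot the two repetitions are then averaged,
yielding RMS1R..RMS3C (mV) and MF1R..MF3C (Hz).

Quality control mirrors the exclusion practice of clinical multichannel sEMG:
epochs with widespread electrode contact loss, mains (50 Hz) interference or
movement bursts are flagged unreliable and the whole session is rejected
rather than repaired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .core import (
    EPOCH_DURATION_S,
    FEATURE_NAMES,
    N_ELECTRODES,
    RINGS,
    SAMPLE_RATE_HZ,
    STATES,
    FeatureVector,
    Recording,
    SessionRejectedError,
    ValidationError,
)

DEFAULT_BAND = (10.0, 500.0)


@dataclass
class BipolarEpoch:
    """16 single-differential traces between circumferentially adjacent electrodes."""

    pairs: np.ndarray  # (16, n_samples)
    ring: int
    state: str
    repetition: int
    sample_rate_hz: int = SAMPLE_RATE_HZ

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=float)
        if self.pairs.ndim != 2 or self.pairs.shape[0] != N_ELECTRODES:
            raise ValidationError(f"expected 16 pair traces, got shape {self.pairs.shape}")


@dataclass
class SpectralEstimate:
    """Welch power spectral density on a regular frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray
    resolution_hz: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValidationError("spectral power must be non-negative")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValidationError("frequency grid must be strictly increasing")


@dataclass
class QCConfig:
    """Thresholds of the artifact detectors (all configurable).

    A channel is flagged for contact loss when its RMS falls below
    ``contact_rms_fraction`` of the epoch's median channel RMS or when more
    than ``clip_fraction`` of its samples sit at the epoch's amplitude
    extreme; for mains interference when the 49-51 Hz band carries more than
    ``mains_power_fraction`` of its band-passed power; for movement bursts
    when any 0.5-s window RMS exceeds ``burst_factor`` times the channel's
    median window RMS.  An epoch is unreliable when more than
    ``max_flagged_channels`` of the 16 channels carry any flag.
    """

    contact_rms_fraction: float = 0.01
    clip_fraction: float = 0.01
    mains_band_hz: tuple[float, float] = (49.0, 51.0)
    mains_power_fraction: float = 0.25
    burst_window_s: float = 0.5
    burst_factor: float = 6.0
    max_flagged_channels: int = 4


@dataclass
class QCReport:
    """Per-channel artifact flags and the epoch-level reliability verdict."""

    ring: int
    state: str
    repetition: int
    contact_loss: list[int]
    mains_interference: list[int]
    movement_burst: list[int]
    channel_rms: list[float]
    mains_fraction: list[float]
    clip_fraction: list[float]
    reliable: bool

    @property
    def flagged_channels(self) -> set[int]:
        return set(self.contact_loss) | set(self.mains_interference) | set(self.movement_burst)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flagged_channels"] = sorted(self.flagged_channels)
        return d


def bandpass(
    trace: np.ndarray,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    sample_rate_hz: int = SAMPLE_RATE_HZ,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward-backward).

    The -3 dB points of the squared (two-pass) response sit at the design
    cutoffs.  Traces shorter than three settling lengths (one settling length
    = one period of the low cutoff) are rejected.
    """
    trace = np.asarray(trace, dtype=float)
    nyq = sample_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValidationError(f"cutoffs must satisfy 0 < {low_hz} < {high_hz} < {nyq}")
    settling = sample_rate_hz / low_hz
    if trace.shape[-1] < 3 * settling:
        raise ValidationError(
            f"trace of {trace.shape[-1]} samples is shorter than 3 settling lengths"
            f" ({3 * settling:.0f} samples at {low_hz} Hz low cutoff)"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=sample_rate_hz, output="sos")
    return sps.sosfiltfilt(sos, trace, axis=-1)


def derive_bipolar(recording: Recording) -> BipolarEpoch:
    """Circumferential single-differential montage with wrap-around.

    Pair ``k`` (1-based) is electrode ``k`` minus electrode ``k mod 16 + 1``;
    pair 16 closes the ring back to electrode 1, so the 16 pair traces sum to
    zero at every sample.
    """
    recording.validate()
    mono = recording.samples
    pairs = mono - np.roll(mono, -1, axis=0)
    return BipolarEpoch(
        pairs=pairs,
        ring=recording.ring,
        state=recording.state,
        repetition=recording.repetition,
        sample_rate_hz=recording.sample_rate_hz,
    )


def compute_rms(trace: np.ndarray) -> float:
    """Root-mean-square amplitude sqrt((a_1^2 + ... + a_n^2) / n)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValidationError("cannot compute RMS of an empty trace")
    if not np.all(np.isfinite(trace)):
        raise ValidationError("trace contains non-finite values")
    return float(np.sqrt(np.mean(np.square(trace))))


def estimate_spectrum(
    trace: np.ndarray,
    sample_rate_hz: int = SAMPLE_RATE_HZ,
    segment_s: float = 1.0,
    overlap: float = 0.5,
) -> SpectralEstimate:
    """Welch PSD: Hann window, 1-s segments, 50 % overlap.

    The density integrates to the trace's mean square power, so downstream
    median-frequency estimates see a consistent normalisation.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.shape[-1] < sample_rate_hz:
        raise ValidationError("spectral estimation requires at least 1 s of signal")
    nperseg = int(segment_s * sample_rate_hz)
    freqs, power = sps.welch(
        trace,
        fs=sample_rate_hz,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="constant",
        scaling="density",
    )
    return SpectralEstimate(frequencies=freqs, power=power, resolution_hz=float(freqs[1] - freqs[0]))


def median_frequency(
    spectrum: SpectralEstimate, band: tuple[float, float] = DEFAULT_BAND
) -> float:
    """Frequency splitting the in-band power into equal halves.

    The cumulative in-band power is interpolated linearly across the crossing
    bin, so a pure tone lands within half a bin of its true frequency.
    """
    f = spectrum.frequencies
    p = spectrum.power
    mask = (f >= band[0]) & (f <= band[1])
    fb = f[mask]
    pb = p[mask]
    if fb.size < 2:
        raise ValidationError("fewer than two spectral bins inside the band")
    total = float(np.sum(pb))
    if total <= 0:
        raise ValidationError("zero in-band power; median frequency undefined")
    cum = np.cumsum(pb)
    half = total / 2.0
    k = int(np.searchsorted(cum, half))
    if k == 0:
        return float(fb[0])
    # linear interpolation between the cumulative values at fb[k-1] and fb[k]
    c0, c1 = cum[k - 1], cum[k]
    if c1 == c0:
        return float(fb[k])
    return float(fb[k - 1] + (half - c0) / (c1 - c0) * (fb[k] - fb[k - 1]))


def _window_rms(trace: np.ndarray, window: int, hop: int) -> np.ndarray:
    n = trace.shape[-1]
    starts = np.arange(0, n - window + 1, hop)
    return np.array([np.sqrt(np.mean(trace[s : s + window] ** 2)) for s in starts])


def qc_assess(recording: Recording, config: QCConfig | None = None) -> QCReport:
    """Flag contact loss, mains interference and movement bursts per channel."""
    config = config or QCConfig()
    recording.validate()
    raw = recording.samples
    fs = recording.sample_rate_hz

    channel_rms = np.sqrt(np.mean(raw**2, axis=1))
    median_rms = float(np.median(channel_rms))
    epoch_peak = float(np.max(np.abs(raw)))

    contact, mains, bursts = [], [], []
    mains_fracs, clip_fracs = [], []

    filtered = bandpass(raw, sample_rate_hz=fs)
    window = int(config.burst_window_s * fs)
    hop = max(1, window // 2)

    for ch in range(raw.shape[0]):
        # contact loss: near-dead channel or railed ADC
        clip_frac = 0.0
        if epoch_peak > 0:
            clip_frac = float(np.mean(np.abs(raw[ch]) >= 0.999 * epoch_peak))
        clip_fracs.append(clip_frac)
        dead = median_rms > 0 and channel_rms[ch] < config.contact_rms_fraction * median_rms
        if dead or clip_frac > config.clip_fraction:
            contact.append(ch)

        # mains interference: share of band-passed power near 50 Hz
        spec = estimate_spectrum(filtered[ch], sample_rate_hz=fs)
        in_mains = (spec.frequencies >= config.mains_band_hz[0]) & (
            spec.frequencies <= config.mains_band_hz[1]
        )
        total = float(np.sum(spec.power))
        frac = float(np.sum(spec.power[in_mains]) / total) if total > 0 else 0.0
        mains_fracs.append(frac)
        if frac > config.mains_power_fraction:
            mains.append(ch)

        # movement bursts: short high-energy transients
        wrms = _window_rms(filtered[ch], window, hop)
        med = float(np.median(wrms))
        if med > 0 and np.max(wrms) > config.burst_factor * med:
            bursts.append(ch)

    flagged = set(contact) | set(mains) | set(bursts)
    n_mains = len(mains)
    reliable = len(flagged) <= config.max_flagged_channels and n_mains <= config.max_flagged_channels
    return QCReport(
        ring=recording.ring,
        state=recording.state,
        repetition=recording.repetition,
        contact_loss=contact,
        mains_interference=mains,
        movement_burst=bursts,
        channel_rms=channel_rms.tolist(),
        mains_fraction=mains_fracs,
        clip_fraction=clip_fracs,
        reliable=reliable,
    )


def extract_features(
    session: Iterable[Recording],
    qc_config: QCConfig | None = QCConfig(),
    band: tuple[float, float] = DEFAULT_BAND,
) -> FeatureVector:
    """Compute the 12-parameter feature vector for one complete session.

    Requires all 12 epochs (3 rings x 2 states x 2 repetitions).  With a QC
    config (the default), every epoch must pass :func:`qc_assess`; otherwise
    the session is rejected with the offending reports attached.  Pass
    ``qc_config=None`` to skip screening.
    """
    session = list(session)
    epochs: dict[tuple[int, str, int], Recording] = {}
    for rec in session:
        rec.validate()
        if rec.key() in epochs:
            raise ValidationError(f"duplicate epoch {rec.key()}")
        epochs[rec.key()] = rec
    expected = {(r, s, rep) for r in RINGS for s in STATES for rep in (1, 2)}
    missing = sorted(expected - set(epochs))
    if missing:
        raise ValidationError(f"incomplete session; missing epochs {missing}")

    if qc_config is not None:
        reports = {key: qc_assess(rec, qc_config) for key, rec in epochs.items()}
        bad = {key: rep for key, rep in reports.items() if not rep.reliable}
        if bad:
            raise SessionRejectedError(
                f"session unreliable: {len(bad)} of 12 epochs failed QC "
                f"({sorted(bad)})",
                reports=reports,
            )

    subject_id = session[0].subject_id
    per_epoch: dict[tuple[int, str, int], tuple[float, float]] = {}
    for key, rec in epochs.items():
        bip = derive_bipolar(rec)
        filtered = bandpass(bip.pairs, low_hz=band[0], high_hz=band[1], sample_rate_hz=rec.sample_rate_hz)
        rms_pairs = [compute_rms(tr) for tr in filtered]
        mf_pairs = [
            median_frequency(estimate_spectrum(tr, sample_rate_hz=rec.sample_rate_hz), band)
            for tr in filtered
        ]
        per_epoch[key] = (float(np.mean(rms_pairs)), float(np.mean(mf_pairs)))

    values: dict[str, float] = {}
    for ring in RINGS:
        for state in STATES:
            reps = [per_epoch[(ring, state, rep)] for rep in (1, 2)]
            values[f"RMS{ring}{state}"] = float(np.mean([r for r, _ in reps]))
            values[f"MF{ring}{state}"] = float(np.mean([m for _, m in reps]))
    return FeatureVector(subject_id=subject_id, values=values)
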
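import numpy as np
import pytest

from emgfi.core import Recording
from emgfi.simulate import SignalTarget, simulate_session


def make_recording(
    samples, ring=1, state="R", repetition=1, subject_id="S001"
) -> Recording:
    return Recording(
        subject_id=subject_id,
        ring=ring,
        state=state,
        repetition=repetition,
        samples=np.asarray(samples, dtype=float),
        duration_s=np.asarray(samples).shape[1] / 2048,
    )


def noise_recording(rng, rms=0.01, n=20480, **kw) -> Recording:
    return make_recording(rng.normal(0.0, rms, (16, n)), **kw)


@pytest.fixture(scope="session")
def clean_session():
    """One simulated 12-epoch session with distinct per-slot RMS/MF targets."""
    profile = {
        (ring, state): SignalTarget(
            rms_mv=0.005 + 0.004 * ring + (0.008 if state == "C" else 0.0),
            mf_hz=70.0 + 15.0 * ring + (10.0 if state == "C" else 0.0),
        )
        for ring in (1, 2, 3)
        for state in ("R", "C")
    }
    return profile, simulate_session(profile, subject_id="S001", seed=20260920)


@pytest.fixture(scope="session")
def small_labeled_cohort():
    """A tiny, cleanly separable 2-feature-driven cohort for tree tests."""
    rng = np.random.default_rng(42)
    from emgfi.simulate import separable_design, simulate_cohort

    return simulate_cohort(separable_design(n_per_group=50), seed=7)
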
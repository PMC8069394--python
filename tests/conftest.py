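import numpy as np
import pytest

from stskit import Session, SkeletonFrame, SyntheticConfig, generate_sts_session
from stskit.joints import N_JOINTS


def make_frame(t_ms=0, score=0.0, base=None, untracked=()):
    """A valid 25-joint frame; optionally mark some joints untracked."""
    rng = np.random.default_rng(t_ms)
    pos = rng.normal(0.0, 0.5, (N_JOINTS, 3)) if base is None else np.array(base, float)
    for j in untracked:
        pos[j] = np.nan
    return SkeletonFrame(t_ms=t_ms, score=score, positions=pos)


def make_session(n=30, dt_ms=100, **meta):
    frames = [make_frame(t_ms=i * dt_ms, score=float(i)) for i in range(n)]
    meta.setdefault("nominal_duration_s", (n - 1) * dt_ms / 1000.0)
    return Session(frames=frames, **meta)


@pytest.fixture
def clean_session():
    """Noise-free deterministic 5-cycle sit-to-stand session + ground truth."""
    cfg = SyntheticConfig(
        n_cycles=5,
        noise_sd_m=0.0,
        shoulder_twist_sd_deg=0.0,
        com_sway_sd_ap_m=0.0,
        com_sway_sd_ml_m=0.0,
        seed=7,
    )
    return generate_sts_session(cfg)


@pytest.fixture
def noisy_session():
    """Default-noise 5-cycle session + ground truth."""
    return generate_sts_session(SyntheticConfig(seed=11))
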
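"""Seeded synthetic sit-to-stand sessions with known ground truth.

The generator emits full 25-joint skeleton sessions emulating the 30 s
sit-to-stand protocol: the subject rises from seat height to stand height and
sits back down ``n_cycles`` times, sampled at 10 Hz. The spine-middle height
follows a raised-cosine profile per cycle (continuous velocity, so peak
detection is exercised realistically); the trunk extends through a
configurable flexion range and the knees sweep from the seated to the
standing angle in phase with the rise. Shoulder twist and whole-body AP/ML
sway are Gaussian per frame, and i.i.d. Gaussian position noise is added per
joint to mimic depth-camera jitter (centimeter order by default).

Joints that no indicator equation touches (head, arms, feet...) are placed by
a fixed template rigidly attached to the trunk; they exist to satisfy the
25-joint schema.

Every session is reproducible: one master seed, with per-session streams
derived by seed-sequence spawning so cohort generation is order-independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError
from . import joints as J
from .session_io import Session, SkeletonFrame, write_session

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate_sts_session",
    "generate_cohort",
    "write_ground_truth",
]

# Body geometry (meters): segment lengths of the rigid template.
_TRUNK_LEN = 0.35          # spine-middle → upper-trunk joint
_SHOULDER_HALF_W = 0.20
_HIP_HALF_W = 0.10
_HIP_DROP = 0.20           # spine-middle → hip line
_FEMUR_LEN = 0.40
_TIBIA_LEN = 0.40


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults describe a frail-elderly 30 s session.

    Heights are spine-middle levels; the 0.30 m seat-to-stand excursion,
    ~80° trunk-flexion range and 90°→180° knee sweep sit in the ranges the
    protocol produces for this population, and 0.01 m joint noise matches
    centimeter-order depth-camera accuracy.
    """

    n_cycles: int = 5
    cycle_period_s: float = 6.0
    seat_height_m: float = 0.85
    stand_height_m: float = 1.15
    trunk_flexion_range_deg: float = 80.0
    knee_sit_deg: float = 90.0
    knee_stand_deg: float = 180.0
    shoulder_twist_sd_deg: float = 2.0
    com_sway_sd_ap_m: float = 0.004
    com_sway_sd_ml_m: float = 0.001
    noise_sd_m: float = 0.01
    sampling_hz: float = 10.0
    duration_s: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_cycles < 0:
            problems.append("n_cycles must be >= 0")
        if self.cycle_period_s <= 0:
            problems.append("cycle_period_s must be > 0")
        if not self.stand_height_m > self.seat_height_m:
            problems.append("stand_height_m must exceed seat_height_m")
        if self.n_cycles * self.cycle_period_s > self.duration_s + 1e-9:
            problems.append("n_cycles * cycle_period_s must fit within duration_s")
        if not 0.0 < self.trunk_flexion_range_deg <= 90.0:
            problems.append("trunk_flexion_range_deg must be in (0, 90]")
        if not 90.0 <= self.knee_sit_deg <= self.knee_stand_deg <= 180.0:
            problems.append("knee angles must satisfy 90 <= sit <= stand <= 180")
        for name in ("shoulder_twist_sd_deg", "com_sway_sd_ap_m",
                     "com_sway_sd_ml_m", "noise_sd_m"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.sampling_hz <= 0 or self.duration_s <= 0:
            problems.append("sampling_hz and duration_s must be > 0")
        if problems:
            raise ConfigError("invalid synthetic config: " + "; ".join(problems))


@dataclass
class SyntheticGroundTruth:
    """What the generator actually injected, for recovery tests."""

    nsu: int
    peak_times_s: list[float]
    valley_times_s: list[float]
    ubfa_range_deg: float
    llfa_sit_deg: float
    llfa_stand_deg: float
    ufv_up_m_s: float
    ufv_down_m_s: float
    com_sway_sd_ap_cm: float
    com_sway_sd_ml_cm: float
    config: SyntheticConfig

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _cycle_fraction(t: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """Raised-cosine stand fraction s(t) in [0, 1]; 0 seated, 1 standing."""
    s = np.zeros_like(t)
    T = cfg.cycle_period_s
    active = t < cfg.n_cycles * T
    s[active] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[active] % T) / T))
    # guard against t exactly at a cycle boundary mapping to ~0 by fp error
    return np.clip(s, 0.0, 1.0)


def generate_sts_session(
    config: SyntheticConfig | None = None,
) -> tuple[Session, SyntheticGroundTruth]:
    """Generate one synthetic sit-to-stand session plus its ground truth.

    The same config (including its seed) yields bit-identical output.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    n_frames = int(round(cfg.duration_s * cfg.sampling_hz))
    t = np.arange(n_frames) / cfg.sampling_hz
    s = _cycle_fraction(t, cfg)

    z7 = cfg.seat_height_m + (cfg.stand_height_m - cfg.seat_height_m) * s

    # Trunk: flexion angle sweeps 90° (seated, vertical) up by the range.
    ubfa_deg = 90.0 + cfg.trunk_flexion_range_deg * s
    ubfa_rad = np.radians(ubfa_deg)

    # Knees: folded knee angle sweeps sit → stand; tibia stays vertical, so
    # the femur inclination is 90° − folded angle (degrees, sagittal plane).
    knee_deg = cfg.knee_sit_deg + (cfg.knee_stand_deg - cfg.knee_sit_deg) * s
    theta_femur = np.radians(90.0 - knee_deg)

    twist = np.radians(rng.normal(0.0, cfg.shoulder_twist_sd_deg, n_frames))
    sway_ap = rng.normal(0.0, cfg.com_sway_sd_ap_m, n_frames)
    sway_ml = rng.normal(0.0, cfg.com_sway_sd_ml_m, n_frames)

    pos = np.zeros((n_frames, J.N_JOINTS, 3))

    def place(idx: int, x, y, z) -> None:
        pos[:, idx, 0] = x
        pos[:, idx, 1] = y
        pos[:, idx, 2] = z

    zeros = np.zeros(n_frames)
    place(J.SPINE_MID, zeros, zeros, z7)
    # upper trunk
    y2 = _TRUNK_LEN * np.cos(ubfa_rad)
    z2 = z7 + _TRUNK_LEN * np.sin(ubfa_rad)
    place(J.UPPER_TRUNK, zeros, y2, z2)
    # shoulders, twisted about the vertical through the upper trunk
    dy_sh = _SHOULDER_HALF_W * np.tan(twist)
    place(J.SHOULDER_LEFT, -_SHOULDER_HALF_W + zeros, y2 - dy_sh, z2 + 0.05)
    place(J.SHOULDER_RIGHT, _SHOULDER_HALF_W + zeros, y2 + dy_sh, z2 + 0.05)
    # hips
    z_hip = z7 - _HIP_DROP
    place(J.HIP_LEFT, -_HIP_HALF_W + zeros, zeros, z_hip)
    place(J.HIP_RIGHT, _HIP_HALF_W + zeros, zeros, z_hip)
    # legs: knee from the femur inclination, ankle straight below the knee
    y_knee = _FEMUR_LEN * np.cos(theta_femur)
    z_knee = z_hip + _FEMUR_LEN * np.sin(theta_femur)
    z_ankle = z_knee - _TIBIA_LEN
    for hip_x, knee_j, ankle_j, foot_j in (
        (-_HIP_HALF_W, J.KNEE_LEFT, J.ANKLE_LEFT, 23),
        (_HIP_HALF_W, J.KNEE_RIGHT, J.ANKLE_RIGHT, 18),
    ):
        place(knee_j, hip_x + zeros, y_knee, z_knee)
        place(ankle_j, hip_x + zeros, y_knee, z_ankle)
        place(foot_j, hip_x + zeros, y_knee + 0.15, z_ankle - 0.05)
    # template joints rigidly attached to the trunk / shoulders
    place(0, zeros, y2, z2 + 0.25)                     # head
    place(1, zeros, y2, z2 + 0.10)                     # neck
    place(16, zeros, zeros, z7 - 0.10)                 # spine base
    for sh, chain in ((J.SHOULDER_LEFT, (4, 8, 9, 12, 13)),
                      (J.SHOULDER_RIGHT, (6, 10, 11, 14, 15))):
        drop = {4: 0.25, 8: 0.50, 9: 0.55, 12: 0.62, 13: 0.58,
                6: 0.25, 10: 0.50, 11: 0.55, 14: 0.62, 15: 0.58}
        for jj in chain:
            place(jj, pos[:, sh, 0], pos[:, sh, 1], pos[:, sh, 2] - drop[jj])

    # whole-body sway, then per-joint sensor noise
    pos[:, :, 0] += sway_ml[:, None]
    pos[:, :, 1] += sway_ap[:, None]
    if cfg.noise_sd_m > 0:
        pos += rng.normal(0.0, cfg.noise_sd_m, pos.shape)

    t_ms = np.round(t * 1000.0).astype(int)
    score = np.floor(t / cfg.cycle_period_s)  # one point per completed cycle
    frames = [
        SkeletonFrame(t_ms=int(t_ms[i]), score=float(score[i]), positions=pos[i])
        for i in range(n_frames)
    ]
    session = Session(
        frames=frames,
        session_id=f"synthetic-{cfg.seed}",
        game_id="equilibrium_paint",
        nominal_duration_s=cfg.duration_s,
        sampling_hz=cfg.sampling_hz,
    )

    T = cfg.cycle_period_s
    half = T / 2.0
    excursion = cfg.stand_height_m - cfg.seat_height_m
    truth = SyntheticGroundTruth(
        nsu=cfg.n_cycles,
        peak_times_s=[(k + 0.5) * T for k in range(cfg.n_cycles)],
        valley_times_s=[k * T for k in range(cfg.n_cycles + 1)],
        ubfa_range_deg=cfg.trunk_flexion_range_deg,
        llfa_sit_deg=cfg.knee_sit_deg,
        llfa_stand_deg=cfg.knee_stand_deg,
        ufv_up_m_s=excursion / half,
        ufv_down_m_s=excursion / half,
        com_sway_sd_ap_cm=cfg.com_sway_sd_ap_m * 100.0,
        com_sway_sd_ml_cm=cfg.com_sway_sd_ml_m * 100.0,
        config=cfg,
    )
    return session, truth


def generate_cohort(
    configs: list[SyntheticConfig] | None = None,
    n_sessions: int = 13,
    base_config: SyntheticConfig | None = None,
    master_seed: int = 0,
) -> list[tuple[Session, SyntheticGroundTruth]]:
    """Generate an independent cohort of synthetic sessions.

    Either pass explicit ``configs`` (used as-is), or a ``base_config`` whose
    per-session seeds are derived from ``master_seed`` by seed-sequence
    spawning (order-independent, no seed collisions).
    """
    if configs is None:
        base = base_config or SyntheticConfig()
        children = np.random.SeedSequence(master_seed).spawn(n_sessions)
        configs = [
            dataclasses.replace(base, seed=int(c.generate_state(1)[0] % (2**31)))
            for c in children
        ]
    return [generate_sts_session(c) for c in configs]


def write_ground_truth(truth: SyntheticGroundTruth, path: str | Path) -> None:
    """Write the ground-truth sidecar JSON next to a generated session."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
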
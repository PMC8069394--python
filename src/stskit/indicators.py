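"""Kinematic indicators for the sit-to-stand exergame.

Six indicator families are computed from the 25-joint skeleton stream, all in
the ML (x) / AP (y) / vertical (z) convention:

* **NSU** — number of sit-up occurrences: stand-up peaks of the spine-middle
  vertical trajectory (see :mod:`stskit.segmentation`).
* **UBFA** — upper-body flexion angle: inclination of the trunk segment from
  the spine-middle joint to the upper-trunk joint in the sagittal plane,
  ``atan2(z2 - z7, y2 - y7)``, folded into [0°, 180°]. A vertical trunk reads
  exactly 90°; leaning forward lowers it.
* **LLFA** — lower-limb flexion angle (knee angle), per side:
  ``180° + θ_femur - θ_tibia`` where the femur and tibia inclinations are
  sagittal-plane ``atan2(Δz, Δy)`` of hip→knee and knee→ankle. After folding
  into [0°, 180°] it equals the interior knee angle: 180° at full extension,
  ≈90° when seated.
* **UBTA** — upper-body twist angle: axial-plane angle of the shoulder line,
  ``arctan((y_right - y_left) / (x_right - x_left))`` in (−90°, 90°). With ML
  positive toward the subject's right, a forward *left* shoulder gives a
  negative value.
* **COM** — center-of-mass proxy: coordinate-wise mean of the two hips and
  the spine-middle joint; its within-phase AP/ML dispersion (sample standard
  deviation, reported in cm) summarizes sway.
* **UfV** — upper-frame velocity: vertical speed of the spine-middle joint
  across one phase, ``(z_peak - z_valley) / (t_peak - t_valley)``; the
  descending value carries a sign flip so both phases report positive speeds.

All angle indicators use two-argument ``atan2`` with explicit folding, which
is invariant under translation and uniform scaling of the skeleton.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, UndefinedAngleError
from . import joints as J
from .segmentation import PhaseSegment, SegmentationParams, segment_session
from .session_io import Session

__all__ = [
    "IndicatorParams",
    "PhaseFeatures",
    "SessionIndicators",
    "CohortSummary",
    "ReferenceValue",
    "ubfa",
    "llfa",
    "ubta",
    "com",
    "com_dispersion",
    "ufv",
    "ubfa_series",
    "llfa_series",
    "ubta_series",
    "com_series",
    "phase_features",
    "compute_session_indicators",
    "cohort_summary",
    "compare_to_reference",
    "load_reference_values",
    "TABLE_ROWS",
]

Side = Literal["left", "right"]
_LEGS = {"left": J.LEG_LEFT, "right": J.LEG_RIGHT}

#: Cohort-report row labels, in presentation order. "Stand" rows aggregate
#: ascending phases, "Sit" rows descending phases.
TABLE_ROWS = (
    "NSU",
    "Stand UBFA range (deg)",
    "Sit UBFA range (deg)",
    "Stand LLFA (deg)",
    "Sit LLFA (deg)",
    "Stand UBTA (deg)",
    "Sit UBTA (deg)",
    "COM stand AP (cm)",
    "COM sit AP (cm)",
    "COM stand ML (cm)",
    "COM sit ML (cm)",
    "UfVup (m/s)",
    "UfVdown (m/s)",
)


@dataclass(frozen=True)
class IndicatorParams:
    """Options for indicator computation.

    ``com_statistic`` selects the within-phase COM dispersion reducer:
    sample standard deviation (default), peak-to-peak range, or mean absolute
    deviation. ``ubfa_offset_deg`` adds a constant to UBFA before folding
    (off by default; see the methods note on the standing-angle convention).
    """

    com_statistic: Literal["sd", "range", "mad"] = "sd"
    ubfa_offset_deg: float = 0.0


# ---------------------------------------------------------------------------
# Frame-level primitives


def _fold_180(angle_deg: float | np.ndarray):
    """Fold an angle in degrees into [0°, 180°]."""
    a = np.mod(angle_deg, 360.0)
    return np.where(a > 180.0, 360.0 - a, a)


def ubfa(positions: np.ndarray, offset_deg: float = 0.0) -> float:
    """Upper-body flexion angle (degrees, folded into [0°, 180°])."""
    p = np.asarray(positions, dtype=float)
    dy = p[J.UPPER_TRUNK, 1] - p[J.SPINE_MID, 1]
    dz = p[J.UPPER_TRUNK, 2] - p[J.SPINE_MID, 2]
    if dy == 0.0 and dz == 0.0:
        raise UndefinedAngleError("trunk joints coincide in the sagittal plane")
    # trunk-line orientation: negative angles fold by +180°
    a = (math.degrees(math.atan2(dz, dy)) + offset_deg) % 180.0
    return float(a)


def llfa(positions: np.ndarray, side: Side) -> float:
    """Lower-limb flexion angle for one side (degrees, folded into [0°, 180°])."""
    hip, knee, ankle = _LEGS[side]
    p = np.asarray(positions, dtype=float)
    femur = p[knee, 1:] - p[hip, 1:]    # (Δy, Δz) hip → knee
    tibia = p[ankle, 1:] - p[knee, 1:]  # (Δy, Δz) knee → ankle
    if not femur.any():
        raise UndefinedAngleError(f"{side} femur has zero sagittal projection")
    if not tibia.any():
        raise UndefinedAngleError(f"{side} tibia has zero sagittal projection")
    theta_femur = math.degrees(math.atan2(femur[1], femur[0]))
    theta_tibia = math.degrees(math.atan2(tibia[1], tibia[0]))
    return float(_fold_180(180.0 + theta_femur - theta_tibia))


def ubta(positions: np.ndarray) -> float:
    """Upper-body twist angle of the shoulder line (degrees, (−90°, 90°))."""
    p = np.asarray(positions, dtype=float)
    dx = p[J.SHOULDER_RIGHT, 0] - p[J.SHOULDER_LEFT, 0]
    dy = p[J.SHOULDER_RIGHT, 1] - p[J.SHOULDER_LEFT, 1]
    if dx == 0.0:
        raise UndefinedAngleError("shoulders have identical mediolateral position")
    return math.degrees(math.atan(dy / dx))


def com(positions: np.ndarray) -> np.ndarray:
    """Center-of-mass proxy: mean of the hips and the spine-middle joint.

    Returns a (3,) array (ML, AP, vertical); NaN if any of the three joints
    is untracked.
    """
    p = np.asarray(positions, dtype=float)
    pts = p[list(J.COM_JOINTS)]
    if not np.isfinite(pts).all():
        return np.full(3, np.nan)
    return pts.mean(axis=0)


def com_dispersion(
    values_m: Sequence[float] | np.ndarray,
    statistic: str = "sd",
) -> float:
    """Within-phase dispersion of one COM coordinate, in centimeters.

    ``values_m`` are COM positions (meters) along one axis within one phase;
    at least two finite samples are required (NaN otherwise).
    """
    v = np.asarray(values_m, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        return float("nan")
    if statistic == "sd":
        disp = v.std(ddof=1)
    elif statistic == "range":
        disp = v.max() - v.min()
    elif statistic == "mad":
        disp = np.abs(v - v.mean()).mean()
    else:
        raise ContractError(f"unknown COM statistic {statistic!r}")
    return float(disp * 100.0)


def ufv(segment: PhaseSegment) -> float:
    """Upper-frame velocity over one phase (m/s, positive for both kinds)."""
    dt = segment.end.t_s - segment.start.t_s
    if dt <= 0:
        raise ContractError("phase segment has non-positive duration")
    v = (segment.end.z_m - segment.start.z_m) / dt
    return v if segment.kind == "ascending" else -v


# ---------------------------------------------------------------------------
# Session-level series (NaN where the required joints are untracked)


def _series(session: Session, fn, *args, **kwargs) -> np.ndarray:
    out = np.empty(len(session))
    for i, frame in enumerate(session.frames):
        try:
            out[i] = fn(frame.positions, *args, **kwargs)
        except UndefinedAngleError:
            out[i] = np.nan
    return out


def ubfa_series(session: Session, offset_deg: float = 0.0) -> np.ndarray:
    pos = session.positions()
    ok = np.isfinite(pos[:, list(J.TRUNK_JOINTS)]).all(axis=(1, 2))
    out = _series(session, ubfa, offset_deg)
    out[~ok] = np.nan
    return out


def llfa_series(session: Session, side: Side) -> np.ndarray:
    pos = session.positions()
    ok = np.isfinite(pos[:, list(_LEGS[side])]).all(axis=(1, 2))
    out = _series(session, llfa, side)
    out[~ok] = np.nan
    return out


def ubta_series(session: Session) -> np.ndarray:
    pos = session.positions()
    ok = np.isfinite(pos[:, list(J.SHOULDER_JOINTS)]).all(axis=(1, 2))
    out = _series(session, ubta)
    out[~ok] = np.nan
    return out


def com_series(session: Session) -> np.ndarray:
    """COM per frame, shape (n_frames, 3); NaN rows where untracked."""
    return np.stack([com(f.positions) for f in session.frames])


# ---------------------------------------------------------------------------
# Phase aggregation


@dataclass
class PhaseFeatures:
    """Indicator values for one ascending or descending phase."""

    kind: Literal["ascending", "descending"]
    ubfa_range_deg: float
    llfa_left_deg: float
    llfa_right_deg: float
    ubta_deg: float
    com_ap_cm: float
    com_ml_cm: float
    ufv_m_s: float

    @property
    def llfa_deg(self) -> float:
        """Mean of the two sides (NaN-aware)."""
        vals = [v for v in (self.llfa_left_deg, self.llfa_right_deg) if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass
class SessionIndicators:
    """Per-phase features plus the session-level summary row."""

    session_id: str
    nsu: int
    phases: list[PhaseFeatures]
    params: IndicatorParams = field(default_factory=IndicatorParams)

    def _phase_mean(self, kind: str, attr: str) -> float:
        vals = [getattr(p, attr) for p in self.phases if p.kind == kind]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def summary_row(self) -> dict[str, float]:
        """Session values keyed by the cohort-report row labels."""
        return {
            "NSU": float(self.nsu),
            "Stand UBFA range (deg)": self._phase_mean("ascending", "ubfa_range_deg"),
            "Sit UBFA range (deg)": self._phase_mean("descending", "ubfa_range_deg"),
            "Stand LLFA (deg)": self._phase_mean("ascending", "llfa_deg"),
            "Sit LLFA (deg)": self._phase_mean("descending", "llfa_deg"),
            "Stand UBTA (deg)": self._phase_mean("ascending", "ubta_deg"),
            "Sit UBTA (deg)": self._phase_mean("descending", "ubta_deg"),
            "COM stand AP (cm)": self._phase_mean("ascending", "com_ap_cm"),
            "COM sit AP (cm)": self._phase_mean("descending", "com_ap_cm"),
            "COM stand ML (cm)": self._phase_mean("ascending", "com_ml_cm"),
            "COM sit ML (cm)": self._phase_mean("descending", "com_ml_cm"),
            "UfVup (m/s)": self._phase_mean("ascending", "ufv_m_s"),
            "UfVdown (m/s)": self._phase_mean("descending", "ufv_m_s"),
        }

    def to_frame(self) -> pd.DataFrame:
        """Per-phase features as a DataFrame (one row per phase)."""
        return pd.DataFrame([vars(p) for p in self.phases])


def phase_features(
    session: Session,
    segments: list[PhaseSegment],
    nsu: int | None = None,
    params: IndicatorParams | None = None,
) -> SessionIndicators:
    """Compute per-phase indicator features and the session summary.

    Each segment's features are computed over its samples including both
    boundary extrema: UBFA range (max − min), phase means of LLFA per side
    and of UBTA, COM AP/ML dispersion, and the phase UfV. Missing joints
    yield NaN for the affected feature only.
    """
    params = params or IndicatorParams()
    u = ubfa_series(session, params.ubfa_offset_deg)
    ll = llfa_series(session, "left")
    lr = llfa_series(session, "right")
    tw = ubta_series(session)
    c = com_series(session)

    phases: list[PhaseFeatures] = []
    for seg in segments:
        lo, hi = seg.frame_span[0], seg.frame_span[1] + 1  # include boundary
        useg = u[lo:hi]
        useg = useg[np.isfinite(useg)]
        ubfa_range = float(useg.max() - useg.min()) if useg.size else float("nan")
        phases.append(
            PhaseFeatures(
                kind=seg.kind,
                ubfa_range_deg=ubfa_range,
                llfa_left_deg=float(np.nanmean(ll[lo:hi])) if np.isfinite(ll[lo:hi]).any() else float("nan"),
                llfa_right_deg=float(np.nanmean(lr[lo:hi])) if np.isfinite(lr[lo:hi]).any() else float("nan"),
                ubta_deg=float(np.nanmean(tw[lo:hi])) if np.isfinite(tw[lo:hi]).any() else float("nan"),
                com_ap_cm=com_dispersion(c[lo:hi, 1], params.com_statistic),
                com_ml_cm=com_dispersion(c[lo:hi, 0], params.com_statistic),
                ufv_m_s=ufv(seg),
            )
        )
    n_peaks = sum(1 for s in segments if s.kind == "ascending") if nsu is None else nsu
    return SessionIndicators(
        session_id=session.session_id, nsu=n_peaks, phases=phases, params=params
    )


def compute_session_indicators(
    session: Session,
    seg_params: SegmentationParams | None = None,
    params: IndicatorParams | None = None,
) -> SessionIndicators:
    """Full per-session pipeline: segment, then aggregate phase features."""
    from .segmentation import count_sit_ups

    _, extrema, segments = segment_session(session, seg_params)
    return phase_features(session, segments, nsu=count_sit_ups(extrema), params=params)


# ---------------------------------------------------------------------------
# Cohort aggregation and literature comparison


@dataclass
class CohortSummary:
    """Mean ± sd (and n) per indicator row over a cohort of sessions."""

    table: pd.DataFrame  # index: TABLE_ROWS; columns: mean, sd, n

    def to_csv(self, path) -> None:
        out = self.table.reset_index().rename(columns={"index": "indicator"})
        out.to_csv(path, index=False)

    def __getitem__(self, row: str) -> pd.Series:
        return self.table.loc[row]


def cohort_summary(indicator_sets: Sequence[SessionIndicators]) -> CohortSummary:
    """Aggregate per-session summary rows into a cohort mean ± sd table.

    A session contributes to a row only when the feature was computable
    there; missing values reduce that row's n.
    """
    if not indicator_sets:
        raise ContractError("cohort_summary needs at least one session")
    rows = pd.DataFrame([s.summary_row() for s in indicator_sets])
    table = pd.DataFrame(
        {
            "mean": rows.mean(),
            "sd": rows.std(ddof=1).fillna(0.0),
            "n": rows.notna().sum().astype(int),
        }
    ).reindex(list(TABLE_ROWS))
    return CohortSummary(table=table)


@dataclass(frozen=True)
class ReferenceValue:
    """A literature mean for one indicator row, with test metadata.

    ``direction`` is the one-tailed alternative for the cohort relative to
    the reference ("greater" means the studied cohort is expected to exceed
    the literature value).
    """

    indicator: str
    mean: float
    units: str = ""
    tails: Literal["one", "two"] = "two"
    direction: Literal["greater", "less"] | None = None
    source: str = ""


def compare_to_reference(
    samples: Sequence[float] | np.ndarray,
    ref: ReferenceValue | float,
    tails: Literal["one", "two"] | None = None,
    direction: Literal["greater", "less"] | None = None,
) -> tuple[float, float]:
    """One-sample t-test of per-session indicator values against a literature mean.

    Returns ``(t, p)``. One-tailed tests use ``direction`` (the alternative
    hypothesis for the sample mean relative to the reference). With zero
    sample variance the test is degenerate and ``(nan, nan)`` is returned.
    """
    if isinstance(ref, ReferenceValue):
        tails = tails or ref.tails
        direction = direction or ref.direction
        ref_mean = ref.mean
    else:
        ref_mean = float(ref)
        tails = tails or "two"
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ContractError("t-test needs at least two finite samples")
    if x.std(ddof=1) == 0.0:
        # Degenerate: no sampling variability. A sample sitting exactly on
        # the reference is maximally consistent with it; otherwise the test
        # statistic is undefined.
        if x.mean() == ref_mean:
            return 0.0, 1.0
        return float("nan"), float("nan")
    if tails == "one":
        if direction not in ("greater", "less"):
            raise ContractError("one-tailed test requires a direction")
        alternative = direction
    else:
        alternative = "two-sided"
    res = stats.ttest_1samp(x, popmean=ref_mean, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def load_reference_values(path=None) -> dict[str, ReferenceValue]:
    """Load reference values (packaged healthy-elderly means by default)."""
    import yaml

    if path is None:
        from importlib import resources

        text = resources.files("stskit.data").joinpath("reference_values.yaml").read_text()
        cfg = yaml.safe_load(text)
    else:
        with open(path, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    refs = {}
    for entry in cfg["references"]:
        rv = ReferenceValue(**entry)
        refs[rv.indicator] = rv
    return refs
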
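"""Reading, validating and writing skeleton session logs.

A session log is a JSON array of timestamped events; each event carries the
recording time in milliseconds, the in-game score and the 3D positions of 25
skeleton joints. Internally all positions live in the mediolateral (x) /
anteroposterior (y) / vertical (z) convention, in meters; device-native axes
are remapped on read via an :class:`AxisMapping`.

Canonical event schema (shipped as ``data/session.schema.json``)::

    [{"t_ms": 0, "score": 0.0, "joints": [[x, y, z], ... 25 entries]}, ...]

An untracked joint is encoded as ``null`` in JSON and as a NaN triple in
memory — distinct from a joint genuinely at the origin.

Logs from other deployments use different field names and device-native axes;
a *dialect* bundles the key names, time unit and axis mapping needed to
translate them into the canonical convention.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import ConfigError, SchemaError
from .joints import N_JOINTS

__all__ = [
    "AxisMapping",
    "SkeletonFrame",
    "Session",
    "Dialect",
    "read_session",
    "write_session",
    "apply_axis_mapping",
    "register_dialect",
    "get_dialect",
    "load_dialect_config",
    "session_json_schema",
]

_AXES = ("x", "y", "z")
_TARGETS = ("ml", "ap", "vertical")


@dataclass(frozen=True)
class AxisMapping:
    """Permutation + sign flips taking device-native axes to ML/AP/vertical.

    ``source`` names, per target axis, which native component (``"x"``,
    ``"y"``, ``"z"``) supplies it; ``sign`` flips it. The identity mapping
    reads native x as ML, y as AP, z as vertical.
    """

    source: tuple[str, str, str] = ("x", "y", "z")  # for (ml, ap, vertical)
    sign: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if sorted(self.source) != list(_AXES):
            raise ConfigError(f"axis permutation must be a bijection on {_AXES}")
        if any(s not in (-1, 1) for s in self.sign):
            raise ConfigError("axis signs must be -1 or +1")

    @property
    def _perm(self) -> list[int]:
        return [_AXES.index(a) for a in self.source]

    def apply(self, positions: np.ndarray) -> np.ndarray:
        """Remap an array whose last axis is (x, y, z) device-native."""
        out = positions[..., self._perm] * np.asarray(self.sign, dtype=float)
        return out

    def inverse(self) -> "AxisMapping":
        src = [""] * 3
        sgn = [0] * 3
        for tgt_i, (axis, s) in enumerate(zip(self.source, self.sign)):
            nat_i = _AXES.index(axis)
            src[nat_i] = _AXES[tgt_i]
            sgn[nat_i] = s
        return AxisMapping(tuple(src), tuple(sgn))  # type: ignore[arg-type]

    @classmethod
    def identity(cls) -> "AxisMapping":
        return cls()


def apply_axis_mapping(positions: np.ndarray, mapping: AxisMapping) -> np.ndarray:
    """Apply ``mapping`` to raw joint positions (last axis = native x,y,z)."""
    return mapping.apply(np.asarray(positions, dtype=float))


@dataclass
class SkeletonFrame:
    """One timestamped 25-joint sample.

    ``positions`` is a (25, 3) float array in ML/AP/vertical order, meters;
    an untracked joint is a row of NaN.
    """

    t_ms: int
    score: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (N_JOINTS, 3):
            raise SchemaError(
                f"frame at t_ms={self.t_ms} has position shape {pos.shape}, "
                f"expected ({N_JOINTS}, 3)"
            )
        # NaN marks "untracked"; anything else must be finite.
        bad = np.isinf(pos) | (np.isnan(pos) & ~np.all(np.isnan(pos), axis=1, keepdims=True))
        if bad.any():
            raise SchemaError(
                f"frame at t_ms={self.t_ms} has non-finite coordinates outside "
                "whole-joint untracked markers"
            )
        self.positions = pos

    def tracked(self, joints: Iterable[int]) -> bool:
        """True if every listed joint has finite coordinates."""
        idx = list(joints)
        return bool(np.isfinite(self.positions[idx]).all())

    def __eq__(self, other: object) -> bool:  # NaN-aware frame equality
        if not isinstance(other, SkeletonFrame):
            return NotImplemented
        return (
            self.t_ms == other.t_ms
            and self.score == other.score
            and np.array_equal(self.positions, other.positions, equal_nan=True)
        )


@dataclass
class Session:
    """An ordered sequence of skeleton frames plus session metadata."""

    frames: list[SkeletonFrame]
    session_id: str = ""
    game_id: str = "equilibrium_paint"
    nominal_duration_s: float = 30.0
    sampling_hz: float = 10.0
    convention: str = "ml_ap_vertical"

    #: tolerated deviation of the recorded span from the nominal duration
    #: before a warning is emitted (STS protocol sessions).
    duration_tolerance_s: float = 5.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise SchemaError("session has no frames")
        t = self.t_ms
        if np.any(np.diff(t) <= 0):
            raise SchemaError("frame timestamps must be strictly increasing")
        span_s = (t[-1] - t[0]) / 1000.0
        if abs(span_s - self.nominal_duration_s) > self.duration_tolerance_s:
            warnings.warn(
                f"session span {span_s:.1f}s deviates from nominal "
                f"{self.nominal_duration_s:.0f}s by more than "
                f"{self.duration_tolerance_s:.0f}s",
                stacklevel=2,
            )

    @property
    def t_ms(self) -> np.ndarray:
        return np.asarray([f.t_ms for f in self.frames], dtype=np.int64)

    @property
    def t_s(self) -> np.ndarray:
        t = self.t_ms
        return (t - t[0]) / 1000.0

    @property
    def scores(self) -> np.ndarray:
        return np.asarray([f.score for f in self.frames], dtype=float)

    def positions(self) -> np.ndarray:
        """Stacked joint positions, shape (n_frames, 25, 3)."""
        return np.stack([f.positions for f in self.frames])

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# Dialects


@dataclass(frozen=True)
class Dialect:
    """Field-name and axis conventions of one family of session logs."""

    name: str
    time_key: str = "t_ms"
    score_key: str = "score"
    joints_key: str = "joints"
    time_scale_to_ms: float = 1.0
    axis_mapping: AxisMapping = field(default_factory=AxisMapping.identity)


#: Depth-camera native axes: x toward the camera's right (subject's left),
#: y up, z from the camera toward the subject. Mapping both horizontal axes
#: with a sign flip yields ML positive toward the subject's right and AP
#: positive toward the camera (the subject's forward).
KINECT_NATIVE = AxisMapping(source=("x", "z", "y"), sign=(-1, -1, 1))

_DIALECTS: dict[str, Dialect] = {}


def register_dialect(dialect: Dialect) -> None:
    _DIALECTS[dialect.name] = dialect


def get_dialect(name: str) -> Dialect:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise ConfigError(
            f"unknown dialect {name!r}; registered: {sorted(_DIALECTS)}"
        ) from None


register_dialect(Dialect(name="canonical"))
# Field names of the released exergame logs are not printed in the source
# publication; this dialect encodes the documented content (time in ms,
# in-game score, 25 joint positions) under assumed key names and the
# device-native axis convention. Adjust via a dialect config if a deployment
# differs.
register_dialect(
    Dialect(
        name="removes",
        time_key="time",
        score_key="score",
        joints_key="joints",
        time_scale_to_ms=1.0,
        axis_mapping=KINECT_NATIVE,
    )
)


def load_dialect_config(path: str | Path) -> Dialect:
    """Register a dialect from a JSON/YAML config file and return it.

    Expected keys: ``name``, optional ``time_key``/``score_key``/``joints_key``,
    ``time_scale_to_ms``, and ``axis_mapping`` with ``source`` (list of three
    of "x","y","z" for ML, AP, vertical) and ``sign`` (three of ±1).
    """
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "name" not in cfg:
        raise ConfigError(f"dialect config {path} must be a mapping with a 'name'")
    am_cfg = cfg.pop("axis_mapping", None)
    mapping = AxisMapping.identity()
    if am_cfg is not None:
        mapping = AxisMapping(
            source=tuple(am_cfg.get("source", _AXES)),
            sign=tuple(am_cfg.get("sign", (1, 1, 1))),
        )
    dialect = Dialect(axis_mapping=mapping, **cfg)
    register_dialect(dialect)
    return dialect


# ---------------------------------------------------------------------------
# Read / write


def _parse_event(event: object, index: int, dialect: Dialect) -> tuple[int, float, np.ndarray]:
    if not isinstance(event, dict):
        raise SchemaError(f"event {index} is not a JSON object")
    for key in (dialect.time_key, dialect.score_key, dialect.joints_key):
        if key not in event:
            raise SchemaError(f"event {index} is missing required key {key!r}")
    t_raw = event[dialect.time_key]
    if not isinstance(t_raw, (int, float)) or isinstance(t_raw, bool):
        raise SchemaError(f"event {index}: time value {t_raw!r} is not numeric")
    t_ms = int(round(float(t_raw) * dialect.time_scale_to_ms))
    score = event[dialect.score_key]
    if not isinstance(score, (int, float)) or isinstance(score, bool):
        raise SchemaError(f"event {index}: score {score!r} is not numeric")
    joints = event[dialect.joints_key]
    if not isinstance(joints, list) or len(joints) != N_JOINTS:
        n = len(joints) if isinstance(joints, list) else "non-list"
        raise SchemaError(
            f"event {index}: expected {N_JOINTS} joint entries, got {n}"
        )
    pos = np.empty((N_JOINTS, 3), dtype=float)
    for j, triple in enumerate(joints):
        if triple is None:
            pos[j] = np.nan
            continue
        if not (isinstance(triple, list) and len(triple) == 3):
            raise SchemaError(f"event {index}, joint {j}: expected [x, y, z] or null")
        try:
            vals = [float(v) for v in triple]
        except (TypeError, ValueError):
            raise SchemaError(f"event {index}, joint {j}: non-numeric coordinate") from None
        if not all(math.isfinite(v) for v in vals):
            raise SchemaError(f"event {index}, joint {j}: non-finite coordinate")
        pos[j] = vals
    return t_ms, float(score), pos


def read_session(
    path: str | Path,
    dialect: str | Dialect = "canonical",
    mapping: AxisMapping | None = None,
    **session_meta,
) -> Session:
    """Read a session log.

    Events are sorted by time and duplicate timestamps collapsed to the last
    occurrence; positions are remapped to ML/AP/vertical via the dialect's
    axis mapping (or an explicit ``mapping`` override).

    Raises :class:`SchemaError` on malformed JSON (naming the byte offset) or
    on any event missing a required key or joint.
    """
    path = Path(path)
    if isinstance(dialect, str):
        dialect = get_dialect(dialect)
    mapping = mapping if mapping is not None else dialect.axis_mapping

    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(
                f"{path}: malformed JSON at byte offset {exc.pos}: {exc.msg}"
            ) from exc
    if isinstance(doc, dict) and "events" in doc:
        events = doc["events"]
    else:
        events = doc
    if not isinstance(events, list):
        raise SchemaError(f"{path}: top level must be an array of events")
    if not events:
        raise SchemaError(f"{path}: session contains no events")

    parsed = [_parse_event(ev, i, dialect) for i, ev in enumerate(events)]
    parsed.sort(key=lambda item: item[0])
    by_time: dict[int, tuple[int, float, np.ndarray]] = {p[0]: p for p in parsed}
    frames = [
        SkeletonFrame(t_ms=t, score=s, positions=apply_axis_mapping(pos, mapping))
        for t, s, pos in (by_time[t] for t in sorted(by_time))
    ]
    meta = {"session_id": path.stem}
    meta.update(session_meta)
    return Session(frames=frames, **meta)


def _triple_to_json(row: np.ndarray) -> list[float] | None:
    if np.isnan(row).all():
        return None
    return [float(v) for v in row]


def write_session(session: Session, path: str | Path) -> None:
    """Write a session in the canonical dialect.

    Numeric text uses Python's shortest round-trip float representation, so
    ``read_session(write_session(s))`` reproduces the frames bit for bit.
    """
    events = [
        {
            "t_ms": int(f.t_ms),
            "score": float(f.score),
            "joints": [_triple_to_json(row) for row in f.positions],
        }
        for f in session.frames
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(events, fh, separators=(",", ":"))
        fh.write("\n")


def session_json_schema() -> dict:
    """The canonical session-log JSON Schema shipped with the package."""
    from importlib import resources

    text = resources.files("stskit.data").joinpath("session.schema.json").read_text()
    return json.loads(text)
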
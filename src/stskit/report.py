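"""Therapist-style session graphs.

Five panels mirror what a clinician reviews after a sit-to-stand session:

a. COM vertical trajectory with stand-up peaks marked and phases shaded
   (light bands = ascending, darker bands = descending);
b. trunk flexion angle (UBFA) over time;
c. knee angle (LLFA), both sides, over time;
d. shoulder twist (UBTA) over time;
e. the COM trace on the transverse (AP-ML) plane, ascending phases drawn in
   one color and descending in another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import ConfigError
from .indicators import (
    IndicatorParams,
    com_series,
    llfa_series,
    ubfa_series,
    ubta_series,
)
from .segmentation import Extremum, PhaseSegment, SegmentationParams, segment_session
from .session_io import Session

__all__ = ["ReportSpec", "render_session_report"]

log = logging.getLogger(__name__)

_PANELS = ("com", "ubfa", "llfa", "ubta", "transverse")


@dataclass(frozen=True)
class ReportSpec:
    """Where and how to render the session report."""

    out_dir: Path = Path(".")
    formats: tuple[str, ...] = ("png",)
    ascending_shade: str = "0.92"   # light gray
    descending_shade: str = "0.78"  # darker gray
    ascending_color: str = "tab:blue"
    descending_color: str = "tab:red"
    panels: tuple[str, ...] = _PANELS
    dpi: int = 110

    def __post_init__(self) -> None:
        bad = set(self.panels) - set(_PANELS)
        if bad:
            raise ConfigError(f"unknown panels: {sorted(bad)}")
        if not self.panels:
            raise ConfigError("at least one report panel must be selected")


def _shade_phases(ax, segments: list[PhaseSegment], t_s, spec: ReportSpec) -> None:
    for seg in segments:
        color = spec.ascending_shade if seg.kind == "ascending" else spec.descending_shade
        ax.axvspan(seg.start.t_s, seg.end.t_s, color=color, zorder=0)


def render_session_report(
    session: Session,
    spec: ReportSpec | None = None,
    seg_params: SegmentationParams | None = None,
    params: IndicatorParams | None = None,
) -> list[Path]:
    """Render the selected panels to files; returns the written paths.

    With no detectable phases the time-series panels are still rendered,
    without shading (a warning is logged).
    """
    spec = spec or ReportSpec()
    params = params or IndicatorParams()
    traj, extrema, segments = segment_session(session, seg_params)
    if not segments:
        log.warning("session %s: no phases detected; rendering without shading",
                    session.session_id)
    t = session.t_s
    peaks = [e for e in extrema if e.kind == "peak"]

    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(fig, stem: str) -> None:
        for ext in spec.formats:
            path = out_dir / f"{session.session_id}_{stem}.{ext}"
            fig.savefig(path, dpi=spec.dpi)
            written.append(path)
        plt.close(fig)

    def timeseries(stem: str, ylabel: str, plot_fn) -> None:
        fig, ax = plt.subplots(figsize=(8, 3), layout="constrained")
        _shade_phases(ax, segments, t, spec)
        plot_fn(ax)
        ax.set_xlabel("time (s)")
        ax.set_ylabel(ylabel)
        ax.set_title(f"{session.session_id} — {ylabel}")
        if plot_fn is not None and ax.get_legend_handles_labels()[0]:
            ax.legend(loc="upper right", fontsize=8)
        save(fig, stem)

    if "com" in spec.panels:
        c = com_series(session)

        def plot_com(ax):
            ax.plot(t, c[:, 2], color="k", lw=1.2, label="COM vertical")
            if peaks:
                ax.plot([p.t_s for p in peaks], [c[p.index, 2] for p in peaks],
                        "v", color="tab:orange", label="stand-up peak")

        timeseries("com", "COM height (m)", plot_com)

    if "ubfa" in spec.panels:
        u = ubfa_series(session, params.ubfa_offset_deg)
        timeseries("ubfa", "UBFA (deg)", lambda ax: ax.plot(t, u, color="tab:green", lw=1.0))

    if "llfa" in spec.panels:
        ll = llfa_series(session, "left")
        lr = llfa_series(session, "right")

        def plot_llfa(ax):
            ax.plot(t, ll, lw=1.0, label="left")
            ax.plot(t, lr, lw=1.0, label="right")

        timeseries("llfa", "LLFA (deg)", plot_llfa)

    if "ubta" in spec.panels:
        w = ubta_series(session)
        timeseries("ubta", "UBTA (deg)", lambda ax: ax.plot(t, w, color="tab:purple", lw=1.0))

    if "transverse" in spec.panels:
        c = com_series(session)
        fig, ax = plt.subplots(figsize=(4.5, 4.5), layout="constrained")
        if segments:
            for seg in segments:
                lo, hi = seg.frame_span[0], seg.frame_span[1] + 1
                color = (spec.ascending_color if seg.kind == "ascending"
                         else spec.descending_color)
                ax.plot(c[lo:hi, 0] * 100, c[lo:hi, 1] * 100, color=color, lw=1.0)
        else:
            ax.plot(c[:, 0] * 100, c[:, 1] * 100, color="k", lw=1.0)
        ax.set_xlabel("ML (cm)")
        ax.set_ylabel("AP (cm)")
        ax.set_title(f"{session.session_id} — COM transverse plane")
        ax.set_aspect("equal", adjustable="datalim")
        save(fig, "transverse")

    return written
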
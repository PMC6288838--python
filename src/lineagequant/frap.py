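"""FRAP-style time-series analysis of per-cell fluorescence traces.

Photobleaching is used here to erase pre-existing (maternal) fluorescent
protein: any subsequent rise in a cell's signal reports new synthesis.
Traces are background-corrected per frame, normalized either to the
pre-bleach baseline (mean of the frames collected before the bleach) or
to the mean intensity of an unbleached control embryo, and summarized by
a paired endpoint test or a least-squares slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CellTrace", "extract_traces", "normalize_prebleach",
           "normalize_to_control", "synthesis_test", "endpoint_slope",
           "traces_to_frame", "plot_traces"]

PREBLEACH_FRAMES = 5          # images collected before the bleach pulse


@dataclass(frozen=True)
class CellTrace:
    """Background-corrected mean intensity of one cell over time."""

    cell: str
    times_s: np.ndarray
    intensity: np.ndarray
    normalized: np.ndarray | None = None
    bleach_time_s: float | None = None
    division_times_s: tuple[float, ...] = ()
    role: str | None = None                 # germline | somatic

    def __post_init__(self):
        t = np.asarray(self.times_s, float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if len(t) != len(self.intensity):
            raise ValueError("times and intensities differ in length")

    @property
    def values(self) -> np.ndarray:
        """Normalized values if available, else raw intensities."""
        return self.intensity if self.normalized is None else self.normalized


def extract_traces(stack: np.ndarray, masks_per_frame: list,
                   camera_bg: float | str = "outside_embryo",
                   bleach_time_s: float | None = None,
                   times_s: np.ndarray | None = None) -> list[CellTrace]:
    """Per-cell background-corrected mean intensities from a time-lapse.

    ``camera_bg`` is either a fixed count value or ``"outside_embryo"``,
    in which case the background is measured per frame from the region
    outside the embryo (valid because these time-lapses have no
    fluorescent bath).  A cell absent from every frame is rejected.
    """
    if len(stack) < 2:
        raise ValueError("need at least 2 frames")
    if len(stack) != len(masks_per_frame):
        raise ValueError("stack and masks_per_frame differ in length")
    times = np.arange(len(stack), dtype=float) if times_s is None else np.asarray(times_s, float)
    per_cell: dict[str, list[tuple[float, float]]] = {}
    all_cells: set[str] = set()
    for frame, masks, t in zip(stack, masks_per_frame, times):
        if camera_bg == "outside_embryo":
            bg = float(frame[masks.bath].mean())
        else:
            bg = float(camera_bg)
        for name, cm in masks.cells.items():
            all_cells.add(name)
            per_cell.setdefault(name, []).append((t, float(frame[cm.total].mean()) - bg))
    traces = []
    for name in sorted(all_cells):
        pts = per_cell.get(name, [])
        if not pts:
            raise ValueError(f"cell {name!r} absent from every frame")
        ts, vals = (np.array(v) for v in zip(*pts))
        traces.append(CellTrace(cell=name, times_s=ts, intensity=vals,
                                bleach_time_s=bleach_time_s))
    return traces


def normalize_prebleach(traces: list[CellTrace], bleach_time_s: float | None = None,
                        n_frames: int = PREBLEACH_FRAMES,
                        baseline_cell: str | None = None) -> list[CellTrace]:
    """Normalize all traces to the pre-bleach baseline intensity.

    The baseline is the mean of the last ``n_frames`` values of
    ``baseline_cell`` (default: the cell that exists before the bleach,
    i.e. the zygote) taken strictly before the bleach time.  Applied to
    already-normalized traces the operation is the identity, since their
    baseline is 1.
    """
    bt = bleach_time_s
    if bt is None:
        bts = {t.bleach_time_s for t in traces if t.bleach_time_s is not None}
        if len(bts) != 1:
            raise ValueError("bleach time not annotated; pass bleach_time_s")
        bt = bts.pop()
    if baseline_cell is None:
        pre = [t for t in traces if np.any(np.asarray(t.times_s) < bt)]
        if not pre:
            raise ValueError("no trace has pre-bleach frames")
        baseline_cell = pre[0].cell
    base_tr = next(t for t in traces if t.cell == baseline_cell)
    sel = np.asarray(base_tr.times_s) < bt
    if not sel.any():
        raise ValueError(f"baseline cell {baseline_cell!r} has no pre-bleach frames")
    baseline = float(base_tr.values[sel][-n_frames:].mean())
    if baseline <= 0:
        raise ValueError("non-positive pre-bleach baseline")
    return [replace(t, normalized=np.asarray(t.values, float) / baseline,
                    bleach_time_s=bt) for t in traces]


def normalize_to_control(traces: list[CellTrace], control: "float | CellTrace",
                         per_timepoint: bool = False) -> list[CellTrace]:
    """Normalize to the mean intensity of an unbleached control embryo.

    ``control`` is a whole-embryo trace (or a precomputed scalar).  By
    default a single scalar -- the control's first-frame value -- is used;
    with ``per_timepoint=True`` each timepoint is divided by the control
    value at the matching time.
    """
    if isinstance(control, CellTrace):
        if per_timepoint:
            interp = lambda ts: np.interp(ts, control.times_s, control.values)  # noqa: E731
        else:
            scalar = float(control.values[0])
            interp = lambda ts: scalar  # noqa: E731
    else:
        interp = lambda ts: float(control)  # noqa: E731
    out = []
    for t in traces:
        denom = interp(np.asarray(t.times_s, float))
        out.append(replace(t, normalized=np.asarray(t.values, float) / denom))
    return out


def synthesis_test(traces_by_embryo: list[list[CellTrace]], cell: str):
    """Paired test for net synthesis in ``cell`` across embryos.

    For each embryo, takes the cell's first post-bleach value (its first
    timepoint, for cells born after the bleach) and its final value; a
    two-tailed paired t-test compares the two.  Returns
    ``(mean_difference, p_value)``.
    """
    first, last = [], []
    for traces in traces_by_embryo:
        tr = next((t for t in traces if t.cell == cell), None)
        if tr is None:
            continue
        vals = np.asarray(tr.values, float)
        if tr.bleach_time_s is not None:
            post = vals[np.asarray(tr.times_s) > tr.bleach_time_s]
        else:
            post = vals
        if len(post) < 2:
            continue
        first.append(post[0])
        last.append(post[-1])
    if len(first) < 2:
        raise ValueError("need the cell's endpoints in at least 2 embryos")
    first, last = np.array(first), np.array(last)
    diff = last - first
    if np.allclose(diff.std(ddof=1), 0.0):
        return float(diff.mean()), 1.0 if np.allclose(diff, 0) else 0.0
    t, p = stats.ttest_rel(last, first)
    return float(diff.mean()), float(p)


def endpoint_slope(trace: CellTrace, window: tuple[float, float]) -> float:
    """Least-squares slope of the trace over a time window (units/s)."""
    t = np.asarray(trace.times_s, float)
    lo, hi = window
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 3:
        raise ValueError("window must contain at least 3 trace points")
    return float(np.polyfit(t[sel], np.asarray(trace.values, float)[sel], 1)[0])


def traces_to_frame(traces: list[CellTrace], embryo_id: str = "e0") -> pd.DataFrame:
    rows = []
    for t in traces:
        norm = t.normalized if t.normalized is not None else [np.nan] * len(t.times_s)
        for ts, raw, nv in zip(t.times_s, t.intensity, norm):
            rows.append((embryo_id, t.cell, ts, raw, nv))
    return pd.DataFrame(rows, columns=["embryo_id", "cell", "time_s",
                                       "intensity", "normalized"])


def plot_traces(traces: list[CellTrace], ax=None):
    """Diagnostic plot of per-cell traces (normalized if available)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for t in traces:
        ax.plot(t.times_s, t.values, label=t.cell)
        if t.bleach_time_s is not None:
            ax.axvline(t.bleach_time_s, ls=":", color="0.6")
    ax.set_xlabel("time after pronuclear meeting (s)")
    ax.set_ylabel("normalized fluorescence")
    ax.legend(fontsize="small")
    return ax
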
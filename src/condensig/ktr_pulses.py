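"""ERK pulse calling from kinase-translocation-reporter (KTR) traces.

A KTR trace is a single tracked cell's cytoplasmic/nuclear reporter intensity
ratio over time (the ratio rises with ERK activity).  Pulses are transient
excursions lasting tens of minutes, detected as local maxima with a minimum
topographic prominence.  Three rules from the upstream experimental analysis
are applied:

* cells with low or no reporter expression are excluded before any counting;
* pulses within a fixed number of frames (default 10, i.e. 50 min at 5-min
  sampling) before a cell division are flagged as division artifacts — such
  pulses occur independently of RAS/ERK signaling — and excluded from counts;
* when a cell divides, the parent's ratio history is duplicated into both
  children for display and tracking continuity, so pulses occurring in a
  shared parental segment are attributed once, to the parent, never counted
  per child.

Traces of dying cells are truncated at the death frame before peak finding,
which removes spurious peaks from apoptotic debris.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .stats_kinetics import fraction_ci


class TraceError(ValueError):
    pass


class LineageError(ValueError):
    pass


TRACE_COLUMNS = [
    "cell_id",
    "parent_id",
    "frame",
    "time_min",
    "ratio",
    "x_px",
    "y_px",
    "expression",
    "divided_this_frame",
    "died_this_frame",
]


@dataclass
class KtrTrace:
    """One tracked cell's reporter time series.

    ``frames`` are contiguous integer frame indices; ``own_start`` marks the
    first frame at which this cell physically existed (later than
    ``frames[0]`` for daughters carrying duplicated parental history).
    """

    cell_id: int
    frames: np.ndarray
    time_min: np.ndarray
    ratio: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    expression: float = 1.0
    parent_id: int | None = None
    division_frames: list[int] = field(default_factory=list)
    death_frame: int | None = None
    own_start: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        n = self.frames.size
        if n == 0:
            raise TraceError("empty trace")
        if any(arr.size != n for arr in (self.time_min, self.ratio, self.x_px, self.y_px)):
            raise TraceError("per-frame arrays must share a length")
        if np.any(np.diff(self.frames) <= 0):
            raise TraceError("frames must be strictly increasing")
        span = (int(self.frames[0]), int(self.frames[-1]))
        if self.death_frame is not None and not span[0] <= self.death_frame <= span[1]:
            raise TraceError("death_frame outside trace span")
        for d in self.division_frames:
            if not span[0] <= d <= span[1]:
                raise TraceError("division frame outside trace span")
        if self.own_start is None:
            self.own_start = span[0]

    @property
    def frame_interval_min(self) -> float:
        steps = np.diff(self.time_min)
        if steps.size and not np.allclose(steps, steps[0]):
            raise TraceError("non-uniform sampling interval")
        return float(steps[0]) if steps.size else 0.0

    def position_at(self, frame: int) -> tuple[float, float] | None:
        """Centroid at a frame, or None if the cell is not tracked there."""
        if frame < self.frames[0] or frame > self.frames[-1]:
            return None
        idx = frame - int(self.frames[0])
        return float(self.x_px[idx]), float(self.y_px[idx])

    def alive_at(self, frame: int) -> bool:
        """True while the cell physically exists (own segment, pre-death)."""
        if frame < self.own_start or frame > self.frames[-1]:
            return False
        if self.death_frame is not None and frame > self.death_frame:
            return False
        return True


@dataclass
class PulseParams:
    """Pulse-calling thresholds.

    ``min_prominence`` is on the (unitless) ratio scale; the default was
    calibrated on synthetic traces with unit pulse amplitude.  The 10-frame
    division exclusion window corresponds to 50 min at 5-min sampling.
    """

    min_prominence: float = 0.5
    min_peak_distance_frames: int = 3
    min_expression: float = 0.2
    division_exclusion_frames: int = 10
    smoothing_window_frames: int | None = None

    def __post_init__(self) -> None:
        if self.min_prominence < 0 or self.min_expression < 0:
            raise TraceError("thresholds must be nonnegative")
        if self.min_peak_distance_frames < 1:
            raise TraceError("min_peak_distance_frames must be >= 1")
        if self.division_exclusion_frames < 0:
            raise TraceError("division_exclusion_frames must be >= 0")
        if self.smoothing_window_frames is not None and self.smoothing_window_frames < 1:
            raise TraceError("smoothing window must be >= 1")


@dataclass
class Pulse:
    cell_id: int
    peak_frame: int
    prominence: float
    width_frames: float
    excluded_reason: str = "none"  # none | division_proximal | low_expression


def traces_from_frame(df: pd.DataFrame) -> list[KtrTrace]:
    """Build :class:`KtrTrace` objects from a tidy trace table.

    Daughter cells carry duplicated parental history, so a daughter's
    ``own_start`` is inferred as one frame past its parent's last frame.
    """
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceError(f"trace table missing columns: {missing}")
    traces: dict[int, KtrTrace] = {}
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        parent = grp["parent_id"].iloc[0]
        parent_id = None if pd.isna(parent) else int(parent)
        died = grp.loc[grp["died_this_frame"] == 1, "frame"]
        divided = grp.loc[grp["divided_this_frame"] == 1, "frame"]
        traces[int(cell_id)] = KtrTrace(
            cell_id=int(cell_id),
            frames=grp["frame"].to_numpy(),
            time_min=grp["time_min"].to_numpy(),
            ratio=grp["ratio"].to_numpy(),
            x_px=grp["x_px"].to_numpy(),
            y_px=grp["y_px"].to_numpy(),
            expression=float(grp["expression"].iloc[0]),
            parent_id=parent_id,
            division_frames=[int(f) for f in divided],
            death_frame=int(died.iloc[0]) if len(died) else None,
        )
    for tr in traces.values():
        if tr.parent_id is not None and tr.parent_id in traces:
            tr.own_start = int(traces[tr.parent_id].frames[-1]) + 1
    return list(traces.values())


def qc_filter(
    traces: list[KtrTrace], min_expression: float
) -> tuple[list[KtrTrace], dict]:
    """Drop traces with reporter expression below the QC cutoff."""
    kept = [t for t in traces if t.expression >= min_expression]
    removed = [t.cell_id for t in traces if t.expression < min_expression]
    log = {
        "n_input": len(traces),
        "n_kept": len(kept),
        "n_removed": len(removed),
        "removed_ids": removed,
    }
    return kept, log


def detect_pulses(trace: KtrTrace, params: PulseParams | None = None) -> list[Pulse]:
    """Call pulses in one trace by prominence-based peak detection.

    Peaks are local maxima of the (optionally median-smoothed) ratio with
    topographic prominence >= ``min_prominence``, separated by at least
    ``min_peak_distance_frames``.  The trace is truncated at the death frame
    first.  Pulses within ``division_exclusion_frames`` before a division are
    flagged ``division_proximal``; pulses of under-expressing cells are
    flagged ``low_expression``.  Flagged pulses are reported but excluded
    from all downstream counts.
    """
    params = params or PulseParams()
    if trace.frames.size < 3:
        return []
    trace.frame_interval_min  # raises on non-uniform sampling
    values = trace.ratio
    frames = trace.frames
    if trace.death_frame is not None:
        keep = frames <= trace.death_frame
        values, frames = values[keep], frames[keep]
    if params.smoothing_window_frames and params.smoothing_window_frames > 1:
        values = ndimage.median_filter(
            values, size=params.smoothing_window_frames, mode="nearest"
        )
    if values.size < 3:
        return []
    idx, props = signal.find_peaks(
        values,
        prominence=params.min_prominence,
        distance=params.min_peak_distance_frames,
    )
    if idx.size == 0:
        return []
    widths = signal.peak_widths(values, idx, rel_height=0.5)[0]
    pulses = []
    for i, peak_i in enumerate(idx):
        peak_frame = int(frames[peak_i])
        reason = "none"
        if trace.expression < params.min_expression:
            reason = "low_expression"
        elif any(
            d - params.division_exclusion_frames <= peak_frame < d
            for d in trace.division_frames
        ):
            reason = "division_proximal"
        pulses.append(
            Pulse(
                cell_id=trace.cell_id,
                peak_frame=peak_frame,
                prominence=float(props["prominences"][i]),
                width_frames=float(widths[i]),
                excluded_reason=reason,
            )
        )
    return pulses


def pulse_table(traces: list[KtrTrace], params: PulseParams | None = None) -> pd.DataFrame:
    """Tidy pulse table over many traces (flagged pulses included)."""
    rows = [
        {
            "cell_id": p.cell_id,
            "peak_frame": p.peak_frame,
            "prominence": p.prominence,
            "width_frames": p.width_frames,
            "excluded_reason": p.excluded_reason,
        }
        for t in traces
        for p in detect_pulses(t, params)
    ]
    return pd.DataFrame(
        rows,
        columns=["cell_id", "peak_frame", "prominence", "width_frames", "excluded_reason"],
    )


def _check_acyclic(lineage: dict[int, list[int]]) -> None:
    parent_of: dict[int, int] = {}
    for parent, children in lineage.items():
        for child in children:
            parent_of[child] = parent
    for start in parent_of:
        seen = set()
        node = start
        while node in parent_of:
            if node in seen:
                raise LineageError("lineage map contains a cycle")
            seen.add(node)
            node = parent_of[node]


def resolve_pulse_owner(
    cell_id: int, peak_frame: int, traces_by_id: dict[int, KtrTrace]
) -> int:
    """Walk up the lineage to the cell that physically exhibited a pulse.

    A pulse at a frame before the cell's own birth lies in duplicated
    parental history and belongs to the ancestor alive at that frame.
    """
    node = traces_by_id.get(cell_id)
    while (
        node is not None
        and node.parent_id is not None
        and node.parent_id in traces_by_id
        and peak_frame < node.own_start
    ):
        node = traces_by_id[node.parent_id]
    return node.cell_id if node is not None else cell_id


def pulses_per_cell(
    traces: list[KtrTrace],
    params: PulseParams | None = None,
    lineage: dict[int, list[int]] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell retained pulse counts with lineage deduplication.

    QC-failing traces are removed first.  Each retained pulse is attributed
    to the cell that was physically alive at its peak frame, so a pulse in a
    shared parental segment is counted once even though it appears in both
    daughters' duplicated histories.  Returns the per-cell count table and a
    summary with the fraction of pulsing cells and its Wilson 95% CI.
    """
    params = params or PulseParams()
    if lineage:
        _check_acyclic(lineage)
    kept, qc_log = qc_filter(traces, params.min_expression)
    traces_by_id = {t.cell_id: t for t in kept}
    unique_pulses: set[tuple[int, int]] = set()
    for trace in kept:
        for pulse in detect_pulses(trace, params):
            if pulse.excluded_reason != "none":
                continue
            owner = resolve_pulse_owner(trace.cell_id, pulse.peak_frame, traces_by_id)
            unique_pulses.add((owner, pulse.peak_frame))
    counts = {t.cell_id: 0 for t in kept}
    for owner, _frame in unique_pulses:
        counts[owner] = counts.get(owner, 0) + 1
    table = pd.DataFrame(
        {"cell_id": list(counts), "n_pulses": list(counts.values())}
    ).sort_values("cell_id", ignore_index=True)
    n_cells = len(kept)
    n_pulsing = int((table["n_pulses"] > 0).sum())
    ci = fraction_ci(n_pulsing, n_cells) if n_cells else (float("nan"), float("nan"))
    summary = {
        "n_cells": n_cells,
        "n_pulsing": n_pulsing,
        "total_pulses": len(unique_pulses),
        "fraction_pulsing": n_pulsing / n_cells if n_cells else float("nan"),
        "fraction_ci95": ci,
        "qc": qc_log,
    }
    return table, summary
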
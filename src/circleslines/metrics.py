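"""Ovalization Index, cycle segmentation and drawing frequency.

The Ovalization Index (OI) quantifies the lateral deviation of a nominally
straight vertical stroke.  Per drawing cycle,

    OI_cycle = 100 * sd(x - mean(x)) / (h / sqrt(2))

where ``h`` is the cycle's vertical semi-extent (half its y-range).  This
normalization anchors the scale: a noise-free vertical line scores 0, a
noise-free circle scores exactly 100 (a circle of radius r has
sd(x) = r/sqrt(2) and h = r), and an ellipse with lateral/vertical semi-axis
ratio a/b scores 100*a/b.  A trajectory's OI is the mean over its complete
cycles, clipped to [0, 100].

Cycles are delimited by successive maxima of y after low-pass smoothing
(moving average, 0.1 s window), keeping half-open [max_i, max_{i+1})
intervals; extrema below a prominence threshold (5% of the block's y-range)
are treated as jitter and ignored.  Drawing frequency is the number of
complete cycles divided by the time they span — the inverse mean cycle
duration, in Hz.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .trajectory import SessionData, Trajectory

__all__ = [
    "DEFAULT_SMOOTH_WINDOW",
    "DEFAULT_MIN_PROMINENCE",
    "NoCycleError",
    "OIResult",
    "segment_cycles",
    "ovalization_index",
    "drawing_frequency",
    "coupling_effect",
    "session_metrics",
    "condition_scores",
]

#: Moving-average smoothing window for cycle segmentation, in seconds.
DEFAULT_SMOOTH_WINDOW = 0.1
#: Minimum peak prominence as a fraction of the block's y-range.
DEFAULT_MIN_PROMINENCE = 0.05


class NoCycleError(RuntimeError):
    """Raised when a trajectory contains no complete drawing cycle."""


@dataclass(frozen=True)
class OIResult:
    """Per-block ovalization summary.

    ``oi`` is the mean of ``per_cycle_oi`` clipped to [0, 100];
    ``frequency_hz`` is the inverse mean duration of the complete cycles.
    """

    oi: float
    n_cycles: int
    frequency_hz: float
    per_cycle_oi: tuple[float, ...]


def _smoothed_y(traj: Trajectory, smooth_window: float) -> np.ndarray:
    if smooth_window <= 0:
        return traj.y
    size = int(round(smooth_window * traj.sampling_rate))
    if size <= 1:
        return traj.y
    if size % 2 == 0:
        # keep the window symmetric so extrema are not phase-shifted
        size += 1
    return uniform_filter1d(traj.y, size=size, mode="nearest")


def segment_cycles(
    traj: Trajectory,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> list[tuple[int, int]]:
    """Delimit complete drawing cycles as half-open sample-index ranges.

    Cycles run from one qualifying y-maximum to the next, ``[max_i,
    max_{i+1})``; only complete cycles are returned, so a trajectory with
    fewer than two qualifying maxima yields an empty list.  On a plateau the
    first sample is taken as the extremum.
    """
    ys = _smoothed_y(traj, smooth_window)
    y_range = float(np.max(traj.y) - np.min(traj.y))
    if y_range == 0.0:
        return []
    peaks, props = find_peaks(
        ys, prominence=min_prominence * y_range, plateau_size=(1, None)
    )
    if "left_edges" in props and len(props["left_edges"]):
        peaks = props["left_edges"]
    if len(peaks) < 2:
        return []
    return [(int(a), int(b)) for a, b in zip(peaks[:-1], peaks[1:])]


def _cycle_oi(x: np.ndarray, y: np.ndarray) -> float | None:
    """OI of one cycle; None when the cycle is vertically degenerate."""
    h = (float(np.max(y)) - float(np.min(y))) / 2.0
    if h == 0.0:
        return None
    sd = float(np.std(x - np.mean(x)))
    return 100.0 * sd / (h / math.sqrt(2.0))


def ovalization_index(
    traj: Trajectory,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> OIResult:
    """Compute the per-block Ovalization Index.

    Raises
    ------
    NoCycleError
        If no complete cycle is found, or every cycle is vertically
        degenerate (zero y-range).
    """
    cycles = segment_cycles(traj, smooth_window, min_prominence)
    if not cycles:
        raise NoCycleError(
            f"no complete drawing cycle in block {traj.block_id} "
            f"({traj.condition}, hand {traj.hand})"
        )
    per_cycle: list[float] = []
    n_degenerate = 0
    for a, b in cycles:
        oi_c = _cycle_oi(traj.x[a:b], traj.y[a:b])
        if oi_c is None:
            n_degenerate += 1
            continue
        per_cycle.append(oi_c)
    if n_degenerate:
        warnings.warn(
            f"skipped {n_degenerate} vertically degenerate cycle(s) in "
            f"block {traj.block_id}",
            RuntimeWarning,
            stacklevel=2,
        )
    if not per_cycle:
        raise NoCycleError(
            f"all cycles vertically degenerate in block {traj.block_id}"
        )
    oi = float(np.clip(np.mean(per_cycle), 0.0, 100.0))
    span = float(traj.time[cycles[-1][1]] - traj.time[cycles[0][0]])
    freq = len(cycles) / span
    return OIResult(
        oi=oi,
        n_cycles=len(cycles),
        frequency_hz=freq,
        per_cycle_oi=tuple(per_cycle),
    )


def drawing_frequency(
    traj: Trajectory,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> float:
    """Average drawing frequency of a block in Hz.

    The number of complete cycles divided by the time they span; equal to
    the inverse of the mean cycle duration.
    """
    cycles = segment_cycles(traj, smooth_window, min_prominence)
    if not cycles:
        raise NoCycleError(
            f"no complete drawing cycle in block {traj.block_id}"
        )
    span = float(traj.time[cycles[-1][1]] - traj.time[cycles[0][0]])
    return len(cycles) / span


def coupling_effect(oi_cl: float, oi_ll: float) -> float:
    """Bimanual coupling effect: OI in CL minus OI in LL.

    A positive value means the non-congruent condition ovalized the line
    strokes more than the congruent one — the interference signature.
    """
    for name, v in (("oi_cl", oi_cl), ("oi_ll", oi_ll)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    return oi_cl - oi_ll


def session_metrics(
    session: SessionData,
    hand: str = "R",
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    on_no_cycle: str = "skip",
) -> pd.DataFrame:
    """Per-block OI and frequency for one hand of a session.

    Returns a table with columns ``block_id, condition, hand, oi, n_cycles,
    frequency_hz``.  Blocks without a complete cycle are skipped (with a
    warning) when ``on_no_cycle="skip"``, or raise when it is ``"raise"``.
    """
    rows = []
    for (block_id, h), traj in sorted(session.items()):
        if h != hand:
            continue
        try:
            res = ovalization_index(traj, smooth_window, min_prominence)
        except NoCycleError:
            if on_no_cycle == "raise":
                raise
            warnings.warn(
                f"block {block_id} ({traj.condition}) skipped: no complete cycle",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "block_id": block_id,
                "condition": traj.condition,
                "hand": hand,
                "oi": res.oi,
                "n_cycles": res.n_cycles,
                "frequency_hz": res.frequency_hz,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["block_id", "condition", "hand", "oi", "n_cycles", "frequency_hz"],
    )


def condition_scores(metrics: pd.DataFrame) -> pd.DataFrame:
    """Condition-level scores: mean OI and frequency over each condition's blocks."""
    if metrics.empty:
        raise ValueError("no block metrics to aggregate")
    return (
        metrics.groupby("condition", sort=True)[["oi", "frequency_hz"]]
        .mean()
        .reset_index()
    )
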
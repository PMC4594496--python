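"""Trajectory container and tabular I/O.

A trajectory is the raw unit of analysis: the timestamped 2-D pen positions
recorded from one hand during one experimental block.  The session-level CSV
layout (``time_s,x_mm,y_mm,hand,block_id,condition``) holds every trajectory
of a recording in long form, one row per pen sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The four experimental conditions of the Circles-Lines paradigm:
#: unimanual lines (L), unimanual circles (C), congruent bimanual
#: lines-lines (LL) and non-congruent circles-lines (CL).
CONDITIONS: tuple[str, ...] = ("L", "C", "LL", "CL")

HANDS: tuple[str, ...] = ("L", "R")

#: Columns of the session CSV, in order.
CSV_COLUMNS = ["time_s", "x_mm", "y_mm", "hand", "block_id", "condition"]


@dataclass
class Trajectory:
    """Pen samples for one hand within one experimental block.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds from session start, strictly increasing.
    x, y : ndarray
        Pen position in millimetres; x is the lateral axis, y the vertical
        drawing axis (increasing upward).
    hand : {"L", "R"}
    block_id : int
        Ordinal of the experimental block within the session.
    condition : {"L", "C", "LL", "CL"}
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hand: str
    block_id: int = 0
    condition: str = "L"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.time.shape == self.x.shape == self.y.shape):
            raise ValueError("time, x and y must have identical shapes")
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("a trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.time)):
            raise ValueError("non-finite sample times")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite coordinates")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Time spanned by the samples, in seconds."""
        return float(self.time[-1] - self.time[0])

    @property
    def sampling_rate(self) -> float:
        """Median sampling rate in Hz."""
        return 1.0 / float(np.median(np.diff(self.time)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "x_mm": self.x,
                "y_mm": self.y,
                "hand": self.hand,
                "block_id": self.block_id,
                "condition": self.condition,
            }
        )


#: A full two-hand recording: trajectories keyed by (block_id, hand).
SessionData = dict[tuple[int, str], Trajectory]


def session_to_frame(session: SessionData) -> pd.DataFrame:
    """Concatenate a session's trajectories into one long-form table."""
    if not session:
        raise ValueError("empty session")
    frames = [session[key].to_frame() for key in sorted(session)]
    return pd.concat(frames, ignore_index=True)[CSV_COLUMNS]


def write_session_csv(session: SessionData, path: str | Path) -> None:
    session_to_frame(session).to_csv(path, index=False, float_format="%.6f")


def frame_to_session(frame: pd.DataFrame) -> SessionData:
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trajectory table is missing columns: {missing}")
    session: SessionData = {}
    for (block_id, hand), grp in frame.groupby(["block_id", "hand"], sort=True):
        grp = grp.sort_values("time_s")
        condition = str(grp["condition"].iloc[0])
        session[(int(block_id), str(hand))] = Trajectory(
            time=grp["time_s"].to_numpy(),
            x=grp["x_mm"].to_numpy(),
            y=grp["y_mm"].to_numpy(),
            hand=str(hand),
            block_id=int(block_id),
            condition=condition,
        )
    return session


def read_session_csv(path: str | Path) -> SessionData:
    """Read a session CSV back into trajectories keyed by (block_id, hand)."""
    return frame_to_session(pd.read_csv(path))
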
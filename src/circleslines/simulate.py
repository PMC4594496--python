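"""Synthetic two-hand drawing sessions and normative cohorts.

The generator emulates the Circles-Lines block paradigm: a session is an
alternation of 15 s experimental blocks (conditions L, C, LL, CL; 6
repetitions each, pseudo-randomly ordered) and 15 s rest blocks, framed by
30 s initial and final rests.  Strokes are harmonic: a "line" is vertical
harmonic motion with a controllable lateral component (the ovalization ratio
``alpha``), a "circle" is uniform circular motion.  Bimanual interference is
modeled as additive lateral contamination of the line-drawing right hand by
the circle-drawing left hand's lateral component, scaled by a ``coupling``
fraction: ``coupling = 0`` reproduces the absent coupling of the motor
neglect phenotype, ``coupling > 0`` the normal interference effect.

Normative cohorts are drawn at the score level from a bivariate normal whose
population parameters equal the requested per-task means, SDs and inter-task
correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory import CONDITIONS, SessionData, Trajectory

__all__ = [
    "TrajectoryParams",
    "BlockSpec",
    "SessionSpec",
    "CohortSpec",
    "CohortResult",
    "generate_stroke_series",
    "generate_session",
    "generate_normative_cohort",
]


@dataclass(frozen=True)
class TrajectoryParams:
    """Kinematic parameters of one hand's drawing.

    Parameters
    ----------
    amplitude : float
        Vertical semi-extent of a stroke in mm (> 0).
    frequency : float
        Drawing cycles per second in Hz (> 0).  Default 1.3 Hz, the
        normative sample's mean drawing frequency.
    ovalization_ratio : float
        Target lateral/vertical semi-axis ratio ``alpha`` in [0, 1]:
        0 gives a strictly vertical line, 1 a circle.
    noise_sd : float
        Isotropic positional jitter SD in mm (>= 0).
    sampling_rate : float
        Samples per second (>= 20 so cycle segmentation is well-posed).
    seed : int or None
        Seed for the jitter stream; a fixed seed gives bitwise-identical
        output.
    """

    amplitude: float = 50.0
    frequency: float = 1.3
    ovalization_ratio: float = 0.0
    noise_sd: float = 1.0
    sampling_rate: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("amplitude must be > 0")
        if not self.frequency > 0:
            raise ValueError("frequency must be > 0")
        if not 0.0 <= self.ovalization_ratio <= 1.0:
            raise ValueError("ovalization_ratio must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_rate < 20:
            raise ValueError("sampling_rate must be >= 20 Hz")


@dataclass(frozen=True)
class BlockSpec:
    """One experimental block: condition, onset and duration in seconds."""

    condition: str
    onset: float
    duration: float = 15.0
    block_id: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SessionSpec:
    """Timeline of a session: ordered blocks plus framing rests.

    The standard paradigm (``SessionSpec.standard``) comprises an initial
    30 s rest, 24 experimental blocks of 15 s (6 repetitions of each of the
    4 conditions, pseudo-randomly ordered with at most 3 consecutive
    repeats of a condition) separated by 15 s rests, and a final 30 s rest.
    """

    blocks: tuple[BlockSpec, ...]
    initial_rest: float = 30.0
    final_rest: float = 30.0
    repetitions: int = 6

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("a session needs at least one block")
        counts: dict[str, int] = {}
        prev_end = None
        prev_onset = -math.inf
        for blk in self.blocks:
            counts[blk.condition] = counts.get(blk.condition, 0) + 1
            if blk.onset <= prev_onset:
                raise ValueError("block onsets must be strictly increasing")
            if prev_end is not None and blk.onset < prev_end:
                raise ValueError("blocks must not overlap")
            prev_onset, prev_end = blk.onset, blk.end
        if self.blocks[0].onset < self.initial_rest:
            raise ValueError("first block starts before the initial rest ends")
        present = set(counts.values())
        if len(present) > 1:
            raise ValueError("each condition must repeat the same number of times")
        object.__setattr__(self, "repetitions", present.pop())

    @property
    def total_duration(self) -> float:
        """Session length in seconds, including the final rest."""
        return self.blocks[-1].end + self.final_rest

    @classmethod
    def standard(
        cls,
        seed: int = 0,
        repetitions: int = 6,
        block_duration: float = 15.0,
        rest_duration: float = 15.0,
        initial_rest: float = 30.0,
        final_rest: float = 30.0,
        conditions: tuple[str, ...] = CONDITIONS,
        max_run: int = 3,
    ) -> "SessionSpec":
        """Build the standard paradigm with a seeded pseudo-random order.

        The order is a seeded shuffle constrained to at most ``max_run``
        consecutive blocks of the same condition.
        """
        rng = np.random.default_rng(seed)
        sequence = list(conditions) * repetitions
        while True:
            order = rng.permutation(len(sequence))
            shuffled = [sequence[i] for i in order]
            run, longest = 1, 1
            for a, b in zip(shuffled, shuffled[1:]):
                run = run + 1 if a == b else 1
                longest = max(longest, run)
            if longest <= max_run:
                break
        blocks = tuple(
            BlockSpec(
                condition=cond,
                onset=initial_rest + i * (block_duration + rest_duration),
                duration=block_duration,
                block_id=i,
            )
            for i, cond in enumerate(shuffled)
        )
        return cls(blocks=blocks, initial_rest=initial_rest, final_rest=final_rest)


def _harmonic(
    params: TrajectoryParams,
    shape: str,
    n: int,
    t_local: np.ndarray,
    phase: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free harmonic stroke components (x, y) in mm."""
    theta = 2.0 * math.pi * params.frequency * t_local + phase
    if shape == "line":
        y = params.amplitude * np.sin(theta)
        x = params.ovalization_ratio * params.amplitude * np.cos(theta)
    elif shape == "circle":
        y = params.amplitude * np.sin(theta)
        x = params.amplitude * np.cos(theta)
    else:
        raise ValueError(f"shape must be 'line' or 'circle', got {shape!r}")
    return x, y


def generate_stroke_series(
    params: TrajectoryParams,
    shape: str,
    duration: float,
    *,
    start_time: float = 0.0,
    phase: float = 0.0,
    hand: str = "R",
    block_id: int = 0,
    condition: str | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Generate one uniformly sampled stroke series.

    A line is vertical harmonic motion in y with lateral displacement
    ``alpha * amplitude * cos`` (the circular-phase x-component); a circle is
    uniform circular motion of radius ``amplitude``.  Isotropic Gaussian
    jitter of SD ``noise_sd`` is added to both axes.  The sample count is
    ``floor(duration * sampling_rate)``.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    n = int(math.floor(duration * params.sampling_rate))
    if n < 2:
        raise ValueError("duration too short for the sampling rate")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t_local = np.arange(n) / params.sampling_rate
    x, y = _harmonic(params, shape, n, t_local, phase)
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, n)
        y = y + rng.normal(0.0, params.noise_sd, n)
    if condition is None:
        condition = "L" if shape == "line" else "C"
    return Trajectory(
        time=start_time + t_local,
        x=x,
        y=y,
        hand=hand,
        block_id=block_id,
        condition=condition,
    )


#: Which hands draw, and what, in each condition.
_CONDITION_SHAPES: dict[str, dict[str, str]] = {
    "L": {"R": "line"},
    "C": {"L": "circle"},
    "LL": {"L": "line", "R": "line"},
    "CL": {"L": "circle", "R": "line"},
}


def generate_session(
    spec: SessionSpec,
    left_params: TrajectoryParams,
    right_params: TrajectoryParams,
    coupling: float = 0.0,
    *,
    phase_lag: float = 0.0,
    seed: int | None = None,
) -> SessionData:
    """Simulate a full two-hand session.

    In CL blocks the right-hand line receives additive lateral contamination
    equal to ``coupling`` times the left-hand circle's noise-free
    x-component, so the constructed right-hand ovalization excess in CL over
    LL is ~``100 * coupling`` OI points.  L, C and LL blocks are
    uncontaminated; rest periods contain no samples.

    Parameters
    ----------
    coupling : float
        Interference fraction in [0, 1]; 0 models the motor-neglect (MN+)
        phenotype, > 0 models controls / the MN- patient.
    phase_lag : float
        Optional phase offset (radians) of the left hand relative to the
        right in bimanual blocks, for modeling asynchronous hands; default 0
        (synchronous movement).
    seed : int or None
        Master seed for all jitter; overrides the per-hand params' seeds.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    params = {"L": left_params, "R": right_params}
    session: SessionData = {}
    for blk in spec.blocks:
        shapes = _CONDITION_SHAPES[blk.condition]
        n = int(math.floor(blk.duration * params["R"].sampling_rate))
        clean: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for hand, shape in shapes.items():
            p = params[hand]
            t_local = np.arange(n) / p.sampling_rate
            phase = phase_lag if hand == "L" else 0.0
            clean[hand] = _harmonic(p, shape, n, t_local, phase)
        if blk.condition == "CL" and coupling > 0:
            lx, _ = clean["L"]
            rx, ry = clean["R"]
            clean["R"] = (rx + coupling * lx, ry)
        for hand in sorted(shapes):
            p = params[hand]
            x, y = clean[hand]
            if p.noise_sd > 0:
                x = x + rng.normal(0.0, p.noise_sd, n)
                y = y + rng.normal(0.0, p.noise_sd, n)
            t_local = np.arange(n) / p.sampling_rate
            session[(blk.block_id, hand)] = Trajectory(
                time=blk.onset + t_local,
                x=x,
                y=y,
                hand=hand,
                block_id=blk.block_id,
                condition=blk.condition,
            )
    return session


@dataclass(frozen=True)
class CohortSpec:
    """Targets for a simulated normative cohort of bivariate task scores.

    Defaults are the published normative sample for the right-hand OI:
    n = 12 healthy participants, task x = LL (5.5 +/- 1.5), task y = CL
    (13.4 +/- 8.4), inter-task correlation r = 0.8.
    """

    n: int = 12
    mean_x: float = 5.5
    sd_x: float = 1.5
    mean_y: float = 13.4
    sd_y: float = 8.4
    r: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a control sample needs n >= 2")
        if not (self.sd_x > 0 and self.sd_y > 0):
            raise ValueError("SDs must be > 0")
        if not -1.0 < self.r < 1.0:
            raise ValueError("inter-task correlation must satisfy |r| < 1")


@dataclass(frozen=True)
class CohortResult:
    """Simulated cohort scores plus their realized sample summary."""

    scores: np.ndarray  # shape (n, 2): columns (x_score, y_score)
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    r: float
    n: int

    @property
    def diff_sd(self) -> float:
        """Realized sample SD of the per-subject y - x discrepancy."""
        return float(np.std(self.scores[:, 1] - self.scores[:, 0], ddof=1))


def generate_normative_cohort(spec: CohortSpec) -> CohortResult:
    """Draw n bivariate-normal (x, y) score pairs with the target moments.

    Population parameters equal the targets; the realized sample summary
    (means, ddof=1 SDs, Pearson r) is returned alongside the raw scores.
    """
    rng = np.random.default_rng(spec.seed)
    cov = np.array(
        [
            [spec.sd_x**2, spec.r * spec.sd_x * spec.sd_y],
            [spec.r * spec.sd_x * spec.sd_y, spec.sd_y**2],
        ]
    )
    scores = rng.multivariate_normal(
        [spec.mean_x, spec.mean_y], cov, size=spec.n, method="cholesky"
    )
    x, y = scores[:, 0], scores[:, 1]
    return CohortResult(
        scores=scores,
        mean_x=float(np.mean(x)),
        sd_x=float(np.std(x, ddof=1)),
        mean_y=float(np.mean(y)),
        sd_y=float(np.std(y, ddof=1)),
        r=float(np.corrcoef(x, y)[0, 1]),
        n=spec.n,
    )
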
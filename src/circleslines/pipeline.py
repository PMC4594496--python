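"""End-to-end study orchestration.

Runs the full Circles-Lines analysis: trajectories (real CSVs or synthetic
sessions) -> per-condition OI and drawing-frequency scores -> single-case
tests against a normative sample -> report tables mirroring the study's
behavioral and ROI results.  Imaging beta values enter as tabular fixtures;
no image processing happens here.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import metadata as _metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fixtures as _fixtures
from .metrics import condition_scores, coupling_effect, session_metrics
from .simulate import (
    CohortResult,
    CohortSpec,
    SessionSpec,
    TrajectoryParams,
    generate_normative_cohort,
    generate_session,
)
from .singlecase import CaseScores, NormativeSummary, case_comparison, rsdt
from .trajectory import SessionData, read_session_csv

try:
    _VERSION = _metadata.version("circleslines")
except _metadata.PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"

__all__ = [
    "MissingConditionError",
    "CaseInput",
    "RoiFixture",
    "StudyConfig",
    "BehavioralReport",
    "ReportBundle",
    "builtin_roi_fixtures",
    "paper_config",
    "demo_config",
    "simulate_case_scores",
    "run_behavioral_analysis",
    "run_roi_analysis",
    "end_to_end",
]

#: Line ovalization ratio whose noise-free OI matches the normative LL mean.
HEALTHY_LINE_ALPHA = 0.055
#: Coupling fraction matching the normative CL - LL effect (~7.9 OI points).
HEALTHY_COUPLING = 0.079

#: Printed MNI coordinates of the analyzed regions of interest.
KNOWN_ROIS: dict[str, tuple[int, int, int]] = {
    "pre-SMA": (4, -2, 52),
    "left PPC": (-37, -50, 33),
    "right PPC": (26, -44, 36),
}

REPORT_COLUMNS = [
    "section",
    "measure",
    "method",
    "contrast",
    "statistic",
    "df",
    "p_two_tailed",
    "inputs_digest",
]


class MissingConditionError(RuntimeError):
    """A case lacks scorable data for a required condition."""


def _digest(*parts: object) -> str:
    """Short stable digest of a test's inputs, for report provenance."""
    raw = repr(parts).encode()
    return hashlib.sha1(raw).hexdigest()[:12]


@dataclass
class CaseInput:
    """One single case: either direct scores or trajectories to score.

    ``scores`` holds (x = LL OI, y = CL OI); when absent, ``session`` (or
    ``trajectory_csv``) is scored with the metrics module.
    """

    label: str
    scores: CaseScores | None = None
    frequency: float | None = None
    session: SessionData | None = None
    trajectory_csv: Path | None = None

    def __post_init__(self) -> None:
        if self.scores is None and self.session is None and self.trajectory_csv is None:
            raise ValueError(f"case {self.label!r}: no scores and no trajectories")


@dataclass
class RoiFixture:
    """Per-ROI beta data: case scores and normative summary.

    MNI coordinates are metadata only and must match the printed triple for
    the named region.
    """

    name: str
    mni: tuple[int, int, int]
    normative: NormativeSummary
    cases: dict[str, CaseScores]
    diff_sd: float | None = None
    printed_diffs: dict[str, float] | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in KNOWN_ROIS:
            raise ValueError(
                f"unknown ROI {self.name!r}; known: {sorted(KNOWN_ROIS)}"
            )
        if tuple(self.mni) != KNOWN_ROIS[self.name]:
            raise ValueError(
                f"MNI coordinates {tuple(self.mni)} do not match the printed "
                f"triple {KNOWN_ROIS[self.name]} for {self.name}"
            )

    def diff(self, label: str) -> float:
        """CL - LL beta difference for a case (printed value when shipped)."""
        if self.printed_diffs and label in self.printed_diffs:
            return self.printed_diffs[label]
        cs = self.cases[label]
        return cs.y - cs.x


@dataclass
class StudyConfig:
    """Everything one analysis run needs.

    Exactly two cases (the two-case comparison is pairwise); the analyzed
    hand is the right (line-drawing) hand and the compared conditions are
    LL vs CL throughout.
    """

    cases: list[CaseInput]
    normative: NormativeSummary
    diff_sd: float | None = None
    printed_diffs: dict[str, float] | None = None
    freq_normative: tuple[float, float, int] | None = None  # (mean, sd, n)
    rois: list[RoiFixture] = field(default_factory=list)
    hand: str = "R"
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.cases) != 2:
            raise ValueError("exactly two case labels are required")
        labels = [c.label for c in self.cases]
        if len(set(labels)) != 2:
            raise ValueError("case labels must be distinct")


@dataclass
class BehavioralReport:
    """Behavioral analysis output: test rows, case scores, skip log."""

    tests: pd.DataFrame
    scores: pd.DataFrame
    skipped: list[str]


@dataclass
class ReportBundle:
    """Paths and tables written by a full end-to-end run."""

    out_dir: Path
    behavioral: BehavioralReport
    roi_tests: pd.DataFrame
    log_lines: list[str]


# ---------------------------------------------------------------------------
# config constructors


def _norm_from_dict(d: dict) -> NormativeSummary:
    return NormativeSummary(
        mean_x=d["mean_x"],
        sd_x=d["sd_x"],
        mean_y=d["mean_y"],
        sd_y=d["sd_y"],
        r=d["r"],
        n=d["n"],
    )


def builtin_roi_fixtures() -> list[RoiFixture]:
    """The three shipped ROI fixtures (pre-SMA, left PPC, right PPC)."""
    data = _fixtures.roi_fixture()
    out = []
    for roi in data["rois"]:
        out.append(
            RoiFixture(
                name=roi["name"],
                mni=tuple(roi["mni"]),
                normative=_norm_from_dict(roi["normative"]),
                cases={
                    lab: CaseScores(x=sc["x"], y=sc["y"])
                    for lab, sc in roi["cases"].items()
                },
                diff_sd=roi["normative"].get("diff_sd"),
                printed_diffs=roi.get("printed_diffs"),
                annotations=roi.get("annotations", {}),
            )
        )
    return out


def paper_config() -> StudyConfig:
    """The published worked example: both patients' printed scores."""
    beh = _fixtures.behavioral_fixture()
    oi = beh["oi"]
    freq = beh["frequency"]
    cases = [
        CaseInput(
            label=lab,
            scores=CaseScores(x=sc["x"], y=sc["y"]),
            frequency=freq["cases"][lab],
        )
        for lab, sc in oi["cases"].items()
    ]
    return StudyConfig(
        cases=cases,
        normative=_norm_from_dict(oi["normative"]),
        diff_sd=oi["normative"]["diff_sd"],
        printed_diffs=oi.get("printed_diffs"),
        freq_normative=(
            freq["normative"]["mean"],
            freq["normative"]["sd"],
            freq["normative"]["n"],
        ),
        rois=builtin_roi_fixtures(),
    )


def demo_config(seed: int = 0) -> StudyConfig:
    """All-synthetic demo: a simulated normative cohort and two simulated
    patients — one with the normal coupling fraction, one with none.

    The cohort is drawn at the score level with the published normative
    targets; the two cases are full simulated sessions scored through the
    metrics module.  ROI fixtures are the shipped printed betas.
    """
    ss = np.random.SeedSequence(seed)
    s_cohort, s_spec, s_a, s_b = [int(s) % (2**31) for s in ss.generate_state(4)]
    cohort = generate_normative_cohort(CohortSpec(seed=s_cohort))
    norm = NormativeSummary(
        mean_x=cohort.mean_x,
        sd_x=cohort.sd_x,
        mean_y=cohort.mean_y,
        sd_y=cohort.sd_y,
        r=cohort.r,
        n=cohort.n,
    )
    spec = SessionSpec.standard(seed=s_spec)
    line = TrajectoryParams(ovalization_ratio=HEALTHY_LINE_ALPHA)
    circle = TrajectoryParams()
    cases = [
        CaseInput(
            label="coupled",
            session=generate_session(spec, circle, line, HEALTHY_COUPLING, seed=s_a),
        ),
        CaseInput(
            label="uncoupled",
            session=generate_session(spec, circle, line, 0.0, seed=s_b),
        ),
    ]
    return StudyConfig(
        cases=cases,
        normative=norm,
        diff_sd=cohort.diff_sd,
        rois=builtin_roi_fixtures(),
        seed=seed,
    )


def simulate_case_scores(
    coupling: float,
    seed: int,
    line_alpha: float = HEALTHY_LINE_ALPHA,
    hand: str = "R",
) -> tuple[CaseScores, float]:
    """Simulate one patient's standard session and score it.

    Returns the (LL, CL) OI scores of the analyzed hand and the mean
    drawing frequency over its blocks.
    """
    spec = SessionSpec.standard(seed=seed)
    line = TrajectoryParams(ovalization_ratio=line_alpha)
    circle = TrajectoryParams()
    session = generate_session(spec, circle, line, coupling, seed=seed)
    table = session_metrics(session, hand=hand)
    cond = condition_scores(table).set_index("condition")
    scores = CaseScores(x=float(cond.loc["LL", "oi"]), y=float(cond.loc["CL", "oi"]))
    return scores, float(table["frequency_hz"].mean())


def from_yaml(path: str | Path) -> StudyConfig:
    """Load a study configuration from YAML.

    Cases carry either a ``scores: {ll, cl}`` mapping (plus optional
    ``frequency``) or a ``trajectories`` CSV path.  ``roi_fixtures`` may be
    ``builtin`` or a path to a JSON file with the same schema as the
    shipped one.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cases = []
    for c in raw["cases"]:
        scores = None
        if "scores" in c:
            scores = CaseScores(x=c["scores"]["ll"], y=c["scores"]["cl"])
        csv = c.get("trajectories")
        if csv is not None:
            csv = (path.parent / csv).resolve()
            if not csv.exists():
                raise FileNotFoundError(f"trajectory file not found: {csv}")
        cases.append(
            CaseInput(
                label=c["label"],
                scores=scores,
                frequency=c.get("frequency"),
                trajectory_csv=csv,
            )
        )
    nd = raw["normative"]
    norm = NormativeSummary(
        mean_x=nd["mean_ll"],
        sd_x=nd["sd_ll"],
        mean_y=nd["mean_cl"],
        sd_y=nd["sd_cl"],
        r=nd["r"],
        n=nd["n"],
    )
    freq_norm = None
    if "frequency_normative" in raw:
        f = raw["frequency_normative"]
        freq_norm = (f["mean"], f["sd"], f["n"])
    rois: list[RoiFixture] = []
    roi_src = raw.get("roi_fixtures")
    if roi_src == "builtin":
        rois = builtin_roi_fixtures()
    return StudyConfig(
        cases=cases,
        normative=norm,
        diff_sd=nd.get("diff_sd"),
        freq_normative=freq_norm,
        rois=rois,
        hand=raw.get("hand", "R"),
        seed=raw.get("seed"),
    )


# ---------------------------------------------------------------------------
# analyses


def _resolve_case(
    case: CaseInput, hand: str, skipped: list[str]
) -> tuple[CaseScores, float | None]:
    """Score a case: pass through direct scores or run the metrics module."""
    if case.scores is not None:
        return case.scores, case.frequency
    session = case.session
    if session is None:
        session = read_session_csv(case.trajectory_csv)
    table = session_metrics(session, hand=hand)
    for cond in ("LL", "CL"):
        if cond not in set(table["condition"]):
            raise MissingConditionError(
                f"case {case.label!r}: no scorable {cond} block for hand {hand}"
            )
    n_blocks = sum(1 for (_, h) in session if h == hand)
    if len(table) < n_blocks:
        skipped.append(
            f"case {case.label}: {n_blocks - len(table)} block(s) without a "
            f"complete cycle were skipped"
        )
    cond = condition_scores(table).set_index("condition")
    scores = CaseScores(x=float(cond.loc["LL", "oi"]), y=float(cond.loc["CL", "oi"]))
    return scores, float(table["frequency_hz"].mean())


def run_behavioral_analysis(config: StudyConfig) -> BehavioralReport:
    """Score both cases and run the behavioral single-case tests.

    Emits one row per test: an RSDT of the LL-vs-CL OI discrepancy for each
    case against the normative sample, a two-case comparison of the CL - LL
    OI differences, and — when a normative frequency summary is available —
    a two-case comparison of the drawing frequencies.
    """
    skipped: list[str] = []
    resolved: list[tuple[str, CaseScores, float | None]] = []
    for case in config.cases:
        scores, freq = _resolve_case(case, config.hand, skipped)
        resolved.append((case.label, scores, freq))

    score_rows = []
    test_rows = []
    diffs: dict[str, float] = {}
    for label, scores, freq in resolved:
        diff = coupling_effect(scores.y, scores.x)
        if config.printed_diffs and label in config.printed_diffs:
            diffs[label] = config.printed_diffs[label]
        else:
            diffs[label] = diff
        score_rows.append(
            {
                "case": label,
                "oi_ll": scores.x,
                "oi_cl": scores.y,
                "cl_minus_ll": diff,
                "frequency_hz": freq,
            }
        )
        res = rsdt(scores, config.normative)
        test_rows.append(
            {
                "section": "behavioral",
                "measure": "OI LL-vs-CL",
                "method": res.method,
                "contrast": f"{label} vs controls",
                "statistic": res.statistic,
                "df": res.df,
                "p_two_tailed": res.p_two_tailed,
                "inputs_digest": _digest(scores, config.normative),
            }
        )

    (lab1, _, f1), (lab2, _, f2) = resolved
    sd_diff = config.diff_sd
    if sd_diff is None:
        sd_diff = config.normative.discrepancy_sd
    res = case_comparison(diffs[lab1], diffs[lab2], sd_diff, config.normative.n)
    test_rows.append(
        {
            "section": "behavioral",
            "measure": "OI CL-LL difference",
            "method": res.method,
            "contrast": f"{lab1} vs {lab2}",
            "statistic": res.statistic,
            "df": res.df,
            "p_two_tailed": res.p_two_tailed,
            "inputs_digest": _digest(diffs[lab1], diffs[lab2], sd_diff),
        }
    )
    if config.freq_normative is not None and f1 is not None and f2 is not None:
        _, f_sd, f_n = config.freq_normative
        res = case_comparison(f1, f2, f_sd, f_n)
        test_rows.append(
            {
                "section": "behavioral",
                "measure": "drawing frequency",
                "method": res.method,
                "contrast": f"{lab1} vs {lab2}",
                "statistic": res.statistic,
                "df": res.df,
                "p_two_tailed": res.p_two_tailed,
                "inputs_digest": _digest(f1, f2, f_sd, f_n),
            }
        )
    elif config.freq_normative is None:
        skipped.append("frequency comparison skipped: no normative frequency summary")

    return BehavioralReport(
        tests=pd.DataFrame(test_rows, columns=REPORT_COLUMNS),
        scores=pd.DataFrame(score_rows),
        skipped=skipped,
    )


def run_roi_analysis(rois: list[RoiFixture]) -> pd.DataFrame:
    """Single-case tests on per-ROI beta values.

    Per ROI: an RSDT of the LL-vs-CL beta discrepancy for each case against
    the normative beta summary, plus a two-case comparison of the CL - LL
    beta differences.  Same report schema as the behavioral analysis.
    """
    rows = []
    for roi in rois:
        labels = list(roi.cases)
        for label in labels:
            res = rsdt(roi.cases[label], roi.normative)
            rows.append(
                {
                    "section": "roi",
                    "measure": f"beta {roi.name}",
                    "method": res.method,
                    "contrast": f"{label} vs controls",
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_two_tailed": res.p_two_tailed,
                    "inputs_digest": _digest(roi.cases[label], roi.normative),
                }
            )
        if len(labels) == 2:
            d1, d2 = roi.diff(labels[0]), roi.diff(labels[1])
            sd = roi.diff_sd if roi.diff_sd is not None else roi.normative.discrepancy_sd
            res = case_comparison(d1, d2, sd, roi.normative.n)
            rows.append(
                {
                    "section": "roi",
                    "measure": f"beta {roi.name} CL-LL difference",
                    "method": res.method,
                    "contrast": f"{labels[0]} vs {labels[1]}",
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_two_tailed": res.p_two_tailed,
                    "inputs_digest": _digest(d1, d2, sd),
                }
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def end_to_end(config: StudyConfig, out_dir: str | Path) -> ReportBundle:
    """Run the whole analysis and write a versioned report directory.

    Writes ``case_scores.tsv``, ``behavioral_tests.tsv``, ``roi_tests.tsv``
    and ``run_log.txt``.  Output is byte-identical across reruns with the
    same configuration and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "behavioral analysis"
    try:
        beh = run_behavioral_analysis(config)
        stage = "roi analysis"
        roi_tests = run_roi_analysis(config.rois)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    fmt = "%.6g"
    beh.scores.to_csv(out_dir / "case_scores.tsv", sep="\t", index=False, float_format=fmt)
    beh.tests.to_csv(
        out_dir / "behavioral_tests.tsv", sep="\t", index=False, float_format=fmt
    )
    roi_tests.to_csv(out_dir / "roi_tests.tsv", sep="\t", index=False, float_format=fmt)

    n = config.normative
    log_lines = [
        f"circleslines version: {_VERSION}",
        f"seed: {config.seed}",
        f"analyzed hand: {config.hand}",
        f"conditions compared: LL vs CL",
        (
            "normative summary: "
            f"LL {n.mean_x:.4g} +/- {n.sd_x:.4g}, CL {n.mean_y:.4g} +/- "
            f"{n.sd_y:.4g}, r {n.r:.4g}, n {n.n}"
        ),
        f"difference SD used for case comparison: "
        f"{(config.diff_sd if config.diff_sd is not None else n.discrepancy_sd):.4g}",
        f"cases: {', '.join(c.label for c in config.cases)}",
        f"behavioral test rows: {len(beh.tests)}",
        f"roi test rows: {len(roi_tests)}",
        "tolerance policy: statistics recomputed from printed rounded inputs "
        "are compared at +/-0.2 (RSDT) and +/-0.05 (case comparison)",
    ]
    for msg in beh.skipped:
        log_lines.append(f"skipped: {msg}")
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return ReportBundle(
        out_dir=out_dir, behavioral=beh, roi_tests=roi_tests, log_lines=log_lines
    )
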
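"""Published worked-example data shipped with the package.

These JSON files carry the study's printed normative summaries, patient
scores and test statistics.  The raw patient trajectories were never
released, so the score-level values here are the only real data the
analyses can be exercised on; everything else is simulated.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any


def _load(name: str) -> dict[str, Any]:
    with resources.files(__package__).joinpath(name).open("r") as fh:
        return json.load(fh)


def behavioral_fixture() -> dict[str, Any]:
    """Printed behavioral results: OI and frequency scores plus normative summary."""
    return _load("behavioral.json")


def roi_fixture() -> dict[str, Any]:
    """Printed ROI beta summaries for pre-SMA, left PPC and right PPC."""
    return _load("roi.json")
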
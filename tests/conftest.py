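"""Shared fixtures: reference trial summaries and synthetic series builders."""
from __future__ import annotations

import numpy as np
import pytest

from ttmloop.trial import TrialSeries, make_series

# Published summary counts for the two automated reference trials (A1, A2):
# total accounted seconds, seconds outside the +/-0.5 and +/-1.0 degC bands
# around the 38.0 degC target, and recorded setting-change counts.  The raw
# second-by-second recordings are not deposited here; series with exactly
# these counts are reconstructed synthetically for metric validation.
REFERENCE_TRIALS = {
    "A1": {
        "total_s": 330960,
        "outside_half_s": 5883,
        "outside_one_s": 0,
        "within_half_pct": 98.22,
        "within_one_pct": 100.00,
        "n_changes": 443,
        "changes_per_hour": 4.82,
    },
    "A2": {
        "total_s": 329270,
        "outside_half_s": 73330,
        "outside_one_s": 0,
        "within_half_pct": 77.73,
        "within_one_pct": 100.00,
        "n_changes": 215,
        "changes_per_hour": 2.35,
    },
}

TARGET = 38.0


def reference_series(
    total_s: int, outside_half_s: int, n_changes: int, label: str
) -> TrialSeries:
    """Synthetic stand-in series with exactly the given outside-band seconds
    (outside +/-0.5 but inside +/-1.0) and setting-change count."""
    temps = np.full(total_s, TARGET)
    temps[:outside_half_s] = TARGET + 0.75  # outside 0.5, inside 1.0
    block = total_s // (n_changes + 1)
    block_id = np.minimum(np.arange(total_s) // block, n_changes)
    heats = np.where(block_id % 2 == 0, "32", "38")
    return make_series(
        np.arange(total_s), temps, list(heats), ["slow"] * total_s,
        metadata={"label": label, "target_temp": TARGET},
    )


@pytest.fixture(scope="session")
def a1_series() -> TrialSeries:
    ref = REFERENCE_TRIALS["A1"]
    return reference_series(ref["total_s"], ref["outside_half_s"], ref["n_changes"], "A1")


@pytest.fixture(scope="session")
def a2_series() -> TrialSeries:
    ref = REFERENCE_TRIALS["A2"]
    return reference_series(ref["total_s"], ref["outside_half_s"], ref["n_changes"], "A2")
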
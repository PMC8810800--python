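"""Shared fixtures: pre-paced states and calibrations are expensive, so
they are computed once per session and shared across the suite.

Test-scale protocol: pre-pacing uses a reduced beat budget (15 beats,
0.05 %/beat criterion) -- enough for stable AP metrics and conduction
behavior, far from the production 0.001 %/beat criterion.
"""

import numpy as np
import pytest

from bacnavsim.calibration import calibrate_1x
from bacnavsim.cell import build_cell, pace_to_equilibrium, simulate_ap

PREPACE_BEATS = 15
PREPACE_PCT = 0.05


@pytest.fixture(scope="session")
def human_calibration():
    cell = build_cell("human")
    return calibrate_1x(cell)


@pytest.fixture(scope="session")
def human_gbar_1x(human_calibration):
    return human_calibration.gbar_1x


@pytest.fixture(scope="session")
def human_eq_state():
    """Human cell state after reduced-budget 1 Hz pre-pacing (no BacNav)."""
    cell = build_cell("human")
    pace_to_equilibrium(cell, criterion_pct=PREPACE_PCT,
                        max_beats=PREPACE_BEATS)
    return cell.state.copy()


@pytest.fixture(scope="session")
def human_dose_series(human_gbar_1x):
    """x_level -> (TraceResult, state) for the paced human cell."""
    out = {}
    for x in (0.0, 0.5, 1.0, 2.0):
        cell = build_cell("human", x_level=x,
                          gbar_1x=human_gbar_1x if x else None)
        pace_to_equilibrium(cell, criterion_pct=PREPACE_PCT,
                            max_beats=PREPACE_BEATS)
        out[x] = (simulate_ap(cell), cell.state.copy())
    return out
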
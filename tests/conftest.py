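"""Shared fixtures.

Expensive simulation products (dose sweeps, reference trajectories) are
session-scoped so independent tests can reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

import thyroblock as tb
from thyroblock.analysis import dose_response
from thyroblock.dosimetry import total_dose
from thyroblock.kinetics import ExposureScenario, simulate
from thyroblock.parameters import load_parameters

REFERENCE_ACTIVITY_BQ = 700_000.0


@pytest.fixture(scope="session")
def params_week0():
    return load_parameters(0)


@pytest.fixture(scope="session")
def traj_week0_unblocked():
    """700 kBq at week 0, no stable iodine."""
    return simulate(
        ExposureScenario(week=0, activity_bq=REFERENCE_ACTIVITY_BQ)
    )


@pytest.fixture(scope="session")
def traj_week0_blocked_100mg():
    """700 kBq + 100 mg stable iodine at week 0, Wolff-Chaikoff on."""
    return simulate(
        ExposureScenario(
            week=0, activity_bq=REFERENCE_ACTIVITY_BQ, stable_dose_mg=100.0
        )
    )


@pytest.fixture(scope="session")
def sweep_week0_with_wc():
    """Full 25-point stable-iodine sweep, maternal gland, WC enabled."""
    return dose_response(0, REFERENCE_ACTIVITY_BQ, wc_enabled=True)


@pytest.fixture(scope="session")
def sweep_week12_fetal_no_wc():
    """Full 25-point sweep of the fetal gland at week 12, competition only."""
    return dose_response(
        12, REFERENCE_ACTIVITY_BQ, wc_enabled=False, gland="fetal"
    )


@pytest.fixture(scope="session")
def dose_week0_unblocked(traj_week0_unblocked):
    return total_dose(traj_week0_unblocked)
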
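"""Shared fixtures: synthetic study conditions used across the suite.

Heavy traces (staged uptake, multi-rate TG/DSC sets) are session-scoped so
each is generated once.
"""

from __future__ import annotations

import numpy as np
import pytest

from cdsorb import (DehydrationParams, SorptionModelParams, generate_dsc,
                    generate_isotherm, generate_staged_uptake, generate_tg)

STUDY_TEMPERATURES = (283.0, 298.0, 313.0)
HEATING_RATES = (5.0, 10.0, 15.0, 20.0)


@pytest.fixture(scope="session")
def sorption_params() -> SorptionModelParams:
    return SorptionModelParams()


@pytest.fixture(scope="session")
def dehydration_params() -> DehydrationParams:
    return DehydrationParams()


@pytest.fixture(scope="session")
def rh_grid() -> np.ndarray:
    return np.round(np.arange(0.05, 0.951, 0.05), 10)


@pytest.fixture(scope="session")
def adsorption_isotherms(sorption_params, rh_grid):
    """Noiseless adsorption branches at the three study temperatures."""
    return [generate_isotherm(sorption_params, T, rh_grid)
            for T in STUDY_TEMPERATURES]


@pytest.fixture(scope="session")
def thermogram_set(dehydration_params):
    """Noiseless TG ramps at the four study heating rates."""
    return [generate_tg(dehydration_params, beta) for beta in HEATING_RATES]


@pytest.fixture(scope="session")
def dsc_set(dehydration_params, thermogram_set):
    """Noiseless DSC traces coupled to the TG ramps."""
    return [generate_dsc(dehydration_params, tg) for tg in thermogram_set]


@pytest.fixture(scope="session")
def uptake_trace_283(sorption_params):
    """Noiseless staged uptake at 283 K over the 10-60% RH window."""
    return generate_staged_uptake(1.1e-4, sorption_params, 283.0,
                                  np.round(np.arange(0.1, 0.61, 0.1), 10))
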
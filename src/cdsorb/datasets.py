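"""Bundled reference measurements for water–β-cyclodextrin sorption.

Small published-style summary tables used in examples and validation: stage
rate constants of water uptake at three temperatures, window-mean uptake
rates with their pressure driving forces, and a multi-heating-rate
isoconversional dehydration table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "uptake_rate_constants",
    "uptake_window_rates",
    "dehydration_isoconversional_table",
]


def uptake_rate_constants() -> pd.DataFrame:
    """Apparent water-uptake rate constants vs adsorption temperature.

    Columns: ``T_K`` (K) and ``k`` (mmol min⁻¹ Pa⁻¹).  The constants fall
    with temperature (anti-Arrhenius), giving an apparent activation energy
    of 7.4 kJ mol⁻¹ under the magnitude convention.
    """
    return pd.DataFrame({
        "T_K": [283.0, 298.0, 313.0],
        "k": [10.64e-5, 9.12e-5, 7.88e-5],
    })


def uptake_window_rates() -> pd.DataFrame:
    """Window-mean uptake rates over the 10–60% RH range.

    Columns: ``T_K``, ``mean_rate`` (mmol min⁻¹) and ``driving_force`` (Pa,
    one 10% RH step at that temperature).
    """
    return pd.DataFrame({
        "T_K": [283.0, 298.0, 313.0],
        "mean_rate": [1.35e-2, 3.25e-2, 4.68e-2],
        "driving_force": [122.8, 316.9, 738.1],
    })


# (alpha, T at beta=5,10,15,20 K/min, dalpha/dt [1e-3 /s] at the same betas)
_FRIEDMAN_ROWS = [
    (0.1, (329.3, 336.5, 350.0, 348.3), (0.5, 0.9, 1.4, 1.7)),
    (0.2, (340.9, 350.5, 363.0, 363.0), (1.0, 1.5, 2.6, 3.6)),
    (0.3, (347.6, 359.5, 370.5, 371.7), (1.4, 2.4, 3.7, 4.6)),
    (0.4, (352.6, 365.5, 376.5, 377.7), (1.8, 3.1, 4.8, 5.8)),
    (0.5, (356.8, 370.0, 381.5, 383.0), (2.2, 3.8, 5.7, 7.0)),
    (0.6, (360.5, 374.5, 385.5, 387.7), (2.6, 4.3, 6.3, 7.7)),
    (0.7, (363.4, 378.0, 389.5, 391.7), (2.7, 4.5, 6.5, 7.8)),
    (0.8, (366.8, 382.0, 393.5, 396.3), (2.6, 4.2, 5.8, 7.0)),
    (0.9, (370.9, 386.5, 398.5, 402.3), (1.7, 3.0, 3.8, 4.4)),
]

_BETAS = (5.0, 10.0, 15.0, 20.0)


def dehydration_isoconversional_table() -> pd.DataFrame:
    """Isoconversional dehydration table at four heating rates (long form).

    Columns: ``alpha``, ``beta`` (K min⁻¹), ``T_K`` (K) and ``rate_per_s``
    (dα/dt, s⁻¹; the tabulated values are in units of 10⁻³ s⁻¹ and are
    rescaled here — the Friedman slope is invariant to that scale).
    """
    rows = []
    for alpha, Ts, rates in _FRIEDMAN_ROWS:
        for beta, T, r in zip(_BETAS, Ts, rates):
            rows.append({"alpha": alpha, "beta": beta, "T_K": T,
                         "rate_per_s": r * 1e-3})
    return pd.DataFrame(rows)
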
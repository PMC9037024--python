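"""Staged water-uptake kinetics: initial rates, stage rate constants, Arrhenius fit.

A dynamic vapor sorption (DVS) experiment steps the relative humidity through
a staircase of set points at fixed temperature.  Within stage *i* at constant
vapor pressure ``P_i`` the uptake obeys

    dq/dt = k_i * P_i * (1 - P_i(q) / P_i)

where ``P_i(q)`` is the equilibrium pressure at the current loading.  Right
after the humidity step ``P_i(q)`` still sits near the previous set point
``P_{i-1}``, so the initial slope of ``q(t)`` is ``k_i * (P_i - P_{i-1})``:
dividing the initial rate by the driving force ``P_i - P_{i-1}`` yields the
stage rate constant, and the temperature dependence of those constants gives
the apparent activation energy of adsorption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CONSTANTS, Constants, KineticFit, kinetic_fit, saturation_pressure, warn

__all__ = [
    "UptakeTrace",
    "StageRate",
    "WindowSummary",
    "initial_rate",
    "stage_rate_constants",
    "ArrheniusModel",
    "arrhenius_fit",
]


@dataclass(frozen=True)
class UptakeTrace:
    """Time-resolved adsorbed amount under a staged humidity program.

    Attributes
    ----------
    T : float
        Adsorption temperature, K.
    times : ndarray
        Minutes, strictly increasing.
    loadings : ndarray
        Adsorbed amount (mmol g⁻¹, or mmol absolute for a known sample mass —
        the unit cancels in the activation energy).
    stage_boundaries : ndarray of int
        Index of the first sample of each stage; starts with 0.
    stage_pressures : ndarray
        Constant vapor pressure of each stage, Pa, strictly increasing.
    initial_pressure : float
        Pressure the sample was equilibrated at before stage 0 (0 for a dry
        start), Pa.
    """

    T: float
    times: np.ndarray
    loadings: np.ndarray
    stage_boundaries: np.ndarray
    stage_pressures: np.ndarray
    initial_pressure: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        q = np.asarray(self.loadings, dtype=float)
        b = np.asarray(self.stage_boundaries, dtype=int)
        p = np.asarray(self.stage_pressures, dtype=float)
        for name, arr in (("times", t), ("loadings", q),
                          ("stage_boundaries", b), ("stage_pressures", p)):
            object.__setattr__(self, name, arr)
        if t.shape != q.shape or t.ndim != 1:
            raise ValueError("times and loadings must be equal-length 1-D")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if b.size != p.size:
            raise ValueError("one stage pressure per stage boundary")
        if b.size == 0 or b[0] != 0 or not np.all(np.diff(b) > 0) or b[-1] >= t.size:
            raise ValueError("stage_boundaries must start at 0, increase, and index the trace")
        if not np.all(np.diff(p) > 0):
            raise ValueError("stage_pressures must be strictly increasing")
        if self.initial_pressure >= p[0]:
            raise ValueError("initial_pressure must lie below the first stage pressure")

    @property
    def n_stages(self) -> int:
        return int(self.stage_boundaries.size)

    def stage_slice(self, stage: int) -> slice:
        """Index slice of the samples belonging to ``stage``."""
        if not 0 <= stage < self.n_stages:
            raise IndexError(f"stage {stage} out of range [0, {self.n_stages})")
        start = int(self.stage_boundaries[stage])
        stop = int(self.stage_boundaries[stage + 1]) if stage + 1 < self.n_stages else self.times.size
        return slice(start, stop)

    def driving_force(self, stage: int) -> float:
        """Pressure step driving stage ``stage``: P_i − P_{i−1}, Pa."""
        prev = self.initial_pressure if stage == 0 else float(self.stage_pressures[stage - 1])
        return float(self.stage_pressures[stage]) - prev

    def stage_rh(self, stage: int) -> float:
        """Relative humidity of the stage set point, fraction."""
        return float(self.stage_pressures[stage]) / saturation_pressure(self.T)


@dataclass(frozen=True)
class StageRate:
    """Initial-rate analysis of one humidity stage."""

    stage_index: int
    rate: float            # mmol min⁻¹ (loading units per minute)
    driving_force: float   # Pa
    k: float               # rate / driving_force, mmol min⁻¹ Pa⁻¹
    r_squared: float

    def __post_init__(self) -> None:
        if self.driving_force <= 0:
            raise ValueError("driving_force must be positive")
        if not np.isclose(self.k, self.rate / self.driving_force, rtol=1e-9, atol=0.0):
            raise ValueError("k inconsistent with rate / driving_force")


@dataclass(frozen=True)
class WindowSummary:
    """Aggregate over the stages inside a humidity window.

    ``k_mean`` divides the window-mean rate by the window-mean driving force
    (the aggregation used when a single rate constant is quoted for a humidity
    range); the per-stage constants are available in the accompanying list.
    """

    mean_rate: float
    mean_driving_force: float
    k_mean: float
    n_stages: int


def initial_rate(trace: UptakeTrace, stage: int, n_points: int = 10) -> StageRate:
    """Initial uptake rate of a stage from the slope over its first samples.

    Ordinary least squares of loading against time over the first ``n_points``
    samples of the stage (the "initial rate method").  A negative fitted slope
    is returned as-is with a warning.
    """
    sl = trace.stage_slice(stage)
    n_avail = sl.stop - sl.start
    if n_avail < n_points:
        raise ValueError(f"stage {stage} has {n_avail} samples < n_points={n_points}")
    t = trace.times[sl][:n_points]
    q = trace.loadings[sl][:n_points]
    if np.allclose(q, q[0]):
        slope, r2 = 0.0, 1.0
    else:
        res = stats.linregress(t, q)
        slope, r2 = float(res.slope), float(res.rvalue) ** 2
    if slope < 0:
        warn(f"stage {stage}: negative initial slope {slope:.3g} mmol/min")
    df = trace.driving_force(stage)
    return StageRate(stage_index=stage, rate=slope, driving_force=df,
                     k=slope / df, r_squared=r2)


def stage_rate_constants(
    trace: UptakeTrace,
    rh_window: tuple[float, float] = (0.10, 0.60),
    n_points: int = 10,
) -> tuple[list[StageRate], WindowSummary]:
    """Per-stage rate constants for the stages inside a humidity window.

    Parameters
    ----------
    trace : UptakeTrace
    rh_window : (lo, hi)
        Stages whose set-point RH lies in [lo, hi] (inclusive, small
        tolerance) are analyzed; low-humidity stages are the stable ones.
    n_points : int
        Samples for each initial-rate fit.

    Returns
    -------
    (rates, summary)
        ``rates`` is one :class:`StageRate` per selected stage; ``summary``
        aggregates the window (mean rate / mean driving force).
    """
    lo, hi = rh_window
    selected = [i for i in range(trace.n_stages) if lo - 1e-9 <= trace.stage_rh(i) <= hi + 1e-9]
    if not selected:
        raise ValueError(f"no stages inside RH window [{lo}, {hi}]")
    rates = [initial_rate(trace, i, n_points=n_points) for i in selected]
    mean_rate = float(np.mean([r.rate for r in rates]))
    mean_df = float(np.mean([r.driving_force for r in rates]))
    summary = WindowSummary(mean_rate=mean_rate, mean_driving_force=mean_df,
                            k_mean=mean_rate / mean_df, n_stages=len(rates))
    return rates, summary


class ArrheniusModel:
    """Arrhenius regression of rate constants against temperature.

    ``ln k = ln A − Ea / (R T)`` fitted by unweighted OLS of ln k on 1/T.
    The activation energy is reported as ``|slope| * R`` so that
    anti-Arrhenius data (k falling with T, as water uptake on β-cyclodextrin
    does) yields the positive apparent activation energy convention; the
    signed slope is kept on the results object.

    Parameters
    ----------
    temperatures : array-like
        Distinct absolute temperatures, K.
    rate_constants : array-like
        Strictly positive rate constants (any consistent unit).

    Examples
    --------
    >>> m = ArrheniusModel([283, 298, 313], [10.64e-5, 9.12e-5, 7.88e-5])
    >>> fit = m.fit()
    >>> round(fit.activation_energy, 1)
    7.4
    """

    def __init__(self, temperatures, rate_constants, constants: Constants = CONSTANTS):
        self.temperatures = np.asarray(temperatures, dtype=float)
        self.rate_constants = np.asarray(rate_constants, dtype=float)
        self.constants = constants
        if self.temperatures.shape != self.rate_constants.shape:
            raise ValueError("temperatures and rate_constants must align")
        if np.any(self.rate_constants <= 0):
            raise ValueError("rate constants must be strictly positive")

    def fit(self) -> KineticFit:
        return kinetic_fit(self.temperatures, self.rate_constants, constants=self.constants)


def arrhenius_fit(k_values, temperatures, constants: Constants = CONSTANTS) -> KineticFit:
    """Functional form of :class:`ArrheniusModel` (k first, then T)."""
    return ArrheniusModel(temperatures, k_values, constants=constants).fit()
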
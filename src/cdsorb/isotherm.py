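"""Isosteric heat of adsorption and hysteresis from multi-temperature isotherms.

At fixed loading q the Clausius–Clapeyron relation gives the isosteric heat

    Q(q) = -R * d(ln P) / d(1/T) |_q

so fitting ln P against 1/T across isotherms measured at two or more
temperatures yields Q at each point of a loading grid.  Q is reported
positive for exothermic adsorption (equilibrium pressure rising with
temperature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CONSTANTS, Constants, Isotherm, saturation_pressure, warn

__all__ = [
    "pressure_at_loading",
    "IsostericHeatModel",
    "IsostericHeatResults",
    "isosteric_heat",
    "HysteresisGap",
    "hysteresis_gap",
]


def pressure_at_loading(iso: Isotherm, q: float) -> float:
    """Equilibrium pressure at loading ``q`` by ln(P)-linear interpolation.

    Interpolates ln P piecewise-linearly against loading (standard DVS
    practice), exact at the measured points.  No extrapolation: ``q`` must
    lie within the measured loading range.
    """
    s = iso.sorted_by_loading()
    qs, ps = s.loadings, s.pressures
    if not (qs[0] <= q <= qs[-1]):
        raise ValueError(f"loading {q} outside measured range [{qs[0]:.4g}, {qs[-1]:.4g}]")
    if np.any(np.diff(qs) <= 0):
        raise ValueError("loadings must be strictly increasing for interpolation")
    return float(np.exp(np.interp(q, qs, np.log(ps))))


@dataclass(frozen=True)
class IsostericHeatResults:
    """Isosteric heat along a loading grid.

    Attributes
    ----------
    loadings : ndarray
        mmol g⁻¹, strictly increasing.
    heats : ndarray
        kJ mol⁻¹, positive for exothermic adsorption.
    r_squared : ndarray
        Per-point goodness of the ln P vs 1/T fit (1.0 at two temperatures).
    n_temperatures : int
    """

    loadings: np.ndarray
    heats: np.ndarray
    r_squared: np.ndarray
    n_temperatures: int

    def __post_init__(self) -> None:
        q = np.asarray(self.loadings, dtype=float)
        h = np.asarray(self.heats, dtype=float)
        r = np.asarray(self.r_squared, dtype=float)
        object.__setattr__(self, "loadings", q)
        object.__setattr__(self, "heats", h)
        object.__setattr__(self, "r_squared", r)
        if not np.all(np.diff(q) > 0):
            raise ValueError("loading grid must be strictly increasing")
        if not np.all(np.isfinite(h)):
            raise ValueError("heats must be finite")
        if self.n_temperatures < 2:
            raise ValueError("need at least two temperatures")

    def summary(self) -> str:
        return "\n".join([
            "Isosteric heat of adsorption (Clausius-Clapeyron)",
            "-------------------------------------------------",
            f"temperatures used : {self.n_temperatures}",
            f"loading grid      : {self.loadings[0]:.3g} - {self.loadings[-1]:.3g} mmol/g "
            f"({self.loadings.size} points)",
            f"Q range           : {self.heats.min():.1f} - {self.heats.max():.1f} kJ/mol",
            f"Q mean            : {self.heats.mean():.1f} kJ/mol",
        ])

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loadings, self.heats, "o-")
        ax.set_xlabel("loading (mmol/g)")
        ax.set_ylabel("isosteric heat (kJ/mol)")
        return ax


class IsostericHeatModel:
    """Clausius–Clapeyron isosteric heat from isotherms at several temperatures.

    Parameters
    ----------
    isotherms : sequence of Isotherm
        Two or more, same branch, distinct temperatures.
    q_grid : array-like, optional
        Loading grid; default 20 evenly spaced points over the common
        loading range, endpoints excluded.
    """

    def __init__(self, isotherms, q_grid=None, constants: Constants = CONSTANTS):
        isotherms = list(isotherms)
        if len(isotherms) < 2:
            raise ValueError("need at least two isotherms")
        branches = {iso.branch for iso in isotherms}
        if len(branches) != 1:
            raise ValueError("all isotherms must be the same branch")
        temps = [iso.T for iso in isotherms]
        if len(set(temps)) != len(temps):
            raise ValueError("isotherm temperatures must be distinct")
        self.isotherms = sorted(isotherms, key=lambda iso: iso.T)
        self.constants = constants
        if q_grid is None:
            lo = max(float(iso.loadings.min()) for iso in self.isotherms)
            hi = min(float(iso.loadings.max()) for iso in self.isotherms)
            if hi <= lo:
                raise ValueError("isotherms share no common loading range")
            q_grid = np.linspace(lo, hi, 22)[1:-1]
        self.q_grid = np.asarray(q_grid, dtype=float)

    def fit(self) -> IsostericHeatResults:
        R = self.constants.R
        loadings, heats, r2s = [], [], []
        for q in self.q_grid:
            invT, lnP = [], []
            for iso in self.isotherms:
                try:
                    p = pressure_at_loading(iso, q)
                except ValueError:
                    continue
                invT.append(1.0 / iso.T)
                lnP.append(np.log(p))
            if len(invT) < 2:
                warn(f"isosteric heat: q={q:.4g} mmol/g covered by fewer than 2 "
                     "temperatures; grid point dropped")
                continue
            res = stats.linregress(invT, lnP)
            loadings.append(q)
            heats.append(-float(res.slope) * R / 1000.0)
            r2s.append(1.0 if len(invT) == 2 else float(res.rvalue) ** 2)
        if not loadings:
            raise ValueError("no loading grid point was covered by two temperatures")
        return IsostericHeatResults(
            loadings=np.array(loadings),
            heats=np.array(heats),
            r_squared=np.array(r2s),
            n_temperatures=len(self.isotherms),
        )


def isosteric_heat(isotherms, q_grid=None, constants: Constants = CONSTANTS) -> IsostericHeatResults:
    """Functional wrapper around :class:`IsostericHeatModel`."""
    return IsostericHeatModel(isotherms, q_grid=q_grid, constants=constants).fit()


@dataclass(frozen=True)
class HysteresisGap:
    """Loading gap between desorption and adsorption branches vs RH."""

    rh: np.ndarray
    gap: np.ndarray   # q_des - q_ads, mmol/g
    area: float       # trapezoidal integral of gap over rh

    def __post_init__(self) -> None:
        object.__setattr__(self, "rh", np.asarray(self.rh, dtype=float))
        object.__setattr__(self, "gap", np.asarray(self.gap, dtype=float))


def hysteresis_gap(ads: Isotherm, des: Isotherm, rh_grid=None) -> HysteresisGap:
    """Quantify the sorption hysteresis loop at one temperature.

    Interpolates loading against relative humidity on both branches and
    reports the per-point gap ``q_des(rh) − q_ads(rh)`` plus its trapezoidal
    integral over rh.  Negative gaps (crossing branches) are reported as-is;
    a negative total area draws a warning.
    """
    if ads.branch != "adsorption" or des.branch != "desorption":
        raise ValueError("expected an adsorption and a desorption branch")
    if ads.T != des.T:
        raise ValueError("branches must share the same temperature")
    psat = saturation_pressure(ads.T)
    rh_a = ads.pressures / psat
    rh_d = des.pressures[::-1] / psat      # into increasing order
    q_d = des.loadings[::-1]
    lo = max(rh_a.min(), rh_d.min())
    hi = min(rh_a.max(), rh_d.max())
    if hi <= lo:
        raise ValueError("branches share no overlapping humidity range")
    if rh_grid is None:
        rh_grid = np.linspace(lo, hi, 20)
    rh_grid = np.asarray(rh_grid, dtype=float)
    if rh_grid.min() < lo - 1e-12 or rh_grid.max() > hi + 1e-12:
        raise ValueError("rh_grid extends beyond the overlapping range")
    gap = np.interp(rh_grid, rh_d, q_d) - np.interp(rh_grid, rh_a, ads.loadings)
    area = float(np.trapezoid(gap, rh_grid))
    if area < 0:
        warn(f"hysteresis area is negative ({area:.3g}); branches cross")
    return HysteresisGap(rh=rh_grid, gap=gap, area=area)
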
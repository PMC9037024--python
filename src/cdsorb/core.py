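"""Shared physical constants, unit conventions and vapor-pressure relations.

Conventions used throughout the package:

* temperatures are kelvin; instrument inputs in Celsius are converted at the
  I/O boundary only, with a 273 K offset (instrument set points are round
  Celsius values reported as rounded kelvin);
* pressures are Pa, loadings are mmol per gram of dry sorbent;
* every ``ln(rate) vs 1/T`` regression in the package reports the activation
  energy as ``|slope| * R`` in kJ/mol, keeping the signed slope alongside so
  anti-Arrhenius behaviour (rate decreasing with temperature) is never lost.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "Constants",
    "CONSTANTS",
    "Isotherm",
    "KineticFit",
    "saturation_pressure",
    "rh_to_pressure",
    "vaporization_enthalpy",
    "kinetic_fit",
]


@dataclass(frozen=True)
class Constants:
    """Physical constants for water / β-cyclodextrin sorption arithmetic.

    Attributes
    ----------
    R : float
        Gas constant, J mol⁻¹ K⁻¹.
    M_water : float
        Molar mass of water, g mol⁻¹.
    M_bcd : float
        Molar mass of β-cyclodextrin (C42H70O35), g mol⁻¹.
    """

    R: float = 8.314
    M_water: float = 18.02
    M_bcd: float = 1135.0

    def __post_init__(self) -> None:
        for name in ("R", "M_water", "M_bcd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Constants.{name} must be strictly positive")


#: Module-wide default constants.
CONSTANTS = Constants()

# Arden Buck correlation coefficients for liquid water (t in Celsius, Pa).
_BUCK_A = 611.21
_BUCK_B = 18.678
_BUCK_C = 234.5
_BUCK_D = 257.14

#: Kelvin offset for the Buck correlation. Instrument temperatures are round
#: Celsius values quoted as rounded kelvin (283 K ≡ 10 °C), so 273 exactly.
KELVIN_OFFSET = 273.0


def saturation_pressure(T: float) -> float:
    """Saturation vapor pressure of pure water, Pa.

    Arden Buck correlation over liquid water, valid between the freezing and
    boiling points.

    Parameters
    ----------
    T : float
        Temperature, K.  Must satisfy 273 < T < 373.
    """
    T = float(T)
    if not 273.0 < T < 373.0:
        raise ValueError(f"saturation_pressure: T={T} K outside (273, 373)")
    t = T - KELVIN_OFFSET
    return _BUCK_A * math.exp((_BUCK_B - t / _BUCK_C) * (t / (_BUCK_D + t)))


def rh_to_pressure(rh: float, T: float) -> float:
    """Convert relative humidity (fraction) to water vapor pressure, Pa."""
    rh = float(rh)
    if not 0.0 <= rh <= 1.0:
        raise ValueError(f"relative humidity {rh} outside [0, 1]")
    if rh == 0.0:
        return 0.0
    return rh * saturation_pressure(T)


def vaporization_enthalpy(T: float, constants: Constants = CONSTANTS) -> float:
    """Molar enthalpy of vaporization of water implied by the Psat correlation.

    Computed as ``R T² d(ln Psat)/dT`` with the analytic derivative of the
    Buck correlation (Clausius–Clapeyron applied to pure water). Returned in
    kJ mol⁻¹; ≈44 kJ mol⁻¹ near room temperature.
    """
    if not 273.0 < float(T) < 373.0:
        raise ValueError(f"vaporization_enthalpy: T={T} K outside (273, 373)")
    t = float(T) - KELVIN_OFFSET
    # ln Psat = ln A + (B - t/C) * t / (D + t); differentiate wrt t.
    num = (_BUCK_B - 2.0 * t / _BUCK_C) * (_BUCK_D + t) - (_BUCK_B * t - t * t / _BUCK_C)
    dlnp_dt = num / (_BUCK_D + t) ** 2
    return constants.R * float(T) ** 2 * dlnp_dt / 1000.0


@dataclass(frozen=True)
class Isotherm:
    """One sorption-isotherm branch at fixed temperature.

    Parameters
    ----------
    T : float
        Temperature, K.
    pressures : ndarray
        Water vapor pressures, Pa, in measurement order: strictly increasing
        on the adsorption branch, strictly decreasing on the desorption
        branch.
    loadings : ndarray
        Adsorbed amount, mmol per g dry sorbent, non-negative.
    branch : str
        ``"adsorption"`` or ``"desorption"``.
    """

    T: float
    pressures: np.ndarray
    loadings: np.ndarray
    branch: str = "adsorption"

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        q = np.asarray(self.loadings, dtype=float)
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "loadings", q)
        if self.branch not in ("adsorption", "desorption"):
            raise ValueError(f"unknown branch {self.branch!r}")
        if p.ndim != 1 or p.shape != q.shape or p.size < 2:
            raise ValueError("pressures and loadings must be equal-length 1-D, n >= 2")
        dp = np.diff(p)
        if self.branch == "adsorption" and not np.all(dp > 0):
            raise ValueError("adsorption-branch pressures must be strictly increasing")
        if self.branch == "desorption" and not np.all(dp < 0):
            raise ValueError("desorption-branch pressures must be strictly decreasing")
        if np.any(q < 0):
            raise ValueError("loadings must be non-negative")
        psat = saturation_pressure(self.T)
        if np.any(p > psat * (1.0 + 1e-9)):
            raise ValueError(f"pressures exceed saturation pressure {psat:.1f} Pa at {self.T} K")

    @property
    def relative_humidities(self) -> np.ndarray:
        """Pressures expressed as fractions of saturation pressure."""
        return self.pressures / saturation_pressure(self.T)

    def sorted_by_loading(self) -> "Isotherm":
        """Same data reordered by increasing loading (for interpolation)."""
        order = np.argsort(self.loadings, kind="stable")
        return _resorted(self, order)


def _resorted(iso: Isotherm, order: np.ndarray) -> Isotherm:
    # Bypass monotonicity validation: construct via __new__-style copy.
    new = object.__new__(Isotherm)
    object.__setattr__(new, "T", iso.T)
    object.__setattr__(new, "pressures", iso.pressures[order])
    object.__setattr__(new, "loadings", iso.loadings[order])
    object.__setattr__(new, "branch", iso.branch)
    return new


@dataclass(frozen=True)
class KineticFit:
    """Result of a ``ln(rate) vs 1/T`` regression.

    Attributes
    ----------
    activation_energy : float
        ``|slope_per_K| * R / 1000``, kJ mol⁻¹ (magnitude convention; the
        signed slope is retained in ``slope_per_K``).
    ln_intercept : float
        Intercept of the regression — the natural log of the pre-exponential
        term in the units of the fitted rate quantity.
    r_squared : float
        Coefficient of determination of the fit.
    n_points : int
        Number of (T, rate) pairs used.
    slope_per_K : float
        Raw fitted slope of ln(rate) against 1/T, K.
    """

    activation_energy: float
    ln_intercept: float
    r_squared: float
    n_points: int
    slope_per_K: float
    constants: Constants = field(default=CONSTANTS, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("KineticFit needs at least 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared {self.r_squared} outside [0, 1]")
        expected = abs(self.slope_per_K) * self.constants.R / 1000.0
        if not math.isclose(self.activation_energy, expected, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("activation_energy inconsistent with slope_per_K")

    @property
    def pre_exponential(self) -> float:
        """exp(ln_intercept), in the units of the fitted rate quantity."""
        return math.exp(self.ln_intercept)

    def summary(self) -> str:
        lines = [
            "ln(rate) vs 1/T regression",
            "--------------------------",
            f"n points            : {self.n_points}",
            f"slope               : {self.slope_per_K:.4g} K",
            f"activation energy   : {self.activation_energy:.4g} kJ/mol",
            f"ln(pre-exponential) : {self.ln_intercept:.4g}",
            f"pre-exponential     : {self.pre_exponential:.4g}",
            f"R^2                 : {self.r_squared:.6f}",
        ]
        return "\n".join(lines)


def kinetic_fit(temperatures, rates, constants: Constants = CONSTANTS) -> KineticFit:
    """Unweighted OLS of ln(rate) against 1/T.

    Parameters
    ----------
    temperatures : array-like
        Absolute temperatures, K (distinct, n >= 2).
    rates : array-like
        Strictly positive rate quantities (rate constants or dα/dt values).
    """
    T = np.asarray(temperatures, dtype=float)
    r = np.asarray(rates, dtype=float)
    if T.shape != r.shape or T.ndim != 1 or T.size < 2:
        raise ValueError("need equal-length 1-D arrays with n >= 2")
    if np.unique(T).size < 2:
        raise ValueError("need at least two distinct temperatures")
    if np.any(r <= 0):
        raise ValueError("rates must be strictly positive for the log transform")
    res = stats.linregress(1.0 / T, np.log(r))
    if T.size == 2 or not np.isfinite(res.rvalue):
        r2 = 1.0  # a two-point or exactly-flat fit has no residual
    else:
        r2 = float(res.rvalue) ** 2
    return KineticFit(
        activation_energy=abs(float(res.slope)) * constants.R / 1000.0,
        ln_intercept=float(res.intercept),
        r_squared=r2,
        n_points=int(T.size),
        slope_per_K=float(res.slope),
        constants=constants,
    )


def warn(message: str) -> None:
    """Emit a package-level UserWarning (single choke point for tests)."""
    warnings.warn(message, UserWarning, stacklevel=3)
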
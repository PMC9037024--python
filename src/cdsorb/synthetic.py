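"""Synthetic instrument traces with known ground truth, for parameter recovery.

Every analysis stage in the package can be validated end-to-end against data
generated here:

* **Isotherms** follow a GAB (Guggenheim–Anderson–de Boer) model with the
  energy constant ``c(T) = c0·exp(Q_c·1000/(R T)) < 1``, which produces the
  convex type-III shape characteristic of water on β-cyclodextrin and gives
  the built-in isosteric heat a closed analytic form (see
  :meth:`SorptionModelParams.isosteric_heat`).  Hysteresis is emulated
  phenomenologically by a loading multiplier on the desorption branch.
* **Staged uptake** integrates the stage rate law
  ``dq/dt = k·P_i·(1 − P_eq(q)/P_i)`` with ``P_eq`` from inverting the GAB
  model, reproducing the fast-then-saturating uptake of a humidity staircase.
* **TG ramps** use single-event first-order Arrhenius dehydration
  ``dα/dt = A·exp(−E/RT)·(1−α)`` along a linear temperature program.  The
  downstream isoconversional estimator never assumes this form — which is
  precisely what makes recovery of E a meaningful test.
* **DSC traces** release heat proportional to the instantaneous water
  desorption rate (endotherm negative), plus a linear instrument baseline
  drift and additive Gaussian noise.

All noise magnitudes default to zero; generators take an explicit ``seed``
and identical seeds give identical traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .core import (CONSTANTS, Constants, Isotherm, saturation_pressure,
                   vaporization_enthalpy, warn)
from .dsc import DscTrace
from .tg import Thermogram
from .uptake import UptakeTrace

__all__ = [
    "SorptionModelParams",
    "DehydrationParams",
    "generate_isotherm",
    "generate_staged_uptake",
    "generate_tg",
    "generate_dsc",
]


@dataclass(frozen=True)
class SorptionModelParams:
    """Ground-truth GAB water-sorption model.

    ``q(x, T) = q_m c k x / ((1 − k x)(1 + (c − 1) k x))`` with water
    activity ``x`` (relative humidity) and ``c = c0·exp(Q_c·1000/(R T))``.

    Attributes
    ----------
    q_m : float
        Monolayer capacity, mmol g⁻¹.
    c0 : float
        Energy-constant prefactor (dimensionless).
    Q_c : float
        Van't Hoff heat governing c(T), kJ mol⁻¹; positive means loadings
        fall as temperature rises (exothermic sorption).
    k_gab : float
        Multilayer constant, in (0, 1].
    hysteresis_factor : float
        >= 1; multiplies the loading on the desorption branch.

    Defaults give ``c(298) ≈ 0.40`` (type III), loadings of a few mmol g⁻¹
    at mid humidity, and a built-in isosteric heat in the mid-40s kJ mol⁻¹ —
    realistic for water on a hydrophilic oligosaccharide.
    """

    q_m: float = 6.0
    c0: float = 0.053
    Q_c: float = 5.0
    k_gab: float = 0.75
    hysteresis_factor: float = 1.2

    def __post_init__(self) -> None:
        if self.q_m <= 0:
            raise ValueError("q_m must be positive")
        if self.c0 <= 0:
            raise ValueError("c0 must be positive")
        if not 0.0 < self.k_gab <= 1.0:
            raise ValueError("k_gab must lie in (0, 1]")
        if self.hysteresis_factor < 1.0:
            raise ValueError("hysteresis_factor must be >= 1")

    def c(self, T: float, constants: Constants = CONSTANTS) -> float:
        """GAB energy constant at temperature T."""
        return self.c0 * math.exp(self.Q_c * 1000.0 / (constants.R * T))

    def loading(self, rh, T: float, constants: Constants = CONSTANTS):
        """Closed-form GAB loading at activity ``rh`` (adsorption branch)."""
        x = np.asarray(rh, dtype=float)
        c = self.c(T, constants)
        kx = self.k_gab * x
        if np.any(kx >= 1.0 - 1e-9):
            raise ValueError("k_gab * rh approaches 1: GAB loading diverges")
        q = self.q_m * c * kx / ((1.0 - kx) * (1.0 + (c - 1.0) * kx))
        return q if q.ndim else float(q)

    def equilibrium_rh(self, q: float, T: float, constants: Constants = CONSTANTS) -> float:
        """Invert the GAB model: activity at which the loading equals ``q``.

        Closed form — the cross-multiplied GAB relation is a quadratic in
        ``k x``; the physical root lies in (0, 1).
        """
        if q < -1e-12:
            raise ValueError("loading must be non-negative")
        if q <= 0.0:
            return 0.0
        c = self.c(T, constants)
        k = self.k_gab
        # q (1 - u)(1 + (c-1) u) = q_m c u,  u = k x
        a = q * (1.0 - c)                      # u^2 coefficient
        b = q * (c - 2.0) - self.q_m * c       # u coefficient (always < 0)
        cc = q                                 # constant
        if abs(a) < 1e-14 * max(abs(b), 1.0):
            u = -cc / b
        else:
            disc = b * b - 4.0 * a * cc
            if disc < 0:
                raise ValueError("loading outside the invertible range of the GAB model")
            # physical branch is the smaller root; the cancellation-free form
            # 2c/(-b + sqrt(disc)) keeps it accurate as q -> 0
            u = 2.0 * cc / (-b + math.sqrt(disc))
        if not 0.0 < u < 1.0:
            raise ValueError("loading outside the invertible range of the GAB model")
        x = u / k
        if not 0.0 < x < 1.0:
            raise ValueError("loading outside the invertible range of the GAB model")
        return x

    def equilibrium_pressure(self, q: float, T: float, constants: Constants = CONSTANTS) -> float:
        """Equilibrium vapor pressure at loading ``q``, Pa."""
        return self.equilibrium_rh(q, T, constants) * saturation_pressure(T)

    def isosteric_heat(self, q: float, T: float, constants: Constants = CONSTANTS) -> float:
        """Built-in isosteric heat, kJ mol⁻¹, by analytic Clausius–Clapeyron.

        Differentiates ``ln P = ln x(q, T) + ln Psat(T)`` at fixed loading:
        the implicit x-derivative follows from the GAB log-derivatives, the
        Psat term is the latent heat of condensation.
        """
        x = self.equilibrium_rh(q, T, constants)
        c = self.c(T, constants)
        kx = self.k_gab * x
        dlnq_dlnx = 1.0 + kx / (1.0 - kx) - (c - 1.0) * kx / (1.0 + (c - 1.0) * kx)
        dlnq_dlnc = 1.0 - c * kx / (1.0 + (c - 1.0) * kx)
        # fixed q: dlnx/d(1/T) = -(dlnq/dlnc)/(dlnq/dlnx) * Q_c*1000/R
        sorption_term = (dlnq_dlnc / dlnq_dlnx) * self.Q_c  # kJ/mol
        return sorption_term + vaporization_enthalpy(T, constants)


@dataclass(frozen=True)
class DehydrationParams:
    """Ground truth for the first-order dehydration event.

    Attributes
    ----------
    E_true : float
        Activation energy, kJ mol⁻¹.  The default sits at the top of the
        activation-energy band observed for β-cyclodextrin dehydration; the
        onset-side tail of a first-order event is governed by E, and this
        choice keeps the event contained inside a 303–473 K ramp at heating
        rates up to 20 K min⁻¹.
    lnA_true : float
        ln of the pre-exponential, ln(s⁻¹).  The default pins the DTG peak
        of a 5 K min⁻¹ ramp at 365 K (the observed peak), from which the
        peaks at 10/15/20 K min⁻¹ follow at 378/386/392 K.
    w_true : float
        Water mass fraction of the wet sample.
    dH_true : float
        Desorption enthalpy, kJ per mol water.
    m_wet : float
        Initial sample mass, mg.
    baseline_slope : float
        DSC baseline drift, mW K⁻¹.
    noise_sd_mass, noise_sd_heat : float
        Additive Gaussian noise SDs (mg, mW); zero by default.
    """

    E_true: float = 55.0
    lnA_true: float = 12.637
    w_true: float = 0.12
    dH_true: float = 67.5
    m_wet: float = 10.0
    baseline_slope: float = 0.0
    noise_sd_mass: float = 0.0
    noise_sd_heat: float = 0.0

    def __post_init__(self) -> None:
        if self.E_true <= 0 or self.dH_true <= 0 or self.m_wet <= 0:
            raise ValueError("E_true, dH_true and m_wet must be positive")
        if not 0.0 < self.w_true < 1.0:
            raise ValueError("w_true must lie in (0, 1)")
        if self.noise_sd_mass < 0 or self.noise_sd_heat < 0:
            raise ValueError("noise SDs must be non-negative")

    def with_realistic_noise(self) -> "DehydrationParams":
        """Instrument-like imperfections: ~0.5% peak-level heat-flow noise,
        a 0.02 mW/K baseline drift and microgram-level balance noise."""
        return replace(self, baseline_slope=0.02, noise_sd_mass=0.003, noise_sd_heat=0.03)

    def rate_constant(self, T, constants: Constants = CONSTANTS):
        """First-order rate constant A·exp(−E/RT), s⁻¹."""
        T = np.asarray(T, dtype=float)
        k = np.exp(self.lnA_true - self.E_true * 1000.0 / (constants.R * T))
        return k if k.ndim else float(k)

    def alpha_on_ramp(self, temperatures, beta: float, constants: Constants = CONSTANTS):
        """Exact conversion profile along a linear ramp.

        ``ln(1−α) = −(A/β_s)·∫ exp(−E/Rτ) dτ``; the temperature integral is
        evaluated by composite trapezoid on an 8× refined grid.
        """
        T = np.asarray(temperatures, dtype=float)
        refine = 8
        T_fine = np.interp(np.arange((T.size - 1) * refine + 1) / refine,
                           np.arange(T.size), T)
        k_fine = self.rate_constant(T_fine, constants)
        beta_s = beta / 60.0
        integral = cumulative_trapezoid(k_fine, T_fine, initial=0.0) / beta_s
        return 1.0 - np.exp(-integral[::refine])

    def dalpha_dt_on_ramp(self, temperatures, beta: float, constants: Constants = CONSTANTS):
        """Exact dehydration rate along a linear ramp, s⁻¹."""
        alpha = self.alpha_on_ramp(temperatures, beta, constants)
        return self.rate_constant(temperatures, constants) * (1.0 - alpha)


def generate_isotherm(
    params: SorptionModelParams,
    T: float,
    rh_grid,
    branch: str = "adsorption",
    noise_sd: float = 0.0,
    seed: int | None = None,
    constants: Constants = CONSTANTS,
) -> Isotherm:
    """One GAB isotherm branch at fixed temperature.

    The desorption branch multiplies the adsorption loading by the hysteresis
    factor and is stored in measurement order (pressure decreasing).  A
    warning is emitted when c(T) >= 1 (shape no longer type III).
    """
    rh = np.asarray(rh_grid, dtype=float)
    if np.any(rh <= 0) or np.any(rh > 0.97):
        raise ValueError("rh_grid must lie inside (0, 0.97]")
    if not np.all(np.diff(rh) > 0):
        raise ValueError("rh_grid must be strictly increasing")
    if params.c(T, constants) >= 1.0:
        warn(f"c(T={T}) >= 1: isotherm shape is no longer type III")
    q = np.asarray(params.loading(rh, T, constants), dtype=float)
    if branch == "desorption":
        q = q * params.hysteresis_factor
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        q = np.clip(q + rng.normal(0.0, noise_sd, size=q.shape), 0.0, None)
    p = rh * saturation_pressure(T)
    if branch == "desorption":
        p, q = p[::-1], q[::-1]
    return Isotherm(T=T, pressures=p, loadings=q, branch=branch)


def generate_staged_uptake(
    k_rate: float,
    params: SorptionModelParams,
    T: float,
    rh_stages,
    dt: float = 0.05,
    stage_duration: float = 180.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    constants: Constants = CONSTANTS,
) -> UptakeTrace:
    """Integrate the staged uptake rate law through a humidity staircase.

    ``dq/dt = k_rate·P_i·(1 − P_eq(q)/P_i)`` within each stage; the sample
    starts dry (q = 0, previous pressure 0).

    Parameters
    ----------
    k_rate : float
        Stage rate constant, mmol min⁻¹ Pa⁻¹ (loading units per minute per
        pascal).
    rh_stages : array-like
        Strictly increasing stage set points, fractions in (0, 0.97).
    dt : float
        Sampling interval, min.
    stage_duration : float
        Length of each stage, min.
    """
    rh = np.asarray(rh_stages, dtype=float)
    if not np.all(np.diff(rh) > 0):
        raise ValueError("rh_stages must be strictly increasing")
    if np.any(rh <= 0) or np.any(rh >= 0.97):
        raise ValueError("rh_stages must lie inside (0, 0.97)")
    if dt <= 0 or stage_duration <= dt:
        raise ValueError("need dt > 0 and stage_duration > dt")
    if k_rate <= 0:
        raise ValueError("k_rate must be positive")
    psat = saturation_pressure(T)
    stage_P = rh * psat
    n_per_stage = int(round(stage_duration / dt))
    q_max = params.loading(0.969, T, constants)

    def rhs(P_i):
        def f(t, y):
            q = min(float(y[0]), q_max)
            P_eq = params.equilibrium_pressure(q, T, constants) if q > 0 else 0.0
            return [k_rate * (P_i - P_eq)]
        return f

    times, loadings, boundaries = [], [], []
    q0 = 0.0
    t_offset = 0.0
    for i, P_i in enumerate(stage_P):
        t_local = np.arange(1, n_per_stage + 1) * dt
        sol = solve_ivp(rhs(P_i), (0.0, t_local[-1]), [q0], t_eval=t_local,
                        rtol=1e-9, atol=1e-12, max_step=dt)
        if not sol.success:
            raise RuntimeError(f"uptake integration failed in stage {i}: {sol.message}")
        boundaries.append(len(times))
        times.extend(t_offset + t_local)
        loadings.extend(sol.y[0])
        q0 = float(sol.y[0][-1])
        if q0 > q_max * (1 - 1e-6):
            raise RuntimeError(f"stage {i}: loading left the invertible GAB range")
        t_offset += t_local[-1]
    q = np.asarray(loadings)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        q = np.clip(q + rng.normal(0.0, noise_sd, size=q.shape), 0.0, None)
    return UptakeTrace(T=T, times=np.asarray(times), loadings=q,
                       stage_boundaries=np.asarray(boundaries, dtype=int),
                       stage_pressures=stage_P, initial_pressure=0.0)


def generate_tg(
    params: DehydrationParams,
    beta: float,
    T_range: tuple[float, float] = (303.0, 473.0),
    dt: float = 1.0,
    seed: int | None = None,
    constants: Constants = CONSTANTS,
) -> Thermogram:
    """First-order dehydration mass-loss curve on a linear heating ramp.

    Parameters
    ----------
    beta : float
        Heating rate, K min⁻¹.
    T_range : (T0, T_end)
        K, within (300, 480) — below the decomposition threshold of
        β-cyclodextrin (no chemistry above dehydration is modelled).
    dt : float
        Sampling interval, s.
    """
    T0, T_end = T_range
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (300.0 < T0 < T_end < 480.0):
        raise ValueError("T_range must be ordered and lie within (300, 480) K")
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, (T_end - T0) / (beta / 60.0) + dt / 2, dt)
    T = T0 + beta / 60.0 * t
    alpha = params.alpha_on_ramp(T, beta, constants)
    if alpha[-1] <= 0.999:
        warn(f"generate_tg: dehydration incomplete (alpha end = {alpha[-1]:.4f}); "
             "widen T_range or slow the ramp")
    mass = params.m_wet * (1.0 - params.w_true * alpha)
    if params.noise_sd_mass > 0:
        rng = np.random.default_rng(seed)
        mass = mass + rng.normal(0.0, params.noise_sd_mass, size=mass.shape)
    return Thermogram(beta=beta, temperatures=T, masses=mass, t0=0.0)


def generate_dsc(
    params: DehydrationParams,
    thermogram: Thermogram,
    seed: int | None = None,
    constants: Constants = CONSTANTS,
) -> DscTrace:
    """Heat-flow trace coupled to a TG ramp generated from the same params.

    Heat flow (mW) = −dH_true · (mol water released per second) · 1e6
    + baseline drift + noise; the endotherm is negative.
    """
    T = thermogram.temperatures
    rate = params.dalpha_dt_on_ramp(T, thermogram.beta, constants)  # 1/s
    mol_total = params.m_wet * params.w_true * 1e-3 / constants.M_water
    heat = -params.dH_true * 1e6 * mol_total * rate  # kJ/mol * mol/s -> mW
    heat = heat + params.baseline_slope * (T - T[0])
    if params.noise_sd_heat > 0:
        rng = np.random.default_rng(seed)
        heat = heat + rng.normal(0.0, params.noise_sd_heat, size=heat.shape)
    return DscTrace(beta=thermogram.beta, temperatures=T, heat_flow=heat,
                    sample_mass=params.m_wet, water_fraction=params.w_true)
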
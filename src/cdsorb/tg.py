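"""Thermogravimetric dehydration analysis.

Covers the mass-loss side of the dehydration of hydrated β-cyclodextrin on a
constant heating ramp: total water content and the hydration stoichiometry
(moles of water per mole of host), derivative thermogravimetry (DTG) and its
peak, normalized conversion curves α(T) with smoothed rates dα/dt, and the
Friedman (differential isoconversional) estimate of the desorption activation
energy from runs at several heating rates.

The Friedman method is model-free: at each fixed conversion α it regresses
ln(dα/dt) on 1/T across heating rates,

    ln(dα/dt)|α = ln[A f(α)] − E(α) / (R T),

so no reaction model f(α) is assumed — the slope alone carries E(α).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core import CONSTANTS, Constants, KineticFit, kinetic_fit, warn

__all__ = [
    "Thermogram",
    "ConversionCurve",
    "IsoconversionalResult",
    "water_content",
    "moles_water_per_host",
    "conversion_curve",
    "dtg_peak",
    "FriedmanModel",
    "friedman_analysis",
    "isoconversional_fit",
]


@dataclass(frozen=True)
class Thermogram:
    """A constant-heating-rate TG record.

    Attributes
    ----------
    beta : float
        Heating rate, K min⁻¹ (> 0).
    temperatures : ndarray
        K, strictly increasing, n >= 20.
    masses : ndarray
        Sample mass, mg or percent of initial mass (analysis uses ratios, so
        both work identically); non-increasing within noise.
    t0 : float
        Start time, min; the time grid is ``t0 + (T - T[0]) / beta``.
    """

    beta: float
    temperatures: np.ndarray
    masses: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "temperatures", T)
        object.__setattr__(self, "masses", m)
        if self.beta <= 0:
            raise ValueError("heating rate beta must be positive")
        if T.shape != m.shape or T.ndim != 1 or T.size < 20:
            raise ValueError("temperatures and masses must be equal-length 1-D, n >= 20")
        if not np.all(np.diff(T) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(m <= 0):
            raise ValueError("masses must be positive")

    @property
    def times(self) -> np.ndarray:
        """Time grid, minutes, from the linear temperature program."""
        return self.t0 + (self.temperatures - self.temperatures[0]) / self.beta


@dataclass(frozen=True)
class ConversionCurve:
    """Normalized extent of dehydration along one heating ramp.

    ``alpha`` is (m0 − m)/(m0 − m∞) clipped to [0, 1]; ``dalpha_dt`` is its
    smoothed time derivative in s⁻¹.
    """

    temperatures: np.ndarray
    alpha: np.ndarray
    dalpha_dt: np.ndarray
    beta: float

    def __post_init__(self) -> None:
        T = np.asarray(self.temperatures, dtype=float)
        a = np.asarray(self.alpha, dtype=float)
        r = np.asarray(self.dalpha_dt, dtype=float)
        for name, arr in (("temperatures", T), ("alpha", a), ("dalpha_dt", r)):
            object.__setattr__(self, name, arr)
        if not (T.shape == a.shape == r.shape) or T.ndim != 1:
            raise ValueError("temperatures, alpha, dalpha_dt must be equal-length 1-D")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if np.any(a < -1e-9) or np.any(a > 1 + 1e-9):
            raise ValueError("alpha outside [0, 1]")
        if np.any(np.diff(a) < -1e-9):
            raise ValueError("alpha must be non-decreasing")


def water_content(
    tg: Thermogram,
    plateau_tol: float = 0.001,
    ref_window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Water mass fraction and dehydration end temperature of a TG run.

    The end temperature ``T_end`` is the first temperature after which every
    remaining mass sample differs from the final mass by less than
    ``plateau_tol`` (fraction) of the final mass — i.e. the curve has entered
    its dry plateau.  The water fraction is (m0 − m_final)/m0.

    Parameters
    ----------
    tg : Thermogram
    plateau_tol : float
        Plateau criterion as a fraction of the final mass (0.001 = 0.1%).
    ref_window : (T_lo, T_hi), optional
        If given, m0 is the mean mass inside this temperature window instead
        of the first sample (use when the ramp starts with a transient).

    Returns
    -------
    (w, T_end)

    Raises
    ------
    ValueError
        If the run never plateaus (incomplete dehydration).
    """
    m = tg.masses
    T = tg.temperatures
    if ref_window is not None:
        lo, hi = ref_window
        mask = (T >= lo) & (T <= hi)
        if not mask.any():
            raise ValueError(f"reference window [{lo}, {hi}] K contains no samples")
        m0 = float(m[mask].mean())
    else:
        m0 = float(m[0])
    m_final = float(m[-min(5, m.size):].mean())  # short tail mean damps noise
    # plateau detection on a short moving average so balance noise comparable
    # to the tolerance cannot push T_end to the end of the run
    win = min(7, m.size)
    kernel = np.ones(win) / win
    m_smooth = np.convolve(np.pad(m, (win // 2, win - 1 - win // 2), mode="edge"),
                           kernel, mode="valid")
    dev = np.abs(m_smooth - m_final) / m_final
    inside = dev < plateau_tol
    # first index from which the trace stays inside the tolerance band
    outside = np.nonzero(~inside)[0]
    i_end = 0 if outside.size == 0 else int(outside[-1]) + 1
    if i_end >= m.size - max(2, m.size // 50):
        raise ValueError("no dry plateau found: dehydration incomplete over the scanned range")
    w = (m0 - m_final) / m0
    return float(w), float(T[i_end])


def moles_water_per_host(w: float, constants: Constants = CONSTANTS) -> float:
    """Moles of water per mole of β-cyclodextrin from the water mass fraction.

    ``n = (w / (1 − w)) * (M_host / M_water)`` — the wet-basis water fraction
    converted to a dry-basis molar ratio.  w = 0.120 gives n ≈ 8.6.
    """
    if not 0.0 <= w < 1.0:
        raise ValueError(f"water fraction {w} outside [0, 1)")
    return (w / (1.0 - w)) * constants.M_bcd / constants.M_water


def conversion_curve(
    tg: Thermogram,
    smooth_window: int = 11,
    plateau_tol: float = 0.001,
    ref_window: tuple[float, float] | None = None,
) -> ConversionCurve:
    """Conversion α(T) and smoothed rate dα/dt from a TG run.

    α = (m0 − m)/(m0 − m∞) clipped to [0, 1]; the derivative dα/dT comes from
    a Savitzky–Golay filter (local quadratic over an odd ``smooth_window``),
    and dα/dt = (β/60)·dα/dT in s⁻¹.
    """
    if smooth_window % 2 == 0 or smooth_window < 5:
        raise ValueError("smooth_window must be odd and >= 5")
    if smooth_window > tg.temperatures.size:
        raise ValueError("smooth_window larger than the trace")
    w, _ = water_content(tg, plateau_tol=plateau_tol, ref_window=ref_window)
    if w <= 0:
        raise ValueError("no mass loss: conversion undefined")
    m = tg.masses
    T = tg.temperatures
    if ref_window is not None:
        lo, hi = ref_window
        m0 = float(m[(T >= lo) & (T <= hi)].mean())
    else:
        m0 = float(m[0])
    m_inf = float(m[-min(5, m.size):].mean())  # consistent with water_content
    alpha_raw = (m0 - m) / (m0 - m_inf)
    alpha = np.clip(np.maximum.accumulate(alpha_raw), 0.0, 1.0)
    dT = np.diff(T)
    if not np.allclose(dT, dT[0], rtol=1e-6, atol=1e-9):
        raise ValueError("conversion_curve requires a uniform temperature grid")
    dalpha_dT = savgol_filter(alpha, smooth_window, polyorder=2, deriv=1, delta=float(dT[0]))
    dalpha_dt = np.maximum(dalpha_dT, 0.0) * tg.beta / 60.0
    return ConversionCurve(temperatures=T, alpha=alpha, dalpha_dt=dalpha_dt, beta=tg.beta)


def dtg_peak(tg: Thermogram, smooth_window: int = 11) -> tuple[float, float]:
    """Location and height of the DTG peak (maximum mass-loss rate).

    Returns ``(T_peak [K], peak rate [% of initial mass per K])``.  Ties are
    broken toward the lowest temperature, with a warning.
    """
    if smooth_window % 2 == 0 or smooth_window < 5:
        raise ValueError("smooth_window must be odd and >= 5")
    if smooth_window > tg.temperatures.size:
        raise ValueError("smooth_window larger than the trace")
    T = tg.temperatures
    pct = tg.masses / tg.masses[0] * 100.0
    dT = np.diff(T)
    if not np.allclose(dT, dT[0], rtol=1e-6, atol=1e-9):
        raise ValueError("dtg_peak requires a uniform temperature grid")
    rate = -savgol_filter(pct, smooth_window, polyorder=2, deriv=1, delta=float(dT[0]))
    peak = float(rate.max())
    idx = np.nonzero(np.isclose(rate, peak, rtol=1e-12, atol=0.0))[0]
    if idx.size > 1:
        warn(f"dtg_peak: {idx.size} equal maxima; reporting the lowest-temperature one")
    i = int(idx[0])
    return float(T[i]), peak


@dataclass(frozen=True)
class IsoconversionalResult:
    """Friedman analysis across heating rates.

    One activation energy per conversion level, plus the per-α interpolated
    (T, dα/dt) tables that produced it.
    """

    alpha_grid: np.ndarray
    E: np.ndarray            # kJ mol⁻¹
    ln_Af: np.ndarray        # intercepts, ln of (A f(α)) in the rate units
    r_squared: np.ndarray
    tables: pd.DataFrame     # columns: alpha, beta, T_K, rate_per_s
    fits: tuple[KineticFit, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        a = np.asarray(self.alpha_grid, dtype=float)
        object.__setattr__(self, "alpha_grid", a)
        for name in ("E", "ln_Af", "r_squared"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any((a <= 0) | (a >= 1)):
            raise ValueError("alpha_grid must lie strictly inside (0, 1)")
        if not (self.E.shape == a.shape == self.ln_Af.shape == self.r_squared.shape):
            raise ValueError("per-alpha arrays must align with alpha_grid")

    @property
    def E_min(self) -> float:
        return float(self.E.min())

    @property
    def E_max(self) -> float:
        return float(self.E.max())

    def summary(self) -> pd.DataFrame:
        """Per-α table: E, ln_Af, R², shaped like an isoconversional report."""
        return pd.DataFrame({
            "alpha": self.alpha_grid,
            "E_kJ_per_mol": self.E,
            "ln_Af": self.ln_Af,
            "r_squared": self.r_squared,
        })

    def plot_arrhenius(self, ax=None):
        """Diagnostic ln(dα/dt) vs 1000/T lines, one per conversion level."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for a in self.alpha_grid:
            sub = self.tables[self.tables["alpha"] == a]
            ax.plot(1000.0 / sub["T_K"], np.log(sub["rate_per_s"]), "o-",
                    label=f"α={a:.1f}")
        ax.set_xlabel("1000 / T (1/K)")
        ax.set_ylabel("ln dα/dt (1/s)")
        ax.legend(fontsize="small")
        return ax


class FriedmanModel:
    """Model-free (Friedman) isoconversional analysis of dehydration kinetics.

    Built from conversion curves measured at several distinct heating rates;
    :meth:`fit` interpolates each curve at the requested conversion levels
    (linearly in T, linearly in ln dα/dt) and regresses ln(dα/dt) on 1/T at
    each level.

    Parameters
    ----------
    curves : sequence of ConversionCurve
        At least two, at distinct heating rates (three or more recommended).
    alpha_grid : array-like, optional
        Conversion levels; default 0.1 … 0.9 in steps of 0.1.
    """

    #: default conversion grid
    DEFAULT_ALPHA_GRID = np.round(np.arange(0.1, 0.91, 0.1), 10)

    def __init__(self, curves, alpha_grid=None, constants: Constants = CONSTANTS):
        curves = list(curves)
        if len(curves) < 2:
            raise ValueError("need at least two conversion curves")
        betas = [c.beta for c in curves]
        if len(set(betas)) != len(betas):
            raise ValueError("heating rates must be distinct")
        self.curves = sorted(curves, key=lambda c: c.beta)
        self.alpha_grid = (np.asarray(alpha_grid, dtype=float)
                          if alpha_grid is not None else self.DEFAULT_ALPHA_GRID.copy())
        if np.any((self.alpha_grid <= 0) | (self.alpha_grid >= 1)):
            raise ValueError("alpha_grid must lie strictly inside (0, 1)")
        self.constants = constants

    @staticmethod
    def _at_alpha(curve: ConversionCurve, a: float) -> tuple[float, float] | None:
        """Interpolated (T, dα/dt) where the curve crosses conversion ``a``."""
        alpha = curve.alpha
        if a < alpha[0] or a > alpha[-1]:
            return None
        j = int(np.searchsorted(alpha, a))
        if j == 0:
            j = 1
        a0, a1 = alpha[j - 1], alpha[j]
        frac = 0.0 if a1 == a0 else (a - a0) / (a1 - a0)
        T = curve.temperatures[j - 1] + frac * (curve.temperatures[j] - curve.temperatures[j - 1])
        r0, r1 = curve.dalpha_dt[j - 1], curve.dalpha_dt[j]
        if r0 <= 0 or r1 <= 0:
            return None
        rate = float(np.exp(np.log(r0) + frac * (np.log(r1) - np.log(r0))))
        return float(T), rate

    def fit(self) -> IsoconversionalResult:
        kept_alpha, Es, lnAfs, r2s, fits = [], [], [], [], []
        rows = []
        for a in self.alpha_grid:
            Ts, rates, betas = [], [], []
            for c in self.curves:
                pt = self._at_alpha(c, a)
                if pt is None:
                    warn(f"friedman: curve at beta={c.beta} K/min excluded at alpha={a}")
                    continue
                Ts.append(pt[0])
                rates.append(pt[1])
                betas.append(c.beta)
            if len(Ts) < 2:
                warn(f"friedman: fewer than 2 curves usable at alpha={a}; grid point dropped")
                continue
            fit = kinetic_fit(Ts, rates, constants=self.constants)
            kept_alpha.append(a)
            Es.append(fit.activation_energy)
            lnAfs.append(fit.ln_intercept)
            r2s.append(fit.r_squared)
            fits.append(fit)
            rows.extend({"alpha": a, "beta": b, "T_K": T, "rate_per_s": r}
                        for b, T, r in zip(betas, Ts, rates))
        if not kept_alpha:
            raise ValueError("no conversion level had two usable curves")
        return IsoconversionalResult(
            alpha_grid=np.array(kept_alpha),
            E=np.array(Es),
            ln_Af=np.array(lnAfs),
            r_squared=np.array(r2s),
            tables=pd.DataFrame(rows, columns=["alpha", "beta", "T_K", "rate_per_s"]),
            fits=tuple(fits),
        )


def friedman_analysis(curves, alpha_grid=None, constants: Constants = CONSTANTS) -> IsoconversionalResult:
    """Functional wrapper around :class:`FriedmanModel`."""
    return FriedmanModel(curves, alpha_grid=alpha_grid, constants=constants).fit()


def isoconversional_fit(temperatures, rates, constants: Constants = CONSTANTS) -> KineticFit:
    """Friedman regression for a single conversion level.

    Direct ln(dα/dt) vs 1/T fit on already-interpolated per-α data, e.g. a
    published isoconversional table.
    """
    return kinetic_fit(temperatures, rates, constants=constants)
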
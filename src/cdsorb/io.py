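"""CSV interchange formats, run configuration and the full-report driver.

All trace kinds share one dialect: a ``#``-prefixed header block of
``key: value`` metadata lines, then a regular comma-separated table.  The
synthetic generators write the same schema the readers consume, so synthetic
fixtures are bit-compatible with exported instrument data.

Schemas (columns after the header block):

========  =======================================  =========================
kind      header keys                              columns
========  =======================================  =========================
isotherm  temperature_K, branch                    pressure_Pa, loading_mmol_per_g
uptake    temperature_K, stage_pressures_Pa,       time_min, loading_mmol
          stage_boundaries, initial_pressure_Pa
tg        beta_K_per_min, t0_min                   temperature_K, mass
dsc       beta_K_per_min, sample_mass_mg,          temperature_K, heat_flow_mW
          [water_fraction]
========  =======================================  =========================

TG masses may be mg or percent of initial mass; the analysis only uses
ratios, so both yield identical conversion curves.
"""

from __future__ import annotations

import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dsc as dsc_mod
from . import isotherm as iso_mod
from . import synthetic as syn
from . import tg as tg_mod
from . import uptake as up_mod
from .core import CONSTANTS, Isotherm
from .dsc import DscTrace
from .tg import Thermogram
from .uptake import UptakeTrace

__all__ = [
    "ParseError",
    "read_trace",
    "write_trace",
    "RunConfig",
    "load_config",
    "default_config",
    "ResultBundle",
    "run_report",
]

logger = logging.getLogger("cdsorb")

_FLOAT_FMT = "%.17g"  # full double precision: written traces round-trip exactly


class ParseError(ValueError):
    """Malformed trace file; carries the path and (1-based) line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}" + (f":{line}" if line is not None else "")
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


def _format_floats(values) -> str:
    return ",".join(_FLOAT_FMT % v for v in np.asarray(values, dtype=float))


def write_trace(obj, path) -> Path:
    """Write a trace object to the package CSV dialect."""
    path = Path(path)
    lines: list[str] = []
    if isinstance(obj, Isotherm):
        lines += [f"# kind: isotherm", f"# temperature_K: {_FLOAT_FMT % obj.T}",
                  f"# branch: {obj.branch}"]
        df = pd.DataFrame({"pressure_Pa": obj.pressures,
                           "loading_mmol_per_g": obj.loadings})
    elif isinstance(obj, UptakeTrace):
        lines += [f"# kind: uptake", f"# temperature_K: {_FLOAT_FMT % obj.T}",
                  f"# stage_pressures_Pa: {_format_floats(obj.stage_pressures)}",
                  f"# stage_boundaries: {','.join(str(int(b)) for b in obj.stage_boundaries)}",
                  f"# initial_pressure_Pa: {_FLOAT_FMT % obj.initial_pressure}"]
        df = pd.DataFrame({"time_min": obj.times, "loading_mmol": obj.loadings})
    elif isinstance(obj, Thermogram):
        lines += [f"# kind: tg", f"# beta_K_per_min: {_FLOAT_FMT % obj.beta}",
                  f"# t0_min: {_FLOAT_FMT % obj.t0}"]
        df = pd.DataFrame({"temperature_K": obj.temperatures, "mass": obj.masses})
    elif isinstance(obj, DscTrace):
        lines += [f"# kind: dsc", f"# beta_K_per_min: {_FLOAT_FMT % obj.beta}",
                  f"# sample_mass_mg: {_FLOAT_FMT % obj.sample_mass}"]
        if obj.water_fraction is not None:
            lines.append(f"# water_fraction: {_FLOAT_FMT % obj.water_fraction}")
        df = pd.DataFrame({"temperature_K": obj.temperatures,
                           "heat_flow_mW": obj.heat_flow})
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())
    return path


def _parse_header(text: str, path) -> tuple[dict, int]:
    header: dict[str, str] = {}
    n = 0
    for raw in text.splitlines():
        if not raw.startswith("#"):
            break
        n += 1
        body = raw.lstrip("#").strip()
        if not body:
            continue
        if ":" not in body:
            raise ParseError(f"malformed header line {raw!r}", path, n)
        key, value = body.split(":", 1)
        header[key.strip()] = value.strip()
    return header, n


def _require(header: dict, key: str, path):
    if key not in header:
        raise ParseError(f"missing required header key '{key}'", path)
    return header[key]


def _check_monotone(values: np.ndarray, name: str, path, header_lines: int,
                    direction: str = "increasing") -> None:
    d = np.diff(values)
    bad = np.nonzero(d <= 0 if direction == "increasing" else d >= 0)[0]
    if bad.size:
        # +1 header row of column names, +1 to land on the second row of the pair
        line = header_lines + 1 + int(bad[0]) + 2
        raise ParseError(f"{name} not strictly {direction} at data row "
                         f"{int(bad[0]) + 2}", path, line)


def read_trace(path, kind: str | None = None):
    """Read a trace file, validate its invariants, and build the domain object.

    Parameters
    ----------
    path : path-like
    kind : str, optional
        Expected kind (``isotherm``, ``uptake``, ``tg`` or ``dsc``); by
        default taken from the file's header.
    """
    path = Path(path)
    text = path.read_text()
    header, n_header = _parse_header(text, path)
    file_kind = _require(header, "kind", path)
    if kind is not None and kind != file_kind:
        raise ParseError(f"expected kind '{kind}' but file declares '{file_kind}'", path)
    try:
        df = pd.read_csv(_io.StringIO(text), comment="#",
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"table parse failure: {exc}", path) from exc

    def col(name):
        if name not in df.columns:
            raise ParseError(f"missing required column '{name}'", path)
        vals = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            raise ParseError(f"non-numeric value in column '{name}' at data row "
                             f"{int(bad[0]) + 1}", path, n_header + 1 + int(bad[0]) + 1)
        return vals

    try:
        if file_kind == "isotherm":
            p = col("pressure_Pa")
            branch = header.get("branch", "adsorption")
            _check_monotone(p, "pressure_Pa", path, n_header,
                            "increasing" if branch == "adsorption" else "decreasing")
            return Isotherm(T=float(_require(header, "temperature_K", path)),
                            pressures=p, loadings=col("loading_mmol_per_g"),
                            branch=branch)
        if file_kind == "uptake":
            t = col("time_min")
            _check_monotone(t, "time_min", path, n_header)
            return UptakeTrace(
                T=float(_require(header, "temperature_K", path)),
                times=t, loadings=col("loading_mmol"),
                stage_boundaries=np.array(
                    [int(x) for x in _require(header, "stage_boundaries", path).split(",")]),
                stage_pressures=np.array(
                    [float(x) for x in _require(header, "stage_pressures_Pa", path).split(",")]),
                initial_pressure=float(header.get("initial_pressure_Pa", 0.0)))
        if file_kind == "tg":
            T = col("temperature_K")
            _check_monotone(T, "temperature_K", path, n_header)
            return Thermogram(beta=float(_require(header, "beta_K_per_min", path)),
                              temperatures=T, masses=col("mass"),
                              t0=float(header.get("t0_min", 0.0)))
        if file_kind == "dsc":
            T = col("temperature_K")
            _check_monotone(T, "temperature_K", path, n_header)
            wf = header.get("water_fraction")
            return DscTrace(beta=float(_require(header, "beta_K_per_min", path)),
                            temperatures=T, heat_flow=col("heat_flow_mW"),
                            sample_mass=float(_require(header, "sample_mass_mg", path)),
                            water_fraction=float(wf) if wf is not None else None)
    except ParseError:
        raise
    except (ValueError, TypeError) as exc:
        raise ParseError(str(exc), path) from exc
    raise ParseError(f"unknown trace kind '{file_kind}'", path)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated analysis configuration (see ``default_config`` for keys)."""

    seed: int = 0
    output_dir: Path = Path("cdsorb_out")
    stages: tuple[str, ...] = ()
    parameters: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    arrhenius: dict = field(default_factory=dict)

    KNOWN_STAGES = ("simulate", "isotherms", "uptake", "tg", "dsc", "arrhenius")

    def __post_init__(self) -> None:
        object.__setattr__(self, "output_dir", Path(self.output_dir))
        object.__setattr__(self, "stages", tuple(self.stages))
        for s in self.stages:
            if s not in self.KNOWN_STAGES:
                raise ValueError(f"unknown stage '{s}' (known: {self.KNOWN_STAGES})")
        for kind, paths in self.inputs.items():
            for p in paths:
                if not Path(p).exists():
                    raise ValueError(f"input file for stage '{kind}' not found: {p}")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        output_dir=raw.get("output_dir", "cdsorb_out"),
        stages=tuple(raw.get("stages", ())),
        parameters=dict(raw.get("parameters", {})),
        synthetic=dict(raw.get("synthetic", {})),
        inputs={k: list(v) for k, v in (raw.get("inputs") or {}).items()},
        arrhenius=dict(raw.get("arrhenius", {})),
    )


def default_config(seed: int = 0, output_dir="cdsorb_out") -> RunConfig:
    """All-synthetic end-to-end configuration with the default study conditions:
    isotherms at 283/298/313 K, a 10–90% humidity staircase, TG/DSC ramps at
    5/10/15/20 K min⁻¹."""
    return RunConfig(
        seed=seed,
        output_dir=output_dir,
        stages=("simulate", "isotherms", "uptake", "tg", "dsc"),
        parameters={},
        synthetic={
            "temperatures_K": [283.0, 298.0, 313.0],
            "heating_rates_K_per_min": [5.0, 10.0, 15.0, 20.0],
            "rh_grid": list(np.round(np.arange(0.05, 0.951, 0.05), 10)),
            "rh_stages": list(np.round(np.arange(0.1, 0.91, 0.1), 10)),
            "k_rate": [10.64e-5, 9.12e-5, 7.88e-5],
            "sorption": {},
            "dehydration": {},
        },
    )


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class ResultBundle:
    """Outputs of :func:`run_report`: summary values, written files, errors."""

    summary: dict = field(default_factory=dict)
    files: list = field(default_factory=list)
    errors: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def _write_csv(df: pd.DataFrame, path: Path, files: list) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    files.append(path)


def _stage_simulate(cfg: RunConfig, bundle: ResultBundle) -> dict:
    s = cfg.synthetic
    sp = syn.SorptionModelParams(**s.get("sorption", {}))
    dp = syn.DehydrationParams(**s.get("dehydration", {}))
    temps = list(s.get("temperatures_K", [283.0, 298.0, 313.0]))
    betas = list(s.get("heating_rates_K_per_min", [5.0, 10.0, 15.0, 20.0]))
    rh_grid = np.asarray(s.get("rh_grid", np.round(np.arange(0.05, 0.951, 0.05), 10)), dtype=float)
    rh_stages = np.asarray(s.get("rh_stages", np.round(np.arange(0.1, 0.91, 0.1), 10)), dtype=float)
    k_rate = s.get("k_rate", 1.0e-4)
    k_rates = list(np.broadcast_to(np.asarray(k_rate, dtype=float), (len(temps),)))
    noise = s.get("noise", {})
    out = cfg.output_dir / "synthetic"
    traces = {"isotherms": [], "uptake": [], "tg": [], "dsc": []}
    # sub-seeds are fixed offsets from the config seed (determinism contract)
    for j, T in enumerate(temps):
        for branch in ("adsorption", "desorption"):
            iso = syn.generate_isotherm(sp, T, rh_grid, branch=branch,
                                        noise_sd=float(noise.get("isotherm", 0.0)),
                                        seed=cfg.seed + 100 + j)
            traces["isotherms"].append(iso)
            bundle.files.append(write_trace(iso, out / f"isotherm_{branch}_{int(T)}K.csv"))
        up = syn.generate_staged_uptake(k_rates[j], sp, T, rh_stages,
                                        noise_sd=float(noise.get("uptake", 0.0)),
                                        seed=cfg.seed + 200 + j)
        traces["uptake"].append(up)
        bundle.files.append(write_trace(up, out / f"uptake_{int(T)}K.csv"))
    for j, beta in enumerate(betas):
        tg = syn.generate_tg(dp, beta, seed=cfg.seed + 300 + j)
        traces["tg"].append(tg)
        bundle.files.append(write_trace(tg, out / f"tg_beta{int(beta)}.csv"))
        d = syn.generate_dsc(dp, tg, seed=cfg.seed + 400 + j)
        traces["dsc"].append(d)
        bundle.files.append(write_trace(d, out / f"dsc_beta{int(beta)}.csv"))
    logger.info("simulate: wrote %d synthetic traces", len(bundle.files))
    return traces


def run_report(cfg: RunConfig) -> ResultBundle:
    """Execute the configured stages and write per-stage CSVs plus a summary.

    Stage failures are recorded in ``bundle.errors``; remaining stages still
    run.  Two runs with the same config and seed produce byte-identical
    outputs.
    """
    bundle = ResultBundle()
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    params = cfg.parameters
    traces: dict = {"isotherms": [], "uptake": [], "tg": [], "dsc": []}

    if "simulate" in cfg.stages:
        try:
            traces = _stage_simulate(cfg, bundle)
        except Exception as exc:
            bundle.errors["simulate"] = f"{type(exc).__name__}: {exc}"
    for kind in traces:
        for p in cfg.inputs.get(kind, ()):
            traces[kind].append(read_trace(p))

    if "isotherms" in cfg.stages:
        try:
            ads = [i for i in traces["isotherms"] if i.branch == "adsorption"]
            model = iso_mod.IsostericHeatModel(ads, q_grid=params.get("q_grid"))
            res = model.fit()
            _write_csv(pd.DataFrame({"loading_mmol_per_g": res.loadings,
                                     "Q_kJ_per_mol": res.heats,
                                     "r_squared": res.r_squared}),
                       out / "isosteric_heat.csv", bundle.files)
            bundle.summary["isosteric_heat_min_kJ_per_mol"] = round(res.heats.min(), 3)
            bundle.summary["isosteric_heat_max_kJ_per_mol"] = round(res.heats.max(), 3)
            des = {i.T: i for i in traces["isotherms"] if i.branch == "desorption"}
            for a in ads:
                if a.T in des:
                    gap = iso_mod.hysteresis_gap(a, des[a.T])
                    bundle.summary[f"hysteresis_area_{int(a.T)}K"] = round(gap.area, 4)
            logger.info("isotherms: Q in [%.1f, %.1f] kJ/mol",
                        res.heats.min(), res.heats.max())
        except Exception as exc:
            bundle.errors["isotherms"] = f"{type(exc).__name__}: {exc}"

    if "uptake" in cfg.stages or "arrhenius" in cfg.stages:
        try:
            if cfg.arrhenius.get("k") and cfg.arrhenius.get("T"):
                ks = [float(x) for x in cfg.arrhenius["k"]]
                Ts = [float(x) for x in cfg.arrhenius["T"]]
            else:
                rh_window = tuple(params.get("rh_window", (0.10, 0.60)))
                n_points = int(params.get("n_points", 10))
                rows, ks, Ts = [], [], []
                for tr in traces["uptake"]:
                    rates, summ = up_mod.stage_rate_constants(tr, rh_window, n_points)
                    rows += [{"T_K": tr.T, "stage": r.stage_index, "rate": r.rate,
                              "driving_force_Pa": r.driving_force, "k": r.k,
                              "r_squared": r.r_squared} for r in rates]
                    ks.append(summ.k_mean)
                    Ts.append(tr.T)
                _write_csv(pd.DataFrame(rows), out / "stage_rates.csv", bundle.files)
            fit = up_mod.ArrheniusModel(Ts, ks).fit()
            _write_csv(pd.DataFrame([{"Ea_kJ_per_mol": fit.activation_energy,
                                      "ln_A": fit.ln_intercept,
                                      "A": fit.pre_exponential,
                                      "r_squared": fit.r_squared,
                                      "n": fit.n_points}]),
                       out / "arrhenius.csv", bundle.files)
            bundle.summary["Ea_adsorption_kJ_per_mol"] = round(fit.activation_energy, 3)
            logger.info("uptake: Ea = %.2f kJ/mol", fit.activation_energy)
        except Exception as exc:
            bundle.errors["uptake"] = f"{type(exc).__name__}: {exc}"

    if "tg" in cfg.stages:
        try:
            smooth = int(params.get("smooth_window", 11))
            ptol = float(params.get("plateau_tol", 0.001))
            curves, rows = [], []
            for tr in traces["tg"]:
                w, T_end = tg_mod.water_content(tr, plateau_tol=ptol)
                n = tg_mod.moles_water_per_host(w)
                Tp, rate = tg_mod.dtg_peak(tr, smooth_window=smooth)
                rows.append({"beta_K_per_min": tr.beta, "water_fraction": w,
                             "T_end_K": T_end, "mol_water_per_mol_host": n,
                             "dtg_peak_K": Tp, "dtg_peak_pct_per_K": rate})
                curves.append(tg_mod.conversion_curve(tr, smooth_window=smooth,
                                                      plateau_tol=ptol))
            _write_csv(pd.DataFrame(rows), out / "tg_summary.csv", bundle.files)
            bundle.summary["water_fraction_mean"] = round(
                float(np.mean([r["water_fraction"] for r in rows])), 5)
            bundle.summary["mol_water_per_mol_host"] = round(
                float(np.mean([r["mol_water_per_mol_host"] for r in rows])), 2)
            if len(curves) >= 2:
                grid = params.get("alpha_grid")
                ir = tg_mod.FriedmanModel(curves, alpha_grid=grid).fit()
                _write_csv(ir.summary(), out / "friedman.csv", bundle.files)
                _write_csv(ir.tables, out / "friedman_tables.csv", bundle.files)
                bundle.summary["Ea_desorption_min_kJ_per_mol"] = round(ir.E_min, 2)
                bundle.summary["Ea_desorption_max_kJ_per_mol"] = round(ir.E_max, 2)
                logger.info("tg: E(alpha) in [%.1f, %.1f] kJ/mol", ir.E_min, ir.E_max)
        except Exception as exc:
            bundle.errors["tg"] = f"{type(exc).__name__}: {exc}"

    if "dsc" in cfg.stages:
        try:
            w_cfg = params.get("water_fraction",
                               bundle.summary.get("water_fraction_mean"))
            anchors = params.get("anchors")
            rows = []
            for tr in traces["dsc"]:
                wf = tr.water_fraction if tr.water_fraction is not None else w_cfg
                res = dsc_mod.DscEnthalpyModel(tr, water_fraction=wf).fit(
                    anchors=tuple(anchors) if anchors else None)
                rows.append({"beta_K_per_min": tr.beta,
                             "specific_J_per_g": res.specific_enthalpy_J_per_g,
                             "dH_kJ_per_mol_water": res.molar_enthalpy_kJ_per_mol,
                             "water_fraction": res.water_fraction})
            _write_csv(pd.DataFrame(rows), out / "dsc_summary.csv", bundle.files)
            vals = [r["dH_kJ_per_mol_water"] for r in rows]
            bundle.summary["dH_mean_kJ_per_mol_water"] = round(float(np.mean(vals)), 2)
            bundle.summary["dH_min_kJ_per_mol_water"] = round(float(np.min(vals)), 2)
            bundle.summary["dH_max_kJ_per_mol_water"] = round(float(np.max(vals)), 2)
            logger.info("dsc: dH mean = %.1f kJ/mol water", float(np.mean(vals)))
        except Exception as exc:
            bundle.errors["dsc"] = f"{type(exc).__name__}: {exc}"

    summary_df = pd.DataFrame(sorted(bundle.summary.items()), columns=["quantity", "value"])
    _write_csv(summary_df, out / "summary.csv", bundle.files)
    (out / "summary.json").write_text(
        json.dumps({"summary": bundle.summary, "errors": bundle.errors},
                   indent=2, sort_keys=True) + "\n")
    bundle.files.append(out / "summary.json")
    return bundle
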
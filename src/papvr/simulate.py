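"""ODE assembly and integration to the periodic steady state.

The closed loop is a stiff ODE system: for each capacitive node
``C dp/dt = sum(inflows) - sum(outflows)``, for each inductive branch
``L dQ/dt = dp - R Q``, and for each chamber ``dV/dt = Q_in - Q_out``
with the chamber pressure given by its time-varying elastance.  Purely
resistive branches (valves, capillary paths, venous pool outlet)
contribute algebraic flows.

Integration proceeds cycle by cycle with a stiff-capable adaptive
solver; the periodic steady state is declared when the cycle-to-cycle
relative change of every cycle-mean state variable falls below a
threshold.  All reported haemodynamics are cycle means there.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.integrate import solve_ivp

from .circuit import (
    AnatomyConfig,
    CircuitModel,
    ModelParameters,
    RLCCompartment,
    build_model,
    default_parameters,
)
from .heart import ConfigurationError, ElastanceParams, ValveParams

logger = logging.getLogger("papvr")

__all__ = [
    "SolverSettings",
    "SimulationResult",
    "IntegrationError",
    "default_initial_state",
    "total_blood_volume",
    "rhs",
    "integrate_cycles",
    "run_to_steady_state",
    "load_config",
    "save_config",
]


class IntegrationError(RuntimeError):
    """Solver failure; carries the last valid state and time."""

    def __init__(self, message: str, t: float | None = None, state: np.ndarray | None = None):
        super().__init__(message)
        self.t = t
        self.state = state


@dataclass(frozen=True)
class SolverSettings:
    """Integration and steady-state settings.

    The output grid doubles as the quadrature grid for cycle means; 400
    points per cycle resolves the valve switching transients well enough
    that reported Qp/Qs is solver-independent to ~3 decimals (200 points
    leaves ~0.01 quadrature noise).
    """

    rel_tol: float = 1e-7
    abs_tol: float = 1e-9
    max_cycles: int = 200
    steady_state_tol: float = 1e-4
    output_points_per_cycle: int = 400
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0 or self.steady_state_tol <= 0:
            raise ConfigurationError("solver tolerances must be > 0")
        if self.max_cycles < 2:
            raise ConfigurationError("max_cycles must be >= 2")
        if self.output_points_per_cycle < 8:
            raise ConfigurationError("output_points_per_cycle must be >= 8")


# ---------------------------------------------------------------------------
# Compiled parameter view (plain floats for a fast right-hand side)
# ---------------------------------------------------------------------------

class _Compiled:
    """Numeric snapshot of a CircuitModel for the scalar right-hand side."""

    __slots__ = (
        "chambers", "valves", "eps",
        "c_sa", "c_sv", "c_vc", "c_pa", "c_cap", "c_pool",
        "r_sys", "l_sys", "r_sven", "r_vc", "l_vc", "r_pool",
        "g_pre", "r_vein", "l_vein", "dest",
        "period",
    )

    def __init__(self, model: CircuitModel):
        p = model.params
        comp = p.compartments
        # chamber tuples: (e_min, e_max-e_min, v_rest, t_onset, t_up, t_down, period)
        self.chambers = {
            name: (
                ch.e_min, ch.e_max - ch.e_min, ch.v_rest,
                ch.t_onset, ch.t_contract, ch.t_relax, ch.period,
            )
            for name, ch in p.chambers.items()
        }
        self.valves = {name: (v.r_open, v.r_closed) for name, v in p.valves.items()}
        self.eps = p.valve_smoothing_eps
        self.c_sa = comp["SYS-AR"].c
        self.c_sv = comp["SYS-VEN"].c
        self.c_vc = comp["VC"].c
        self.c_pa = comp["PUL-AR"].c
        self.c_pool = comp["VEN-PUL-POOL"].c
        self.r_sys = comp["SYS-AR"].r + comp["SYS-C"].r
        self.l_sys = comp["SYS-AR"].l
        self.r_sven = comp["SYS-VEN"].r
        self.r_vc = comp["VC"].r
        self.l_vc = comp["VC"].l
        self.r_pool = comp["VEN-PUL-POOL"].r
        self.c_cap = tuple(
            comp["PUL-C-OX"].c * v.capillary_fraction for v in model.veins
        )
        self.g_pre = tuple(
            sum(model.vein_precap_conductances(v.index)) for v in model.veins
        )
        self.r_vein = tuple(v.r_vein for v in model.veins)
        self.l_vein = tuple(v.l_vein for v in model.veins)
        # 0 -> pulmonary venous pool, 1 -> RA, 2 -> caval node
        self.dest = tuple(
            {"LA": 0, "RA": 1, "VC": 2}[v.destination] for v in model.veins
        )
        self.period = p.chambers["LV"].period


def _activation(t: float, ch: tuple) -> float:
    _, _, _, onset, up, down, period = ch
    phase = (t / period - onset) % 1.0
    if phase < up:
        return 0.5 * (1.0 - math.cos(math.pi * phase / up)) if up > 0 else 0.0
    if phase < up + down:
        return 0.5 * (1.0 + math.cos(math.pi * (phase - up) / down)) if down > 0 else 0.0
    return 0.0


def _pressure(volume: float, t: float, ch: tuple) -> float:
    e_min, de, v_rest, *_ = ch
    return (e_min + de * _activation(t, ch)) * (volume - v_rest)


def _diode(dp: float, valve: tuple, eps: float) -> float:
    r_open, r_closed = valve
    if eps > 0.0:
        sigma = 0.5 * (1.0 + math.tanh(dp / eps))
    else:
        sigma = 1.0 if dp > 0.0 else 0.0
    return dp * (sigma / r_open + (1.0 - sigma) / r_closed)


def rhs(t: float, y: np.ndarray, model: CircuitModel, _compiled: _Compiled | None = None):
    """Time derivative of the state vector.

    State layout: [V_LA, V_LV, V_RA, V_RV, p_sys_ar, p_sys_ven, p_vc,
    p_pul_ar, p_cap_1..4, p_ven_pool, q_sys_ar, q_vc, q_vein_1..4].
    """
    c = _compiled if _compiled is not None else _Compiled(model)
    (v_la, v_lv, v_ra, v_rv, p_sa, p_sv, p_vc, p_pa) = y[:8]
    p_cap = y[8:12]
    p_pool = y[12]
    q_sa = y[13]
    q_vc = y[14]
    q_vein = y[15:19]

    p_la = _pressure(v_la, t, c.chambers["LA"])
    p_lv = _pressure(v_lv, t, c.chambers["LV"])
    p_ra = _pressure(v_ra, t, c.chambers["RA"])
    p_rv = _pressure(v_rv, t, c.chambers["RV"])

    q_mv = _diode(p_la - p_lv, c.valves["MV"], c.eps)
    q_av = _diode(p_lv - p_sa, c.valves["AV"], c.eps)
    q_tv = _diode(p_ra - p_rv, c.valves["TV"], c.eps)
    q_pv = _diode(p_rv - p_pa, c.valves["PV"], c.eps)

    q_pool_out = (p_pool - p_la) / c.r_pool
    q_sven = (p_sv - p_vc) / c.r_sven

    dy = np.empty_like(y)
    ra_in = q_vc
    vc_in = q_sven - q_vc
    pool_in = -q_pool_out
    q_pre_total = 0.0
    dest_p = (p_pool, p_ra, p_vc)
    for i in range(4):
        q_pre = (p_pa - p_cap[i]) * c.g_pre[i]
        q_pre_total += q_pre
        dy[8 + i] = (q_pre - q_vein[i]) / c.c_cap[i]
        dy[15 + i] = (p_cap[i] - dest_p[c.dest[i]] - c.r_vein[i] * q_vein[i]) / c.l_vein[i]
        if c.dest[i] == 0:
            pool_in += q_vein[i]
        elif c.dest[i] == 1:
            ra_in += q_vein[i]
        else:
            vc_in += q_vein[i]

    dy[0] = q_pool_out - q_mv          # V_LA
    dy[1] = q_mv - q_av                # V_LV
    dy[2] = ra_in - q_tv               # V_RA
    dy[3] = q_tv - q_pv                # V_RV
    dy[4] = (q_av - q_sa) / c.c_sa     # p_sys_ar
    dy[5] = (q_sa - q_sven) / c.c_sv   # p_sys_ven
    dy[6] = vc_in / c.c_vc             # p_vc
    dy[7] = (q_pv - q_pre_total) / c.c_pa  # p_pul_ar
    dy[12] = pool_in / c.c_pool        # p_ven_pool
    dy[13] = (p_sa - p_sv - c.r_sys * q_sa) / c.l_sys
    dy[14] = (p_vc - p_ra - c.r_vc * q_vc) / c.l_vc
    return dy


def _derived_flows(t: np.ndarray, states: np.ndarray, c: _Compiled) -> pd.DataFrame:
    """Chamber pressures and algebraic flows on the output grid (vectorised)."""
    def act(ch):
        _, _, _, onset, up, down, period = ch
        phase = np.mod(t / period - onset, 1.0)
        a = np.zeros_like(phase)
        if up > 0:
            a = np.where(phase < up, 0.5 * (1 - np.cos(np.pi * phase / up)), a)
        if down > 0:
            mask = (phase >= up) & (phase < up + down)
            a = np.where(mask, 0.5 * (1 + np.cos(np.pi * (phase - up) / down)), a)
        return a

    def pres(vol, ch):
        return (ch[0] + ch[1] * act(ch)) * (vol - ch[2])

    def diode(dp, valve):
        r_open, r_closed = valve
        sigma = 0.5 * (1 + np.tanh(dp / c.eps)) if c.eps > 0 else (dp > 0).astype(float)
        return dp * (sigma / r_open + (1 - sigma) / r_closed)

    p_la = pres(states[:, 0], c.chambers["LA"])
    p_lv = pres(states[:, 1], c.chambers["LV"])
    p_ra = pres(states[:, 2], c.chambers["RA"])
    p_rv = pres(states[:, 3], c.chambers["RV"])
    out = {
        "p_la": p_la, "p_lv": p_lv, "p_ra": p_ra, "p_rv": p_rv,
        "q_mv": diode(p_la - p_lv, c.valves["MV"]),
        "q_av": diode(p_lv - states[:, 4], c.valves["AV"]),
        "q_tv": diode(p_ra - p_rv, c.valves["TV"]),
        "q_pv": diode(p_rv - states[:, 7], c.valves["PV"]),
        "q_pool": (states[:, 12] - p_la) / c.r_pool,
    }
    return pd.DataFrame(out)


@dataclass
class SimulationResult:
    """Trajectories and per-cycle means of one integration run."""

    time: np.ndarray
    states: np.ndarray
    state_names: tuple[str, ...]
    cycle_means: pd.DataFrame  # one row per cycle; states + derived flows/pressures
    converged: bool
    n_cycles_run: int
    final_rel_change: float
    model: CircuitModel
    settings: SolverSettings

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    @property
    def final_cycle_means(self) -> pd.Series:
        return self.cycle_means.iloc[-1]

    def to_frame(self) -> pd.DataFrame:
        """Waveforms: time, every state variable and the derived valve/pool
        flows and chamber pressures, one row per output time."""
        df = pd.DataFrame(self.states, columns=list(self.state_names))
        df.insert(0, "time", self.time)
        derived = _derived_flows(self.time, self.states, _Compiled(self.model))
        return pd.concat([df, derived], axis=1)

    def final_cycle_frame(self) -> pd.DataFrame:
        n = self.settings.output_points_per_cycle + 1
        return self.to_frame().iloc[-n:].reset_index(drop=True)


def default_initial_state(model: CircuitModel) -> np.ndarray:
    """Physiological guess: uniform 10 mmHg pressures, zero flows, chambers
    at v_rest + 50 mL; ``volume_offset`` mL added at the systemic venous node."""
    y = np.zeros(len(model.state_layout))
    for i, ch in enumerate(("LA", "LV", "RA", "RV")):
        y[i] = model.chambers[ch].v_rest + 50.0
    y[4:13] = 10.0
    y[5] += model.params.volume_offset / model.compartments["SYS-VEN"].c
    return y


def total_blood_volume(state: np.ndarray, model: CircuitModel) -> float:
    """Chamber volumes plus stressed volume stored on every capacitive node."""
    c = _Compiled(model)
    vol = float(np.sum(state[:4]))
    caps = [c.c_sa, c.c_sv, c.c_vc, c.c_pa, *c.c_cap, c.c_pool]
    vol += float(np.dot(caps, state[4:13]))
    return vol


def _cycle_means(t: np.ndarray, states: np.ndarray, c: _Compiled) -> pd.Series:
    span = t[-1] - t[0]
    means = np.trapezoid(states, t, axis=0) / span
    derived = _derived_flows(t, states, c)
    dmeans = np.trapezoid(derived.to_numpy(), t, axis=0) / span
    return means, dmeans, list(derived.columns)


def integrate_cycles(
    model: CircuitModel,
    settings: SolverSettings | None = None,
    initial_state: np.ndarray | None = None,
    n_cycles: int | None = None,
    stop_at_tol: bool = False,
) -> SimulationResult:
    """Integrate a fixed number of cardiac cycles (or until the steady-state
    criterion if ``stop_at_tol``), returning trajectories and cycle means."""
    if settings is None:
        settings = SolverSettings()
    if n_cycles is None:
        n_cycles = settings.max_cycles
    c = _Compiled(model)
    y = (
        default_initial_state(model)
        if initial_state is None
        else np.asarray(initial_state, dtype=float).copy()
    )
    period = c.period
    npts = settings.output_points_per_cycle
    times: list[np.ndarray] = []
    trajs: list[np.ndarray] = []
    mean_rows: list[np.ndarray] = []
    prev_means: np.ndarray | None = None
    rel_change = np.inf
    converged = False
    n_run = 0
    fun = lambda t, yy: rhs(t, yy, model, c)
    for k in range(n_cycles):
        t0, t1 = k * period, (k + 1) * period
        t_eval = np.linspace(t0, t1, npts + 1)
        sol = solve_ivp(
            fun, (t0, t1), y, method=settings.method,
            rtol=settings.rel_tol, atol=settings.abs_tol, t_eval=t_eval,
        )
        if not sol.success or not np.all(np.isfinite(sol.y)):
            raise IntegrationError(
                f"solver failed in cycle {k + 1}: {sol.message}", t=sol.t[-1] if len(sol.t) else t0,
                state=sol.y[:, -1] if sol.y.size else y,
            )
        y = sol.y[:, -1].copy()
        n_run = k + 1
        states_k = sol.y.T
        smeans, dmeans, dnames = _cycle_means(sol.t, states_k, c)
        row = np.concatenate([smeans, dmeans])
        mean_rows.append(row)
        # store trajectory without duplicating the shared endpoint
        if k == 0:
            times.append(sol.t)
            trajs.append(states_k)
        else:
            times.append(sol.t[1:])
            trajs.append(states_k[1:])
        if prev_means is not None:
            denom = np.maximum(np.abs(prev_means), 0.5)
            rel_change = float(np.max(np.abs(row - prev_means) / denom))
            if stop_at_tol and rel_change < settings.steady_state_tol:
                converged = True
                prev_means = row
                break
        prev_means = row
    if not stop_at_tol:
        converged = rel_change < settings.steady_state_tol
    columns = list(model.state_names) + dnames
    cycle_means = pd.DataFrame(mean_rows, columns=columns)
    cycle_means.index.name = "cycle"
    return SimulationResult(
        time=np.concatenate(times),
        states=np.vstack(trajs),
        state_names=model.state_names,
        cycle_means=cycle_means,
        converged=converged,
        n_cycles_run=n_run,
        final_rel_change=rel_change,
        model=model,
        settings=settings,
    )


def run_to_steady_state(
    model: CircuitModel,
    settings: SolverSettings | None = None,
    initial_state: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate cycle by cycle until every cycle-mean state variable changes
    by less than ``steady_state_tol`` (relative) between consecutive cycles,
    or ``max_cycles`` is reached (then ``converged`` is False)."""
    if settings is None:
        settings = SolverSettings()
    result = integrate_cycles(
        model, settings, initial_state, n_cycles=settings.max_cycles, stop_at_tol=True
    )
    if not result.converged:
        logger.warning(
            "steady state not reached in %d cycles (rel change %.3g)",
            result.n_cycles_run, result.final_rel_change,
        )
    return result


# ---------------------------------------------------------------------------
# Config file IO (YAML)
# ---------------------------------------------------------------------------

def _params_to_dict(p: ModelParameters) -> dict:
    return {
        "heart": {
            name: {
                "e_max": ch.e_max, "e_min": ch.e_min, "v_rest": ch.v_rest,
                "t_onset": ch.t_onset, "t_contract": ch.t_contract,
                "t_relax": ch.t_relax, "period": ch.period,
            }
            for name, ch in p.chambers.items()
        },
        "valves": {
            name: {"r_open": v.r_open, "r_closed": v.r_closed}
            for name, v in p.valves.items()
        },
        "compartments": {
            name: {"r": comp.r, "l": comp.l, "c": comp.c}
            for name, comp in p.compartments.items()
        },
        "veins": {
            "r": p.vein_r, "l": p.vein_l,
            "capillary_fractions": list(p.capillary_fractions),
            "sh_fraction": p.sh_fraction,
        },
        "volume_offset": p.volume_offset,
        "valve_smoothing_eps": p.valve_smoothing_eps,
    }


def _params_from_dict(d: dict) -> ModelParameters:
    defaults = default_parameters()
    chambers = {
        name: ElastanceParams(**spec) for name, spec in d.get("heart", {}).items()
    } or defaults.chambers
    valves = {
        name: ValveParams(**spec) for name, spec in d.get("valves", {}).items()
    } or defaults.valves
    comps = {
        name: RLCCompartment(name, **spec)
        for name, spec in d.get("compartments", {}).items()
    } or defaults.compartments
    veins = d.get("veins", {})
    return ModelParameters(
        chambers=chambers,
        valves=valves,
        compartments=comps,
        vein_r=veins.get("r", defaults.vein_r),
        vein_l=veins.get("l", defaults.vein_l),
        capillary_fractions=tuple(
            veins.get("capillary_fractions", defaults.capillary_fractions)
        ),
        sh_fraction=veins.get("sh_fraction", defaults.sh_fraction),
        volume_offset=d.get("volume_offset", defaults.volume_offset),
        valve_smoothing_eps=d.get("valve_smoothing_eps", defaults.valve_smoothing_eps),
    )


def load_config(path: str | Path) -> tuple[ModelParameters, AnatomyConfig, SolverSettings]:
    """Read a YAML model configuration (sections heart / valves /
    compartments / veins / anatomy / solver; missing sections fall back to
    the calibrated defaults)."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    params = _params_from_dict(d)
    a = d.get("anatomy", {})
    anatomy = AnatomyConfig(
        variant=a.get("variant", "baseline"),
        anomalous_veins=frozenset(a.get("anomalous_veins", [])),
        pvr_wood_units=a.get("pvr_wood_units", 1.0),
        anomalous_postcap_scale=a.get("anomalous_postcap_scale", 1.0),
    )
    s = d.get("solver", {})
    settings = SolverSettings(**s) if s else SolverSettings()
    return params, anatomy, settings


def save_config(
    path: str | Path,
    params: ModelParameters,
    anatomy: AnatomyConfig | None = None,
    settings: SolverSettings | None = None,
) -> None:
    d = _params_to_dict(params)
    if anatomy is not None:
        d["anatomy"] = {
            "variant": anatomy.variant,
            "anomalous_veins": sorted(anatomy.anomalous_veins),
            "pvr_wood_units": anatomy.pvr_wood_units,
            "anomalous_postcap_scale": anatomy.anomalous_postcap_scale,
        }
    if settings is not None:
        d["solver"] = {
            "rel_tol": settings.rel_tol, "abs_tol": settings.abs_tol,
            "max_cycles": settings.max_cycles,
            "steady_state_tol": settings.steady_state_tol,
            "output_points_per_cycle": settings.output_points_per_cycle,
            "method": settings.method,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
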
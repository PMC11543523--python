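"""Qp/Qs metric, parameter sweeps and baseline calibration.

Qp is defined as the cycle-mean pulmonary-valve flow and Qs as the
cycle-mean aortic-valve flow, both over the final converged cycle; at the
periodic steady state these equal the vein-sum and systemic-return
definitions.  Sweeps cover the number of anomalous veins (1-3), the
precapillary pulmonary resistance (up to 8 Wood units) and the
postcapillary resistance of the anomalous limb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .circuit import (
    WOOD_UNIT,
    AnatomyConfig,
    CircuitModel,
    ModelParameters,
    build_model,
    default_parameters,
    scale_anomalous_postcap,
    set_pvr,
)
from .heart import ConfigurationError
from .simulate import SimulationResult, SolverSettings, run_to_steady_state

logger = logging.getLogger("papvr")

__all__ = [
    "HemodynamicSummary",
    "SweepResult",
    "CalibrationTargets",
    "compute_qp_qs",
    "simulate_variant",
    "sweep_vein_count",
    "sweep_pvr",
    "sweep_anomalous_postcap",
    "calibrate_baseline",
    "reproduce_model_table",
    "DEFAULT_PVR_GRID",
]

#: Precapillary PVR sweep grid (Wood units), baseline to 8 WU
DEFAULT_PVR_GRID = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)

_ML_S_TO_L_MIN = 0.06

#: default identity of the anomalous veins for k = 1..3
_DEFAULT_VEIN_SETS = {0: frozenset(), 1: frozenset({1}), 2: frozenset({1, 2}), 3: frozenset({1, 2, 3})}


@dataclass(frozen=True)
class HemodynamicSummary:
    """Cycle-mean haemodynamics at the periodic steady state."""

    qp: float  # L/min, pulmonary valve
    qs: float  # L/min, aortic valve
    qp_qs: float
    pressures: dict  # site -> {"mean", "systolic", "diastolic"} (mmHg)
    vein_flows: tuple[float, float, float, float]  # L/min, cycle means
    pvr_effective: float  # (mean PA - mean LA) / Qp, in WU
    converged: bool
    n_cycles: int

    @property
    def shunt_flow(self) -> float:
        """Anomalous (left-to-right shunt) flow, L/min."""
        return self.qp - self.qs


@dataclass
class SweepResult:
    """One summary per grid point along a single swept axis."""

    axis: str
    grid: tuple[float, ...]
    summaries: list[HemodynamicSummary]
    variant: str
    n_anomalous: int

    def qp_qs(self) -> np.ndarray:
        return np.array([s.qp_qs for s in self.summaries])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                self.axis: list(self.grid),
                "qp_qs": [s.qp_qs for s in self.summaries],
                "qp_l_min": [s.qp for s in self.summaries],
                "qs_l_min": [s.qs for s in self.summaries],
                "mean_pa_mmhg": [s.pressures["PA"]["mean"] for s in self.summaries],
                "mean_ra_mmhg": [s.pressures["RA"]["mean"] for s in self.summaries],
                "converged": [s.converged for s in self.summaries],
            }
        )
        df["variant"] = self.variant
        if self.axis != "n_anomalous":
            df["n_anomalous"] = self.n_anomalous
        return df


def _pressure_stats(series: np.ndarray) -> dict:
    return {
        "mean": float(np.mean(series)),
        "systolic": float(np.max(series)),
        "diastolic": float(np.min(series)),
    }


def compute_qp_qs(result: SimulationResult, model: CircuitModel | None = None,
                  force: bool = False) -> HemodynamicSummary:
    """Haemodynamic summary from the final cycle of a converged run.

    Raises unless the run converged (pass ``force=True`` to override).
    """
    if not result.converged and not force:
        raise ConfigurationError(
            "simulation did not reach periodic steady state (use force=True to summarise anyway)"
        )
    if model is None:
        model = result.model
    means = result.final_cycle_means
    qp = float(means["q_pv"]) * _ML_S_TO_L_MIN
    qs = float(means["q_av"]) * _ML_S_TO_L_MIN
    final = result.final_cycle_frame()
    pressures = {
        "PA": _pressure_stats(final["p_pul_ar"].to_numpy()),
        "RA": _pressure_stats(final["p_ra"].to_numpy()),
        "LA": _pressure_stats(final["p_la"].to_numpy()),
        "aorta": _pressure_stats(final["p_sys_ar"].to_numpy()),
    }
    vein_flows = tuple(
        float(means[f"q_vein_{i}"]) * _ML_S_TO_L_MIN for i in (1, 2, 3, 4)
    )
    vein_sum = sum(vein_flows)
    if qp > 0 and abs(vein_sum - qp) > 0.005 * qp:
        logger.warning(
            "vein-flow sum %.4f L/min deviates from Qp %.4f by more than 0.5%%", vein_sum, qp
        )
    dp = pressures["PA"]["mean"] - pressures["LA"]["mean"]
    pvr_eff = dp / (qp / _ML_S_TO_L_MIN) / WOOD_UNIT if qp > 0 else float("nan")
    return HemodynamicSummary(
        qp=qp,
        qs=qs,
        qp_qs=qp / qs if qs > 0 else float("inf"),
        pressures=pressures,
        vein_flows=vein_flows,
        pvr_effective=pvr_eff,
        converged=result.converged,
        n_cycles=result.n_cycles_run,
    )


def _anatomy(variant: str, k: int, pvr: float = 1.0, postcap_scale: float = 1.0) -> AnatomyConfig:
    if k == 0:
        return AnatomyConfig(variant="baseline", pvr_wood_units=pvr)
    return AnatomyConfig(
        variant=variant, anomalous_veins=_DEFAULT_VEIN_SETS[k],
        pvr_wood_units=pvr, anomalous_postcap_scale=postcap_scale,
    )


def simulate_variant(
    variant: str,
    k: int,
    params: ModelParameters | None = None,
    pvr: float = 1.0,
    postcap_scale: float = 1.0,
    settings: SolverSettings | None = None,
    initial_state: np.ndarray | None = None,
) -> tuple[HemodynamicSummary, SimulationResult]:
    """Build, run to steady state and summarise one anatomy."""
    model = build_model(_anatomy(variant, k, pvr, postcap_scale), params)
    result = run_to_steady_state(model, settings, initial_state)
    return compute_qp_qs(result, model, force=not result.converged), result


def sweep_vein_count(
    variant: str,
    params: ModelParameters | None = None,
    k_values: tuple[int, ...] = (0, 1, 2, 3),
    pvr: float = 1.0,
    settings: SolverSettings | None = None,
) -> SweepResult:
    """Qp/Qs versus number of anomalous veins at fixed precapillary PVR."""
    summaries = []
    warm = None
    for k in k_values:
        s, r = simulate_variant(variant, k, params, pvr=pvr, settings=settings,
                                initial_state=warm)
        warm = r.final_state
        summaries.append(s)
    return SweepResult(
        axis="n_anomalous", grid=tuple(float(k) for k in k_values),
        summaries=summaries, variant=variant, n_anomalous=max(k_values),
    )


def sweep_pvr(
    variant: str,
    k: int,
    params: ModelParameters | None = None,
    pvr_grid: tuple[float, ...] = DEFAULT_PVR_GRID,
    settings: SolverSettings | None = None,
) -> SweepResult:
    """Qp/Qs versus precapillary pulmonary resistance (Wood units)."""
    if k < 1:
        raise ConfigurationError("PVR sweep requires >= 1 anomalous vein")
    summaries = []
    warm = None
    for wu in pvr_grid:
        s, r = simulate_variant(variant, k, params, pvr=wu, settings=settings,
                                initial_state=warm)
        warm = r.final_state
        summaries.append(s)
    return SweepResult(
        axis="pvr_wood_units", grid=tuple(pvr_grid), summaries=summaries,
        variant=variant, n_anomalous=k,
    )


def sweep_anomalous_postcap(
    variant: str,
    k: int,
    params: ModelParameters | None = None,
    factor_grid: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
    pvr: float = 1.0,
    settings: SolverSettings | None = None,
) -> SweepResult:
    """Qp/Qs versus the resistance scaling of the anomalous venous limb."""
    if k < 1:
        raise ConfigurationError("postcapillary sweep requires >= 1 anomalous vein")
    if min(factor_grid) < 1.0:
        raise ConfigurationError("scaling factors must be >= 1")
    summaries = []
    warm = None
    for f in factor_grid:
        s, r = simulate_variant(variant, k, params, pvr=pvr, postcap_scale=f,
                                settings=settings, initial_state=warm)
        warm = r.final_state
        summaries.append(s)
    return SweepResult(
        axis="postcap_scale", grid=tuple(factor_grid), summaries=summaries,
        variant=variant, n_anomalous=k,
    )


# ---------------------------------------------------------------------------
# Baseline calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationTargets:
    """Clinical-normal anchors for the baseline (no-shunt) anatomy."""

    cardiac_output: float = 5.0  # L/min
    mean_pa: float = 16.0  # mmHg
    mean_ra: float = 8.0   # mmHg
    mean_aortic: float = 90.0  # mmHg
    # normalisation scales for the residuals (the accepted tolerances)
    scales: tuple[float, float, float, float] = (0.5, 3.0, 3.0, 10.0)


def _apply_calibration(params: ModelParameters, x: np.ndarray) -> ModelParameters:
    """x = [volume offset delta (mL), log systemic-R scale,
    log ventricular e_max scale, log RA elastance scale]."""
    dv, log_rs, log_emax, log_era = x
    comps = dict(params.compartments)
    for name in ("SYS-AR", "SYS-C"):
        comps[name] = replace(comps[name], r=comps[name].r * float(np.exp(log_rs)))
    chambers = dict(params.chambers)
    for name in ("LV", "RV"):
        chambers[name] = chambers[name].scaled(e_max_factor=float(np.exp(log_emax)))
    chambers["RA"] = chambers["RA"].scaled(
        e_max_factor=float(np.exp(log_era)), e_min_factor=float(np.exp(log_era))
    )
    return params.replace(
        compartments=comps, chambers=chambers,
        volume_offset=params.volume_offset + float(dv),
    )


def calibrate_baseline(
    targets: CalibrationTargets | None = None,
    params: ModelParameters | None = None,
    settings: SolverSettings | None = None,
    max_nfev: int = 25,
) -> ModelParameters:
    """Adjust stressed volume, systemic resistance and chamber elastances so
    the baseline anatomy hits the clinical anchors (CO, mean PA, mean RA,
    mean aortic pressure) at 1 WU.

    Bounded least squares over four scalar handles; raises with a
    calibration report if the anchors cannot be reached within bounds.
    """
    if targets is None:
        targets = CalibrationTargets()
    if params is None:
        params = default_parameters()
    if settings is None:
        settings = SolverSettings()
    warm: dict = {"state": None}

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _apply_calibration(params, x)
        model = build_model(AnatomyConfig(variant="baseline"), p)
        result = run_to_steady_state(model, settings, initial_state=warm["state"])
        warm["state"] = result.final_state
        s = compute_qp_qs(result, model, force=not result.converged)
        t, sc = targets, targets.scales
        return np.array([
            (s.qs - t.cardiac_output) / sc[0],
            (s.pressures["PA"]["mean"] - t.mean_pa) / sc[1],
            (s.pressures["RA"]["mean"] - t.mean_ra) / sc[2],
            (s.pressures["aorta"]["mean"] - t.mean_aortic) / sc[3],
        ])

    x0 = np.zeros(4)
    bounds = (
        np.array([-1500.0, np.log(0.25), np.log(0.25), np.log(0.25)]),
        np.array([1500.0, np.log(4.0), np.log(4.0), np.log(4.0)]),
    )
    fit = least_squares(
        residuals, x0, bounds=bounds, diff_step=[0.02, 0.02, 0.02, 0.02],
        xtol=1e-3, ftol=1e-4, gtol=None, max_nfev=max_nfev,
    )
    final = residuals(fit.x)
    if np.any(np.abs(final) > 1.0):
        raise ConfigurationError(
            "calibration failed to reach anchors within tolerance: "
            f"normalised residuals {np.round(final, 3).tolist()} "
            "(order: CO, mean PA, mean RA, mean aortic)"
        )
    logger.info("calibration residuals (normalised): %s", np.round(final, 4).tolist())
    return _apply_calibration(params, fit.x)


def reproduce_model_table(
    params: ModelParameters | None = None,
    settings: SolverSettings | None = None,
    pvr_baseline: float = 1.0,
    pvr_high: float = 8.0,
) -> pd.DataFrame:
    """The 2x3 (variant x vein-count) Qp/Qs grid at baseline PVR plus the
    RA-minus-VC differences at baseline and at high (8 WU) resistance."""
    rows = []
    cache: dict[tuple[str, int, float], float] = {}
    for variant in ("RA", "VC"):
        warm = None
        for k in (1, 2, 3):
            for pvr in (pvr_baseline, pvr_high):
                s, r = simulate_variant(variant, k, params, pvr=pvr,
                                        settings=settings, initial_state=warm)
                warm = r.final_state
                cache[(variant, k, pvr)] = s.qp_qs
            rows.append(
                dict(variant=variant, n_anomalous=k,
                     qp_qs=cache[(variant, k, pvr_baseline)],
                     qp_qs_at_high_pvr=cache[(variant, k, pvr_high)])
            )
    table = pd.DataFrame(rows)
    diff_base = {
        k: cache[("RA", k, pvr_baseline)] - cache[("VC", k, pvr_baseline)] for k in (1, 2, 3)
    }
    diff_high = {
        k: cache[("RA", k, pvr_high)] - cache[("VC", k, pvr_high)] for k in (1, 2, 3)
    }
    table["ra_minus_vc_at_baseline"] = [diff_base[k] for k in table["n_anomalous"]]
    table["ra_minus_vc_at_high_pvr"] = [diff_high[k] for k in table["n_anomalous"]]
    return table
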
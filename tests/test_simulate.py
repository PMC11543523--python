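"""ODE assembly, closed-form integrator oracles, conservation and
steady-state detection."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from papvr import (
    AnatomyConfig,
    SolverSettings,
    build_model,
    default_initial_state,
    default_parameters,
    integrate_cycles,
    load_config,
    rhs,
    run_to_steady_state,
    save_config,
    total_blood_volume,
)
from papvr.experiments import compute_qp_qs


def _passive_params():
    p = default_parameters()
    chambers = {
        name: ch.scaled(e_max_factor=ch.e_min / ch.e_max)
        for name, ch in p.chambers.items()
    }
    return p.replace(chambers=chambers, volume_offset=0.0)


def test_rhs_equilibrium_fixed_point():
    """Uniform pressures, zero flows and chamber volumes matching the node
    pressure give an exact fixed point of the passive system."""
    params = _passive_params()
    model = build_model(AnatomyConfig(variant="baseline"), params)
    p0 = 10.0
    y = np.zeros(len(model.state_layout))
    for i, name in enumerate(("LA", "LV", "RA", "RV")):
        ch = params.chambers[name]
        y[i] = ch.v_rest + p0 / ch.e_min
    y[4:13] = p0
    dy = rhs(0.37, y, model)
    assert np.max(np.abs(dy)) < 1e-12


def test_rl_branch_matches_closed_form():
    """Constant-pressure step on an R-L branch relaxes to dp/R with time
    constant L/R; the integrator at default tolerances tracks the closed
    form to better than 1e-6 relative."""
    r, l, dp = 0.18, 5e-4, 8.0
    settings = SolverSettings()
    sol = solve_ivp(lambda t, q: (dp - r * q[0]) / l, (0, 0.05), [0.0],
                    method=settings.method, rtol=settings.rel_tol,
                    atol=settings.abs_tol, t_eval=np.linspace(0, 0.05, 50))
    exact = dp / r * (1 - np.exp(-r / l * sol.t))
    err = np.abs(sol.y[0] - exact) / (dp / r)
    assert np.max(err) < 1e-6


def test_rc_node_matches_closed_form():
    """A capacitive node charged through a resistor follows the exponential
    RC solution to better than 1e-6 relative."""
    r, c, p_src = 0.5, 4.0, 20.0
    settings = SolverSettings()
    sol = solve_ivp(lambda t, p: (p_src - p[0]) / (r * c), (0, 10.0), [0.0],
                    method=settings.method, rtol=settings.rel_tol,
                    atol=settings.abs_tol, t_eval=np.linspace(0, 10, 50))
    exact = p_src * (1 - np.exp(-sol.t / (r * c)))
    err = np.abs(sol.y[0] - exact) / p_src
    assert np.max(err) < 1e-6


def test_total_blood_volume_conserved(baseline_result):
    """Closed loop: total volume drifts < 0.1 mL per cycle."""
    model = baseline_result.model
    npts = baseline_result.settings.output_points_per_cycle
    states = baseline_result.states
    vols = [total_blood_volume(states[k * npts], model)
            for k in range(baseline_result.n_cycles_run)]
    drift = np.max(np.abs(np.diff(vols)))
    assert drift < 0.1


def test_zero_mean_capacitor_current_at_steady_state(baseline_tight):
    """Periodicity implies zero net charge per cycle on every node."""
    model = baseline_tight.model
    final = baseline_tight.final_cycle_frame()
    period = model.chambers["LV"].period
    comp = model.compartments
    caps = {
        "p_sys_ar": comp["SYS-AR"].c, "p_sys_ven": comp["SYS-VEN"].c,
        "p_vc": comp["VC"].c, "p_pul_ar": comp["PUL-AR"].c,
        "p_ven_pool": comp["VEN-PUL-POOL"].c,
    }
    for i, v in enumerate(model.veins):
        caps[f"p_cap_{v.index}"] = comp["PUL-C-OX"].c * v.capillary_fraction
    for name, c in caps.items():
        series = final[name].to_numpy()
        mean_current = c * (series[-1] - series[0]) / period
        assert abs(mean_current) < 1e-3, name


def test_mean_flow_consistency(baseline_result):
    """Cycle-mean pulmonary valve flow = vein sum = tricuspid flow, and
    aortic = mitral, all to < 0.5%."""
    means = baseline_result.final_cycle_means
    q_pv = means["q_pv"]
    vein_sum = sum(means[f"q_vein_{i}"] for i in (1, 2, 3, 4))
    assert vein_sum == pytest.approx(q_pv, rel=5e-3)
    assert means["q_tv"] == pytest.approx(q_pv, rel=5e-3)
    assert means["q_mv"] == pytest.approx(means["q_av"], rel=5e-3)


def test_valve_rectification(baseline_result):
    """Mean reverse flow through each valve < 1% of mean forward flow."""
    final = baseline_result.final_cycle_frame()
    t = final["time"].to_numpy()
    for valve in ("q_mv", "q_av", "q_tv", "q_pv"):
        q = final[valve].to_numpy()
        fwd = np.trapezoid(np.clip(q, 0, None), t)
        rev = -np.trapezoid(np.clip(q, None, 0), t)
        assert rev < 0.01 * fwd, valve


def test_passive_heart_relaxes_to_no_flow():
    """Without the elastance pump the loop decays to equilibrium: all
    cycle-mean valve flows go to zero."""
    model = build_model(AnatomyConfig(variant="baseline"), _passive_params())
    res = integrate_cycles(model, SolverSettings(max_cycles=200), n_cycles=40)
    means = res.final_cycle_means
    for valve in ("q_mv", "q_av", "q_tv", "q_pv"):
        assert abs(means[valve]) < 0.5  # mL/s, decaying toward 0
    # later cycles are closer to equilibrium than early ones
    q0 = abs(res.cycle_means["q_av"].iloc[5])
    assert abs(means["q_av"]) < q0


def test_steady_state_detection_and_restart(baseline_result):
    assert baseline_result.converged
    assert baseline_result.n_cycles_run < 60
    assert baseline_result.final_rel_change < baseline_result.settings.steady_state_tol
    # fixed point of the cycle map: restarting converges immediately
    res2 = run_to_steady_state(baseline_result.model,
                               initial_state=baseline_result.final_state)
    assert res2.converged and res2.n_cycles_run <= 2


def test_non_convergence_is_flagged_not_raised():
    model = build_model(AnatomyConfig(variant="baseline"))
    res = run_to_steady_state(model, SolverSettings(max_cycles=2, steady_state_tol=1e-12))
    assert not res.converged
    with pytest.raises(Exception):
        compute_qp_qs(res)
    summary = compute_qp_qs(res, force=True)
    assert summary.qp > 0


def test_solver_tolerance_convergence(baseline_result):
    """Halving rel_tol changes the cycle-mean aortic flow by < 0.5%."""
    model = baseline_result.model
    tight = SolverSettings(rel_tol=5e-8, abs_tol=5e-10)
    res = run_to_steady_state(model, tight, initial_state=baseline_result.final_state)
    q_ref = baseline_result.final_cycle_means["q_av"]
    assert res.final_cycle_means["q_av"] == pytest.approx(q_ref, rel=5e-3)


def test_config_round_trip(tmp_path):
    params = default_parameters()
    anatomy = AnatomyConfig(variant="VC", anomalous_veins=frozenset({2, 3}),
                            pvr_wood_units=2.5)
    settings = SolverSettings(max_cycles=77)
    path = tmp_path / "model.yaml"
    save_config(path, params, anatomy, settings)
    p2, a2, s2 = load_config(path)
    assert a2 == anatomy
    assert s2.max_cycles == 77
    assert p2.chambers["LV"] == params.chambers["LV"]
    assert p2.compartments["VC"] == params.compartments["VC"]
    assert p2.volume_offset == params.volume_offset


def test_waveform_export_shape(baseline_result):
    df = baseline_result.to_frame()
    assert "time" in df.columns
    for name in baseline_result.state_names:
        assert name in df.columns
    for extra in ("q_mv", "q_av", "q_tv", "q_pv", "p_ra", "p_la"):
        assert extra in df.columns
    assert len(df) == len(baseline_result.time)


def test_default_initial_state_volume_offset():
    params = default_parameters()
    model = build_model(AnatomyConfig(variant="baseline"), params)
    y = default_initial_state(model)
    base = default_initial_state(
        build_model(AnatomyConfig(variant="baseline"), params.replace(volume_offset=0.0))
    )
    dv = total_blood_volume(y, model) - total_blood_volume(base, model)
    assert dv == pytest.approx(params.volume_offset, rel=1e-9)
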
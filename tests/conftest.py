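"""Shared fixtures: the calibrated parameter set and converged runs are
expensive (seconds each), so they are computed once per session."""

import pytest

from papvr import AnatomyConfig, build_model, run_to_steady_state
from papvr.experiments import calibrate_baseline, compute_qp_qs, simulate_variant


@pytest.fixture(scope="session")
def params():
    """Baseline-calibrated parameter set (clinical-normal anchors)."""
    return calibrate_baseline()


@pytest.fixture(scope="session")
def baseline_result(params):
    model = build_model(AnatomyConfig(variant="baseline"), params)
    result = run_to_steady_state(model)
    assert result.converged
    return result


@pytest.fixture(scope="session")
def baseline_tight(baseline_result):
    """Baseline refined to a much tighter periodicity tolerance (warm
    restart), for checks on limit-cycle properties such as zero-mean
    capacitor currents."""
    from papvr import SolverSettings

    settings = SolverSettings(steady_state_tol=3e-6)
    result = run_to_steady_state(baseline_result.model, settings,
                                 initial_state=baseline_result.final_state)
    assert result.converged
    return result


@pytest.fixture(scope="session")
def baseline_summary(baseline_result):
    return compute_qp_qs(baseline_result)


@pytest.fixture(scope="session")
def variant_summaries(params):
    """Steady-state summaries for every (variant, vein count, PVR) the
    reproduction experiments need, warm-started along each variant."""
    out = {}
    for variant in ("RA", "VC"):
        warm = None
        for k in (1, 2, 3):
            for wu in (1.0, 8.0):
                s, r = simulate_variant(variant, k, params, pvr=wu, initial_state=warm)
                warm = r.final_state
                out[(variant, k, wu)] = s
    return out
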
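"""Active elements of the closed loop: time-varying elastance chambers and diode valves.

The four cardiac chambers are modelled as pressure generators
``p = E(t) * (V - V_rest)`` where the elastance ``E(t)`` rises and falls
once per cardiac cycle, mimicking contraction.  The four valves are
non-ideal diodes: a small forward resistance when the pressure gradient is
favourable and a large (but finite) reverse resistance otherwise, so a
small regurgitant leak is permitted.

Units throughout the package: pressure mmHg, volume mL, time s
(resistance mmHg*s/mL, compliance mL/mmHg, inertance mmHg*s^2/mL).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ConfigurationError",
    "ElastanceParams",
    "ValveParams",
    "activation",
    "elastance",
    "chamber_pressure",
    "valve_flow",
]


class ConfigurationError(ValueError):
    """Raised when model parameters violate their invariants."""


@dataclass(frozen=True)
class ElastanceParams:
    """Per-chamber contraction model.

    Parameters
    ----------
    e_max, e_min:
        Peak and baseline elastance (mmHg/mL), ``e_max >= e_min > 0``.
    v_rest:
        Unstressed volume (mL) at which the chamber pressure is zero.
    t_onset:
        Activation onset as a fraction of the cycle period, in [0, 1).
    t_contract, t_relax:
        Durations of the contraction (upstroke) and relaxation
        (downstroke) phases, as fractions of the period;
        ``t_contract + t_relax <= 1``.
    period:
        Cardiac cycle length (s).
    """

    e_max: float
    e_min: float
    v_rest: float
    t_onset: float
    t_contract: float
    t_relax: float
    period: float

    def __post_init__(self) -> None:
        if not (self.e_max >= self.e_min > 0.0):
            raise ConfigurationError(
                f"require e_max >= e_min > 0, got e_max={self.e_max}, e_min={self.e_min}"
            )
        if self.v_rest < 0.0:
            raise ConfigurationError(f"v_rest must be >= 0, got {self.v_rest}")
        if not (0.0 <= self.t_onset < 1.0):
            raise ConfigurationError(f"t_onset must lie in [0, 1), got {self.t_onset}")
        if self.t_contract < 0.0 or self.t_relax < 0.0:
            raise ConfigurationError("timing fractions must be non-negative")
        if self.t_contract + self.t_relax > 1.0 + 1e-12:
            raise ConfigurationError(
                f"t_contract + t_relax must be <= 1, got {self.t_contract + self.t_relax}"
            )
        if self.period <= 0.0:
            raise ConfigurationError(f"period must be > 0, got {self.period}")

    def scaled(self, e_max_factor: float = 1.0, e_min_factor: float = 1.0) -> "ElastanceParams":
        """Return a copy with elastances multiplied by the given factors."""
        return replace(
            self, e_max=self.e_max * e_max_factor, e_min=self.e_min * e_min_factor
        )


@dataclass(frozen=True)
class ValveParams:
    """Non-ideal diode valve: forward and reverse resistances (mmHg*s/mL)."""

    r_open: float
    r_closed: float

    def __post_init__(self) -> None:
        if not (0.0 < self.r_open < self.r_closed):
            raise ConfigurationError(
                f"require 0 < r_open < r_closed, got {self.r_open}, {self.r_closed}"
            )
        if not np.isfinite(self.r_closed):
            raise ConfigurationError("r_closed must be finite (non-ideal diode)")


def activation(t, params: ElastanceParams):
    """Normalised activation in [0, 1]: raised-cosine up over ``t_contract``,
    raised-cosine down over ``t_relax``, zero in the remaining (diastolic)
    part of the cycle.  Periodic with ``params.period`` and continuous.

    Accepts scalar or array ``t``.
    """
    phase = np.mod(t / params.period - params.t_onset, 1.0)
    up = params.t_contract
    down = params.t_relax
    a = np.zeros_like(phase, dtype=float)
    if up > 0.0:
        in_up = phase < up
        a = np.where(in_up, 0.5 * (1.0 - np.cos(np.pi * phase / max(up, 1e-300))), a)
    if down > 0.0:
        in_down = (phase >= up) & (phase < up + down)
        a = np.where(
            in_down, 0.5 * (1.0 + np.cos(np.pi * (phase - up) / max(down, 1e-300))), a
        )
    if np.ndim(t) == 0:
        return float(a)
    return a


def elastance(t, params: ElastanceParams):
    """Time-varying elastance ``E(t) = e_min + (e_max - e_min) * activation(t)``."""
    return params.e_min + (params.e_max - params.e_min) * activation(t, params)


def chamber_pressure(volume, t, params: ElastanceParams):
    """Chamber pressure ``p = E(t) * (V - v_rest)`` (mmHg)."""
    return elastance(t, params) * (volume - params.v_rest)


def valve_flow(p_upstream, p_downstream, valve: ValveParams, smoothing_eps: float = 1e-3):
    """Flow through a non-ideal diode valve (mL/s).

    The conductance blends smoothly from ``1/r_closed`` to ``1/r_open``
    over a pressure window of width ``smoothing_eps`` (mmHg) around zero,
    keeping the ODE right-hand side continuously differentiable for the
    implicit solver.  Both branches pass through Q = 0 at dp = 0.
    """
    dp = np.asarray(p_upstream, dtype=float) - np.asarray(p_downstream, dtype=float)
    if smoothing_eps > 0.0:
        sigma = 0.5 * (1.0 + np.tanh(dp / smoothing_eps))
    else:
        sigma = np.where(dp > 0.0, 1.0, 0.0)
    g = sigma / valve.r_open + (1.0 - sigma) / valve.r_closed
    q = dp * g
    if np.ndim(p_upstream) == 0 and np.ndim(p_downstream) == 0:
        return float(q)
    return q
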
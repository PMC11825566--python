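"""Diffusion Model of Conflict (DMC) trial simulator.

DMC decomposes conflict-task processing into a controlled process — a
constant drift ``mu_c`` toward the correct response — and an automatic
process driven by the task-irrelevant information, whose expected
activation is a pulse: it rises, peaks, and passively decays back to zero.
The expected automatic activation at time ``t`` (ms) is the rescaled gamma
pulse

    E(t) = A * exp(-t / tau) * (t * e / ((a - 1) * tau)) ** (a - 1),

which vanishes at t -> 0 and t -> infinity and attains its maximum ``A``
exactly at t* = (a - 1) * tau.  The automatic drift is its derivative,

    dE/dt = E(t) * ((a - 1) / t - 1 / tau),

added to ``mu_c`` in the congruent condition, subtracted in the
incongruent one, and absent in the neutral one.  A small ``tau`` gives the
early pulse characteristic of the Simon task (negative-going delta plots);
a large ``tau`` gives the late pulse of flanker/Stroop tasks
(positive-going delta plots).

The speed-accuracy tradeoff is modeled purely through the boundary
separation ``boundary_b``; the per-focus defaults in
:data:`DMC_FOCUS_BOUNDARIES` keep the printed speed/accuracy anchors
(31.30/71.30 for the flanker-type pulse, 34.56/74.56 for the Simon-type
pulse) with the balanced focus at their midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._euler import SimulatedTrial, attach_nondecision, first_passage
from .core_design import Congruency, ResponseFocus

__all__ = [
    "DMCParams",
    "DMC_FOCUS_BOUNDARIES",
    "default_dmc_params",
    "automatic_activation",
    "automatic_drift",
    "condition_drift",
    "simulate_dmc",
]


@dataclass(frozen=True)
class DMCParams:
    """Full DMC parameterization.

    Units: evidence is arbitrary; time is ms, so drifts are evidence/ms and
    ``sigma`` is evidence per sqrt(ms).
    """

    A: float = 20.0  # pulse amplitude (peak automatic activation)
    tau: float = 150.0  # pulse characteristic time, ms
    shape_a: float = 2.0  # pulse shape, dimensionless > 1
    mu_c: float = 0.5  # controlled drift, evidence/ms
    sigma: float = 4.0  # diffusion coefficient, evidence/sqrt(ms)
    boundary_b: float = 51.30  # absorbing boundary, evidence units
    start_x0: float = 0.0
    ter_mean: float = 300.0  # non-decision mean, ms
    ter_sd: float = 30.0  # non-decision SD, ms
    dt: float = 1.0  # Euler step, ms
    max_time: float = 2500.0  # censoring horizon, ms

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("A must be nonnegative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.shape_a <= 1:
            raise ValueError("shape_a must exceed 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.boundary_b <= 0:
            raise ValueError("boundary_b must be positive")
        if abs(self.start_x0) >= self.boundary_b:
            raise ValueError("|start_x0| must be below boundary_b")
        if self.ter_sd < 0:
            raise ValueError("ter_sd must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.max_time < self.ter_mean:
            raise ValueError("max_time must be at least ter_mean")

    @property
    def pulse_peak_time(self) -> float:
        """Time at which the automatic pulse attains its maximum A, ms."""
        return (self.shape_a - 1.0) * self.tau


#: Per-focus boundary separation: flanker/stroop keep the printed
#: speed/accuracy anchors 31.30/71.30, simon 34.56/74.56; the balanced
#: focus sits at their midpoint.
DMC_FOCUS_BOUNDARIES: dict[str, dict[ResponseFocus, float]] = {
    "flanker": {
        ResponseFocus.SPEED: 31.30,
        ResponseFocus.BALANCED: 51.30,
        ResponseFocus.ACCURACY: 71.30,
    },
    "stroop": {
        ResponseFocus.SPEED: 31.30,
        ResponseFocus.BALANCED: 51.30,
        ResponseFocus.ACCURACY: 71.30,
    },
    "simon": {
        ResponseFocus.SPEED: 34.56,
        ResponseFocus.BALANCED: 54.56,
        ResponseFocus.ACCURACY: 74.56,
    },
}

#: Pulse timing by task: late peak for flanker/Stroop, early peak for Simon.
_TASK_TAU = {"flanker": 150.0, "stroop": 150.0, "simon": 30.0}


def default_dmc_params(task: str = "flanker", focus: ResponseFocus | str = ResponseFocus.BALANCED) -> DMCParams:
    """Task preset: pulse timing and boundary appropriate for the task/focus."""
    if task not in _TASK_TAU:
        raise ValueError(f"unknown task {task!r}; valid tasks: {', '.join(_TASK_TAU)}")
    focus = ResponseFocus(focus)
    return DMCParams(tau=_TASK_TAU[task], boundary_b=DMC_FOCUS_BOUNDARIES[task][focus])


def _check_t(t: np.ndarray | float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    return t


def automatic_activation(t: np.ndarray | float, params: DMCParams) -> np.ndarray | float:
    """Expected automatic activation E(t) of the pulse, evidence units."""
    t = _check_t(t)
    a1 = params.shape_a - 1.0
    out = params.A * np.exp(-t / params.tau) * (t * np.e / (a1 * params.tau)) ** a1
    return out if out.ndim else float(out)


def automatic_drift(t: np.ndarray | float, params: DMCParams) -> np.ndarray | float:
    """Automatic drift dE/dt, evidence/ms; zero at the pulse peak."""
    t = _check_t(t)
    a1 = params.shape_a - 1.0
    e_t = params.A * np.exp(-t / params.tau) * (t * np.e / (a1 * params.tau)) ** a1
    out = e_t * (a1 / t - 1.0 / params.tau)
    return out if out.ndim else float(out)


def condition_drift(
    t: np.ndarray | float, condition: Congruency | str, params: DMCParams
) -> np.ndarray | float:
    """Superimposed drift for one congruency condition.

    Congruent adds the automatic drift to the controlled drift, incongruent
    subtracts it, neutral carries the controlled drift alone — so
    congruent(t) + incongruent(t) = 2 mu_c for every t.
    """
    condition = Congruency(condition)
    if condition is Congruency.NEUTRAL:
        t = _check_t(t)
        out = np.broadcast_to(np.asarray(params.mu_c, dtype=float), t.shape).copy()
        return out if out.ndim else float(out)
    sign = 1.0 if condition is Congruency.CONGRUENT else -1.0
    auto = automatic_drift(t, params)
    return params.mu_c + sign * auto


def simulate_dmc(
    params: DMCParams, condition: Congruency | str, n: int, seed: int
) -> list[SimulatedTrial]:
    """Simulate ``n`` DMC trials in one congruency condition.

    Euler–Maruyama between symmetric boundaries ±boundary_b; upper-boundary
    absorption is a correct response.  RT adds a truncated-normal
    non-decision time.  The noise stream depends only on the seed and on
    absorption history, never on the condition label, so with ``A = 0`` the
    three conditions produce identical trial lists under the same seed.
    """
    condition = Congruency(condition)
    rng = np.random.default_rng(seed)
    decision_time, upper, censored = first_passage(
        lambda t: np.broadcast_to(
            np.asarray(condition_drift(t, condition, params), dtype=float), t.shape
        ),
        sigma=params.sigma,
        boundary=params.boundary_b,
        x0=params.start_x0,
        dt=params.dt,
        max_time=params.max_time,
        n=n,
        rng=rng,
    )
    return attach_nondecision(
        decision_time, upper, censored,
        ter_mean=params.ter_mean, ter_sd=params.ter_sd, rng=rng,
    )


def with_boundary(params: DMCParams, boundary: float) -> DMCParams:
    """Copy of ``params`` with a different boundary separation."""
    return replace(params, boundary_b=boundary)
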
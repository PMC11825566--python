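"""Shared Euler–Maruyama first-passage engine for the two diffusion models.

A single evidence accumulator starts at ``x0`` and evolves as

    X(t + dt) = X(t) + mu(t) dt + sigma sqrt(dt) eps,   eps ~ N(0, 1),

until it is absorbed at +b (mapped to a correct response) or -b (error).
The drift ``mu`` depends only on elapsed time, never on the state, so it is
precomputed on the step grid once per call; it is evaluated at step
midpoints (t_k = (k + 1/2) dt), which halves the weak discretization bias
relative to the left endpoint and keeps the evaluation strictly inside the
pulse's domain of definition.  Walks not absorbed by ``max_time`` are
censored.

The noise stream is consumed only by active (unabsorbed) walkers, so two
calls with the same seed and identical drift arrays produce bitwise
identical trajectories — the property the simulators rely on when the
conditions collapse onto a common generative law.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["SimulatedTrial", "first_passage", "attach_nondecision"]


@dataclass
class SimulatedTrial:
    """Outcome of one simulated diffusion trial.

    ``decision_time`` and ``rt`` are ``None`` for censored trials (no
    boundary reached within the censoring horizon); otherwise
    ``rt = decision_time + non-decision sample``.
    """

    decision_time: float | None
    rt: float | None
    correct: bool
    censored: bool


def first_passage(
    drift: Callable[[np.ndarray], np.ndarray],
    *,
    sigma: float,
    boundary: float,
    x0: float,
    dt: float,
    max_time: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate ``n`` first-passage times between symmetric boundaries.

    Returns ``(decision_time, upper, censored)`` arrays; ``decision_time``
    is NaN where ``censored``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(max_time / dt))
    t_mid = (np.arange(n_steps) + 0.5) * dt
    mu = np.asarray(drift(t_mid), dtype=float)

    x = np.full(n, float(x0))
    alive = np.arange(n)
    decision_time = np.full(n, np.nan)
    upper = np.zeros(n, dtype=bool)
    noise_scale = sigma * np.sqrt(dt)

    for k in range(n_steps):
        if alive.size == 0:
            break
        x = x + mu[k] * dt + noise_scale * rng.standard_normal(alive.size)
        hit_upper = x >= boundary
        hit_lower = x <= -boundary
        hit = hit_upper | hit_lower
        if hit.any():
            absorbed = alive[hit]
            decision_time[absorbed] = (k + 1) * dt
            upper[alive[hit_upper]] = True
            keep = ~hit
            x = x[keep]
            alive = alive[keep]

    censored = np.isnan(decision_time)
    return decision_time, upper, censored


def attach_nondecision(
    decision_time: np.ndarray,
    upper: np.ndarray,
    censored: np.ndarray,
    *,
    ter_mean: float,
    ter_sd: float,
    rng: np.random.Generator,
) -> list[SimulatedTrial]:
    """Add truncated-normal non-decision time and package trials.

    The non-decision component is Normal(ter_mean, ter_sd) truncated below
    at zero by resampling.  One draw is made per trial (censored trials
    included) so the stream layout does not depend on absorption outcomes.
    """
    n = decision_time.size
    ter = rng.normal(ter_mean, ter_sd, n)
    if ter_sd > 0:
        bad = ter < 0
        while bad.any():
            ter[bad] = rng.normal(ter_mean, ter_sd, int(bad.sum()))
            bad = ter < 0
    trials: list[SimulatedTrial] = []
    for i in range(n):
        if censored[i]:
            trials.append(SimulatedTrial(None, None, False, True))
        else:
            dtime = float(decision_time[i])
            trials.append(SimulatedTrial(dtime, dtime + float(ter[i]), bool(upper[i]), False))
    return trials
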
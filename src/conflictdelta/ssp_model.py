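"""Shrinking Spotlight Model (SSP) trial simulator.

SSP models flanker-type interference as spatial attention: a Gaussian
attention window centered on the target narrows linearly over time, so an
increasing share of attention falls on the target and the drift rate grows
toward the target's perceptual input.  The display is the standard
five-item flanker layout — unit-width items abutting, the target spanning
[-0.5, 0.5], an inner and an outer flanker pair.  At time ``t`` the
attention SD is

    s(t) = max(sd0 - shrink_rate * t, sd_min)

and the share of attention on each item is the Gaussian mass over its
interval.  The drift is

    v(t) = p * target_share + s_f * p * (inner + outer shares),

with ``s_f`` = +1 (congruent), 0 (neutral: flankers carry no response
signal), -1 (incongruent).  Early in an incongruent trial the flankers
outweigh the target and the drift is negative; it crosses zero exactly
once as the spotlight narrows.

Boundaries per response focus keep the printed speed/accuracy anchors 2000
and 4000 (balanced at 3000); the remaining scale parameters are calibrated
so that speed-focus accuracy lands in the observed 65–85% band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from ._euler import SimulatedTrial, attach_nondecision, first_passage
from .core_design import Congruency, ResponseFocus

__all__ = [
    "SSPParams",
    "SSP_FOCUS_BOUNDARIES",
    "default_ssp_params",
    "AttentionShares",
    "attention_sd",
    "attention_shares",
    "ssp_drift",
    "simulate_ssp",
]


@dataclass(frozen=True)
class SSPParams:
    """Full SSP parameterization (time in ms, space in item widths)."""

    p_strength: float = 8.0  # perceptual input per fully attended item, evidence/ms
    sd0: float = 1.8  # initial attention SD, item widths
    shrink_rate: float = 0.01  # SD decrease, item widths/ms
    sd_min: float = 0.001  # SD floor
    sigma: float = 100.0  # diffusion coefficient, evidence/sqrt(ms)
    boundary_B: float = 3000.0
    ter_mean: float = 300.0
    ter_sd: float = 30.0
    dt: float = 1.0
    max_time: float = 2500.0
    item_width: float = 1.0
    flankers_per_side: int = 2

    def __post_init__(self) -> None:
        if not (self.sd0 > self.sd_min > 0):
            raise ValueError("require sd0 > sd_min > 0")
        if self.shrink_rate < 0:
            raise ValueError("shrink_rate must be nonnegative")
        if self.p_strength < 0:
            raise ValueError("p_strength must be nonnegative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.boundary_B <= 0:
            raise ValueError("boundary_B must be positive")
        if self.ter_sd < 0:
            raise ValueError("ter_sd must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.item_width != 1.0 or self.flankers_per_side != 2:
            raise ValueError("the five-item unit-width layout is fixed")


#: Boundary per response focus: the printed speed/accuracy anchors 2000 and
#: 4000, with the balanced focus at their midpoint.
SSP_FOCUS_BOUNDARIES: dict[ResponseFocus, float] = {
    ResponseFocus.SPEED: 2000.0,
    ResponseFocus.BALANCED: 3000.0,
    ResponseFocus.ACCURACY: 4000.0,
}


def default_ssp_params(focus: ResponseFocus | str = ResponseFocus.BALANCED) -> SSPParams:
    """Flanker-calibrated preset at the boundary for one response focus."""
    return SSPParams(boundary_B=SSP_FOCUS_BOUNDARIES[ResponseFocus(focus)])


@dataclass(frozen=True)
class AttentionShares:
    """Attention mass on the target, inner flanker pair and outer pair.

    Shares sum to at most 1; mass beyond ±2.5 item widths falls outside
    the display.
    """

    target: float | np.ndarray
    inner_pair: float | np.ndarray
    outer_pair: float | np.ndarray


def attention_sd(t: np.ndarray | float, params: SSPParams) -> np.ndarray | float:
    """Attention SD at time t: linear shrink floored at sd_min."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    out = np.maximum(params.sd0 - params.shrink_rate * t, params.sd_min)
    return out if out.ndim else float(out)


def attention_shares(t: np.ndarray | float, params: SSPParams) -> AttentionShares:
    """Gaussian attention mass per display item at time t.

    The target occupies [-0.5, 0.5]; the inner pair [±0.5, ±1.5]; the
    outer pair [±1.5, ±2.5].
    """
    s = np.asarray(attention_sd(t, params), dtype=float)
    target = norm.cdf(0.5 / s) - norm.cdf(-0.5 / s)
    inner = 2.0 * (norm.cdf(1.5 / s) - norm.cdf(0.5 / s))
    outer = 2.0 * (norm.cdf(2.5 / s) - norm.cdf(1.5 / s))
    if s.ndim == 0:
        return AttentionShares(float(target), float(inner), float(outer))
    return AttentionShares(target, inner, outer)


_SIGN = {Congruency.CONGRUENT: 1.0, Congruency.NEUTRAL: 0.0, Congruency.INCONGRUENT: -1.0}


def ssp_drift(
    t: np.ndarray | float, condition: Congruency | str, params: SSPParams
) -> np.ndarray | float:
    """Time-varying drift for one congruency condition, evidence/ms."""
    condition = Congruency(condition)
    shares = attention_shares(t, params)
    flanker = np.asarray(shares.inner_pair) + np.asarray(shares.outer_pair)
    out = params.p_strength * np.asarray(shares.target) + _SIGN[condition] * params.p_strength * flanker
    return out if np.ndim(out) else float(out)


def simulate_ssp(
    params: SSPParams, condition: Congruency | str, n: int, seed: int
) -> list[SimulatedTrial]:
    """Simulate ``n`` SSP trials in one congruency condition.

    Same Euler–Maruyama / absorption / non-decision / censoring contract as
    :func:`conflictdelta.dmc_model.simulate_dmc`, with boundaries
    ±boundary_B.
    """
    condition = Congruency(condition)
    rng = np.random.default_rng(seed)
    decision_time, upper, censored = first_passage(
        lambda t: np.broadcast_to(
            np.asarray(ssp_drift(t, condition, params), dtype=float), t.shape
        ),
        sigma=params.sigma,
        boundary=params.boundary_B,
        x0=0.0,
        dt=params.dt,
        max_time=params.max_time,
        n=n,
        rng=rng,
    )
    return attach_nondecision(
        decision_time, upper, censored,
        ter_mean=params.ter_mean, ter_sd=params.ter_sd, rng=rng,
    )


def with_boundary(params: SSPParams, boundary: float) -> SSPParams:
    """Copy of ``params`` with a different boundary separation."""
    return replace(params, boundary_B=boundary)
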
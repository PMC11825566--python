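"""Synthetic speed-accuracy-tradeoff experiments from either diffusion model.

A synthetic participant runs the full protocol of one experiment: a
practice phase at the balanced boundary, deadline calibration from the
practice RT distribution (mean - SD for speed, mean + SD for balanced,
mean + 3 SD for accuracy), then the blocked test schedule in which each
block carries a single response focus whose boundary is looked up from the
participant's focus -> boundary map.  After every block the deadline of
that block's focus is nudged toward its target accuracy by a proportional
controller.  Deadline violations are notified, never removed: responses
slower than the deadline are recorded with ``exceeded_deadline`` set.

Cohorts add normally distributed between-participant variability on the
primary drift parameter (``mu_c`` for DMC, ``p_strength`` for SSP) and on
the mean non-decision time, reproducing the spread of individual mean RTs
seen in group data.  Per-participant seeds are derived deterministically
from the cohort seed and participant index, so a cohort equals the
concatenation of its individually generated participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import dmc_model, ssp_model
from .core_design import (
    TARGET_ACCURACY,
    Congruency,
    ExperimentDesign,
    ResponseFocus,
    ScheduleSlot,
    TrialRecord,
    generate_schedule,
)

__all__ = [
    "Deadlines",
    "Variability",
    "ParticipantSpec",
    "calibrate_deadlines",
    "adapt_deadline",
    "synthesize_participant",
    "synthesize_cohort",
    "participant_seed",
    "perturb_spec",
    "default_participant_spec",
]

#: Deadlines are never adapted below this floor, ms.
DEADLINE_FLOOR = 150.0


@dataclass
class Deadlines:
    """Per-focus response deadlines, ms (speed <= balanced <= accuracy)."""

    speed: float
    balanced: float
    accuracy: float

    def get(self, focus: ResponseFocus) -> float:
        return getattr(self, ResponseFocus(focus).value)

    def set(self, focus: ResponseFocus, value: float) -> None:
        setattr(self, ResponseFocus(focus).value, value)


@dataclass(frozen=True)
class Variability:
    """Between-participant perturbation SDs (zero disables a component)."""

    drift_sd: float = 0.0  # SD on mu_c (DMC) or p_strength (SSP)
    ter_sd: float = 0.0  # SD on the mean non-decision time, ms

    def __post_init__(self) -> None:
        if self.drift_sd < 0 or self.ter_sd < 0:
            raise ValueError("perturbation SDs must be nonnegative")


@dataclass(frozen=True)
class ParticipantSpec:
    """Generative description of one synthetic participant."""

    participant_id: str
    model: str  # 'dmc' or 'ssp'
    base_params: dmc_model.DMCParams | ssp_model.SSPParams
    focus_boundaries: dict[ResponseFocus, float]
    variability: Variability = field(default_factory=Variability)

    def __post_init__(self) -> None:
        if self.model not in ("dmc", "ssp"):
            raise ValueError("model must be 'dmc' or 'ssp'")
        missing = [f for f in ResponseFocus if f not in self.focus_boundaries]
        if missing:
            raise ValueError(f"focus_boundaries missing levels: {missing}")


def default_participant_spec(
    model: str, task: str, participant_id: str = "P000", *, variability: Variability | None = None
) -> ParticipantSpec:
    """Study-condition preset for one synthetic participant.

    Boundary maps carry the printed speed/accuracy anchors of each model;
    default variability gives individual mean-RT spreads of a few tens of
    ms, typical of small within-subject samples.
    """
    if model == "dmc":
        base = dmc_model.default_dmc_params(task)
        boundaries = dict(dmc_model.DMC_FOCUS_BOUNDARIES[task])
        var = variability if variability is not None else Variability(drift_sd=0.05, ter_sd=20.0)
    elif model == "ssp":
        if task != "flanker":
            raise ValueError("the SSP preset models the flanker display only")
        base = ssp_model.default_ssp_params()
        boundaries = dict(ssp_model.SSP_FOCUS_BOUNDARIES)
        var = variability if variability is not None else Variability(drift_sd=0.8, ter_sd=20.0)
    else:
        raise ValueError("model must be 'dmc' or 'ssp'")
    return ParticipantSpec(participant_id, model, base, boundaries, var)


def calibrate_deadlines(practice_rts: list[float] | np.ndarray) -> Deadlines:
    """Deadlines from the practice RT distribution.

    speed = mean - SD, balanced = mean + SD, accuracy = mean + 3 SD, with
    the sample SD (n - 1 denominator).  Needs at least two RTs.
    """
    rts = np.asarray(practice_rts, dtype=float)
    if rts.size < 2:
        raise ValueError("need at least 2 practice RTs to compute an SD")
    m = float(rts.mean())
    sd = float(rts.std(ddof=1))
    return Deadlines(speed=m - sd, balanced=m + sd, accuracy=m + 3.0 * sd)


def adapt_deadline(
    current: float, observed_accuracy: float, target_accuracy: float, gain: float = 0.5
) -> float:
    """Proportional deadline adjustment toward a target accuracy.

    Returns ``current * (1 - gain * (observed - target))`` floored at
    150 ms: over-accurate performance shortens the deadline, under-accurate
    performance lengthens it, and on-target performance leaves it alone.
    """
    if current <= 0:
        raise ValueError("current deadline must be positive")
    for name, p in (("observed_accuracy", observed_accuracy), ("target_accuracy", target_accuracy)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be a proportion in [0, 1]")
    return max(current * (1.0 - gain * (observed_accuracy - target_accuracy)), DEADLINE_FLOOR)


def _simulate(spec: ParticipantSpec, boundary: float, condition: Congruency, n: int, seed: int):
    if spec.model == "dmc":
        params = replace(spec.base_params, boundary_b=boundary)
        return dmc_model.simulate_dmc(params, condition, n, seed)
    params = replace(spec.base_params, boundary_B=boundary)
    return ssp_model.simulate_ssp(params, condition, n, seed)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def synthesize_participant(
    design: ExperimentDesign, spec: ParticipantSpec, seed: int, *, gain: float = 0.5
) -> list[TrialRecord]:
    """Run one synthetic participant through the full experiment.

    Practice is simulated at the balanced boundary with an equal congruency
    mix; its non-censored RTs calibrate the deadlines.  Each test block is
    then simulated at its focus's boundary (grouping the block's trials by
    congruency for vectorized simulation, then restoring schedule order),
    and afterwards that focus's deadline is adapted toward its target
    accuracy.  Deterministic under ``seed``.
    """
    root = np.random.SeedSequence(seed)
    practice_ss, schedule_ss, blocks_ss = root.spawn(3)

    # practice at the balanced boundary, equal congruency mix
    n_per = design.practice_trials // len(Congruency)
    counts = {c: n_per for c in Congruency}
    counts[Congruency.NEUTRAL] += design.practice_trials - n_per * len(Congruency)
    practice_rts: list[float] = []
    bal_boundary = spec.focus_boundaries[ResponseFocus.BALANCED]
    for cond, cond_ss in zip(Congruency, practice_ss.spawn(len(Congruency))):
        if counts[cond] == 0:
            continue
        trials = _simulate(spec, bal_boundary, cond, counts[cond], _child_seed(cond_ss))
        practice_rts.extend(t.rt for t in trials if t.rt is not None)
    deadlines = calibrate_deadlines(practice_rts)

    schedule = generate_schedule(design, _child_seed(schedule_ss))
    records: list[TrialRecord] = []
    block_seeds = blocks_ss.spawn(design.n_blocks)
    for block_index in range(design.n_blocks):
        slots = [s for s in schedule if s.block_index == block_index]
        focus = slots[0].focus
        boundary = spec.focus_boundaries[focus]
        deadline = deadlines.get(focus)
        # simulate per congruency group, then restore schedule order
        by_cond: dict[Congruency, list] = {}
        for cond, cond_ss in zip(Congruency, block_seeds[block_index].spawn(len(Congruency))):
            k = sum(1 for s in slots if s.congruency is cond)
            by_cond[cond] = (
                _simulate(spec, boundary, cond, k, _child_seed(cond_ss)) if k else []
            )
        cursor = {c: 0 for c in Congruency}
        block_records: list[TrialRecord] = []
        for trial_index, slot in enumerate(slots):
            sim = by_cond[slot.congruency][cursor[slot.congruency]]
            cursor[slot.congruency] += 1
            rt = sim.rt
            correct = bool(sim.correct) and rt is not None
            block_records.append(
                TrialRecord(
                    participant_id=spec.participant_id,
                    task=design.task,
                    focus=focus,
                    congruency=slot.congruency,
                    block_index=block_index,
                    trial_index=trial_index,
                    rt=rt,
                    correct=correct,
                    deadline=deadline,
                    exceeded_deadline=(rt is None) or (rt > deadline),
                    flagged_fast=(rt is not None and rt < 150.0),
                )
            )
        records.extend(block_records)
        observed = float(np.mean([r.correct for r in block_records]))
        deadlines.set(focus, adapt_deadline(deadline, observed, TARGET_ACCURACY[focus], gain))
    return records


def participant_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-participant seed derived from the cohort seed."""
    return _child_seed(np.random.SeedSequence([cohort_seed, index]))


def perturb_spec(base_spec: ParticipantSpec, cohort_seed: int, index: int) -> ParticipantSpec:
    """Participant ``index``'s spec: perturbed parameters, unique id."""
    rng = np.random.default_rng(np.random.SeedSequence([cohort_seed, index, 1]))
    var = base_spec.variability
    params = base_spec.base_params
    if var.drift_sd > 0:
        if base_spec.model == "dmc":
            mu = max(params.mu_c + rng.normal(0.0, var.drift_sd), 0.05)
            params = replace(params, mu_c=mu)
        else:
            p = max(params.p_strength + rng.normal(0.0, var.drift_sd), 0.5)
            params = replace(params, p_strength=p)
    if var.ter_sd > 0:
        ter = max(params.ter_mean + rng.normal(0.0, var.ter_sd), 100.0)
        params = replace(params, ter_mean=ter)
    return replace(
        base_spec,
        participant_id=f"{base_spec.participant_id}-{index:03d}",
        base_params=params,
    )


def synthesize_cohort(
    design: ExperimentDesign,
    base_spec: ParticipantSpec,
    n_participants: int,
    seed: int,
    *,
    gain: float = 0.5,
) -> list[TrialRecord]:
    """Concatenated trial logs of a perturbed synthetic cohort."""
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    records: list[TrialRecord] = []
    for i in range(n_participants):
        spec_i = perturb_spec(base_spec, seed, i)
        records.extend(
            synthesize_participant(design, spec_i, participant_seed(seed, i), gain=gain)
        )
    return records
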
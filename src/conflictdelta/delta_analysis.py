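"""Delta-plot decomposition of congruency effects into facilitation and inhibition.

The congruency effect — the RT cost of incongruent relative to congruent
irrelevant information — conflates two components that a neutral condition
separates: *facilitation* (neutral minus congruent: the gain from
compatible irrelevant information) and *inhibition* (incongruent minus
neutral: the cost of incompatible information).  Their sum telescopes back
to the congruency effect, so at every RT percentile

    d_cong(p) = d_fac(p) + d_inh(p)

holds exactly.  This module computes these delta curves per participant
from RT quantiles of correct trials, Vincentizes them (averages
per-participant quantile values at matched probabilities) to the group
level, and builds conditional-accuracy-style percent-error delta functions
from RT-binned error rates.

Filtering follows the protocol of the underlying experiments: no trial is
removed on the basis of its RT (the deadline manipulation makes fast and
slow responses part of the design), but anticipatory responses below
150 ms are flagged, and participants with too many flags or with overall
accuracy below 75% are dropped entirely.  RT analyses use correct trials
only; error analyses use all responded trials.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_design import Congruency, ResponseFocus, TrialRecord, records_to_frame

__all__ = [
    "TEN_BIN_GRID",
    "EIGHT_BIN_GRID",
    "DeltaCurve",
    "CAFCurve",
    "AnalysisSet",
    "filter_trials",
    "rt_quantiles",
    "participant_delta_curve",
    "vincentize",
    "group_delta_curve",
    "caf_curves",
    "group_caf_curve",
    "condition_summaries",
    "quantile_long_table",
    "caf_long_table",
]

logger = logging.getLogger(__name__)

#: Ten-percentile grid (5%, 15%, ..., 95%) used by the flanker and Stroop analyses.
TEN_BIN_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.10), 3))
#: Eight-percentile grid (6.25%, 18.75%, ..., 93.75%) used by the Simon analysis.
EIGHT_BIN_GRID = tuple(np.round(np.arange(0.0625, 1.0, 0.125), 5))

GRIDS = {"ten": TEN_BIN_GRID, "eight": EIGHT_BIN_GRID}


@dataclass
class DeltaCurve:
    """Facilitation/inhibition/congruency differences on a percentile grid.

    ``x_rt`` is the plotting abscissa: by default the mean of the three
    condition quantiles at each percentile.  The additivity identity
    ``d_cong = d_fac + d_inh`` holds elementwise to floating tolerance.
    """

    probs: np.ndarray
    x_rt: np.ndarray
    d_fac: np.ndarray
    d_inh: np.ndarray
    d_cong: np.ndarray
    focus: ResponseFocus
    n_participants: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        for name in ("x_rt", "d_fac", "d_inh", "d_cong"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != self.probs.shape:
                raise ValueError(f"{name} must match probs in length")
        if np.any(np.diff(self.probs) <= 0):
            raise ValueError("probs must be strictly increasing")
        self.focus = ResponseFocus(self.focus)


@dataclass
class CAFCurve:
    """RT-binned error rates per condition and their delta functions.

    ``d_fac_pe = pe_neutral - pe_congruent`` and
    ``d_inh_pe = pe_incongruent - pe_neutral``; ``x_rt`` is the mean
    binned RT across the three conditions.
    """

    bin_centers: np.ndarray
    pe_congruent: np.ndarray
    pe_neutral: np.ndarray
    pe_incongruent: np.ndarray
    d_fac_pe: np.ndarray
    d_inh_pe: np.ndarray
    x_rt: np.ndarray
    focus: ResponseFocus
    n_participants: int = 1

    def __post_init__(self) -> None:
        for name in (
            "bin_centers", "pe_congruent", "pe_neutral", "pe_incongruent",
            "d_fac_pe", "d_inh_pe", "x_rt",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        for name in ("pe_congruent", "pe_neutral", "pe_incongruent"):
            v = getattr(self, name)
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        self.focus = ResponseFocus(self.focus)


@dataclass
class AnalysisSet:
    """Filtered trial tables ready for RT and error analyses.

    ``rt_trials`` holds correct, non-omitted trials (RT analyses);
    ``all_trials`` holds correct and error trials of retained participants
    (error analyses).  ``exclusion_log`` records removed participants and
    skipped analysis cells with reasons.
    """

    rt_trials: pd.DataFrame
    all_trials: pd.DataFrame
    exclusion_log: list[str]

    @property
    def participants(self) -> list[str]:
        return sorted(self.all_trials["participant_id"].unique())


def filter_trials(
    records: list[TrialRecord],
    *,
    fast_flag_threshold: float = 0.10,
    min_accuracy: float = 0.75,
) -> AnalysisSet:
    """Apply participant-level exclusions and split RT/error trial sets.

    No trial is excluded by RT.  A participant is removed entirely when
    their proportion of flagged (< 150 ms) responses exceeds
    ``fast_flag_threshold`` or their overall accuracy falls below
    ``min_accuracy``.
    """
    df = records_to_frame(records)
    log: list[str] = []
    keep: list[str] = []
    for pid, sub in df.groupby("participant_id", sort=True, observed=True):
        flagged = float(sub["flagged_fast"].mean())
        accuracy = float(sub["correct"].mean())
        if accuracy < min_accuracy:
            log.append(f"participant {pid} removed: percent correct {100 * accuracy:.1f}% < {100 * min_accuracy:.0f}%")
        elif flagged > fast_flag_threshold:
            log.append(f"participant {pid} removed: {100 * flagged:.1f}% responses flagged below 150 ms")
        else:
            keep.append(pid)
    for line in log:
        logger.warning(line)
    all_trials = df[df["participant_id"].isin(keep)].reset_index(drop=True)
    if all_trials.empty:
        raise ValueError("all participants excluded; nothing to analyze")
    rt_trials = all_trials[all_trials["correct"] & all_trials["rt"].notna()].reset_index(drop=True)
    return AnalysisSet(rt_trials=rt_trials, all_trials=all_trials, exclusion_log=log)


def rt_quantiles(values, probs) -> np.ndarray:
    """Linear-interpolation quantiles of an RT sample.

    Uses the order-statistic convention that places the k-th of n sorted
    values at probability (k - 1)/(n - 1), clamping beyond the extremes —
    numpy's ``linear`` method.  Fixing the convention keeps outputs
    bit-comparable across implementations.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty RT sample")
    probs = np.asarray(probs, dtype=float)
    if np.any((probs <= 0) | (probs >= 1)) or np.any(np.diff(probs) <= 0):
        raise ValueError("probs must be strictly increasing within (0, 1)")
    return np.quantile(values, probs, method="linear")


def participant_delta_curve(
    analysis_set: AnalysisSet,
    participant: str,
    focus: ResponseFocus | str,
    probs=TEN_BIN_GRID,
) -> DeltaCurve:
    """Facilitation/inhibition/congruency deltas for one participant and focus.

    Quantiles are computed per congruency condition from correct trials;
    every condition must contribute at least one trial.
    """
    focus = ResponseFocus(focus)
    sub = analysis_set.rt_trials
    sub = sub[(sub["participant_id"] == participant) & (sub["focus"] == focus.value)]
    q = {}
    for cond in Congruency:
        rts = sub.loc[sub["congruency"] == cond.value, "rt"].to_numpy()
        if rts.size == 0:
            raise ValueError(
                f"participant {participant}, focus {focus.value}: no correct trials in {cond.value}"
            )
        q[cond] = rt_quantiles(rts, probs)
    qc, qn, qi = q[Congruency.CONGRUENT], q[Congruency.NEUTRAL], q[Congruency.INCONGRUENT]
    return DeltaCurve(
        probs=np.asarray(probs, dtype=float),
        x_rt=(qc + qn + qi) / 3.0,
        d_fac=qn - qc,
        d_inh=qi - qn,
        d_cong=qi - qc,
        focus=focus,
        n_participants=1,
    )


def vincentize(curves: list[DeltaCurve]) -> DeltaCurve:
    """Group-average per-participant delta curves at matched probabilities."""
    if not curves:
        raise ValueError("no curves to vincentize")
    first = curves[0]
    for c in curves[1:]:
        if not np.allclose(c.probs, first.probs) or c.focus is not first.focus:
            raise ValueError("curves must share the percentile grid and focus")
    return DeltaCurve(
        probs=first.probs.copy(),
        x_rt=np.mean([c.x_rt for c in curves], axis=0),
        d_fac=np.mean([c.d_fac for c in curves], axis=0),
        d_inh=np.mean([c.d_inh for c in curves], axis=0),
        d_cong=np.mean([c.d_cong for c in curves], axis=0),
        focus=first.focus,
        n_participants=sum(c.n_participants for c in curves),
    )


def group_delta_curve(
    analysis_set: AnalysisSet, focus: ResponseFocus | str, probs=TEN_BIN_GRID
) -> DeltaCurve:
    """Vincentized delta curve over all analyzable participants at one focus."""
    curves = []
    for pid in analysis_set.participants:
        try:
            curves.append(participant_delta_curve(analysis_set, pid, focus, probs))
        except ValueError as err:
            analysis_set.exclusion_log.append(f"delta curve skipped: {err}")
            logger.warning("delta curve skipped: %s", err)
    if not curves:
        raise ValueError(f"no participant has all three conditions at focus {focus}")
    return vincentize(curves)


def _rank_bins(rts: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Split trial indices into n_bins equal-probability RT bins.

    Rank-based splitting (stable sort, near-equal bin counts) is the
    discrete counterpart of cutting at within-condition RT quantiles; it
    guarantees nonempty, equally filled bins even with tied RTs.
    """
    order = np.argsort(rts, kind="stable")
    return np.array_split(order, n_bins)


def caf_curves(
    analysis_set: AnalysisSet,
    participant: str,
    focus: ResponseFocus | str,
    n_bins: int = 5,
) -> CAFCurve:
    """Binned percent-error delta functions for one participant and focus.

    Correct and error trials are pooled per congruency condition, binned
    by RT into ``n_bins`` equal-probability bins within that condition,
    and the per-bin error rate computed.  Bin centers sit at
    (2k - 1)/(2 n_bins).  The bin-count-weighted mean of the per-bin error
    rates reproduces the condition's overall error rate exactly.
    """
    focus = ResponseFocus(focus)
    sub = analysis_set.all_trials
    sub = sub[
        (sub["participant_id"] == participant)
        & (sub["focus"] == focus.value)
        & sub["rt"].notna()
    ]
    pe: dict[Congruency, np.ndarray] = {}
    mean_rt: dict[Congruency, np.ndarray] = {}
    for cond in Congruency:
        cond_sub = sub[sub["congruency"] == cond.value]
        if len(cond_sub) < n_bins:
            raise ValueError(
                f"participant {participant}, focus {focus.value}, {cond.value}: "
                f"{len(cond_sub)} responded trials < {n_bins} bins"
            )
        rts = cond_sub["rt"].to_numpy()
        correct = cond_sub["correct"].to_numpy()
        bins = _rank_bins(rts, n_bins)
        pe[cond] = np.array([1.0 - correct[b].mean() for b in bins])
        mean_rt[cond] = np.array([rts[b].mean() for b in bins])
    centers = (2.0 * np.arange(1, n_bins + 1) - 1.0) / (2.0 * n_bins)
    return CAFCurve(
        bin_centers=centers,
        pe_congruent=pe[Congruency.CONGRUENT],
        pe_neutral=pe[Congruency.NEUTRAL],
        pe_incongruent=pe[Congruency.INCONGRUENT],
        d_fac_pe=pe[Congruency.NEUTRAL] - pe[Congruency.CONGRUENT],
        d_inh_pe=pe[Congruency.INCONGRUENT] - pe[Congruency.NEUTRAL],
        x_rt=np.mean([mean_rt[c] for c in Congruency], axis=0),
        focus=focus,
    )


def group_caf_curve(
    analysis_set: AnalysisSet, focus: ResponseFocus | str, n_bins: int = 5
) -> CAFCurve:
    """Participant-averaged percent-error delta curve at one focus."""
    curves = []
    for pid in analysis_set.participants:
        try:
            curves.append(caf_curves(analysis_set, pid, focus, n_bins))
        except ValueError as err:
            analysis_set.exclusion_log.append(f"CAF skipped: {err}")
            logger.warning("CAF skipped: %s", err)
    if not curves:
        raise ValueError(f"no participant has enough trials at focus {focus}")
    first = curves[0]
    mean = lambda name: np.mean([getattr(c, name) for c in curves], axis=0)
    return CAFCurve(
        bin_centers=first.bin_centers.copy(),
        pe_congruent=mean("pe_congruent"),
        pe_neutral=mean("pe_neutral"),
        pe_incongruent=mean("pe_incongruent"),
        d_fac_pe=mean("d_fac_pe"),
        d_inh_pe=mean("d_inh_pe"),
        x_rt=mean("x_rt"),
        focus=first.focus,
        n_participants=len(curves),
    )


def condition_summaries(analysis_set: AnalysisSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean RT and percent correct per focus x congruency.

    Returns ``(participant_table, group_table)``.  Mean RT uses correct
    trials only; percent correct uses all trials; the group table adds the
    standard error across participant means.
    """
    keys = ["focus", "congruency"]
    rt = (
        analysis_set.rt_trials.groupby(["participant_id", *keys], observed=True)["rt"]
        .mean()
        .rename("mean_rt")
    )
    pc = (
        analysis_set.all_trials.groupby(["participant_id", *keys], observed=True)["correct"]
        .mean()
        .mul(100.0)
        .rename("percent_correct")
    )
    participant_table = pd.concat([rt, pc], axis=1).reset_index()
    grouped = participant_table.groupby(keys, observed=True)
    n = grouped["participant_id"].nunique()
    group_table = grouped[["mean_rt", "percent_correct"]].agg(["mean", "sem"])
    group_table.columns = ["_".join(c) for c in group_table.columns]
    group_table = group_table.rename(
        columns={
            "mean_rt_mean": "mean_rt",
            "mean_rt_sem": "se_rt",
            "percent_correct_mean": "percent_correct",
            "percent_correct_sem": "se_percent_correct",
        }
    )
    group_table["n_participants"] = n
    group_table = group_table.fillna({"se_rt": 0.0, "se_percent_correct": 0.0}).reset_index()
    return participant_table, group_table


def quantile_long_table(analysis_set: AnalysisSet, probs=TEN_BIN_GRID) -> pd.DataFrame:
    """Per-participant RT quantiles in long form for the distributional ANOVA.

    One row per participant x focus x congruency x percentile; participants
    missing any cell are dropped (with a logged reason) to keep the design
    balanced.
    """
    rows = []
    incomplete = set()
    for (pid, focus, cong), sub in analysis_set.rt_trials.groupby(
        ["participant_id", "focus", "congruency"], observed=False
    ):
        if sub.empty:
            incomplete.add(pid)
            continue
        q = rt_quantiles(sub["rt"].to_numpy(), probs)
        rows.extend(
            {"participant_id": pid, "focus": focus, "congruency": cong, "percentile": p, "rt": v}
            for p, v in zip(probs, q)
        )
    table = pd.DataFrame(rows)
    if incomplete:
        for pid in sorted(incomplete):
            analysis_set.exclusion_log.append(
                f"quantile table: participant {pid} dropped (missing a focus x congruency cell)"
            )
        table = table[~table["participant_id"].isin(incomplete)].reset_index(drop=True)
    return table


def caf_long_table(analysis_set: AnalysisSet, n_bins: int = 5) -> pd.DataFrame:
    """Per-participant binned error rates in long form for the error ANOVA."""
    rows = []
    for pid in analysis_set.participants:
        per_focus = {}
        try:
            for focus in ResponseFocus:
                per_focus[focus] = caf_curves(analysis_set, pid, focus, n_bins)
        except ValueError as err:
            analysis_set.exclusion_log.append(f"error-rate table: {err}")
            continue
        for focus, curve in per_focus.items():
            for cond, pe in (
                (Congruency.CONGRUENT, curve.pe_congruent),
                (Congruency.NEUTRAL, curve.pe_neutral),
                (Congruency.INCONGRUENT, curve.pe_incongruent),
            ):
                rows.extend(
                    {
                        "participant_id": pid,
                        "focus": focus.value,
                        "congruency": cond.value,
                        "bin_center": c,
                        "error_rate": v,
                    }
                    for c, v in zip(curve.bin_centers, pe)
                )
    return pd.DataFrame(rows)
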
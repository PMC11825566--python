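"""Fully within-subject repeated-measures ANOVA with partial eta-squared.

Implements the classical univariate sums-of-squares decomposition for
balanced, fully within-subject designs with up to three factors.  Every
effect (main effect or interaction) is tested against its own
subject-by-effect interaction mean square,

    F_E = (SS_E / df_E) / (SS_{E x S} / df_{E x S}),
    partial eta^2 = SS_E / (SS_E + SS_{E x S}),

with df_E the product of (levels - 1) over the factors in E and
df_{E x S} = (n_subjects - 1) * df_E.  Replicates within a subject x cell
are collapsed to the cell mean before decomposition.  No sphericity
correction is applied by default; a Greenhouse-Geisser option estimates
Box's epsilon from the subject covariance of orthonormal effect contrasts
and deflates both degrees of freedom.

Sums of squares are computed with the standard "uncorrected sums" identity:
for any subset T of the classification factors (subject included),

    A(T) = sum over cells of T of (cell total)^2 / (observations per total),
    SS(T) = sum over S subseteq T of (-1)^{|T| - |S|} A(S),

which reduces to textbook formulas and is exact for balanced data.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = ["EffectResult", "AnovaResult", "rm_anova", "anova_report"]


@dataclass(frozen=True)
class EffectResult:
    """One tested effect of a within-subject ANOVA."""

    name: str
    F: float
    df_num: float
    df_den: float
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float
    gg_epsilon: float | None = None


@dataclass(frozen=True)
class AnovaResult:
    effects: tuple[EffectResult, ...]

    def __getitem__(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


def _uncorrected_sum(y: np.ndarray, kept_axes: tuple[int, ...]) -> float:
    """A(T): squared totals over the kept axes, scaled by cells summed."""
    other = tuple(ax for ax in range(y.ndim) if ax not in kept_axes)
    totals = y.sum(axis=other) if other else y
    n_summed = int(np.prod([y.shape[ax] for ax in other])) if other else 1
    return float(np.sum(np.square(totals))) / n_summed


def _ss(y: np.ndarray, axes: tuple[int, ...], cache: dict) -> float:
    """SS for the subset of axes via inclusion-exclusion over A(.)."""
    total = 0.0
    for r in range(len(axes) + 1):
        for sub in combinations(axes, r):
            if sub not in cache:
                cache[sub] = _uncorrected_sum(y, sub)
            total += (-1) ** (len(axes) - r) * cache[sub]
    return total


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (columns orthogonal to 1)."""
    helmert = np.zeros((k, k - 1))
    for j in range(1, k):
        helmert[:j, j - 1] = 1.0
        helmert[j, j - 1] = -j
        helmert[:, j - 1] /= np.linalg.norm(helmert[:, j - 1])
    return helmert


def _gg_epsilon(y: np.ndarray, factor_axes: tuple[int, ...]) -> float:
    """Box's epsilon for one effect from the subject contrast covariance."""
    other = tuple(ax for ax in range(1, y.ndim) if ax not in factor_axes)
    z = y.mean(axis=other) if other else y  # subjects x effect cells
    z = z.reshape(z.shape[0], -1)
    contrast = None
    for ax in factor_axes:
        c = _orthonormal_contrasts(y.shape[ax])
        contrast = c if contrast is None else np.kron(contrast, c)
    v = contrast.T @ np.cov(z, rowvar=False, ddof=1) @ contrast
    d = v.shape[0]
    denom = d * float(np.trace(v @ v))
    if denom <= 0:
        return 1.0
    return min(float(np.trace(v)) ** 2 / denom, 1.0)


def rm_anova(
    long_table: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str,
    *,
    greenhouse_geisser: bool = False,
) -> AnovaResult:
    """Repeated-measures ANOVA on a long-format balanced table.

    Parameters
    ----------
    long_table
        One row per observation with columns for ``subject``, each factor
        in ``within`` and the dependent variable ``dv``.
    within
        One to three within-subject factor names; every subject must be
        observed in every factor-level combination.
    greenhouse_geisser
        If True, deflate each effect's degrees of freedom by Box's
        epsilon before computing p.

    Raises
    ------
    ValueError
        If the design is unbalanced; the offending subject x cell
        combinations are listed.
    """
    if not 1 <= len(within) <= 3:
        raise ValueError("within must name one to three factors")
    cells = long_table.groupby([subject, *within], sort=True, observed=True)[dv].mean()
    wide = cells.unstack(within)
    subjects = wide.index
    full_cols = pd.MultiIndex.from_product(
        [sorted(long_table[f].unique()) for f in within], names=within
    ) if len(within) > 1 else pd.Index(sorted(long_table[within[0]].unique()), name=within[0])
    wide = wide.reindex(columns=full_cols)
    if wide.isna().any().any():
        missing = [
            f"{s} x {c}" for s in subjects for c in wide.columns if pd.isna(wide.loc[s, c])
        ]
        raise ValueError("unbalanced design; missing cells: " + "; ".join(map(str, missing)))

    level_counts = [len(lv) for lv in (full_cols.levels if len(within) > 1 else [full_cols])]
    y = wide.to_numpy().reshape(len(subjects), *level_counts)
    n_subj = y.shape[0]
    if n_subj < 2:
        raise ValueError("need at least two subjects")

    cache: dict = {}
    factor_axes = {name: i + 1 for i, name in enumerate(within)}
    effects: list[EffectResult] = []
    # main effects first, then two-way interactions, then the three-way
    for order in range(1, len(within) + 1):
        for combo in combinations(within, order):
            axes = tuple(factor_axes[f] for f in combo)
            ss_e = _ss(y, axes, cache)
            ss_err = _ss(y, (0, *axes), cache)
            df_num = float(np.prod([y.shape[ax] - 1 for ax in axes]))
            df_den = (n_subj - 1) * df_num
            ms_err = ss_err / df_den
            f_val = (ss_e / df_num) / ms_err if ms_err > 0 else 0.0
            f_val = max(f_val, 0.0)
            eps = None
            if greenhouse_geisser:
                eps = _gg_epsilon(y, axes)
                p = float(f_dist.sf(f_val, df_num * eps, df_den * eps))
            else:
                p = float(f_dist.sf(f_val, df_num, df_den))
            pes = ss_e / (ss_e + ss_err) if (ss_e + ss_err) > 0 else 0.0
            effects.append(
                EffectResult(
                    name=" x ".join(combo),
                    F=f_val,
                    df_num=df_num,
                    df_den=df_den,
                    p=p,
                    partial_eta_sq=min(max(pes, 0.0), 1.0),
                    ss_effect=ss_e,
                    ss_error=ss_err,
                    gg_epsilon=eps,
                )
            )
    return AnovaResult(effects=tuple(effects))


def _fmt_p(p: float) -> str:
    return "p < .001" if p < 0.001 else f"p = {p:.3f}"


def anova_report(results: AnovaResult | list[EffectResult]) -> str:
    """Render effects as ``F(df1, df2) = x, p = y, etap2 = z`` rows.

    Effects appear in their computed order (main effects, then
    interactions); the output is deterministic for identical input.
    """
    effects = results.effects if isinstance(results, AnovaResult) else tuple(results)
    if not effects:
        raise ValueError("no effects to report")
    lines = []
    for e in effects:
        df1 = int(e.df_num) if float(e.df_num).is_integer() else e.df_num
        df2 = int(e.df_den) if float(e.df_den).is_integer() else e.df_den
        lines.append(
            f"{e.name}: F({df1}, {df2}) = {e.F:.2f}, {_fmt_p(e.p)}, "
            f"\N{GREEK SMALL LETTER ETA}p\N{SUPERSCRIPT TWO} = {e.partial_eta_sq:.3f}"
        )
    return "\n".join(lines)
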
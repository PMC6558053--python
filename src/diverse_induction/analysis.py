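"""Descriptive and Bayesian analysis of argument-strength ratings.

All condition summaries average within participant first (over the
three diverse and three nondiverse targets) and only then across
participants, so standard errors reflect between-participant
variability.  Fillers are excluded from target summaries.

The module also provides a JZS (Jeffreys-Zellner-Siow) paired-samples
Bayes factor: the paired differences are reduced to a one-sample t
statistic and the Cauchy prior on standardized effect size is
marginalized by adaptive quadrature.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

from .experiment import ExperimentDesign, validate_ratings

TARGET_TYPES = ("diverse_target", "nondiverse_target")
DEFAULT_EFFECT_EPSILON = 1.0 / 3.0  # one rating step across three targets


class DegenerateDataError(ValueError):
    """Input with too few observations or zero variance."""


@dataclass(frozen=True)
class CellSummary:
    group: str
    condition: str  # "diverse" | "nondiverse"
    mean: float
    se: float
    n: int


@dataclass(frozen=True)
class SubjectSummary:
    participant_id: str
    group: str
    mean_diverse: float
    mean_nondiverse: float

    @property
    def effect(self) -> float:
        return self.mean_diverse - self.mean_nondiverse


@dataclass(frozen=True)
class EffectSummary:
    """Per-group diversity effects and their interaction contrast."""

    weak_effect: float
    strong_effect: float
    interaction: float  # strong_effect - weak_effect, exactly
    marginals: dict


def _participant_condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """One row per participant: group, mean_diverse, mean_nondiverse."""
    targets = table[table["trial_type"].isin(TARGET_TYPES)]
    wide = (
        targets.groupby(["participant_id", "group", "trial_type"])["rating"]
        .mean()
        .unstack("trial_type")
        .reset_index()
    )
    wide = wide.rename(
        columns={
            "diverse_target": "mean_diverse",
            "nondiverse_target": "mean_nondiverse",
        }
    )
    return wide


def summarize_cells(
    table: pd.DataFrame, design: ExperimentDesign | None = None
) -> list[CellSummary]:
    """Mean and SE of participant-level means for each group x condition."""
    table = validate_ratings(table, design)
    per_subject = _participant_condition_means(table)
    out = []
    for group in ("weak", "strong"):
        sub = per_subject[per_subject["group"] == group]
        if sub.empty:
            raise DegenerateDataError(f"no participants in group {group!r}")
        for condition, col in (
            ("diverse", "mean_diverse"),
            ("nondiverse", "mean_nondiverse"),
        ):
            vals = sub[col].to_numpy(float)
            se = 0.0 if len(vals) < 2 else float(vals.std(ddof=1) / math.sqrt(len(vals)))
            out.append(
                CellSummary(
                    group=group,
                    condition=condition,
                    mean=float(vals.mean()),
                    se=se,
                    n=len(vals),
                )
            )
    return out


def cell_mean(cells: Sequence[CellSummary], group: str, condition: str) -> CellSummary:
    for c in cells:
        if c.group == group and c.condition == condition:
            return c
    raise KeyError(f"no cell ({group}, {condition})")


def marginal_means(cells: Sequence[CellSummary]) -> dict[str, float]:
    """Marginals as exact n-weighted averages of the four cell means."""

    def wavg(subset: list[CellSummary]) -> float:
        total = sum(c.n for c in subset)
        return sum(c.mean * c.n for c in subset) / total

    return {
        "diverse": wavg([c for c in cells if c.condition == "diverse"]),
        "nondiverse": wavg([c for c in cells if c.condition == "nondiverse"]),
        "weak": wavg([c for c in cells if c.group == "weak"]),
        "strong": wavg([c for c in cells if c.group == "strong"]),
    }


def effect_summary(
    table: pd.DataFrame, design: ExperimentDesign | None = None
) -> EffectSummary:
    """Per-group diversity effects (participant-level mean differences)."""
    table = validate_ratings(table, design)
    per_subject = _participant_condition_means(table)
    effects = {}
    for group in ("weak", "strong"):
        sub = per_subject[per_subject["group"] == group]
        if sub.empty:
            raise DegenerateDataError(f"no participants in group {group!r}")
        effects[group] = float(
            (sub["mean_diverse"] - sub["mean_nondiverse"]).mean()
        )
    cells = summarize_cells(table, design)
    return EffectSummary(
        weak_effect=effects["weak"],
        strong_effect=effects["strong"],
        interaction=effects["strong"] - effects["weak"],
        marginals=marginal_means(cells),
    )


def ecdf_by_argument(
    table: pd.DataFrame, design: ExperimentDesign | None = None
) -> pd.DataFrame:
    """Empirical CDF of ratings per (argument, group) at each scale point.

    Returns a long table with columns ``argument_id, group, x, F`` where
    ``F`` is the fraction of that group's participants who rated the
    argument at or below ``x``, for ``x`` in 1..7.
    """
    design = design or ExperimentDesign()
    table = validate_ratings(table, design)
    xs = np.arange(design.scale_min, design.scale_max + 1)
    rows = []
    for (arg, group), sub in table.groupby(["argument_id", "group"]):
        ratings = sub["rating"].to_numpy()
        for x in xs:
            rows.append((arg, group, int(x), float((ratings <= x).mean())))
    return pd.DataFrame(rows, columns=["argument_id", "group", "x", "F"])


def pooled_condition_ecdf(
    table: pd.DataFrame, design: ExperimentDesign | None = None
) -> pd.DataFrame:
    """ECDF of participant condition means, pooled over same-type targets."""
    design = design or ExperimentDesign()
    table = validate_ratings(table, design)
    per_subject = _participant_condition_means(table)
    xs = np.arange(design.scale_min, design.scale_max + 1)
    rows = []
    for group, sub in per_subject.groupby("group"):
        for condition, col in (
            ("diverse", "mean_diverse"),
            ("nondiverse", "mean_nondiverse"),
        ):
            vals = sub[col].to_numpy(float)
            for x in xs:
                rows.append(
                    (group, condition, int(x), float((vals <= x).mean()))
                )
    return pd.DataFrame(rows, columns=["group", "condition", "x", "F"])


@dataclass(frozen=True)
class SubjectEffects:
    """Per-participant diversity effects and group-level fractions.

    ``fraction_nonpositive`` counts participants whose effect is <= 0;
    ``fraction_near_zero`` uses the looser criterion effect <= epsilon,
    reading "little to no effect" as anything below one rating step
    across the three targets.
    """

    summaries: tuple[SubjectSummary, ...]
    fraction_nonpositive: dict
    fraction_near_zero: dict
    epsilon: float


def subject_summaries(
    table: pd.DataFrame,
    design: ExperimentDesign | None = None,
    epsilon: float = DEFAULT_EFFECT_EPSILON,
) -> SubjectEffects:
    """Per-participant diverse/nondiverse means and insensitivity fractions."""
    table = validate_ratings(table, design)
    per_subject = _participant_condition_means(table)
    summaries = tuple(
        SubjectSummary(
            participant_id=row.participant_id,
            group=row.group,
            mean_diverse=float(row.mean_diverse),
            mean_nondiverse=float(row.mean_nondiverse),
        )
        for row in per_subject.itertuples()
    )
    frac_nonpos, frac_near = {}, {}
    for group in ("weak", "strong"):
        effects = np.array([s.effect for s in summaries if s.group == group])
        if effects.size:
            frac_nonpos[group] = float((effects <= 0).mean())
            frac_near[group] = float((effects <= epsilon).mean())
    return SubjectEffects(
        summaries=summaries,
        fraction_nonpositive=frac_nonpos,
        fraction_near_zero=frac_near,
        epsilon=epsilon,
    )


def jzs_bf_from_t(t: float, n: int, r_scale: float = math.sqrt(2) / 2) -> float:
    """JZS Bayes factor (BF10) for a one-sample t statistic.

    Marginalizes the noncentral-t likelihood over a Cauchy(0, r) prior
    on the standardized effect size by adaptive quadrature, split at the
    likelihood peak so narrow integrands at large n are not missed.
    """
    if n < 2:
        raise DegenerateDataError("need at least two observations")
    if r_scale <= 0:
        raise ValueError("r_scale must be positive")
    nu = n - 1
    sqrt_n = math.sqrt(n)

    def integrand(delta: float) -> float:
        try:
            like = float(stats.nct.pdf(t, nu, delta * sqrt_n))
        except OverflowError:  # boost tgamma overflow deep in the tail
            return 0.0
        if not math.isfinite(like):
            return 0.0
        return like * stats.cauchy.pdf(delta, 0.0, r_scale)

    peak = t / sqrt_n
    with warnings.catch_warnings():
        # deep-tail nct evaluations trigger harmless boost warnings
        warnings.simplefilter("ignore", RuntimeWarning)
        left, _ = integrate.quad(
            integrand, -np.inf, peak, epsabs=1e-14, epsrel=1e-10, limit=200
        )
        right, _ = integrate.quad(
            integrand, peak, np.inf, epsabs=1e-14, epsrel=1e-10, limit=200
        )
    m1 = left + right
    m0 = stats.t.pdf(t, nu)
    return m1 / m0


def jzs_paired_bf(
    differences: Sequence[float], r_scale: float = math.sqrt(2) / 2
) -> float:
    """JZS Bayes factor (BF10) for paired differences against zero."""
    d = np.asarray(differences, float)
    if d.size < 2:
        raise DegenerateDataError("need at least two paired differences")
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise DegenerateDataError("paired differences have zero variance")
    t = float(d.mean() / (sd / math.sqrt(d.size)))
    return jzs_bf_from_t(t, int(d.size), r_scale)
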
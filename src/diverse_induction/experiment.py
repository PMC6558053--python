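"""Synthetic two-group property-induction rating experiment.

Emulates a between-subjects design in which 184 participants, split
equally into a *strong*-sampling and a *weak*-sampling instruction
group, each rate 12 inductive arguments (three diverse targets, three
nondiverse targets, six fillers) on a 1-7 likelihood scale.

Response model, per participant: a normal subject-level offset is added
to the relevant condition mean, a latent normal rating is drawn, then
rounded to the nearest integer and clamped to the scale.  In the strong
group a configurable minority of participants is "diversity
insensitive": their diverse-condition mean equals their nondiverse
mean.  The remaining (sensitive) participants' diverse mean is raised
so that the *group-level* diverse cell mean still equals the configured
value; cell means therefore stay interpretable as population targets
regardless of the insensitive fraction.

Default cell means (weak-diverse 5.38, weak-nondiverse 5.08,
strong-diverse 4.78, strong-nondiverse 3.88) are the unique values
consistent with marginal means of 5.08 (diverse), 4.48 (nondiverse),
5.23 (weak group) and 4.33 (strong group) once the weak-group diversity
gap is set to 0.30 — a modest but positive weak-condition effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("weak", "strong")
TRIAL_TYPES = ("diverse_target", "nondiverse_target", "filler")
SCALE_MIN, SCALE_MAX = 1, 7

#: Target arguments: three premise categories and a superordinate
#: conclusion, in matched diverse/nondiverse versions.
TARGET_ARGUMENTS: dict[str, dict] = {
    "mammals-diverse": {
        "premises": ("dogs", "rats", "whales"),
        "conclusion": "all mammals",
        "trial_type": "diverse_target",
    },
    "sea_creatures-diverse": {
        "premises": ("octopi", "eels", "trout"),
        "conclusion": "all sea creatures",
        "trial_type": "diverse_target",
    },
    "insects-diverse": {
        "premises": ("flies", "termites", "millipedes"),
        "conclusion": "all insects",
        "trial_type": "diverse_target",
    },
    "mammals-nondiverse": {
        "premises": ("rabbits", "raccoons", "squirrels"),
        "conclusion": "all mammals",
        "trial_type": "nondiverse_target",
    },
    "sea_creatures-nondiverse": {
        "premises": ("sardines", "herring", "anchovies"),
        "conclusion": "all sea creatures",
        "trial_type": "nondiverse_target",
    },
    "insects-nondiverse": {
        "premises": ("bees", "wasps", "hornets"),
        "conclusion": "all insects",
        "trial_type": "nondiverse_target",
    },
}

#: Filler arguments differ by group: in the strong group they resemble
#: targets; in the weak group they mix superordinates and include
#: negative ("NOT have") premises to convey random selection.
FILLER_ARGUMENTS: dict[str, tuple[str, ...]] = {
    "strong": tuple(f"strong-filler-{i}" for i in range(1, 7)),
    "weak": tuple(f"weak-filler-{i}" for i in range(1, 7)),
}

RATINGS_COLUMNS = ("participant_id", "group", "trial_type", "argument_id", "rating")


class RatingsValidationError(ValueError):
    """A ratings table violates the experimental design schema."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Structural constants of the experiment."""

    n_per_group: int = 92
    n_diverse_targets: int = 3
    n_nondiverse_targets: int = 3
    n_fillers: int = 6
    scale_min: int = SCALE_MIN
    scale_max: int = SCALE_MAX

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be below scale_max")

    @property
    def trials_per_participant(self) -> int:
        return self.n_diverse_targets + self.n_nondiverse_targets + self.n_fillers

    @property
    def n_participants(self) -> int:
        return 2 * self.n_per_group


@dataclass(frozen=True)
class GeneratorParams:
    """Population parameters of the response model.

    ``cell_means`` are ordered (weak-diverse, weak-nondiverse,
    strong-diverse, strong-nondiverse) on the rating scale.
    ``rating_sd`` is the trial-level latent noise; ``subject_sd`` the
    between-participant offset SD; ``insensitive_fraction_strong`` the
    probability that a strong-group participant shows no diversity
    effect.
    """

    cell_means: tuple[float, float, float, float] = (5.38, 5.08, 4.78, 3.88)
    rating_sd: float = 1.1
    subject_sd: float = 0.5
    insensitive_fraction_strong: float = 0.30
    seed: int = 0

    def __post_init__(self):
        means = tuple(float(m) for m in self.cell_means)
        object.__setattr__(self, "cell_means", means)
        if len(means) != 4 or not all(SCALE_MIN <= m <= SCALE_MAX for m in means):
            raise ValueError("cell_means must be four values inside [1, 7]")
        if self.rating_sd < 0 or self.subject_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.insensitive_fraction_strong <= 1.0:
            raise ValueError("insensitive_fraction_strong must lie in [0, 1]")

    def group_means(self, group: str) -> tuple[float, float]:
        """(diverse, nondiverse) configured cell means for *group*."""
        wd, wn, sd, sn = self.cell_means
        return (wd, wn) if group == "weak" else (sd, sn)

    def sensitive_diverse_mean(self) -> float:
        """Diverse-cell mean of sensitive strong-group participants.

        Chosen so the insensitive/sensitive mixture reproduces the
        configured strong-diverse cell mean.
        """
        _, _, sd, sn = self.cell_means
        f = self.insensitive_fraction_strong
        if f >= 1.0:
            return sd
        return (sd - f * sn) / (1.0 - f)


def _discretized_mean(mu: float, sd: float) -> float:
    """Expected value of round-then-clamp applied to ``N(mu, sd)``."""
    if sd == 0:
        return float(min(max(round(mu), SCALE_MIN), SCALE_MAX))
    ks = np.arange(SCALE_MIN, SCALE_MAX + 1)
    upper = np.where(ks == SCALE_MAX, np.inf, ks + 0.5)
    lower = np.where(ks == SCALE_MIN, -np.inf, ks - 0.5)
    p = stats.norm.cdf(upper, mu, sd) - stats.norm.cdf(lower, mu, sd)
    return float((ks * p).sum())


def expected_cell_means(params: GeneratorParams) -> dict[str, float]:
    """Exact expected observed cell means under the response model.

    Accounts for subject offsets, rounding, clamping, and the
    insensitive mixture in the strong group.  Keys: ``weak_diverse``,
    ``weak_nondiverse``, ``strong_diverse``, ``strong_nondiverse``.
    """
    sd_tot = float(np.hypot(params.rating_sd, params.subject_sd))
    wd, wn, sdm, sn = params.cell_means
    f = params.insensitive_fraction_strong
    strong_diverse = (1 - f) * _discretized_mean(
        params.sensitive_diverse_mean(), sd_tot
    ) + f * _discretized_mean(sn, sd_tot)
    return {
        "weak_diverse": _discretized_mean(wd, sd_tot),
        "weak_nondiverse": _discretized_mean(wn, sd_tot),
        "strong_diverse": strong_diverse,
        "strong_nondiverse": _discretized_mean(sn, sd_tot),
    }


def _draw_ratings(rng, mu: np.ndarray, sd: float) -> np.ndarray:
    latent = mu if sd == 0 else rng.normal(mu, sd)
    return np.clip(np.rint(latent), SCALE_MIN, SCALE_MAX).astype(int)


def generate_ratings(
    design: ExperimentDesign | None = None,
    params: GeneratorParams | None = None,
) -> pd.DataFrame:
    """Generate a long-format ratings table, reproducible from the seed.

    Returns a table with columns ``participant_id, group, trial_type,
    argument_id, rating`` — one row per trial, 12 per participant, weak
    group first.
    """
    design = design or ExperimentDesign()
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed)

    diverse_ids = [
        a for a, s in TARGET_ARGUMENTS.items() if s["trial_type"] == "diverse_target"
    ][: design.n_diverse_targets]
    nondiverse_ids = [
        a
        for a, s in TARGET_ARGUMENTS.items()
        if s["trial_type"] == "nondiverse_target"
    ][: design.n_nondiverse_targets]

    rows = []
    pid = 0
    for group in GROUPS:
        mu_d, mu_n = params.group_means(group)
        grand = 0.5 * (mu_d + mu_n)
        filler_ids = list(FILLER_ARGUMENTS[group])[: design.n_fillers]
        offsets = rng.normal(0.0, params.subject_sd, design.n_per_group)
        if group == "strong":
            insensitive = (
                rng.random(design.n_per_group) < params.insensitive_fraction_strong
            )
            mu_d_subject = np.where(
                insensitive, mu_n, params.sensitive_diverse_mean()
            )
        else:
            mu_d_subject = np.full(design.n_per_group, mu_d)

        for i in range(design.n_per_group):
            pid += 1
            pid_str = f"P{pid:03d}"
            off = offsets[i]
            specs = (
                [(a, "diverse_target", mu_d_subject[i]) for a in diverse_ids]
                + [(a, "nondiverse_target", mu_n) for a in nondiverse_ids]
                + [(a, "filler", grand) for a in filler_ids]
            )
            mus = np.array([mu + off for _, _, mu in specs])
            ratings = _draw_ratings(rng, mus, params.rating_sd)
            for (arg_id, ttype, _), r in zip(specs, ratings):
                rows.append((pid_str, group, ttype, arg_id, int(r)))

    return pd.DataFrame(rows, columns=list(RATINGS_COLUMNS))


def validate_ratings(
    table: pd.DataFrame, design: ExperimentDesign | None = None
) -> pd.DataFrame:
    """Check a ratings table against the design schema.

    Raises :class:`RatingsValidationError` naming the offending row or
    participant.  Returns the table (with ``rating`` coerced to int)
    for chaining.
    """
    design = design or ExperimentDesign()
    missing = [c for c in RATINGS_COLUMNS if c not in table.columns]
    if missing:
        raise RatingsValidationError(f"missing columns: {missing}")
    ratings = pd.to_numeric(table["rating"], errors="coerce")
    bad = table.index[ratings.isna() | (ratings != ratings.round())]
    if len(bad):
        raise RatingsValidationError(
            f"non-integer rating at row {int(bad[0])}"
        )
    out_of_range = table.index[
        (ratings < design.scale_min) | (ratings > design.scale_max)
    ]
    if len(out_of_range):
        row = int(out_of_range[0])
        raise RatingsValidationError(
            f"rating {table.loc[row, 'rating']} out of range "
            f"[{design.scale_min}, {design.scale_max}] at row {row}"
        )
    bad_group = set(table["group"]) - set(GROUPS)
    if bad_group:
        raise RatingsValidationError(f"unknown group labels: {sorted(bad_group)}")
    bad_type = set(table["trial_type"]) - set(TRIAL_TYPES)
    if bad_type:
        raise RatingsValidationError(f"unknown trial types: {sorted(bad_type)}")
    dupes = table.duplicated(subset=["participant_id", "argument_id"])
    if dupes.any():
        row = int(table.index[dupes][0])
        raise RatingsValidationError(
            f"duplicate (participant, argument) pair at row {row}"
        )
    counts = table.groupby("participant_id").size()
    wrong = counts[counts != design.trials_per_participant]
    if len(wrong):
        raise RatingsValidationError(
            f"participant {wrong.index[0]!r} has {int(wrong.iloc[0])} records, "
            f"expected {design.trials_per_participant}"
        )
    table = table.copy()
    table["rating"] = ratings.astype(int)
    return table


def write_ratings(table: pd.DataFrame, path) -> None:
    """Write a validated ratings table to CSV."""
    validate_ratings(table).to_csv(path, index=False)


def read_ratings(path, design: ExperimentDesign | None = None) -> pd.DataFrame:
    """Read and validate a ratings CSV (lossless round-trip of writes)."""
    table = pd.read_csv(path, dtype={"participant_id": str})
    return validate_ratings(table, design)
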
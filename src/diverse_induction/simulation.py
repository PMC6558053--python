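"""Generalization as a function of premise diversity.

The six-hypothesis taxonomy illustrates the sampling-assumption effect
at two diversity levels only.  To show it is generic, this module sweeps
premise diversity continuously over a larger hypothesis space: items are
integer positions ``1..m`` on a line, hypotheses are all contiguous
intervals ``[a, b]`` with a uniform prior — the standard 1-D consequence
space of Bayesian generalization models.  Diversity is operationalized
as the normalized span of the premise set; generalization to the
superordinate (the whole domain) is measured as the posterior
probability that a randomly chosen domain member bears the property —
the expected fraction of the domain covered by the true extension,
``sum_h P(h|x) |h| / m``.  This graded measure, rather than the
posterior mass on the single full-domain interval, is used because the
all-or-none measure is vanishingly small everywhere except at extreme
diversity and therefore cannot express graded rating differences.

A companion fitting routine maps the two sweep curves onto four observed
rating-cell means (weak/strong x diverse/nondiverse) by estimating a
latent "perceived" diversity for the diverse premises (``d``) and the
nondiverse premises (``n``) along with an affine probability-to-rating
map, minimizing the sum of squared errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .hypotheses import Hypothesis, HypothesisSpace
from .induction import Evidence, Polarity, Sampling, posterior

FULL_DOMAIN_LABEL = "domain"


def interval_label(a: int, b: int) -> str:
    return f"[{a},{b}]"


def build_interval_space(m: int) -> HypothesisSpace:
    """All ``m(m+1)/2`` contiguous intervals over positions ``1..m``.

    Extension size is the interval length; the prior is uniform over
    intervals.  The full interval ``[1, m]`` carries the label
    ``"domain"`` so it can serve as the superordinate conclusion.
    """
    if m < 2:
        raise ValueError(f"domain_size must be >= 2, got {m}")
    items = [str(i) for i in range(1, m + 1)]
    all_items = frozenset(items)
    hyps = []
    for a in range(1, m + 1):
        for b in range(a, m + 1):
            members = frozenset(items[a - 1 : b])
            label = FULL_DOMAIN_LABEL if (a == 1 and b == m) else interval_label(a, b)
            hyps.append(
                Hypothesis(
                    label=label,
                    extension_size=b - a + 1,
                    members=members,
                    non_members=all_items - members,
                )
            )
    return HypothesisSpace(tuple(hyps))


def place_premises(m: int, n_premises: int, spread: float) -> Evidence:
    """Place ``n_premises`` positive premises with the given diversity.

    The premises cover ``ceil(spread * (m - 1)) + 1`` positions (at
    least ``n_premises``), centred in the domain, equally spaced with
    deterministic rounding to integer positions.  ``spread = 0`` yields
    a contiguous centre block; ``spread = 1`` spans the full domain.
    """
    if not 0.0 <= spread <= 1.0:
        raise ValueError(f"spread must lie in [0, 1], got {spread}")
    if n_premises < 1 or n_premises > m:
        raise ValueError(f"need 1 <= n_premises <= {m}, got {n_premises}")
    # round before ceil so binary-float noise (e.g. 0.1*100 = 10.000...02)
    # cannot bump the span by a whole position
    span = math.ceil(round(spread * (m - 1), 9)) + 1
    span = min(max(span, n_premises), m)
    lo = (m - span) // 2 + 1
    hi = lo + span - 1
    if n_premises == 1:
        positions = [(lo + hi) // 2]
    else:
        raw = lo + np.arange(n_premises) * (hi - lo) / (n_premises - 1)
        positions = sorted(set(int(round(x)) for x in raw))
        free = [p for p in range(lo, hi + 1) if p not in positions]
        while len(positions) < n_premises:  # defensive: rounding collisions
            positions.append(free.pop(0))
        positions.sort()
    return Evidence(tuple((str(p), Polarity.HAVE) for p in positions))


@dataclass(frozen=True)
class SimulationConfig:
    """Sweep settings: domain size, premise count, and diversity grid."""

    domain_size: int = 101
    n_premises: int = 3
    diversity_grid: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 51))
    seed: int = 0

    def __post_init__(self):
        if self.n_premises < 2:
            raise ValueError("n_premises must be >= 2")
        if self.domain_size < self.n_premises:
            raise ValueError("domain_size must be >= n_premises")
        grid = tuple(float(s) for s in self.diversity_grid)
        object.__setattr__(self, "diversity_grid", grid)
        arr = np.asarray(grid)
        if arr.size == 0 or np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("diversity_grid values must lie in [0, 1]")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("diversity_grid must be strictly increasing")


@dataclass
class GeneralizationCurve:
    """Superordinate generalization vs. diversity, per sampling model."""

    diversity: np.ndarray
    g_weak: np.ndarray
    g_strong: np.ndarray

    def __post_init__(self):
        self.diversity = np.asarray(self.diversity, float)
        self.g_weak = np.asarray(self.g_weak, float)
        self.g_strong = np.asarray(self.g_strong, float)
        if not (len(self.diversity) == len(self.g_weak) == len(self.g_strong)):
            raise ValueError("curve arrays must have equal length")
        for name, arr in (("g_weak", self.g_weak), ("g_strong", self.g_strong)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} values must be probabilities")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "diversity": self.diversity,
                "g_weak": self.g_weak,
                "g_strong": self.g_strong,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneralizationCurve":
        return cls(
            df["diversity"].to_numpy(),
            df["g_weak"].to_numpy(),
            df["g_strong"].to_numpy(),
        )


def expected_coverage(
    space: HypothesisSpace, ev: Evidence, sampling: Sampling
) -> float:
    """Posterior probability that a random domain item bears the property.

    ``sum_h P(h|x) |h| / m`` where ``|h|`` counts the listed members and
    ``m`` the items of the domain — the expected fraction of the
    superordinate covered by the property's true extension.  Requires a
    space with fully enumerated memberships (e.g. an interval space).
    """
    res = posterior(space, ev, sampling)
    sizes = np.array([len(h.members) for h in space.hypotheses], float)
    n_items = len(frozenset().union(*(h.members | h.non_members for h in space)))
    return float((res.posterior * sizes).sum() / n_items)


def diversity_sweep(config: SimulationConfig) -> GeneralizationCurve:
    """Generalization to the superordinate at each diversity level.

    Deterministic: premises are placed by :func:`place_premises` and the
    posterior is exact, so identical configs give identical curves.
    """
    space = build_interval_space(config.domain_size)
    sizes = np.array([h.extension_size for h in space.hypotheses], float)
    g_weak, g_strong = [], []
    for spread in config.diversity_grid:
        ev = place_premises(config.domain_size, config.n_premises, spread)
        for out, sampling in ((g_weak, Sampling.WEAK), (g_strong, Sampling.STRONG)):
            res = posterior(space, ev, sampling)
            out.append(float((res.posterior * sizes).sum() / config.domain_size))
    return GeneralizationCurve(
        np.asarray(config.diversity_grid), np.asarray(g_weak), np.asarray(g_strong)
    )


@dataclass
class LatentDiversityFit:
    """Latent perceived diversities and the fitted rating map.

    ``d_hat``/``n_hat`` are the perceived diversities of the diverse and
    nondiverse premise sets; ``scale_slope``/``scale_intercept`` map
    model generalization probabilities onto the 1-7 rating scale;
    ``predicted_cells`` are the model means in the order (weak-diverse,
    weak-nondiverse, strong-diverse, strong-nondiverse).
    """

    d_hat: float
    n_hat: float
    scale_slope: float
    scale_intercept: float
    sse: float
    predicted_cells: tuple[float, float, float, float]

    def to_dict(self) -> dict:
        return {
            "d_hat": self.d_hat,
            "n_hat": self.n_hat,
            "scale_slope": self.scale_slope,
            "scale_intercept": self.scale_intercept,
            "sse": self.sse,
            "predicted_cells": {
                "weak_diverse": self.predicted_cells[0],
                "weak_nondiverse": self.predicted_cells[1],
                "strong_diverse": self.predicted_cells[2],
                "strong_nondiverse": self.predicted_cells[3],
            },
        }


def _model_vector(curve: GeneralizationCurve, d: float, n: float) -> np.ndarray:
    gw = np.interp([d, n], curve.diversity, curve.g_weak)
    gs = np.interp([d, n], curve.diversity, curve.g_strong)
    return np.array([gw[0], gw[1], gs[0], gs[1]])


def _affine_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares ``y ~ a*x + b`` with the slope constrained to a >= 0."""
    xm, ym = x.mean(), y.mean()
    vx = float(((x - xm) ** 2).sum())
    if vx <= 1e-30:
        a = 0.0
    else:
        a = float(((x - xm) * (y - ym)).sum() / vx)
        a = max(a, 0.0)
    b = float(ym - a * xm)
    sse = float(((a * x + b - y) ** 2).sum())
    return a, b, sse


def fit_latent_diversity(
    curve: GeneralizationCurve,
    cell_means: Sequence[float],
    grid_step: float = 0.01,
    refine: bool = True,
) -> LatentDiversityFit:
    """Fit latent diversities (d, n) and an affine rating map by SSE.

    ``cell_means`` are the observed means in the order (weak-diverse,
    weak-nondiverse, strong-diverse, strong-nondiverse).  A grid search
    over ``(d, n)`` in the unit square with ``n <= d`` solves the affine
    map in closed form at each point; the grid minimizer is then refined
    by a local simplex search.  Ties in SSE prefer the smallest ``d - n``
    and then the smallest ``d``, so uninformative (flat) cell means
    collapse to a degenerate ``d_hat = n_hat`` fit.
    """
    y = np.asarray(cell_means, float)
    if y.shape != (4,) or not np.all(np.isfinite(y)):
        raise ValueError("cell_means must be four finite numbers")
    if not 0 < grid_step <= 0.5:
        raise ValueError("grid_step must lie in (0, 0.5]")

    axis = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    axis = np.clip(axis, 0.0, 1.0)
    dd, nn = np.meshgrid(axis, axis, indexing="ij")
    mask = nn <= dd
    d_flat, n_flat = dd[mask], nn[mask]

    gw_d = np.interp(d_flat, curve.diversity, curve.g_weak)
    gw_n = np.interp(n_flat, curve.diversity, curve.g_weak)
    gs_d = np.interp(d_flat, curve.diversity, curve.g_strong)
    gs_n = np.interp(n_flat, curve.diversity, curve.g_strong)
    X = np.stack([gw_d, gw_n, gs_d, gs_n], axis=1)

    xm = X.mean(axis=1, keepdims=True)
    ym = y.mean()
    vx = ((X - xm) ** 2).sum(axis=1)
    cov = ((X - xm) * (y - ym)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(vx > 1e-30, cov / np.where(vx > 0, vx, 1.0), 0.0)
    slope = np.maximum(slope, 0.0)
    intercept = ym - slope * xm[:, 0]
    resid = slope[:, None] * X + intercept[:, None] - y[None, :]
    sse = (resid**2).sum(axis=1)

    best = sse.min()
    tied = np.flatnonzero(sse <= best + 1e-12)
    order = np.lexsort((d_flat[tied], d_flat[tied] - n_flat[tied]))
    pick = tied[order[0]]
    d_hat, n_hat = float(d_flat[pick]), float(n_flat[pick])

    def objective(theta: np.ndarray) -> float:
        d, n = theta
        if not (0.0 <= n <= d <= 1.0):
            return 1e6 + abs(d - n)
        return _affine_fit(_model_vector(curve, d, n), y)[2]

    if refine:
        res = optimize.minimize(
            objective,
            x0=np.array([d_hat, n_hat]),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 500},
        )
        if res.fun <= sse[pick]:
            d_hat, n_hat = float(res.x[0]), float(res.x[1])

    x_best = _model_vector(curve, d_hat, n_hat)
    a, b, final_sse = _affine_fit(x_best, y)
    predicted = tuple(float(v) for v in a * x_best + b)
    return LatentDiversityFit(
        d_hat=d_hat,
        n_hat=n_hat,
        scale_slope=a,
        scale_intercept=b,
        sse=final_sse,
        predicted_cells=predicted,  # type: ignore[arg-type]
    )
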
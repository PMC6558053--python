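"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
explicit enumeration of ordered draws for posteriors, exact rational
arithmetic over all intervals for the sweep, and a dense trapezoid
quadrature of the Zellner-Siow g-representation for the JZS Bayes
factor.  They are deliberately slow and simple.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np

from diverse_induction import Polarity, is_consistent


def brute_posterior(space, ev, sampling: str) -> np.ndarray:
    """Posterior by enumerating ordered without-replacement draws.

    Each hypothesis's extension is materialized as named members plus
    anonymous filler tokens up to ``extension_size``; the strong
    likelihood is the fraction of ordered m-tuples equal to the premise
    sequence.
    """
    pos = ev.positive_items
    m = len(pos)
    weights: list[Fraction] = []
    for h, pr in zip(space.hypotheses, space.prior):
        prior = Fraction(pr).limit_denominator(10**12)
        if not is_consistent(h, ev):
            weights.append(Fraction(0))
            continue
        if sampling == "weak":
            weights.append(prior)
            continue
        ext = list(h.members) + [
            f"~{h.label}~{i}" for i in range(h.extension_size - len(h.members))
        ]
        total = 0
        favorable = 0
        for tup in itertools.permutations(ext, m):
            total += 1
            if tup == tuple(pos):
                favorable += 1
        weights.append(prior * Fraction(favorable, total))
    z = sum(weights)
    if z == 0:
        raise ZeroDivisionError("no consistent hypothesis")
    return np.array([float(w / z) for w in weights])


def brute_interval_coverage(m: int, positions: tuple[int, ...], sampling: str) -> float:
    """Expected covered fraction of ``1..m`` by exact rational enumeration."""
    lo, hi = min(positions), max(positions)
    n_pos = len(positions)
    num = Fraction(0)
    z = Fraction(0)
    for a in range(1, m + 1):
        for b in range(a, m + 1):
            if not (a <= lo and b >= hi):
                continue
            size = b - a + 1
            if sampling == "weak":
                lik = Fraction(1)
            else:
                lik = Fraction(1)
                for k in range(n_pos):
                    lik /= size - k
            z += lik
            num += lik * Fraction(size, m)
    return float(num / z)


def jzs_bf_gform(t: float, n: int, r: float = math.sqrt(2) / 2) -> float:
    """JZS BF10 via the Zellner-Siow g-representation.

    ``delta | g ~ N(0, g r^2)``, ``g ~ InvGamma(1/2, 1/2)``; the
    marginal likelihood reduces to a one-dimensional integral over g in
    elementary functions, evaluated by trapezoid on a dense log grid.
    """
    nu = n - 1
    u = np.linspace(-15.0, 15.0, 400_001)
    g = np.exp(u)
    ngr = 1.0 + n * g * r * r
    dens = (
        ngr**-0.5
        * (1.0 + t * t / (ngr * nu)) ** (-(nu + 1) / 2)
        * (2 * np.pi) ** -0.5
        * g**-1.5
        * np.exp(-1.0 / (2 * g))
    )
    m1 = np.trapezoid(dens * g, u)  # dg = g du
    m0 = (1.0 + t * t / nu) ** (-(nu + 1) / 2)
    return float(m1 / m0)


def random_small_space(rng, max_hypotheses=6, max_size=50, n_items=4):
    """A random decidable space for oracle-equivalence checks."""
    from diverse_induction import Hypothesis, HypothesisSpace

    items = [f"i{j}" for j in range(n_items)]
    k = int(rng.integers(2, max_hypotheses + 1))
    hyps = []
    for j in range(k):
        members = frozenset(i for i in items if rng.random() < 0.6)
        size = int(rng.integers(max(1, len(members)), max_size + 1))
        hyps.append(
            Hypothesis(f"h{j}", size, members, frozenset(set(items) - members))
        )
    prior = rng.random(k) + 0.05
    return HypothesisSpace(tuple(hyps), prior), items


def random_evidence(rng, items, max_premises=3):
    from diverse_induction import Evidence

    n = int(rng.integers(1, max_premises + 1))
    chosen = rng.choice(items, size=n, replace=False)
    premises = tuple(
        (str(i), Polarity.HAVE if rng.random() < 0.8 else Polarity.NOT_HAVE)
        for i in chosen
    )
    return Evidence(premises)
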
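"""Bayesian belief updating under weak and strong sampling.

Given premises asserting that categories do (or do not) carry a novel
property, the reasoner updates a prior over candidate extensions via
Bayes' rule.  The likelihood encodes the *sampling assumption*:

* **weak sampling** — premise items were observed at random,
  irrespective of the property, so the likelihood is a constant over
  every hypothesis consistent with the evidence and zero elsewhere;
* **strong sampling** — positive premise items were drawn (without
  replacement) from the set of property bearers, so each of the ``m``
  positive premises contributes a factor ``1/(|h| - k)`` for
  ``k = 0..m-1``.  Smaller consistent hypotheses thereby receive higher
  likelihood — the *size principle*.

Negative (``not have``) premises act as consistency filters only: the
strong model samples among property bearers, so an item reported not to
bear the property carries a constant likelihood factor under both
sampling schemes.

Posterior arithmetic is done in log space so that large extensions
(thousands of species, several premises) cannot underflow.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .hypotheses import Hypothesis, HypothesisSpace, is_consistent


class Polarity(enum.Enum):
    """Whether a premise asserts the item has, or lacks, the property."""

    HAVE = "+"
    NOT_HAVE = "-"


class Sampling(str, enum.Enum):
    """How the reasoner believes the premise items were selected."""

    WEAK = "weak"
    STRONG = "strong"


class EvidenceError(ValueError):
    """Malformed evidence (empty, duplicated items, bad syntax)."""


class NoConsistentHypothesisError(ValueError):
    """No hypothesis in the space is consistent with the evidence."""


class InfiniteSupportError(ZeroDivisionError):
    """Likelihood ratio denominator is zero (unbounded support for a)."""


class InsufficientExtensionError(ValueError):
    """A hypothesis is too small to supply the positive premises."""


@dataclass(frozen=True)
class Evidence:
    """An ordered set of premises ``(item_id, polarity)``.

    Sampling is always *without replacement*: the same item cannot be
    drawn twice, so duplicate item ids are rejected.
    """

    premises: tuple[tuple[str, Polarity], ...]

    def __post_init__(self):
        premises = tuple((i, Polarity(p)) for i, p in self.premises)
        object.__setattr__(self, "premises", premises)
        if not premises:
            raise EvidenceError("evidence needs at least one premise")
        ids = [i for i, _ in premises]
        if len(set(ids)) != len(ids):
            raise EvidenceError(f"duplicate premise items in {ids}")

    @property
    def positive_items(self) -> tuple[str, ...]:
        return tuple(i for i, p in self.premises if p is Polarity.HAVE)

    @property
    def n_positive(self) -> int:
        return len(self.positive_items)

    def __str__(self) -> str:
        return ",".join(f"{i}{p.value}" for i, p in self.premises)


def parse_evidence(text: str) -> Evidence:
    """Parse a compact premise string such as ``"wolf+,dog+"`` or ``"carp-"``.

    Items without an explicit trailing ``+``/``-`` are positive.
    """
    premises = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            raise EvidenceError(f"empty premise token in {text!r}")
        if token.endswith("+"):
            premises.append((token[:-1], Polarity.HAVE))
        elif token.endswith("-"):
            premises.append((token[:-1], Polarity.NOT_HAVE))
        else:
            premises.append((token, Polarity.HAVE))
    return Evidence(tuple(premises))


def evidence(*items: str) -> Evidence:
    """Convenience constructor: ``evidence("wolf+", "dog+")``."""
    return parse_evidence(",".join(items))


def likelihood_weak(h: Hypothesis, ev: Evidence) -> float:
    """Weak-sampling likelihood: 1 if consistent, else 0."""
    return 1.0 if is_consistent(h, ev) else 0.0


def log_likelihood_strong(h: Hypothesis, ev: Evidence) -> float:
    """Log of the strong-sampling likelihood (``-inf`` if inconsistent)."""
    m = ev.n_positive
    if not is_consistent(h, ev):
        return -math.inf
    if h.extension_size < m:
        raise InsufficientExtensionError(
            f"{h.label}: extension of size {h.extension_size} cannot yield "
            f"{m} distinct positive premises"
        )
    return -sum(math.log(h.extension_size - k) for k in range(m))


def likelihood_strong(h: Hypothesis, ev: Evidence) -> float:
    """Strong-sampling likelihood: sequential draws among property bearers.

    ``prod_{k=0..m-1} 1/(|h|-k)`` over the ``m`` positive premises
    (without replacement); zero if the hypothesis is inconsistent.
    Negative premises contribute a constant factor of one.
    """
    return math.exp(log_likelihood_strong(h, ev))


def _log_likelihoods(
    space: HypothesisSpace, ev: Evidence, sampling: Sampling
) -> np.ndarray:
    sampling = Sampling(sampling)
    out = np.empty(len(space))
    for i, h in enumerate(space.hypotheses):
        if sampling is Sampling.WEAK:
            out[i] = 0.0 if is_consistent(h, ev) else -math.inf
        else:
            out[i] = log_likelihood_strong(h, ev)
    return out


@dataclass
class PosteriorResult:
    """Per-hypothesis likelihoods and the normalized posterior."""

    labels: tuple[str, ...]
    prior: np.ndarray
    likelihood: np.ndarray
    posterior: np.ndarray
    normalizer: float
    sampling: Sampling

    def posterior_of(self, label: str) -> float:
        return float(self.posterior[self.labels.index(label)])

    def likelihood_of(self, label: str) -> float:
        return float(self.likelihood[self.labels.index(label)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "prior": self.prior,
                "likelihood": self.likelihood,
                "posterior": self.posterior,
            }
        )

    def to_json(self, **kwargs) -> str:
        payload = {
            "sampling": self.sampling.value,
            "normalizer": self.normalizer,
            "hypotheses": self.to_frame().to_dict(orient="records"),
        }
        return json.dumps(payload, **kwargs)


def posterior(
    space: HypothesisSpace, ev: Evidence, sampling: Sampling
) -> PosteriorResult:
    """Bayes-rule posterior ``P(h|x) = P(x|h) P(h) / sum P(x|h') P(h')``.

    Raises :class:`NoConsistentHypothesisError` when the evidence rules
    out every hypothesis (zero normalizer).
    """
    sampling = Sampling(sampling)
    log_lik = _log_likelihoods(space, ev, sampling)
    with np.errstate(divide="ignore"):
        log_prior = np.where(space.prior > 0, np.log(space.prior), -math.inf)
    log_w = log_prior + log_lik
    if np.all(np.isneginf(log_w)):
        raise NoConsistentHypothesisError(
            f"no hypothesis with positive prior is consistent with {ev}"
        )
    log_z = float(logsumexp(log_w))
    post = np.exp(log_w - log_z)
    post /= post.sum()  # absorb rounding so the simplex invariant is exact
    return PosteriorResult(
        labels=space.labels,
        prior=space.prior.copy(),
        likelihood=np.exp(log_lik),
        posterior=post,
        normalizer=math.exp(log_z),
        sampling=sampling,
    )


def likelihood_ratio(
    space: HypothesisSpace,
    ev: Evidence,
    label_a: str,
    label_b: str,
    sampling: Sampling,
) -> float:
    """Ratio ``P(x | h_a) / P(x | h_b)`` under the given sampling model."""
    sampling = Sampling(sampling)
    ha, hb = space[label_a], space[label_b]
    if sampling is Sampling.WEAK:
        la = 0.0 if is_consistent(ha, ev) else -math.inf
        lb = 0.0 if is_consistent(hb, ev) else -math.inf
    else:
        la = log_likelihood_strong(ha, ev)
        lb = log_likelihood_strong(hb, ev)
    if lb == -math.inf:
        raise InfiniteSupportError(
            f"likelihood of {label_b!r} is zero; ratio is unbounded"
        )
    return math.exp(la - lb)


def argument_strength(
    space: HypothesisSpace,
    ev: Evidence,
    conclusion_label: str,
    sampling: Sampling,
) -> float:
    """Probability that the conclusion category's extension is covered.

    The strength of the argument "premises, therefore all members of
    *conclusion* have the property" is the posterior mass on hypotheses
    whose extension includes the conclusion's extension — the conclusion
    hypothesis itself plus any labelled superset, as witnessed by the
    declared member sets.
    """
    result = posterior(space, ev, sampling)
    covered = set(space.supersets_of(conclusion_label))
    return float(
        sum(p for lbl, p in zip(result.labels, result.posterior) if lbl in covered)
    )
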
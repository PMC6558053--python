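"""Hypothesis spaces for category-based induction.

A reasoner entertains a set of candidate *hypotheses* about which
categories share a novel property.  Each hypothesis has a label, a
real-world extension size ``|h|`` (a count of species, used by the
strong-sampling likelihood), explicit sets of known members and known
non-members, and a prior weight.  Membership is stored explicitly rather
than derived from a tree: the spaces used here are flat lists of
candidate extensions, and an item whose membership is not recorded in
either set is treated as *undecidable* (an error) rather than silently
assumed absent, because a silent default would corrupt likelihoods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .induction import Evidence

logger = logging.getLogger(__name__)

PRIOR_TOL = 1e-12


class SpaceValidationError(ValueError):
    """Raised when a hypothesis or space violates a structural invariant."""


class UndecidableMembershipError(LookupError):
    """An evidence item is in neither the members nor the non-members set."""

    def __init__(self, item_id: str, label: str):
        super().__init__(
            f"membership of item {item_id!r} in hypothesis {label!r} is "
            f"undecidable: it appears in neither members nor non_members"
        )
        self.item_id = item_id
        self.label = label


@dataclass(frozen=True)
class Item:
    """A category that can appear as a premise (e.g. ``dog``)."""

    id: str
    display_name: str = ""

    def __post_init__(self):
        if not self.id:
            raise SpaceValidationError("item id must be non-empty")
        if not self.display_name:
            object.__setattr__(self, "display_name", self.id)


@dataclass(frozen=True)
class Hypothesis:
    """A candidate extension of the property.

    Parameters
    ----------
    label
        Unique name within a space (e.g. ``"canines"``).
    extension_size
        Real-world size ``|h|`` of the extension — a positive integer
        count of species.  Drives the strong-sampling likelihood.
    members
        Item ids known to belong to the extension.
    non_members
        Item ids known *not* to belong.
    """

    label: str
    extension_size: int
    members: frozenset[str] = frozenset()
    non_members: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.label:
            raise SpaceValidationError("hypothesis label must be non-empty")
        if isinstance(self.extension_size, bool) or not isinstance(
            self.extension_size, (int, np.integer)
        ):
            raise SpaceValidationError(
                f"{self.label}: extension_size must be an integer count, "
                f"got {self.extension_size!r}"
            )
        if self.extension_size < 1:
            raise SpaceValidationError(
                f"{self.label}: extension_size must be positive"
            )
        object.__setattr__(self, "members", frozenset(self.members))
        object.__setattr__(self, "non_members", frozenset(self.non_members))
        if self.extension_size < len(self.members):
            raise SpaceValidationError(
                f"{self.label}: extension_size {self.extension_size} is "
                f"smaller than the {len(self.members)} listed members"
            )
        overlap = self.members & self.non_members
        if overlap:
            raise SpaceValidationError(
                f"{self.label}: items {sorted(overlap)} listed as both "
                f"members and non-members"
            )


@dataclass(eq=False)
class HypothesisSpace:
    """An ordered list of hypotheses with a prior distribution.

    The prior is normalized on construction; an all-zero or negative
    weight vector is rejected.
    """

    hypotheses: tuple[Hypothesis, ...]
    prior: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.hypotheses = tuple(self.hypotheses)
        if not self.hypotheses:
            raise SpaceValidationError("a space needs at least one hypothesis")
        labels = [h.label for h in self.hypotheses]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise SpaceValidationError(f"duplicate hypothesis labels: {dupes}")
        if self.prior is None:
            self.prior = np.full(len(self.hypotheses), 1.0 / len(self.hypotheses))
        self.prior = np.asarray(self.prior, dtype=float)
        if self.prior.shape != (len(self.hypotheses),):
            raise SpaceValidationError(
                f"prior has shape {self.prior.shape}, expected "
                f"({len(self.hypotheses)},)"
            )
        if np.any(self.prior < 0) or not np.all(np.isfinite(self.prior)):
            raise SpaceValidationError("prior weights must be finite and >= 0")
        total = self.prior.sum()
        if total <= 0:
            raise SpaceValidationError("prior weights must not all be zero")
        self.prior = self.prior / total
        self._index = {h.label: i for i, h in enumerate(self.hypotheses)}

    def __len__(self) -> int:
        return len(self.hypotheses)

    def __iter__(self):
        return iter(self.hypotheses)

    def __getitem__(self, label: str) -> Hypothesis:
        try:
            return self.hypotheses[self._index[label]]
        except KeyError:
            raise KeyError(f"no hypothesis labelled {label!r}") from None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(h.label for h in self.hypotheses)

    def index(self, label: str) -> int:
        if label not in self._index:
            raise KeyError(f"no hypothesis labelled {label!r}")
        return self._index[label]

    def prior_of(self, label: str) -> float:
        return float(self.prior[self.index(label)])

    def supersets_of(self, label: str) -> tuple[str, ...]:
        """Labels of hypotheses whose extension provably includes *label*'s.

        Inclusion is witnessed through the declared member sets: ``g``
        includes ``h`` when every listed member of ``h`` is a listed
        member of ``g``.  The conclusion hypothesis must therefore list
        at least one member.
        """
        target = self[label]
        if not target.members:
            raise SpaceValidationError(
                f"{label!r} lists no members; extension inclusion cannot "
                f"be witnessed"
            )
        return tuple(
            h.label for h in self.hypotheses if target.members <= h.members
        )


def is_consistent(h: Hypothesis, evidence: "Evidence") -> bool:
    """True iff every premise agrees with the hypothesis's membership sets.

    A positive (``have``) premise must name a member; a negative
    (``not have``) premise must name a non-member.  Raises
    :class:`UndecidableMembershipError` for an item in neither set.
    """
    from .induction import Polarity

    for item_id, polarity in evidence.premises:
        if item_id in h.members:
            if polarity is not Polarity.HAVE:
                return False
        elif item_id in h.non_members:
            if polarity is not Polarity.NOT_HAVE:
                return False
        else:
            raise UndecidableMembershipError(item_id, h.label)
    return True


def space_from_taxonomy(
    sizes: Mapping[str, int],
    parents: Mapping[str, str | None],
    item_categories: Mapping[str, str],
    prior: Sequence[float] | None = None,
    order: Sequence[str] | None = None,
) -> HypothesisSpace:
    """Build a flat hypothesis space from a nesting declaration.

    Each hypothesis corresponds to a named taxon; an item belongs to
    every ancestor-or-self of its assigned category and to no other
    listed taxon (closed world over the listed items).
    """
    labels = list(order) if order is not None else list(sizes)
    unknown = set(parents) - set(sizes)
    if unknown:
        raise SpaceValidationError(f"parents reference unknown taxa: {sorted(unknown)}")

    def ancestors(label: str) -> set[str]:
        out = {label}
        cur = parents.get(label)
        seen = {label}
        while cur is not None:
            if cur in seen:
                raise SpaceValidationError(f"cycle in taxonomy at {cur!r}")
            out.add(cur)
            seen.add(cur)
            cur = parents.get(cur)
        return out

    item_taxa = {
        item: ancestors(cat) for item, cat in item_categories.items()
    }
    all_items = set(item_categories)
    hyps = []
    for label in labels:
        members = frozenset(i for i, taxa in item_taxa.items() if label in taxa)
        hyps.append(
            Hypothesis(
                label=label,
                extension_size=sizes[label],
                members=members,
                non_members=frozenset(all_items - members),
            )
        )
    return HypothesisSpace(tuple(hyps), None if prior is None else np.asarray(prior))


#: Real-world extension sizes for the six-hypothesis mammal example.
TOY_SIZES = {
    "canines": 36,
    "ursines": 8,
    "placentals": 4000,
    "macropods": 59,
    "marsupials": 334,
    "mammals": 5000,
}

_TOY_PARENTS = {
    "canines": "placentals",
    "ursines": "placentals",
    "placentals": "mammals",
    "macropods": "marsupials",
    "marsupials": "mammals",
    "mammals": None,
}

_TOY_ITEMS = {"dog": "canines", "wolf": "canines", "koala": "marsupials"}


def build_toy_space() -> HypothesisSpace:
    """The six-hypothesis mammal taxonomy with a uniform prior.

    Hypotheses: canines (36 species), ursines (8), placentals (4000),
    macropods (59), marsupials (334) and mammals (5000), each with prior
    1/6.  Items dog and wolf are canines (hence placentals and mammals);
    koala is a marsupial (hence a mammal) and not a placental.
    """
    return space_from_taxonomy(
        TOY_SIZES, _TOY_PARENTS, _TOY_ITEMS, order=list(TOY_SIZES)
    )


def space_to_config(space: HypothesisSpace) -> dict:
    """Serialize a space to the plain-dict config format of :func:`load_space`."""
    return {
        "hypotheses": [
            {
                "label": h.label,
                "size": int(h.extension_size),
                "members": sorted(h.members),
                "non_members": sorted(h.non_members),
                "prior": float(space.prior[i]),
            }
            for i, h in enumerate(space.hypotheses)
        ]
    }


def load_space(source) -> HypothesisSpace:
    """Load a hypothesis space from a JSON config file, path, or dict.

    The config holds a ``hypotheses`` list of objects with keys
    ``label``, ``size``, ``members``, ``non_members`` and optional
    ``prior``.  Priors that sum to a positive value other than one are
    normalized with a logged warning; missing priors mean uniform.
    """
    if isinstance(source, dict):
        config = source
    else:
        with open(source) as fh:
            config = json.load(fh)
    entries = config.get("hypotheses")
    if not entries:
        raise SpaceValidationError("config lists no hypotheses")
    hyps = []
    weights: list[float] = []
    has_prior = any("prior" in e for e in entries)
    for e in entries:
        hyps.append(
            Hypothesis(
                label=e["label"],
                extension_size=e["size"],
                members=frozenset(e.get("members", ())),
                non_members=frozenset(e.get("non_members", ())),
            )
        )
        if has_prior:
            weights.append(float(e.get("prior", 0.0)))
    prior = np.asarray(weights) if has_prior else None
    if prior is not None and abs(prior.sum() - 1.0) > PRIOR_TOL:
        if prior.sum() > 0:
            logger.warning(
                "prior weights sum to %.6g, normalizing to 1", prior.sum()
            )
    return HypothesisSpace(tuple(hyps), prior)
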
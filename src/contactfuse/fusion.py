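"""Fusion of a general top-L contact list with beta-sheet-specific contacts.

Strand-pairing predictors emit contacts grouped into ladders (one group
per predicted strand pairing, parallel or antiparallel).  Pairings made
of only one or two contacts carry a high false-positive rate and are
dropped.  The surviving beta contacts are then united with the general
top-L list: any top-L pair with a beta contact in its neighbourhood
(same pair, or one index shifted by at most two residues) has its
squared-well bonus doubled from -15.00 to -30.00; beta contacts that
match nothing in the top-L list are appended at the baseline -15.00.
No further length cutoff is applied after fusion, so the fused list may
be longer than L.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Sequence

from .model import (
    DEFAULT_WELL_DEPTH,
    BoundsError,
    ContactMap,
    ContactPair,
    is_neighbor,
)

__all__ = [
    "StrandPairGroup",
    "FusedRestraintSet",
    "filter_sparse_groups",
    "fuse",
    "restraint_count",
    "MIN_GROUP_SIZE",
]

#: Strand pairings with fewer contacts than this are discarded.
MIN_GROUP_SIZE = 3


@dataclass
class StrandPairGroup:
    """Contacts predicted as one strand pairing, with its direction."""

    group_id: str
    direction: str  # "parallel" | "antiparallel"
    members: List[ContactPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in ("parallel", "antiparallel"):
            raise ValueError(f"unknown strand direction {self.direction!r}")
        if not self.members:
            raise ValueError(f"strand group {self.group_id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class FusedRestraintSet:
    """Result of uniting top-L and beta-specific contacts.

    ``pairs`` holds the top-L contacts first (in their ranked order,
    upweighted where matched) followed by the added beta contacts in
    input order.  ``n_topL + n_added == len(pairs)`` always.
    """

    pairs: List[ContactPair]
    n_topL: int
    n_upweighted: int
    n_added: int

    def __post_init__(self) -> None:
        if self.n_topL + self.n_added != len(self.pairs):
            raise ValueError("provenance counts inconsistent with pair list")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def pair_set(self) -> set:
        return {p.key for p in self.pairs}


def filter_sparse_groups(
    groups: Iterable[StrandPairGroup], min_size: int = MIN_GROUP_SIZE
) -> List[StrandPairGroup]:
    """Drop strand pairings composed of fewer than ``min_size`` contacts.

    One- and two-contact pairings are removed by default owing to their
    high false-positive rate.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    return [g for g in groups if len(g) >= min_size]


def fuse(
    top_l: ContactMap,
    beta: Sequence[StrandPairGroup],
    base_wd: float = DEFAULT_WELL_DEPTH,
    upweight_multiplier: float = 2.0,
) -> FusedRestraintSet:
    """Unite a top-L contact map with filtered beta-specific contacts.

    For every top-L pair, if any beta contact falls within its
    neighbour tolerance the pair's well depth becomes
    ``base_wd * upweight_multiplier`` (-30.00 at the defaults; a pair
    is upweighted at most once however many beta contacts match it).
    Beta contacts that match at least one top-L pair are consumed;
    the rest are appended at ``base_wd``, de-duplicated on their
    residue pair.  ``top_l`` is expected to be length-selected already
    and ``beta`` filtered by :func:`filter_sparse_groups`.
    """
    length = top_l.length
    beta_members: List[ContactPair] = []
    for group in beta:
        for m in group.members:
            if m.res2 > length or m.res1 < 1:
                raise BoundsError(
                    f"beta contact ({m.res1}, {m.res2}) outside [1, {length}]"
                )
            beta_members.append(m)

    fused: List[ContactPair] = []
    beta_consumed = [False] * len(beta_members)
    n_up = 0
    for p in top_l:
        matched = False
        for k, b in enumerate(beta_members):
            if is_neighbor(b, p):
                matched = True
                beta_consumed[k] = True
        if matched:
            fused.append(
                replace(p, weight=base_wd * upweight_multiplier,
                        source="fused_upweighted")
            )
            n_up += 1
        else:
            fused.append(replace(p, weight=base_wd))

    n_topl = len(fused)
    seen = {p.key for p in fused}
    n_added = 0
    for k, b in enumerate(beta_members):
        if beta_consumed[k] or b.key in seen:
            continue
        fused.append(replace(b, weight=base_wd, source="fused_added"))
        seen.add(b.key)
        n_added += 1

    return FusedRestraintSet(
        pairs=fused, n_topL=n_topl, n_upweighted=n_up, n_added=n_added
    )


def restraint_count(fused: FusedRestraintSet) -> int:
    """Number of restraints the fused list will generate."""
    return len(fused.pairs)
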
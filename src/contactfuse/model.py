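"""Core contact-map data model.

A contact map is a scored list of residue-index pairs over a target
sequence of length L.  Pairs are stored canonically (``res1 < res2``,
1-based) and iterate in descending confidence order, which makes the
top-L cut a simple prefix.  Every downstream stage (fusion, restraint
generation, precision scoring) builds on the operations here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Tuple

__all__ = [
    "ContactPair",
    "ContactMap",
    "BoundsError",
    "SelfContactError",
    "canonicalize",
    "top_l_select",
    "is_neighbor",
    "DEFAULT_WELL_DEPTH",
    "NEIGHBOR_OFFSETS",
]

#: Baseline squared-well depth assigned to every selected contact
#: (Rosetta energy units; negative = bonus).
DEFAULT_WELL_DEPTH = -15.0

#: Neighbour tolerance around a contact (i, j): the pair itself plus
#: single-index shifts of up to two residues on either side.
NEIGHBOR_OFFSETS: Tuple[Tuple[int, int], ...] = (
    (0, 0),
    (0, 1), (0, -1), (0, 2), (0, -2),
    (1, 0), (-1, 0), (2, 0), (-2, 0),
)


class BoundsError(ValueError):
    """A residue index falls outside [1, L]."""


class SelfContactError(ValueError):
    """A pair contacts a residue with itself."""


@dataclass
class ContactPair:
    """A single predicted residue-residue contact.

    Attributes
    ----------
    res1, res2:
        1-based residue indices, stored with ``res1 < res2``.
    raw_score:
        Predictor confidence (dimensionless).
    weight:
        Squared-well depth the pair will carry as a restraint
        (energy units, always <= 0).
    source:
        Provenance tag: ``general`` (from the general predictor),
        ``beta_specific`` (from a strand-pairing predictor),
        ``fused_upweighted`` or ``fused_added`` (set during fusion).
    group_id:
        Strand-pairing identifier for beta-specific contacts, else None.
    """

    res1: int
    res2: int
    raw_score: float
    weight: float = DEFAULT_WELL_DEPTH
    source: str = "general"
    group_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.res1 == self.res2:
            raise SelfContactError(
                f"self-contact ({self.res1}, {self.res2}) is not a valid pair"
            )
        if self.res1 > self.res2:
            self.res1, self.res2 = self.res2, self.res1
        if self.res1 < 1:
            raise BoundsError(f"residue index {self.res1} < 1")
        if self.weight > 0:
            raise ValueError(f"well depth must be <= 0, got {self.weight}")

    @property
    def key(self) -> Tuple[int, int]:
        return (self.res1, self.res2)


@dataclass
class ContactMap:
    """An ordered, duplicate-free contact list over a target sequence.

    Iteration order is descending ``raw_score``; ties break on
    ascending ``(res1, res2)`` so ranking is deterministic.
    """

    target_id: str
    sequence: str
    contacts: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        if not self.sequence:
            raise ValueError("contact map requires a non-empty sequence")
        length = len(self.sequence)
        seen = set()
        for p in self.contacts:
            if p.res2 > length:
                raise BoundsError(
                    f"contact ({p.res1}, {p.res2}) outside sequence of length {length}"
                )
            if p.key in seen:
                raise ValueError(f"duplicate contact pair {p.key}")
            seen.add(p.key)
        self.contacts.sort(key=_rank_key)

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self) -> Iterator[ContactPair]:
        return iter(self.contacts)

    @property
    def length(self) -> int:
        """Target chain length L."""
        return len(self.sequence)

    def pair_set(self) -> set:
        return {p.key for p in self.contacts}


def _rank_key(p: ContactPair) -> Tuple[float, int, int]:
    return (-p.raw_score, p.res1, p.res2)


def canonicalize(
    pairs: Iterable[Tuple[int, int, float]],
    sequence: str,
    target_id: str = "",
    min_separation: int = 0,
) -> ContactMap:
    """Build a canonical :class:`ContactMap` from raw (i, j, score) triples.

    Pairs are reordered so ``res1 < res2``, duplicates collapse keeping
    the maximum score, and the result is ranked by descending score.
    ``min_separation`` optionally drops pairs with ``|i - j|`` below the
    given value (0 = keep all; some comparison protocols use 5).
    """
    length = len(sequence)
    best: dict = {}
    for res1, res2, score in pairs:
        if res1 == res2:
            raise SelfContactError(f"self-contact ({res1}, {res2})")
        lo, hi = (res1, res2) if res1 < res2 else (res2, res1)
        if lo < 1 or hi > length:
            raise BoundsError(
                f"contact ({res1}, {res2}) outside [1, {length}]"
            )
        if hi - lo < min_separation:
            continue
        key = (lo, hi)
        if key not in best or score > best[key]:
            best[key] = score
    contacts = [ContactPair(r1, r2, s) for (r1, r2), s in best.items()]
    return ContactMap(target_id=target_id, sequence=sequence, contacts=contacts)


def top_l_select(cmap: ContactMap, l: int) -> ContactMap:
    """Keep the ``min(l, |contacts|)`` highest-confidence pairs.

    This is the standard top-L cut with L the target chain length:
    only the L best-scoring predicted contacts are carried forward as
    restraints.  Selected pairs are (re)assigned the baseline well
    depth of -15.00.
    """
    if l <= 0:
        raise ValueError(f"top-L cut requires l >= 1, got {l}")
    selected = [
        replace(p, weight=DEFAULT_WELL_DEPTH) for p in cmap.contacts[:l]
    ]
    return ContactMap(cmap.target_id, cmap.sequence, selected)


def is_neighbor(a: ContactPair, b: ContactPair) -> bool:
    """True if ``b`` lies within the neighbour tolerance of ``a``.

    Neighbours of (i, j) are the pair itself and the eight single-index
    shifts (i, j±1), (i, j±2), (i±1, j), (i±2, j); equality counts so
    that an identical beta-specific pair upweights rather than
    duplicates a general one.
    """
    bk = b.key
    for di, dj in NEIGHBOR_OFFSETS:
        si, sj = a.res1 + di, a.res2 + dj
        if si == sj:
            continue
        if si > sj:
            si, sj = sj, si
        if (si, sj) == bk:
            return True
    return False
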
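"""Squared-well (FADE) distance restraints from contact pairs.

Each contact becomes an atom-pair restraint between the two C-beta
atoms (C-alpha for glycine) evaluated with the FADE functional: a flat
energy bonus of depth ``wd`` while the inter-atom distance lies inside
the well, smoothly faded to zero at the well edges, and exactly zero
beyond them — so a false-positive contact never exerts a long-range
attraction.  The default parameterization (lb, ub, z) = (-10, 19, 10)
puts the full-depth region at [0, 9] Angstrom: a restraint is satisfied
when the two atoms are within 9 A, and the bonus vanishes beyond 19 A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Union

from .fusion import FusedRestraintSet
from .model import BoundsError, ContactMap, ContactPair

__all__ = ["FadeParams", "RestraintRecord", "pairs_to_restraints", "fade_energy"]

GLYCINE = "G"


@dataclass(frozen=True)
class FadeParams:
    """Parameters of the FADE well.

    lb, ub : float
        Outer bounds (Angstrom) beyond which the energy is zero.
    z : float
        Width of each fade zone; the full-depth region is
        [lb + z, ub - z].
    wd : float
        Well depth (energy units, <= 0).
    offset : float
        Constant added inside the well (0 for a pure bonus).
    """

    lb: float = -10.0
    ub: float = 19.0
    z: float = 10.0
    wd: float = -15.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.lb < self.ub:
            raise ValueError(f"need lb < ub, got ({self.lb}, {self.ub})")
        if not 0 < self.z <= (self.ub - self.lb) / 2:
            raise ValueError(
                f"fade zone {self.z} must lie in (0, (ub-lb)/2]"
            )
        if self.wd > 0:
            raise ValueError(f"well depth must be <= 0, got {self.wd}")


@dataclass(frozen=True)
class RestraintRecord:
    """One atom-pair restraint, serializable as a constraint-file line."""

    res1: int
    res2: int
    atom1: str
    atom2: str
    params: FadeParams

    def __post_init__(self) -> None:
        if not self.res1 < self.res2:
            raise ValueError("restraint residues must satisfy res1 < res2")


def _atom_for(residue: str) -> str:
    return "CA" if residue == GLYCINE else "CB"


def pairs_to_restraints(
    pairs: Union[FusedRestraintSet, ContactMap, Iterable[ContactPair]],
    sequence: str,
) -> List[RestraintRecord]:
    """Convert contact pairs to FADE restraint records.

    The well depth of each record is taken from the pair's weight
    (-15.00 baseline, -30.00 for upweighted beta contacts); the atom is
    C-beta, or C-alpha where the sequence has glycine.
    """
    records = []
    length = len(sequence)
    for p in pairs:
        if p.res2 > length:
            raise BoundsError(
                f"contact ({p.res1}, {p.res2}) beyond sequence length {length}"
            )
        records.append(
            RestraintRecord(
                res1=p.res1,
                res2=p.res2,
                atom1=_atom_for(sequence[p.res1 - 1]),
                atom2=_atom_for(sequence[p.res2 - 1]),
                params=FadeParams(wd=p.weight),
            )
        )
    return records


def fade_energy(d: float, p: FadeParams = FadeParams()) -> float:
    """Evaluate the FADE well at distance ``d`` (Angstrom).

    Returns ``wd + offset`` on the full-depth region [lb+z, ub-z], zero
    outside [lb, ub], and a cubic-Hermite (smoothstep) interpolation in
    the fade zones, with zero slope at both zone edges — continuous and
    once-differentiable everywhere.
    """
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    if d <= p.lb or d >= p.ub:
        return 0.0
    if p.lb + p.z <= d <= p.ub - p.z:
        return p.wd + p.offset
    if d < p.lb + p.z:  # rising fade-in (unreachable for d >= 0 at defaults)
        t = (d - p.lb) / p.z
    else:  # fade-out toward ub
        t = (p.ub - d) / p.z
    smooth = 3.0 * t * t - 2.0 * t * t * t
    return p.wd * smooth + p.offset * smooth
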
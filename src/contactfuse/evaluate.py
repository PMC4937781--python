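"""Scoring contact predictions against a crystal structure, and the
molecular-replacement success gate.

Reference contacts are every residue pair whose representative atoms
(C-beta; C-alpha for glycine or residues missing C-beta) lie within the
distance cutoff (9 A by default, inclusive) in the crystal structure.
Predicted pairs are true positives if present in that reference set —
an exact membership test, with no neighbour tolerance — and precision
is PPV = TP / (TP + FP).  Pairs touching residues that are unresolved
in the crystal cannot be verified and are excluded from both counts.

The MR gate reproduces the stringent success criterion used for
ab initio molecular replacement trials: SHELXE correlation coefficient
CC >= 25.00, mean traced chain length ACL >= 10.00, and a rebuild
Rfree <= 0.45 from either rebuilding program (so the minimum of the
available Rfree values is compared).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import Align
from scipy.spatial.distance import pdist, squareform

from .fusion import FusedRestraintSet
from .io import SequenceRecord, StructureModel
from .model import ContactMap, ContactPair

__all__ = [
    "ReferenceContactSet",
    "PrecisionReport",
    "MRTrialResult",
    "NumberingMismatchError",
    "UndefinedPPVError",
    "map_numbering",
    "extract_reference_contacts",
    "ppv",
    "mr_success",
    "CC_THRESHOLD",
    "ACL_THRESHOLD",
    "RFREE_THRESHOLD",
]

CC_THRESHOLD = 25.0
ACL_THRESHOLD = 10.0
RFREE_THRESHOLD = 0.45

GLY3 = "GLY"


class NumberingMismatchError(ValueError):
    """Structure and model sequences align below the identity floor."""


class UndefinedPPVError(ValueError):
    """No verifiable predictions: PPV has an empty denominator."""


@dataclass(frozen=True)
class ReferenceContactSet:
    """Structure-derived true contacts in model (target) numbering."""

    pairs: FrozenSet[Tuple[int, int]]
    resolved: FrozenSet[int]        # model indices with usable coordinates
    cutoff: float = 9.0
    n_skipped: int = 0              # residues lacking both CA and CB

    def __contains__(self, pair: Tuple[int, int]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class PrecisionReport:
    tp: int
    fp: int
    unverifiable: int

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)


@dataclass(frozen=True)
class MRTrialResult:
    """One molecular-replacement trial: SHELXE CC, trace length, Rfree."""

    shelxe_cc: float
    acl: float
    rfree_candidates: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.rfree_candidates:
            raise ValueError("at least one Rfree candidate is required")
        for r in self.rfree_candidates:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"Rfree {r} outside [0, 1]")
        if self.acl < 0:
            raise ValueError(f"ACL must be >= 0, got {self.acl}")

    @property
    def success(self) -> bool:
        return mr_success(self)


def map_numbering(
    model_seq: SequenceRecord,
    structure: StructureModel,
    identity_floor: float = 0.90,
) -> Dict[int, int]:
    """Map structure residue positions to 1-based model sequence indices.

    The structure's observed sequence is globally aligned (free end
    gaps) to the modelled FASTA sequence; unaligned structure residues
    are dropped and the mapping is strictly increasing.  An alignment
    identity below ``identity_floor`` raises, guarding against chain
    mix-ups.
    """
    target = model_seq.ungapped
    query = structure.one_letter_sequence()
    if not query:
        raise NumberingMismatchError("structure contains no residues")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # Biopython < 1.86 naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    alignment = aligner.align(target, query)[0]
    mapping: Dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for offset in range(t1 - t0):
            ti, qi = t0 + offset, q0 + offset
            aligned_cols += 1
            if target[ti] == query[qi]:
                matches += 1
            mapping[qi] = ti + 1  # structure position -> 1-based model index
    if aligned_cols == 0 or matches / aligned_cols < identity_floor:
        identity = matches / aligned_cols if aligned_cols else 0.0
        raise NumberingMismatchError(
            f"structure/model sequence identity {identity:.2f} below "
            f"floor {identity_floor:.2f}"
        )
    return mapping


def _representative_atom(residue) -> Optional[np.ndarray]:
    """CB, falling back to CA for glycine or incomplete side chains."""
    if residue.name == GLY3:
        return residue.ca
    if residue.cb is not None:
        return residue.cb
    return residue.ca


def extract_reference_contacts(
    structure: StructureModel,
    mapping: Dict[int, int],
    cutoff: float = 9.0,
    min_separation: int = 0,
) -> ReferenceContactSet:
    """All mapped residue pairs within ``cutoff`` (inclusive) of one
    another, measured between representative atoms."""
    indices: List[int] = []
    coords: List[np.ndarray] = []
    n_skipped = 0
    for pos, res in enumerate(structure.residues):
        if pos not in mapping:
            continue
        atom = _representative_atom(res)
        if atom is None:
            n_skipped += 1
            continue
        indices.append(mapping[pos])
        coords.append(atom)
    pairs = set()
    if len(coords) >= 2:
        dmat = squareform(pdist(np.array(coords)))
        n = len(indices)
        for a in range(n):
            for b in range(a + 1, n):
                i, j = sorted((indices[a], indices[b]))
                if j - i < min_separation:
                    continue
                if dmat[a, b] <= cutoff:
                    pairs.add((i, j))
    return ReferenceContactSet(
        pairs=frozenset(pairs),
        resolved=frozenset(indices),
        cutoff=cutoff,
        n_skipped=n_skipped,
    )


def ppv(
    predictions: Union[ContactMap, FusedRestraintSet, Iterable[ContactPair]],
    reference: ReferenceContactSet,
) -> PrecisionReport:
    """Score predicted contacts against the reference set.

    Exact-pair membership decides true/false positives; pairs involving
    residues without crystal coordinates are counted unverifiable and
    excluded from the denominator.
    """
    tp = fp = unverifiable = 0
    for p in predictions:
        if p.res1 not in reference.resolved or p.res2 not in reference.resolved:
            unverifiable += 1
        elif p.key in reference.pairs:
            tp += 1
        else:
            fp += 1
    if tp + fp == 0:
        raise UndefinedPPVError(
            "no verifiable predictions: every pair involves unresolved "
            "residues (or the prediction list is empty)"
        )
    return PrecisionReport(tp=tp, fp=fp, unverifiable=unverifiable)


def mr_success(
    trial: MRTrialResult,
    cc_threshold: float = CC_THRESHOLD,
    acl_threshold: float = ACL_THRESHOLD,
    rfree_threshold: float = RFREE_THRESHOLD,
) -> bool:
    """Apply the MR success gate (all comparisons inclusive)."""
    return (
        trial.shelxe_cc >= cc_threshold
        and trial.acl >= acl_threshold
        and min(trial.rfree_candidates) <= rfree_threshold
    )
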
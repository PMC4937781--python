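"""Alignment diversity statistics.

Covariance-based contact prediction needs a deep, diverse multiple
sequence alignment.  Two descriptors are computed here:

* ``Neff`` — the effective number of sequences: alignment members are
  clustered at 62% pairwise identity, each sequence gets a fractional
  weight of 1/(its cluster size), and Neff is the sum of those weights
  (equivalently, the number of clusters).  An Neff above ~100 is the
  usual minimum for reliable covariance signals.
* ``eta`` — the diversity factor sqrt(N / L) required by beta-strand
  contact filtering, with N the raw sequence count and L the target
  chain length.

Clustering follows the CD-HIT conventions (identity denominator = the
shorter ungapped length; greedy assignment to the first representative
above threshold after sorting by length) but uses a direct O(n^2)
greedy pass rather than CD-HIT's word-filter heuristics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

from .io import FormatError, SequenceRecord

__all__ = [
    "Msa",
    "MsaDiversity",
    "pairwise_identity",
    "greedy_cluster",
    "neff",
    "eta",
    "diversity",
    "IDENTITY_THRESHOLD",
]

#: Clustering identity threshold for Neff.
IDENTITY_THRESHOLD = 0.62


@dataclass
class Msa:
    """An alignment: equal-length gapped records, query first."""

    records: List[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("MSA requires at least one record")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise FormatError(
                f"MSA records have unequal aligned lengths {sorted(lengths)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def target_length(self) -> int:
        """Ungapped length L of the query (first) record."""
        return len(self.records[0].ungapped)


@dataclass(frozen=True)
class MsaDiversity:
    n: int
    n_eff: float
    n_clusters: int
    eta: float


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction of identical aligned columns over the shorter ungapped
    length (CD-HIT convention).  Columns where either record has a gap
    never count as matches."""
    if len(a) != len(b):
        raise ValueError(
            f"aligned lengths differ: {len(a)} vs {len(b)}"
        )
    matches = sum(
        1
        for x, y in zip(a.residues, b.residues)
        if x == y and x != "-"
    )
    denom = min(len(a.ungapped), len(b.ungapped))
    if denom == 0:
        raise ValueError("cannot compare all-gap sequences")
    return matches / denom


def greedy_cluster(
    msa: Msa, threshold: float = IDENTITY_THRESHOLD
) -> List[List[SequenceRecord]]:
    """Greedy identity clustering at the given threshold.

    Records are visited by descending ungapped length (ties keep input
    order); each joins the first cluster whose founder it matches at
    >= threshold identity, otherwise it founds a new cluster.
    """
    ordered = sorted(
        range(len(msa.records)),
        key=lambda k: (-len(msa.records[k].ungapped), k),
    )
    clusters: List[List[SequenceRecord]] = []
    founders: List[SequenceRecord] = []
    for k in ordered:
        rec = msa.records[k]
        for c, founder in enumerate(founders):
            if pairwise_identity(rec, founder) >= threshold:
                clusters[c].append(rec)
                break
        else:
            clusters.append([rec])
            founders.append(rec)
    return clusters


def neff(msa: Msa, threshold: float = IDENTITY_THRESHOLD) -> float:
    """Effective sequence count: sum of fractional weights 1/|cluster|,
    i.e. the number of identity clusters."""
    clusters = greedy_cluster(msa, threshold)
    return float(sum(len(c) * (1.0 / len(c)) for c in clusters))


def eta(n: int, l: int) -> float:
    """Diversity factor sqrt(N / L) for beta-contact filtering."""
    if n < 1 or l < 1:
        raise ValueError(f"eta requires n >= 1 and l >= 1, got ({n}, {l})")
    return math.sqrt(n / l)


def diversity(msa: Msa, threshold: float = IDENTITY_THRESHOLD) -> MsaDiversity:
    """Full diversity report for an alignment."""
    clusters = greedy_cluster(msa, threshold)
    n = len(msa)
    return MsaDiversity(
        n=n,
        n_eff=float(len(clusters)),
        n_clusters=len(clusters),
        eta=eta(n, msa.target_length),
    )
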
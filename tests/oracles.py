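"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each rule from its definition (offset
enumeration, exhaustive distance scans, naive greedy passes) rather
than calling the code paths they verify.
"""

from typing import List, Sequence, Tuple

import numpy as np

NINE_OFFSETS = [
    (0, 0),
    (0, 1), (0, -1), (0, 2), (0, -2),
    (1, 0), (-1, 0), (2, 0), (-2, 0),
]


def neighbor_oracle(a_key: Tuple[int, int], b_key: Tuple[int, int]) -> bool:
    """b is a neighbour of a iff it appears in a's 9-offset enumeration."""
    i, j = a_key
    targets = set()
    for di, dj in NINE_OFFSETS:
        si, sj = i + di, j + dj
        if si != sj:
            targets.add((min(si, sj), max(si, sj)))
    return b_key in targets


def fuse_oracle(
    topl_keys: Sequence[Tuple[int, int]],
    beta_keys: Sequence[Tuple[int, int]],
    base_wd: float = -15.0,
    mult: float = 2.0,
):
    """Naive all-pairs fusion: returns (ordered pair keys, weights,
    sources) exactly as the fused list should read."""
    keys, weights, sources = [], [], []
    for p in topl_keys:
        matched = any(neighbor_oracle(b, p) for b in beta_keys)
        keys.append(p)
        weights.append(base_wd * mult if matched else base_wd)
        sources.append("fused_upweighted" if matched else "general")
    seen = set(keys)
    for b in beta_keys:
        if any(neighbor_oracle(b, p) for p in topl_keys):
            continue
        if b in seen:
            continue
        keys.append(b)
        weights.append(base_wd)
        sources.append("fused_added")
        seen.add(b)
    return keys, weights, sources


def contact_scan(coords: List[np.ndarray], indices: List[int], cutoff: float):
    """Exhaustive all-pairs distance scan."""
    pairs = set()
    for a in range(len(coords)):
        for b in range(a + 1, len(coords)):
            d = float(np.sqrt(np.sum((coords[a] - coords[b]) ** 2)))
            if d <= cutoff:
                i, j = sorted((indices[a], indices[b]))
                pairs.add((i, j))
    return pairs


def greedy_cluster_oracle(sequences: Sequence[str], threshold: float):
    """Naive restatement of the greedy clustering rule over gapped
    aligned strings; returns clusters of indices into ``sequences``."""

    def ungapped_len(s: str) -> int:
        return len(s.replace("-", ""))

    def identity(a: str, b: str) -> float:
        matches = sum(
            1 for x, y in zip(a, b) if x == y and x != "-"
        )
        return matches / min(ungapped_len(a), ungapped_len(b))

    order = sorted(range(len(sequences)),
                   key=lambda k: (-ungapped_len(sequences[k]), k))
    clusters: List[List[int]] = []
    for k in order:
        for cluster in clusters:
            if identity(sequences[k], sequences[cluster[0]]) >= threshold:
                cluster.append(k)
                break
        else:
            clusters.append([k])
    return clusters
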
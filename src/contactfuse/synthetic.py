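"""Deterministic synthetic fixtures with known ground truth.

Every input class the toolkit consumes can be generated here without
touching external databases: idealized structures whose contact
geometry is known analytically (helix, beta-hairpin, two-sheet
sandwich), contact maps with a PPV fixed by construction, beta-strand
ladder groups that exercise the fusion neighbour rule, and alignments
with a controlled mutation rate.  All generators are pure functions of
a :class:`FixtureSpec` (seed included), so fixtures are bit-reproducible
and can be written out in the corresponding standard formats for
end-to-end command-line round trips.

The geometry is idealized, not physical: strands are straight, the
helix is a perfect spiral, and side chains beyond C-beta do not exist.
That is sufficient because the toolkit only ever measures CA/CB
distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import gemmi
import numpy as np

from .evaluate import ReferenceContactSet, extract_reference_contacts
from .fusion import StrandPairGroup
from .io import ResidueRecord, SequenceRecord, StructureModel
from .model import ContactMap, ContactPair
from .msa import Msa

__all__ = [
    "FixtureSpec",
    "make_sequence",
    "make_structure",
    "identity_mapping",
    "make_reference",
    "make_contact_map",
    "make_strand_groups",
    "make_msa",
    "write_fixture_dir",
    "structure_to_pdb_string",
]

TOPOLOGIES = ("helix", "hairpin", "sheet-sandwich")

AA20 = "ACDEFGHIKLMNPQRSTVWY"

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# Idealized backbone parameters (Angstrom / degrees).
HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST = 100.0
STRAND_RISE = 3.4        # per-residue translation along a straight strand
STRAND_SPACING = 4.8     # inter-strand spacing within a sheet
SHEET_SPACING = 10.0     # sheet-to-sheet spacing in the sandwich
CB_OFFSET = 1.5


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic target."""

    seed: int = 0
    l: int = 24
    topology: str = "hairpin"
    n_true: int = 8
    n_false: int = 2
    msa_n: int = 10
    msa_mutation_rate: float = 0.3

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(
                f"unsupported topology {self.topology!r}; "
                f"choose from {TOPOLOGIES}"
            )
        if self.n_true < 0 or self.n_false < 0:
            raise ValueError("pair counts must be >= 0")
        if self.topology == "hairpin" and self.l < 8:
            raise ValueError("hairpin topology requires l >= 8")
        if self.topology == "sheet-sandwich" and self.l < 16:
            raise ValueError("sheet-sandwich topology requires l >= 16")
        if self.l < 4:
            raise ValueError("target length must be >= 4")


def make_sequence(spec: FixtureSpec) -> SequenceRecord:
    """Deterministic random sequence for the target (glycines included
    so the CA fallback rule is exercised)."""
    rng = np.random.default_rng(spec.seed)
    letters = rng.choice(list(AA20), size=spec.l)
    # guarantee at least one glycine away from the termini
    gly_pos = int(rng.integers(1, spec.l - 1))
    letters[gly_pos] = "G"
    return SequenceRecord(f"synthetic_{spec.topology}_{spec.seed}", "".join(letters))


def _helix_coords(l: int) -> Tuple[np.ndarray, np.ndarray]:
    idx = np.arange(l)
    theta = np.deg2rad(HELIX_TWIST * idx)
    ca = np.stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta),
         HELIX_RISE * idx], axis=1
    )
    cb = np.stack(
        [(HELIX_RADIUS + CB_OFFSET) * np.cos(theta),
         (HELIX_RADIUS + CB_OFFSET) * np.sin(theta),
         HELIX_RISE * idx], axis=1
    )
    return ca, cb


def _hairpin_coords(l: int, x0: float = 0.0, z0: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Two straight antiparallel strands; residue i pairs residue l+1-i
    across a 4.8 A gap."""
    h = l // 2
    ca = np.zeros((l, 3))
    for i in range(1, l + 1):
        if i <= h:
            ca[i - 1] = (x0, (i - 1) * STRAND_RISE, z0)
        else:
            ca[i - 1] = (x0 + STRAND_SPACING, (l - i) * STRAND_RISE, z0)
    # pleated CB: alternate above/below the strand plane
    cb = ca.copy()
    cb[:, 2] += CB_OFFSET * np.where(np.arange(l) % 2 == 0, 1.0, -1.0)
    return ca, cb


def _sandwich_coords(l: int) -> Tuple[np.ndarray, np.ndarray]:
    m = l // 2
    ca1, cb1 = _hairpin_coords(m, x0=0.0, z0=0.0)
    ca2, cb2 = _hairpin_coords(l - m, x0=0.0, z0=SHEET_SPACING)
    return np.vstack([ca1, ca2]), np.vstack([cb1, cb2])


def make_structure(spec: FixtureSpec) -> StructureModel:
    """Idealized coordinates for the chosen topology.

    Cross-strand partners (i, l+1-i) of a hairpin and helical (i, i+4)
    pairs sit well inside the 9 A contact cutoff by construction.  A
    small seeded jitter (<= 0.05 A) keeps distinct seeds distinct
    without disturbing any contact classification.
    """
    sequence = make_sequence(spec)
    if spec.topology == "helix":
        ca, cb = _helix_coords(spec.l)
    elif spec.topology == "hairpin":
        ca, cb = _hairpin_coords(spec.l)
    else:
        ca, cb = _sandwich_coords(spec.l)
    rng = np.random.default_rng(spec.seed + 7919)
    jitter = rng.uniform(-0.05, 0.05, size=ca.shape)
    ca = ca + jitter
    cb = cb + jitter
    residues = []
    for i, letter in enumerate(sequence.residues):
        residues.append(
            ResidueRecord(
                chain_id="A",
                seqnum=i + 1,
                name=THREE_LETTER[letter],
                ca=ca[i],
                cb=None if letter == "G" else cb[i],
            )
        )
    return StructureModel(residues=residues)


def identity_mapping(structure: StructureModel) -> Dict[int, int]:
    """Trivial mapping for fixtures whose numbering is already 1..L."""
    return {pos: pos + 1 for pos in range(len(structure.residues))}


def make_reference(spec: FixtureSpec, cutoff: float = 9.0) -> ReferenceContactSet:
    """Reference contacts of the generated structure."""
    structure = make_structure(spec)
    return extract_reference_contacts(structure, identity_mapping(structure), cutoff)


def make_contact_map(
    spec: FixtureSpec, reference: ReferenceContactSet
) -> ContactMap:
    """Contact map with PPV fixed by construction.

    ``n_true`` pairs are drawn from the reference set with high scores
    and ``n_false`` pairs from its complement (over resolved residues)
    with lower, interleaving scores, so that
    PPV = n_true / (n_true + n_false) exactly.
    """
    rng = np.random.default_rng(spec.seed + 104729)
    ref_pairs = sorted(reference.pairs)
    if len(ref_pairs) < spec.n_true:
        raise ValueError(
            f"reference has {len(ref_pairs)} pairs, need {spec.n_true}"
        )
    resolved = sorted(reference.resolved)
    complement = [
        p for p in itertools.combinations(resolved, 2)
        if p not in reference.pairs
    ]
    if len(complement) < spec.n_false:
        raise ValueError(
            f"complement has {len(complement)} pairs, need {spec.n_false}"
        )
    true_idx = rng.choice(len(ref_pairs), size=spec.n_true, replace=False)
    false_idx = rng.choice(len(complement), size=spec.n_false, replace=False)
    contacts = [
        ContactPair(*ref_pairs[k], raw_score=float(rng.uniform(0.55, 1.0)))
        for k in true_idx
    ]
    contacts += [
        ContactPair(*complement[k], raw_score=float(rng.uniform(0.05, 0.65)))
        for k in false_idx
    ]
    sequence = make_sequence(spec)
    return ContactMap(sequence.id, sequence.residues, contacts)


def _antiparallel_ladders(
    reference: ReferenceContactSet, min_run: int
) -> List[List[Tuple[int, int]]]:
    """Maximal runs (i, j), (i+1, j-1), ... within the reference set."""
    pairs = set(reference.pairs)
    ladders = []
    for i, j in sorted(pairs):
        if (i - 1, j + 1) in pairs:
            continue  # not a run start
        run = []
        a, b = i, j
        while (a, b) in pairs and a < b:
            run.append((a, b))
            a, b = a + 1, b - 1
        if len(run) >= min_run:
            ladders.append(run)
    return ladders


def make_strand_groups(
    reference: ReferenceContactSet,
    n_groups: int = 1,
    group_size: int = 3,
    jitter: int = 0,
    seed: int = 0,
    length: Optional[int] = None,
) -> List[StrandPairGroup]:
    """Antiparallel ladder groups drawn from the reference contacts.

    ``jitter`` > 0 perturbs one index of one member per group by up to
    ``jitter`` (<= 2) residues, producing a pair that is *near* a true
    contact — exactly the case the fusion neighbour tolerance exists
    for.
    """
    if group_size < 1:
        raise ValueError(f"group_size must be >= 1, got {group_size}")
    if not 0 <= jitter <= 2:
        raise ValueError(f"jitter must be within [0, 2], got {jitter}")
    rng = np.random.default_rng(seed + 15485863)
    ladders = _antiparallel_ladders(reference, group_size)
    if len(ladders) < n_groups:
        raise ValueError(
            f"reference supports only {len(ladders)} ladder(s) of size "
            f">= {group_size}, need {n_groups}"
        )
    chosen = rng.choice(len(ladders), size=n_groups, replace=False)
    limit = length or max(reference.resolved)
    groups = []
    for g, k in enumerate(sorted(chosen)):
        run = ladders[k][:group_size]
        members = [
            ContactPair(i, j, raw_score=float(rng.uniform(0.5, 1.0)),
                        source="beta_specific", group_id=f"B{g + 1}")
            for i, j in run
        ]
        if jitter > 0:
            m = members[int(rng.integers(len(members)))]
            shift = int(rng.integers(1, jitter + 1)) * (1 if rng.random() < 0.5 else -1)
            new1 = min(max(m.res1 + shift, 1), limit)
            if new1 != m.res2:
                m.res1, m.res2 = sorted((new1, m.res2))
        groups.append(
            StrandPairGroup(group_id=f"B{g + 1}", direction="antiparallel",
                            members=members)
        )
    return groups


def make_msa(spec: FixtureSpec) -> Msa:
    """Query plus mutated copies at a per-column substitution rate."""
    if not 0.0 <= spec.msa_mutation_rate <= 1.0:
        raise ValueError(
            f"mutation rate {spec.msa_mutation_rate} outside [0, 1]"
        )
    if spec.msa_n < 1:
        raise ValueError("MSA needs at least one sequence")
    rng = np.random.default_rng(spec.seed + 32452843)
    query = make_sequence(spec)
    records = [SequenceRecord("query", query.residues)]
    for k in range(spec.msa_n - 1):
        chars = list(query.residues)
        for col in range(len(chars)):
            if rng.random() < spec.msa_mutation_rate:
                choices = [a for a in AA20 if a != chars[col]]
                chars[col] = choices[int(rng.integers(len(choices)))]
        records.append(SequenceRecord(f"s{k + 1}", "".join(chars)))
    return Msa(records=records)


def structure_to_pdb_string(structure: StructureModel) -> str:
    """Serialize a StructureModel as minimal PDB text (via gemmi)."""
    st = gemmi.Structure()
    st.name = "synthetic"
    model = gemmi.Model("1")
    chains: Dict[str, gemmi.Chain] = {}
    for rec in structure.residues:
        chain = chains.get(rec.chain_id)
        if chain is None:
            chain = gemmi.Chain(rec.chain_id)
            chains[rec.chain_id] = chain
        res = gemmi.Residue()
        res.name = rec.name
        res.seqid = gemmi.SeqId(rec.seqnum, " ")
        res.het_flag = "A"
        for atom_name, coord in (("CA", rec.ca), ("CB", rec.cb)):
            if coord is None:
                continue
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*[float(x) for x in coord])
            atom.occ = 1.0
            res.add_atom(atom)
        chain.add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def write_fixture_dir(spec: FixtureSpec, outdir) -> Dict[str, Path]:
    """Emit a complete fixture directory in standard formats.

    Writes structure.pdb, target.fa, pred.rr, beta.tsv and msa.fa so
    every reader (and the command-line pipeline) can be exercised
    end-to-end on files.
    """
    from . import io as iomod  # local import to avoid cycle at module load

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequence = make_sequence(spec)
    structure = make_structure(spec)
    reference = make_reference(spec)
    cmap = make_contact_map(spec, reference)
    paths = {
        "structure": outdir / "structure.pdb",
        "fasta": outdir / "target.fa",
        "rr": outdir / "pred.rr",
        "beta": outdir / "beta.tsv",
        "msa": outdir / "msa.fa",
    }
    paths["structure"].write_text(structure_to_pdb_string(structure))
    paths["fasta"].write_text(f">{sequence.id}\n{sequence.residues}\n")
    iomod.write_casp_rr(cmap, paths["rr"])
    if spec.topology in ("hairpin", "sheet-sandwich"):
        groups = make_strand_groups(
            reference, n_groups=1, group_size=3, seed=spec.seed,
            length=spec.l,
        )
    else:
        groups = []
    iomod.write_bbcontacts_table(groups, paths["beta"])
    msa = make_msa(spec)
    with open(paths["msa"], "w") as handle:
        for rec in msa.records:
            handle.write(f">{rec.id}\n{rec.residues}\n")
    return paths
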
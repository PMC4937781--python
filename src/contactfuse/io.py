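"""Readers and writers for the external formats the toolkit touches.

Sequence files go through Biopython, coordinate files through gemmi and
tabular beta-contact files through pandas; the Rosetta constraint-file
dialect (one ``AtomPair ... FADE ...`` line per restraint) has its own
reader/writer here because its numeric formatting must be byte-stable.

All readers accept a path, a string of file content is not guessed —
pass an open text handle or ``io.StringIO`` for in-memory input.
Residue numbering in every in-memory object is 1-based over the target
sequence.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, TextIO, Tuple, Union

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

from .fusion import StrandPairGroup
from .model import BoundsError, ContactMap, ContactPair, canonicalize
from .restraints import FadeParams, RestraintRecord

__all__ = [
    "SequenceRecord",
    "ResidueRecord",
    "StructureModel",
    "FormatError",
    "read_fasta",
    "read_msa_fasta",
    "read_casp_rr",
    "read_score_matrix",
    "read_bbcontacts_table",
    "write_restraint_file",
    "read_restraint_file",
    "read_structure",
]

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX-")

Source = Union[str, Path, TextIO]


class FormatError(ValueError):
    """An input file violates its documented dialect."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence, possibly gapped (aligned FASTA)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - AMINO_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r} has invalid characters {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ResidueRecord:
    """One residue of a crystal structure with its CA/CB coordinates."""

    chain_id: str
    seqnum: int            # author residue number
    name: str              # three-letter residue name
    ca: Optional[np.ndarray] = None
    cb: Optional[np.ndarray] = None


@dataclass
class StructureModel:
    """First-model, polymer-only view of a coordinate file."""

    residues: List[ResidueRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def one_letter_sequence(self) -> str:
        out = []
        for r in self.residues:
            info = gemmi.find_tabulated_residue(r.name)
            code = info.one_letter_code.upper() if info else "X"
            out.append(code if code.isalpha() else "X")
        return "".join(out)


def _open(source: Source):
    """Return (handle, needs_close) for a path or an open text stream."""
    if isinstance(source, (str, Path)):
        return open(source, "r"), True
    return source, False


def _read_text(source: Source) -> str:
    handle, close = _open(source)
    try:
        return handle.read()
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(source: Source) -> List[SequenceRecord]:
    """Read plain or aligned FASTA; gap characters are preserved."""
    handle, close = _open(source)
    try:
        records = [
            SequenceRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        if close:
            handle.close()
    if not records:
        raise FormatError("FASTA input contains no records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sequence ids in FASTA input")
    return records


def read_msa_fasta(source: Source) -> List[SequenceRecord]:
    """Read aligned FASTA; all records must share one aligned length."""
    records = read_fasta(source)
    lengths = {len(r) for r in records}
    if len(lengths) != 1:
        raise FormatError(
            f"aligned FASTA records have unequal lengths {sorted(lengths)}"
        )
    return records


# ---------------------------------------------------------------------------
# CASP RR contact lists

def read_casp_rr(
    source: Source,
    sequence: SequenceRecord,
    strict_confidence: bool = False,
) -> ContactMap:
    """Read a CASP-RR-style contact list into a canonical map.

    Rows are ``i j d_lo d_hi confidence``; header/comment lines
    (non-numeric first token, e.g. PFRMAT/TARGET/MODEL, or the bare
    sequence) are skipped.  ``strict_confidence`` additionally requires
    scores in [0, 1].
    """
    triples: List[Tuple[int, int, float]] = []
    for lineno, raw in enumerate(_read_text(source).splitlines(), start=1):
        line = raw.strip()
        if not line or line.upper() == "END":
            continue
        tokens = line.split()
        first = tokens[0]
        if not (first.lstrip("+-").isdigit()):
            continue  # header, remark or sequence line
        if len(tokens) < 5:
            raise FormatError(f"line {lineno}: expected 'i j d_lo d_hi conf'")
        try:
            i, j = int(tokens[0]), int(tokens[1])
            conf = float(tokens[4])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
        if not math.isfinite(conf):
            raise FormatError(f"line {lineno}: non-finite confidence")
        if strict_confidence and not 0.0 <= conf <= 1.0:
            raise FormatError(
                f"line {lineno}: confidence {conf} outside [0, 1]"
            )
        triples.append((i, j, conf))
    try:
        return canonicalize(triples, sequence.ungapped, target_id=sequence.id)
    except (BoundsError, ValueError) as exc:
        raise FormatError(str(exc)) from None


def write_casp_rr(cmap: ContactMap, dest: Source) -> None:
    """Write a contact map as a CASP-RR-style list (``i j 0 8 conf``)."""
    handle, close = (open(dest, "w"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        handle.write("PFRMAT RR\n")
        if cmap.target_id:
            handle.write(f"TARGET {cmap.target_id}\n")
        for p in cmap:
            handle.write(f"{p.res1} {p.res2} 0 8 {p.raw_score:.6f}\n")
        handle.write("END\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Square score matrices (CCMpred dialect)

def read_score_matrix(
    source: Source, sequence: SequenceRecord, atol: float = 1e-6
) -> ContactMap:
    """Read an L x L whitespace-separated score matrix.

    Produces one contact per upper-triangle cell (the file is 0-based;
    the model is 1-based).  The matrix must be square of side L and
    symmetric within ``atol``.
    """
    rows = [line.split() for line in _read_text(source).splitlines() if line.strip()]
    length = len(sequence.ungapped)
    if len(rows) != length or any(len(r) != length for r in rows):
        shape = (len(rows), len(rows[0]) if rows else 0)
        raise FormatError(
            f"score matrix shape {shape} does not match sequence length {length}"
        )
    try:
        mat = np.array(rows, dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric matrix entry: {exc}") from None
    if not np.allclose(mat, mat.T, atol=atol, rtol=0.0):
        raise FormatError(f"score matrix asymmetric beyond tolerance {atol}")
    iu, ju = np.triu_indices(length, k=1)
    triples = [
        (int(i) + 1, int(j) + 1, float(mat[i, j])) for i, j in zip(iu, ju)
    ]
    return canonicalize(triples, sequence.ungapped, target_id=sequence.id)


# ---------------------------------------------------------------------------
# bbcontacts beta-strand tables

_BB_REQUIRED = {"identifier", "direction", "score", "res1", "res2"}
_BB_ALIASES = {
    "viterbiscore": "score",
    "diversityvalue": "diversity",
    "indexpred": "index",
}


def read_bbcontacts_table(
    source: Source, sequence: SequenceRecord
) -> List[StrandPairGroup]:
    """Read a bbcontacts-style TSV into strand-pairing groups.

    The published tool emits columns (identifier, diversityvalue,
    direction, viterbiscore, indexpred, state, res1, res2); a leading
    '#' on the header is tolerated.  Contacts are grouped by
    (identifier, direction); the state column is ignored.
    """
    text = _read_text(source)
    first_nl = text.find("\n")
    header = text[: first_nl if first_nl >= 0 else len(text)]
    body = text[first_nl + 1:] if first_nl >= 0 else ""
    names = header.lstrip("#").strip().lower().split("\t")
    if len(names) == 1:
        names = header.lstrip("#").strip().split()
    names = [_BB_ALIASES.get(n, n) for n in names]
    missing = _BB_REQUIRED - set(names)
    if missing:
        raise FormatError(f"bbcontacts table missing columns {sorted(missing)}")
    if not body.strip():
        return []
    df = pd.read_csv(
        _io.StringIO(body), sep=r"\s+", names=names, comment="#"
    )
    length = len(sequence.ungapped)
    groups: Dict[Tuple[str, str], List[ContactPair]] = {}
    order: List[Tuple[str, str]] = []
    for row in df.itertuples(index=False):
        direction = str(row.direction).lower()
        if direction not in ("parallel", "antiparallel"):
            raise FormatError(f"unknown strand direction {row.direction!r}")
        r1, r2 = int(row.res1), int(row.res2)
        if r1 < 1 or r2 < 1 or r1 > length or r2 > length:
            raise FormatError(
                f"beta contact ({r1}, {r2}) outside [1, {length}]"
            )
        key = (str(row.identifier), direction)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(
            ContactPair(
                r1, r2, float(row.score),
                source="beta_specific", group_id=str(row.identifier),
            )
        )
    return [
        StrandPairGroup(group_id=gid, direction=direction, members=groups[(gid, direction)])
        for gid, direction in order
    ]


def write_bbcontacts_table(
    groups: Sequence[StrandPairGroup], dest: Source
) -> None:
    """Write strand-pairing groups in the bbcontacts TSV dialect."""
    handle, close = (open(dest, "w"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        handle.write(
            "#identifier\tdiversityvalue\tdirection\tviterbiscore\t"
            "indexpred\tstate\tres1\tres2\n"
        )
        for g in groups:
            for k, m in enumerate(g.members):
                state = (
                    "first" if k == 0
                    else "last" if k == len(g.members) - 1
                    else "internal"
                )
                handle.write(
                    f"{g.group_id}\t0.0\t{g.direction.capitalize()}\t"
                    f"{m.raw_score:.6f}\t{k}\t{state}\t{m.res1}\t{m.res2}\n"
                )
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# Rosetta constraint files (AtomPair / FADE dialect)

def _fmt_bound(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


def write_restraint_file(
    restraints: Sequence[RestraintRecord], dest: Source
) -> None:
    """Write ``AtomPair <a1> <r1> <a2> <r2> FADE <lb> <ub> <z> <wd> <offset>``.

    Bounds are printed as integers when integral and the well depth to
    two decimals, so output files are byte-stable across platforms.
    """
    handle, close = (open(dest, "w"), True) if isinstance(dest, (str, Path)) else (dest, False)
    try:
        for r in restraints:
            p = r.params
            handle.write(
                f"AtomPair {r.atom1} {r.res1} {r.atom2} {r.res2} FADE "
                f"{_fmt_bound(p.lb)} {_fmt_bound(p.ub)} {_fmt_bound(p.z)} "
                f"{p.wd:.2f} {_fmt_bound(p.offset)}\n"
            )
    finally:
        if close:
            handle.close()


def read_restraint_file(source: Source) -> List[RestraintRecord]:
    """Parse a constraint file written by :func:`write_restraint_file`."""
    records = []
    for lineno, raw in enumerate(_read_text(source).splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        if len(tokens) != 11 or tokens[0] != "AtomPair" or tokens[5] != "FADE":
            raise FormatError(
                f"line {lineno}: not an 'AtomPair ... FADE ...' record"
            )
        try:
            records.append(
                RestraintRecord(
                    res1=int(tokens[2]),
                    res2=int(tokens[4]),
                    atom1=tokens[1],
                    atom2=tokens[3],
                    params=FadeParams(
                        lb=float(tokens[6]),
                        ub=float(tokens[7]),
                        z=float(tokens[8]),
                        wd=float(tokens[9]),
                        offset=float(tokens[10]),
                    ),
                )
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from None
    return records


# ---------------------------------------------------------------------------
# PDB coordinate files

def _pick_atom(residue: gemmi.Residue, name: str) -> Optional[np.ndarray]:
    """Select one atom by name: highest occupancy, then altloc order."""
    candidates = [a for a in residue if a.name == name]
    if not candidates:
        return None
    best = min(candidates, key=lambda a: (-a.occ, a.altloc))
    return np.array([best.pos.x, best.pos.y, best.pos.z])


def read_structure(source: Source) -> StructureModel:
    """Read PDB coordinates: first model only, HETATM ignored, altlocs
    resolved by highest occupancy then alphabetical altloc id."""
    structure = gemmi.read_pdb_string(_read_text(source))
    if len(structure) == 0:
        raise FormatError("coordinate file contains no models")
    model = structure[0]
    residues: List[ResidueRecord] = []
    n_ca = 0
    for chain in model:
        for res in chain:
            if res.het_flag != "A":  # skip HETATM (ligands, waters)
                continue
            ca = _pick_atom(res, "CA")
            cb = _pick_atom(res, "CB")
            for coord in (ca, cb):
                if coord is not None and not np.all(np.isfinite(coord)):
                    raise FormatError(
                        f"non-finite coordinates in residue {res.seqid.num}"
                    )
            if ca is not None:
                n_ca += 1
            residues.append(
                ResidueRecord(
                    chain_id=chain.name,
                    seqnum=res.seqid.num,
                    name=res.name,
                    ca=ca,
                    cb=cb,
                )
            )
    if n_ca == 0:
        raise FormatError("structure has no CA atoms")
    return StructureModel(residues=residues)
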
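"""Numbering alignment, reference-contact extraction, PPV and the MR gate."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from contactfuse.evaluate import (
    MRTrialResult,
    NumberingMismatchError,
    UndefinedPPVError,
    extract_reference_contacts,
    map_numbering,
    mr_success,
    ppv,
)
from contactfuse.io import ResidueRecord, SequenceRecord, StructureModel
from contactfuse.model import ContactPair
from contactfuse.synthetic import identity_mapping

from oracles import contact_scan


def _linear_structure(names, spacing=3.8):
    """Residues along the x axis; CB 1.5 A above CA."""
    residues = []
    for k, name in enumerate(names):
        ca = np.array([k * spacing, 0.0, 0.0])
        cb = None if name == "GLY" else ca + np.array([0.0, 1.5, 0.0])
        residues.append(ResidueRecord("A", k + 1, name, ca=ca, cb=cb))
    return StructureModel(residues=residues)


class TestMapNumbering:
    def test_identical_sequences_identity_mapping(self):
        model = _linear_structure(["ALA", "LEU", "GLY", "LYS", "TRP"] * 3)
        seq = SequenceRecord("t", model.one_letter_sequence())
        mapping = map_numbering(seq, model)
        assert mapping == {k: k + 1 for k in range(15)}

    def test_truncated_structure_offsets_mapping(self):
        names = ["ALA", "LEU", "GLY", "LYS", "TRP", "PHE", "SER", "THR",
                 "VAL", "ILE", "MET", "ASN"]
        full = _linear_structure(names)
        seq = SequenceRecord("t", full.one_letter_sequence())
        truncated = StructureModel(residues=full.residues[3:])
        mapping = map_numbering(seq, truncated)
        assert min(mapping.values()) == 4
        values = [mapping[k] for k in sorted(mapping)]
        assert values == sorted(values)  # strictly increasing

    def test_unrelated_sequences_rejected(self):
        model = _linear_structure(["ALA"] * 12)
        with pytest.raises(NumberingMismatchError):
            map_numbering(SequenceRecord("t", "W" * 12), model)


class TestExtractReferenceContacts:
    def test_inclusive_9A_boundary(self):
        near = _linear_structure(["ALA", "LEU"], spacing=8.90)
        far = _linear_structure(["ALA", "LEU"], spacing=9.10)
        assert (1, 2) in extract_reference_contacts(near, identity_mapping(near)).pairs
        assert (1, 2) not in extract_reference_contacts(far, identity_mapping(far)).pairs

    def test_glycine_measured_at_calpha(self):
        model = _linear_structure(["GLY", "GLY"], spacing=5.0)
        ref = extract_reference_contacts(model, identity_mapping(model))
        assert (1, 2) in ref.pairs

    def test_residue_without_any_atom_skipped(self):
        model = _linear_structure(["ALA", "LEU", "LYS"], spacing=5.0)
        model.residues[1].ca = None
        model.residues[1].cb = None
        ref = extract_reference_contacts(model, identity_mapping(model))
        assert ref.n_skipped == 1
        assert 2 not in ref.resolved

    def test_min_separation_filter(self):
        model = _linear_structure(["ALA"] * 4, spacing=4.0)
        ref = extract_reference_contacts(
            model, identity_mapping(model), min_separation=2
        )
        assert all(j - i >= 2 for i, j in ref.pairs)

    @given(st.integers(0, 40))
    def test_agrees_with_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        residues, coords, indices = [], [], []
        for k in range(n):
            pos = rng.uniform(0, 25, size=3)
            residues.append(
                ResidueRecord("A", k + 1, "ALA", ca=pos, cb=pos + [0, 1.5, 0])
            )
            coords.append(pos + [0, 1.5, 0])
            indices.append(k + 1)
        model = StructureModel(residues=residues)
        ref = extract_reference_contacts(model, identity_mapping(model))
        assert ref.pairs == frozenset(contact_scan(coords, indices, 9.0))


class TestPPV:
    REF_PAIRS = frozenset({(1, 5), (2, 6), (3, 7), (4, 8)})

    def _reference(self):
        from contactfuse.evaluate import ReferenceContactSet
        return ReferenceContactSet(
            pairs=self.REF_PAIRS, resolved=frozenset(range(1, 9))
        )

    def test_subset_of_reference_scores_one(self):
        preds = [ContactPair(1, 5, 0.9), ContactPair(2, 6, 0.8)]
        assert ppv(preds, self._reference()).ppv == 1.0

    def test_three_true_one_false(self):
        preds = [ContactPair(1, 5, 0.9), ContactPair(2, 6, 0.8),
                 ContactPair(3, 7, 0.7), ContactPair(1, 8, 0.6)]
        report = ppv(preds, self._reference())
        assert (report.tp, report.fp, report.ppv) == (3, 1, 0.75)

    def test_unresolved_pairs_are_unverifiable(self):
        preds = [ContactPair(1, 5, 0.9), ContactPair(10, 20, 0.8)]
        report = ppv(preds, self._reference())
        assert report.unverifiable == 1 and report.ppv == 1.0

    def test_all_unverifiable_raises(self):
        preds = [ContactPair(10, 20, 0.8)]
        with pytest.raises(UndefinedPPVError):
            ppv(preds, self._reference())

    def test_monotone_under_appending(self):
        preds = [ContactPair(1, 5, 0.9), ContactPair(1, 8, 0.6)]
        base = ppv(preds, self._reference()).ppv
        with_false = ppv(preds + [ContactPair(2, 8, 0.5)], self._reference()).ppv
        with_true = ppv(preds + [ContactPair(4, 8, 0.5)], self._reference()).ppv
        assert with_false <= base <= with_true

    def test_order_invariant(self):
        preds = [ContactPair(1, 5, 0.9), ContactPair(1, 8, 0.6)]
        assert ppv(preds, self._reference()) == ppv(preds[::-1], self._reference())


class TestMRGate:
    @pytest.mark.parametrize(
        "cc, acl, rfree, expected",
        [
            (30.0, 15.0, (0.40,), True),
            (24.99, 15.0, (0.40,), False),
            (30.0, 9.99, (0.40,), False),
            (30.0, 15.0, (0.46,), False),
            (25.00, 10.00, (0.45,), True),     # inclusive boundary
            (30.0, 15.0, (0.50, 0.44), True),  # either rebuild may pass
        ],
    )
    def test_gate(self, cc, acl, rfree, expected):
        trial = MRTrialResult(shelxe_cc=cc, acl=acl, rfree_candidates=rfree)
        assert mr_success(trial) is expected
        assert trial.success is expected

    def test_missing_rfree_rejected(self):
        with pytest.raises(ValueError):
            MRTrialResult(shelxe_cc=30.0, acl=15.0, rfree_candidates=())

    @given(st.floats(0, 60), st.floats(0, 60), st.floats(0.2, 10),
           st.floats(0, 0.45))
    def test_monotone(self, cc, acl, dcc, drfree):
        base = MRTrialResult(cc, acl, (0.45,))
        better = MRTrialResult(cc + dcc, acl + dcc, (0.45 - drfree,))
        if mr_success(base):
            assert mr_success(better)
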
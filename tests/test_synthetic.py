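"""Synthetic fixture generators: geometry, constructed PPV, ladders,
alignments and determinism."""

import numpy as np
import pytest

from contactfuse.evaluate import extract_reference_contacts, ppv
from contactfuse.fusion import filter_sparse_groups, fuse
from contactfuse.model import top_l_select
from contactfuse.msa import neff
from contactfuse.synthetic import (
    FixtureSpec,
    identity_mapping,
    make_contact_map,
    make_msa,
    make_reference,
    make_sequence,
    make_strand_groups,
    make_structure,
    write_fixture_dir,
)

from oracles import contact_scan


class TestMakeStructure:
    def test_hairpin_cross_strand_pairs_in_contact(self):
        spec = FixtureSpec(seed=2, l=12, topology="hairpin")
        ref = make_reference(spec)
        for i in range(1, 6):
            assert (i, 12 + 1 - i) in ref.pairs

    def test_helix_i_i4_pairs_in_contact(self):
        spec = FixtureSpec(seed=2, l=12, topology="helix")
        ref = make_reference(spec)
        for i in range(1, 8):
            assert (i, i + 4) in ref.pairs

    def test_sandwich_has_ladders_in_both_sheets(self):
        spec = FixtureSpec(seed=2, l=32, topology="sheet-sandwich")
        groups = make_strand_groups(make_reference(spec), n_groups=2,
                                    group_size=3, seed=2, length=32)
        assert len(groups) == 2

    def test_too_short_hairpin_rejected(self):
        with pytest.raises(ValueError):
            FixtureSpec(seed=0, l=2, topology="hairpin")

    def test_unsupported_topology_rejected(self):
        with pytest.raises(ValueError):
            FixtureSpec(seed=0, l=12, topology="barrel")

    def test_reference_matches_brute_force_scan(self):
        for topology, l in (("helix", 15), ("hairpin", 14),
                            ("sheet-sandwich", 20)):
            spec = FixtureSpec(seed=5, l=l, topology=topology)
            model = make_structure(spec)
            ref = make_reference(spec)
            coords, indices = [], []
            for k, res in enumerate(model.residues):
                atom = res.ca if res.cb is None else res.cb
                coords.append(atom)
                indices.append(k + 1)
            assert ref.pairs == frozenset(contact_scan(coords, indices, 9.0))

    def test_deterministic_in_seed(self):
        spec = FixtureSpec(seed=9, l=16, topology="hairpin")
        a = make_structure(spec)
        b = make_structure(spec)
        assert all(
            np.array_equal(x.ca, y.ca)
            for x, y in zip(a.residues, b.residues)
        )
        other = make_structure(FixtureSpec(seed=10, l=16, topology="hairpin"))
        assert not np.array_equal(a.residues[0].ca, other.residues[0].ca)


class TestMakeContactMap:
    @pytest.mark.parametrize("n_true, n_false, expected", [
        (8, 2, 0.8), (5, 0, 1.0), (0, 5, 0.0),
    ])
    def test_ppv_by_construction(self, n_true, n_false, expected):
        spec = FixtureSpec(seed=4, l=24, topology="hairpin",
                           n_true=n_true, n_false=n_false)
        ref = make_reference(spec)
        cmap = make_contact_map(spec, ref)
        if n_true + n_false == 0:
            pytest.skip("empty map")
        report = ppv(cmap, ref)
        assert report.ppv == pytest.approx(expected)
        assert report.unverifiable == 0

    def test_insufficient_reference_rejected(self):
        spec = FixtureSpec(seed=4, l=8, topology="hairpin", n_true=10_000)
        with pytest.raises(ValueError):
            make_contact_map(spec, make_reference(spec))


class TestMakeStrandGroups:
    def test_unjittered_members_are_reference_contacts(self):
        spec = FixtureSpec(seed=6, l=20, topology="hairpin")
        ref = make_reference(spec)
        groups = make_strand_groups(ref, n_groups=1, group_size=3,
                                    jitter=0, seed=6, length=20)
        assert all(m.key in ref.pairs for m in groups[0].members)

    def test_size_two_groups_removed_entirely_by_filter(self):
        spec = FixtureSpec(seed=6, l=20, topology="hairpin")
        groups = make_strand_groups(make_reference(spec), n_groups=1,
                                    group_size=2, seed=6, length=20)
        assert filter_sparse_groups(groups) == []

    def test_jittered_member_still_triggers_upweighting(self):
        from contactfuse.model import canonicalize

        spec = FixtureSpec(seed=6, l=20, topology="hairpin")
        ref = make_reference(spec)
        sequence = make_sequence(spec).residues
        # top-L list = the unjittered ladder; beta = the same ladder with
        # one index nudged by <= 1: every member must still match
        clean = make_strand_groups(ref, n_groups=1, group_size=4,
                                   jitter=0, seed=6, length=20)[0]
        top = canonicalize(
            [(m.res1, m.res2, 0.9 - 0.01 * k)
             for k, m in enumerate(clean.members)],
            sequence,
        )
        jittered = make_strand_groups(ref, n_groups=1, group_size=4,
                                      jitter=1, seed=6, length=20)
        fused = fuse(top_l_select(top, len(sequence)), jittered)
        assert fused.n_upweighted == len(clean.members)
        assert fused.n_added == 0

    def test_invalid_arguments_rejected(self):
        spec = FixtureSpec(seed=6, l=20, topology="hairpin")
        ref = make_reference(spec)
        with pytest.raises(ValueError):
            make_strand_groups(ref, group_size=0)
        with pytest.raises(ValueError):
            make_strand_groups(ref, jitter=3)
        with pytest.raises(ValueError):
            make_strand_groups(ref, n_groups=50, group_size=3)


class TestMakeMsa:
    def test_zero_mutation_rate_gives_neff_one(self):
        spec = FixtureSpec(seed=3, l=24, msa_n=10, msa_mutation_rate=0.0)
        assert neff(make_msa(spec)) == 1.0

    def test_high_mutation_rate_gives_all_singletons(self):
        spec = FixtureSpec(seed=3, l=100, msa_n=10, msa_mutation_rate=0.9)
        assert neff(make_msa(spec)) == 10.0

    def test_single_sequence(self):
        spec = FixtureSpec(seed=3, l=24, msa_n=1)
        assert neff(make_msa(spec)) == 1.0

    def test_invalid_rate_rejected(self):
        spec = FixtureSpec(seed=3, l=24, msa_mutation_rate=1.5)
        with pytest.raises(ValueError):
            make_msa(spec)

    def test_deterministic_in_seed(self):
        spec = FixtureSpec(seed=8, l=30, msa_n=6, msa_mutation_rate=0.3)
        a = make_msa(spec)
        b = make_msa(spec)
        assert [r.residues for r in a.records] == [r.residues for r in b.records]


def test_fixture_dir_roundtrip(tmp_path):
    """Files written by the generator re-read into equal objects."""
    from contactfuse import io as iomod

    spec = FixtureSpec(seed=12, l=24, topology="hairpin")
    paths = write_fixture_dir(spec, tmp_path)
    target = iomod.read_fasta(paths["fasta"])[0]
    assert target.residues == make_sequence(spec).residues
    cmap = iomod.read_casp_rr(paths["rr"], target)
    assert cmap.pair_set() == make_contact_map(spec, make_reference(spec)).pair_set()
    model = iomod.read_structure(paths["structure"])
    assert model.one_letter_sequence() == target.residues
    ref_disk = extract_reference_contacts(model, identity_mapping(model))
    assert ref_disk.pairs == make_reference(spec).pairs
    groups = iomod.read_bbcontacts_table(paths["beta"], target)
    assert len(groups) == 1 and len(groups[0]) >= 3
    msa_records = iomod.read_msa_fasta(paths["msa"])
    assert len(msa_records) == spec.msa_n
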
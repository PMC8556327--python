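"""Structure model: file round trips, protomer grouping, superposition."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phycoring.structure import (Assembly, Atom, StructureParseError,
                                 group_protomers, match_ca, read_structure,
                                 superpose, write_structure)
from phycoring.synthetic import RingSpec, build_ring


def _toy_chain(chain_id, resnums, offset=np.zeros(3), resname="ALA"):
    return [Atom("C", "CA", np.array([float(i), 0.0, 0.0]) + offset,
                 resname, r, chain_id) for i, r in enumerate(resnums)]


class TestFileRoundTrip:
    @pytest.mark.parametrize("suffix", [".pdb", ".cif"])
    def test_roundtrip_preserves_atoms(self, tmp_path, hexamer_ring, suffix):
        asm, _ = hexamer_ring
        path = tmp_path / f"ring{suffix}"
        write_structure(asm, path)
        back = read_structure(path)
        assert len(back.atoms) == len(asm.atoms)
        assert np.abs(back.coords() - asm.coords()).max() < 1e-3
        assert back.chain_ids() == asm.chain_ids()
        assert [a.residue_number for a in back.atoms] == \
               [a.residue_number for a in asm.atoms]

    def test_hetero_flags_survive_roundtrip(self, tmp_path, hexamer_ring):
        asm, _ = hexamer_ring
        path = tmp_path / "ring.pdb"
        write_structure(asm, path)
        back = read_structure(path)
        het = [a for a in back.atoms if a.is_hetero]
        assert len(het) == sum(a.is_hetero for a in asm.atoms)
        assert {a.residue_name for a in het} == {"CYC"}

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(StructureParseError, match="no such file"):
            read_structure(tmp_path / "nope.pdb")

    def test_no_atoms_raises(self, tmp_path):
        empty = tmp_path / "empty.pdb"
        empty.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(StructureParseError, match="no atoms"):
            read_structure(empty)

    def test_unknown_format_raises(self, tmp_path, hexamer_ring):
        asm, _ = hexamer_ring
        with pytest.raises(StructureParseError, match="unknown"):
            write_structure(asm, tmp_path / "x.pdb", format="xyz")


class TestGroupProtomers:
    @pytest.mark.parametrize("pairing", ["by_contact", "by_order"])
    def test_d3_ring_gives_six_protomers(self, hexamer_ring, pairing):
        asm, _ = hexamer_ring
        bare = Assembly(asm.atoms, [], "bare")
        grouped = group_protomers(bare, pairing)
        assert grouped.n == 6
        chains = {c for p in grouped.protomers
                  for c in (p.alpha_chain, p.beta_chain)}
        assert len(chains) == 12  # every chain in exactly one protomer

    def test_c4_indices_follow_azimuth(self, c4_ring):
        asm, _ = c4_ring
        bare = Assembly(asm.atoms, [], "bare")
        grouped = group_protomers(bare, "by_contact")
        assert sorted(p.index for p in grouped.protomers) == [0, 1, 2, 3]
        cents = [grouped.protomer_centroid(p)
                 for p in sorted(grouped.protomers, key=lambda p: p.index)]
        az = [math.atan2(c[1], c[0]) % (2 * math.pi) for c in cents]
        gaps = np.diff(az + [az[0] + 2 * math.pi]) % (2 * math.pi)
        assert np.allclose(gaps, math.pi / 2, atol=1e-6)

    def test_odd_chain_count_rejected(self):
        atoms = (_toy_chain("A", range(1, 11)) +
                 _toy_chain("B", range(1, 11), np.array([0.0, 3.0, 0.0])) +
                 _toy_chain("C", range(1, 11), np.array([0.0, 60.0, 0.0])))
        with pytest.raises(ValueError, match="odd number"):
            group_protomers(Assembly(atoms), "by_order")

    def test_ambiguous_contacts_rejected(self):
        # B and C are equidistant contact partners of A
        atoms = (_toy_chain("A", range(1, 11)) +
                 _toy_chain("B", range(1, 11), np.array([0.0, 3.0, 0.0])) +
                 _toy_chain("C", range(1, 11), np.array([0.0, -3.0, 0.0])) +
                 _toy_chain("D", range(1, 11), np.array([0.0, 6.0, 0.0])))
        with pytest.raises(ValueError, match="ambiguous"):
            group_protomers(Assembly(atoms), "by_contact")


class TestSuperpose:
    def test_identity(self, rng):
        X = rng.normal(size=(20, 3))
        t = superpose(X, X)
        assert t.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(angle=st.floats(5.0, 175.0), seed=st.integers(0, 10_000))
    def test_recovers_known_rotation(self, angle, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(15, 3))
        th = math.radians(angle)
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        Y = X @ R.T + np.array([1.0, 2.0, 3.0])
        t = superpose(X, Y)
        assert t.rmsd < 1e-8
        assert t.angle_deg == pytest.approx(angle, abs=1e-8)

    def test_rmsd_symmetric_and_explicit(self, rng):
        X = rng.normal(size=(25, 3))
        Y = X + rng.normal(scale=0.3, size=(25, 3))
        fwd, rev = superpose(X, Y), superpose(Y, X)
        assert fwd.rmsd == pytest.approx(rev.rmsd, abs=1e-8)
        resid = fwd.apply(X) - Y
        assert fwd.rmsd == pytest.approx(
            math.sqrt((resid ** 2).sum() / len(X)), abs=1e-12)

    def test_fixed_point(self, rng):
        X = rng.normal(size=(12, 3))
        Y = X + rng.normal(scale=0.2, size=(12, 3))
        once = superpose(X, Y)
        again = superpose(once.apply(X), Y)
        assert again.rmsd == pytest.approx(once.rmsd, abs=1e-9)

    def test_proper_rotation_even_for_mirrored_input(self, rng):
        X = rng.normal(size=(30, 3))
        Y = X * np.array([1.0, 1.0, -1.0])  # reflection
        t = superpose(X, Y)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-10)

    def test_input_validation(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="differ in length"):
            superpose(X, X[:4])
        with pytest.raises(ValueError, match="at least 3"):
            superpose(X[:2], X[:2])


class TestMatchCa:
    def test_self_match_pairs_everything(self):
        asm = Assembly(_toy_chain("A", range(1, 31)))
        A, B = match_ca(asm, "A", asm, "A")
        assert A.shape == (30, 3) and np.allclose(A, B)

    def test_by_resnum_intersects_ranges(self):
        asm = Assembly(_toy_chain("A", range(1, 101)) +
                       _toy_chain("B", range(51, 151),
                                  np.array([0.0, 50.0, 0.0])))
        A, B = match_ca(asm, "A", asm, "B", mode="by_resnum")
        assert A.shape[0] == 50

    def test_by_resnum_empty_intersection(self):
        asm = Assembly(_toy_chain("A", range(1, 10)) +
                       _toy_chain("B", range(100, 110),
                                  np.array([0.0, 50.0, 0.0])))
        with pytest.raises(ValueError, match="share no residue numbers"):
            match_ca(asm, "A", asm, "B", mode="by_resnum")

    def test_alignment_excludes_internal_deletion(self):
        # AVLIMFWY vs AVLMFWY: the Ile is deleted in chain B
        seq_a, seq_b = "AVLIMFWY", "AVLMFWY"
        one2three = {"A": "ALA", "V": "VAL", "L": "LEU", "I": "ILE",
                     "M": "MET", "F": "PHE", "W": "TRP", "Y": "TYR"}
        mk = lambda cid, seq, dy: [
            Atom("C", "CA", np.array([3.8 * i, dy, 0.0]), one2three[c],
                 i + 1, cid) for i, c in enumerate(seq)]
        asm = Assembly(mk("A", seq_a, 0.0) + mk("B", seq_b, 10.0))
        A, B = match_ca(asm, "A", asm, "B", mode="by_alignment")
        assert A.shape[0] == 7  # the deleted position is not paired
        # chain A indices paired: 0,1,2 then 4.. (x = 3.8*i)
        assert 3.8 * 3 not in A[:, 0]


class TestRingConstructionRoundTrip:
    def test_grouping_matches_construction(self):
        asm, truth = build_ring(RingSpec(n=4, layers=2))
        bare = Assembly(asm.atoms, [], "bare")
        grouped = group_protomers(bare, "by_contact")
        assert grouped.n == 8
        built_pairs = {frozenset((p.alpha_chain, p.beta_chain))
                       for p in asm.protomers}
        found_pairs = {frozenset((p.alpha_chain, p.beta_chain))
                       for p in grouped.protomers}
        assert built_pairs == found_pairs
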
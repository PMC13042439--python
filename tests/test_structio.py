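"""Structure I/O, fragmentation and guest-distance tests."""

import numpy as np
import pytest

from qmregion.structio import (
    Atom,
    Fragment,
    FragmentMap,
    FragmentMapError,
    Structure,
    StructureParseError,
    build_fragment_map,
    min_distance_profile,
    pair_min_distances,
    read_structure,
    strip_guest,
    write_structure,
)

from conftest import rigid_motion

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  C   ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  O   ALA A   1       2.200   1.100   0.000  1.00  0.00           O
ATOM      4  N   GLY A   2       3.700   0.000   0.000  1.00  0.00           N
ATOM      5  C   GLY A   2       5.200   0.000   0.000  1.00  0.00           C
HETATM    6  C   LIG A  99       0.000   5.000   0.000  1.00  0.00           C
HETATM    7  O   LIG A  99       1.200   5.400   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  C  AALA A   1       0.000   0.000   0.000  0.50  0.00           C
ATOM      2  C  BALA A   1       0.300   0.000   0.000  0.50  0.00           C
END
"""


def random_structure(n, seed=0, elements=("C", "N", "O", "H", "Si")):
    rng = np.random.default_rng(seed)
    return Structure(
        atoms=[Atom(element=str(rng.choice(elements))) for _ in range(n)],
        coords=rng.uniform(-8, 8, (n, 3)),
    )


class TestReadWrite:
    def test_minimal_xyz(self, tmp_path):
        p = tmp_path / "h.xyz"
        p.write_text("1\n\nH 0 0 0\n")
        s = read_structure(p)
        assert s.n_atoms == 1
        assert s.atoms[0].element == "H"
        np.testing.assert_allclose(s.coords, [[0.0, 0.0, 0.0]])

    @pytest.mark.parametrize("fmt,tol", [("xyz", 1e-6), ("pdb", 1e-3)])
    def test_round_trip_precision(self, tmp_path, fmt, tol):
        s = random_structure(10, seed=3)
        p = tmp_path / f"s.{fmt}"
        write_structure(s, p)
        back = read_structure(p)
        assert back.elements == s.elements
        np.testing.assert_allclose(back.coords, s.coords, atol=tol)

    def test_altloc_keeps_one_atom(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(ALTLOC_PDB)
        assert read_structure(p).n_atoms == 1

    def test_missing_file_and_malformed(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.xyz")
        bad = tmp_path / "bad.xyz"
        bad.write_text("2\n\nC 0 0 zz\nC 0 0 1\n")
        with pytest.raises(StructureParseError, match="line"):
            read_structure(bad)

    def test_unknown_element_flagged(self, tmp_path):
        p = tmp_path / "u.xyz"
        p.write_text("1\n\nXx 0 0 0\n")
        with pytest.warns(UserWarning, match="unknown element"):
            s = read_structure(p)
        assert not s.atoms[0].known_element


class TestFragmentMap:
    def test_by_residue_toy_peptide(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        s = read_structure(p)
        fmap = build_fragment_map(s, guest_selector="LIG")
        assert len(fmap) == 3
        assert len(fmap.guest_ids()) == 1
        guest = fmap.by_id(fmap.guest_ids()[0])
        assert len(guest.atom_indices) == 2
        fmap.validate(s)

    def test_explicit_split(self):
        s = random_structure(6)
        frags = [
            Fragment(id=0, name="A", atom_indices=(0, 1, 2)),
            Fragment(id=1, name="B", atom_indices=(3, 4, 5)),
        ]
        fmap = build_fragment_map(s, mode="explicit", explicit_spec=frags)
        assert len(fmap) == 2

    def test_explicit_overlap_and_gap_rejected(self):
        s = random_structure(4)
        overlap = [
            Fragment(id=0, name="A", atom_indices=(0, 1)),
            Fragment(id=1, name="B", atom_indices=(1, 2, 3)),
        ]
        with pytest.raises(FragmentMapError, match="atom 1"):
            build_fragment_map(s, mode="explicit", explicit_spec=overlap)
        gap = [Fragment(id=0, name="A", atom_indices=(0, 1))]
        with pytest.raises(FragmentMapError, match="not covered"):
            build_fragment_map(s, mode="explicit", explicit_spec=gap)

    def test_no_guest_matched(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        s = read_structure(p)
        with pytest.raises(FragmentMapError, match="guest"):
            build_fragment_map(s, guest_selector="XYZ")

    def test_residue_grouping_order_insensitive(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(TOY_PDB)
        s = read_structure(p)
        fmap = build_fragment_map(s, guest_selector="LIG")
        # shuffle atom order, rebuild, compare fragment *contents* by name
        rng = np.random.default_rng(5)
        perm = rng.permutation(s.n_atoms)
        shuffled = Structure(
            atoms=[s.atoms[i] for i in perm], coords=s.coords[perm]
        )
        fmap2 = build_fragment_map(shuffled, guest_selector="LIG")
        by_name = lambda fm, struct: {
            f.name: sorted(struct.atoms[i].serial for i in f.atom_indices)
            for f in fm
        }
        assert by_name(fmap, s) == by_name(fmap2, shuffled)

    def test_json_round_trip(self):
        s = random_structure(6)
        fmap = build_fragment_map(
            s,
            mode="explicit",
            explicit_spec=[
                Fragment(id=0, name="A", atom_indices=(0, 1, 2), role="guest"),
                Fragment(id=1, name="B", atom_indices=(3, 4, 5), formal_charge=-1),
            ],
        )
        back = FragmentMap.from_json(fmap.to_json())
        assert [ (f.id, f.name, f.atom_indices, f.role, f.formal_charge) for f in back ] == \
               [ (f.id, f.name, f.atom_indices, f.role, f.formal_charge) for f in fmap ]

    def test_partition_completeness(self):
        for seed in range(5):
            s = random_structure(20, seed=seed)
            frags = []
            idx = np.arange(20)
            np.random.default_rng(seed).shuffle(idx)
            for k, chunk in enumerate(np.array_split(idx, 4)):
                frags.append(Fragment(id=k, name=f"F{k}", atom_indices=tuple(chunk)))
            fmap = FragmentMap(frags)
            fmap.validate(s)
            assert sum(len(f.atom_indices) for f in fmap) == s.n_atoms


class TestMinDistance:
    def make(self, coords_by_frag, roles):
        atoms, coords, frags = [], [], []
        i = 0
        for fid, (xyz, role) in enumerate(zip(coords_by_frag, roles)):
            start = i
            for p in xyz:
                atoms.append(Atom(element="C"))
                coords.append(p)
                i += 1
            frags.append(
                Fragment(id=fid, name=f"F{fid}", atom_indices=tuple(range(start, i)), role=role)
            )
        return Structure(atoms=atoms, coords=np.array(coords)), FragmentMap(frags)

    def test_three_four_five(self):
        s, fm = self.make([[[0, 0, 0]], [[3, 4, 0]]], ["host", "guest"])
        prof = min_distance_profile(s, fm)
        assert prof[0] == pytest.approx(5.0)
        assert prof[1] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        s = random_structure(50, seed=11)
        frags = []
        idx = np.arange(50)
        rng.shuffle(idx)
        chunks = np.array_split(idx, 5)
        for k, chunk in enumerate(chunks):
            frags.append(
                Fragment(
                    id=k, name=f"F{k}", atom_indices=tuple(chunk),
                    role="guest" if k == 2 else "host",
                )
            )
        fm = FragmentMap(frags)
        prof = min_distance_profile(s, fm)
        gidx = list(chunks[2])
        for k, chunk in enumerate(chunks):
            expected = min(
                float(np.linalg.norm(s.coords[a] - s.coords[b]))
                for a in chunk
                for b in gidx
            ) if k != 2 else 0.0
            assert prof[k] == pytest.approx(expected, abs=1e-12)

    def test_rigid_motion_invariance(self):
        s = random_structure(30, seed=2)
        frags = [
            Fragment(id=0, name="A", atom_indices=tuple(range(10)), role="guest"),
            Fragment(id=1, name="B", atom_indices=tuple(range(10, 30))),
        ]
        fm = FragmentMap(frags)
        p1 = min_distance_profile(s, fm)
        moved = Structure(atoms=s.atoms, coords=rigid_motion(s.coords, seed=9))
        p2 = min_distance_profile(moved, fm)
        for fid in p1:
            assert p2[fid] == pytest.approx(p1[fid], abs=1e-9)

    def test_rmin_never_increases_when_fragment_grows(self):
        s = random_structure(30, seed=4)
        guest = Fragment(id=0, name="G", atom_indices=(0, 1, 2), role="guest")
        rest = tuple(range(3, 30))
        small = FragmentMap([guest, Fragment(id=1, name="B", atom_indices=rest[:10]),
                             Fragment(id=2, name="C", atom_indices=rest[10:])])
        # grow fragment 1 by absorbing fragment 2
        big = FragmentMap([guest, Fragment(id=1, name="B", atom_indices=rest)])
        p_small = min_distance_profile(s, small)
        p_big = min_distance_profile(s, big)
        assert p_big[1] <= p_small[1] + 1e-12

    def test_pair_min_distances_consistent(self):
        s = random_structure(20, seed=8)
        fm = FragmentMap([
            Fragment(id=0, name="A", atom_indices=tuple(range(10)), role="guest"),
            Fragment(id=1, name="B", atom_indices=tuple(range(10, 20))),
        ])
        pm = pair_min_distances(s, fm)
        prof = min_distance_profile(s, fm)
        assert pm[(0, 1)] == pytest.approx(prof[1])


def test_strip_guest_preserves_ids_and_coords():
    rng = np.random.default_rng(1)
    s = random_structure(12, seed=1)
    fm = FragmentMap([
        Fragment(id=3, name="G", atom_indices=(4, 5), role="guest"),
        Fragment(id=1, name="A", atom_indices=(0, 1, 2, 3)),
        Fragment(id=2, name="B", atom_indices=tuple(range(6, 12))),
    ])
    host, host_map, kept = strip_guest(s, fm)
    assert host.n_atoms == 10
    assert sorted(host_map.ids) == [1, 2]
    np.testing.assert_allclose(host.coords, s.coords[kept])
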
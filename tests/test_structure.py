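import math

import numpy as np
import pytest

import kvarpred as kv
from kvarpred.structure import (
    FD_DISTANCE_FLOOR,
    NV_LOWER,
    NV_UPPER,
    StructureError,
    StructureModel,
)


def cloud(points, aas=None, axis_point=(0.0, 0.0, 0.0)):
    points = np.asarray(points, dtype=float)
    n = len(points)
    if aas is None:
        aas = ["A"] * n
    return StructureModel(
        np.arange(1, n + 1), np.array(aas, dtype=object), points,
        axis_point=np.asarray(axis_point), axis_dir=np.array([0.0, 0.0, 1.0]),
    )


def random_cloud(rng, n=50, scale=15.0):
    aas = rng.choice(list("ARNDCQEGHILKMFPSTWYV"), size=n)
    return cloud(rng.uniform(-scale, scale, size=(n, 3)), aas=list(aas))


class TestPoreAxisDistance:
    def test_on_axis_point(self):
        st = cloud([[0, 0, 12], [5, 5, 0]])
        assert kv.pore_axis_distance(st, 1) == pytest.approx(0.0)

    def test_three_four_five(self):
        st = cloud([[3, 4, 7], [0, 0, 0]])
        assert kv.pore_axis_distance(st, 1) == pytest.approx(5.0)

    def test_rotation_about_axis_preserves_distance(self):
        theta = 1.234
        p = np.array([3.0, 4.0, 7.0])
        q = np.array([
            p[0] * np.cos(theta) - p[1] * np.sin(theta),
            p[0] * np.sin(theta) + p[1] * np.cos(theta),
            -2.0,
        ])
        st = cloud([p, q])
        assert kv.pore_axis_distance(st, 1) == pytest.approx(kv.pore_axis_distance(st, 2))

    def test_unresolved_position_raises(self):
        st = cloud([[0, 0, 0]])
        with pytest.raises(StructureError):
            kv.pore_axis_distance(st, 99)


class TestMembraneBurial:
    def test_center_is_fully_buried(self):
        st = cloud([[0, 0, 0]])
        assert kv.membrane_burial(st, 1) == 1.0

    def test_deep_solution_weight_vanishes(self):
        st = cloud([[0, 0, 40]])
        assert kv.membrane_burial(st, 1) < 0.01

    @pytest.mark.parametrize("z", [0.0, 3.7, 15.0, 17.2, 19.9, 25.0])
    def test_slab_symmetry(self, z):
        m = kv.MembraneModel()
        assert m.weight(z) == pytest.approx(m.weight(-z))

    def test_plateau_monotone_decay_and_continuity(self):
        m = kv.MembraneModel()
        zs = np.linspace(0, 30, 2000)
        ws = np.array([m.weight(z) for z in zs])
        assert np.all(ws[zs <= 15.0] == 1.0)
        assert np.all(np.diff(ws) <= 1e-12)          # non-increasing in |z|
        assert np.max(np.abs(np.diff(ws))) < 5e-3    # no jumps on a fine grid
        assert np.all((ws >= 0) & (ws <= 1))


def brute_force_fd(points, aas, i, table, prop, radius, mutant_aa):
    """Independent double-loop evaluation of the inverse-distance average."""
    num = den = 0.0
    for j in range(len(points)):
        if j == i:
            continue
        d = math.dist(points[i], points[j])
        if d <= radius:
            w = 1.0 / max(d, FD_DISTANCE_FLOOR)
            num += w * table.get(aas[j], prop)
            den += w
    if den == 0.0:
        return table.get(mutant_aa, prop)
    return num / den


class TestFunctionalDensity:
    def test_hand_worked_two_neighbor_case(self, table):
        # neighbors at d=2 (property 1.0) and d=4 (property 0.0):
        # (1.0/2) / (1/2 + 1/4) = 2/3
        class StubTable:
            def get(self, aa, prop):
                return {"C": 1.0, "G": 0.0}.get(aa, 0.5)

        st = cloud([[0, 0, 0], [2, 0, 0], [4, 0, 0]], aas=["A", "C", "G"])
        val = kv.functional_density(st, 1, StubTable(), "p", radius=5.0, mutant_aa="A")
        assert val == pytest.approx(2.0 / 3.0)

    def test_empty_neighborhood_falls_back_to_mutant_property(self, table):
        st = cloud([[0, 0, 0], [30, 0, 0]], aas=["A", "W"])
        val = kv.functional_density(st, 1, table, "hydrophobicity", 1.0, mutant_aa="W")
        assert val == table.get("W", "hydrophobicity")

    @pytest.mark.parametrize("radius", [1.0, 6.5, 12.0])
    def test_matches_brute_force_oracle_on_random_clouds(self, table, radius):
        rng = np.random.default_rng(42)
        for _ in range(20):
            st = random_cloud(rng)
            aas = [str(a) for a in st.wt_aas]
            for pos in rng.integers(1, len(st) + 1, size=5):
                expected = brute_force_fd(
                    st.points, aas, int(pos) - 1, table, "polarizability", radius, "W"
                )
                got = kv.functional_density(
                    st, int(pos), table, "polarizability", radius, "W"
                )
                assert got == pytest.approx(expected, abs=1e-9)


def brute_force_nv(points, i):
    num = np.zeros(3)
    den = 0.0
    for j in range(len(points)):
        if j == i:
            continue
        d = math.dist(points[i], points[j])
        if d >= NV_UPPER or d == 0:
            continue
        w = 1.0 if d <= NV_LOWER else 0.5 * (
            1 + math.cos(math.pi * (d - NV_LOWER) / (NV_UPPER - NV_LOWER))
        )
        num += w * (np.asarray(points[j]) - np.asarray(points[i])) / d
        den += w
    if den == 0.0:
        return 1.0
    return min(1.0, float(np.linalg.norm(num)) / den)


class TestNeighborVector:
    def test_isolated_residue_is_fully_exposed(self):
        st = cloud([[0, 0, 0], [50, 0, 0]])
        assert kv.neighbor_vector(st, 1) == 1.0

    def test_symmetric_shell_cancels(self):
        shell = [[6, 0, 0], [-6, 0, 0], [0, 6, 0], [0, -6, 0], [0, 0, 6], [0, 0, -6]]
        st = cloud([[0, 0, 0]] + shell)
        assert kv.neighbor_vector(st, 1) == pytest.approx(0.0, abs=1e-12)

    def test_single_contact_neighbor_gives_one(self):
        st = cloud([[0, 0, 0], [3.3, 0, 0]])
        assert kv.neighbor_vector(st, 1) == pytest.approx(1.0)

    def test_bounded_and_matches_oracle_on_random_configurations(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            st = random_cloud(rng, n=10, scale=8.0)
            for pos in range(1, 11):
                nv = kv.neighbor_vector(st, pos)
                assert 0.0 <= nv <= 1.0
                assert nv == pytest.approx(brute_force_nv(st.points, pos - 1), abs=1e-9)

    def test_removing_the_counterweight_raises_exposure(self):
        # a one-sided cluster plus one opposing neighbor: deleting the
        # opposing neighbor can only make the site look more exposed
        with_counter = cloud([[0, 0, 0], [5, 0, 0], [5, 1, 0], [-5, 0, 0]])
        without = cloud([[0, 0, 0], [5, 0, 0], [5, 1, 0]])
        assert kv.neighbor_vector(without, 1) >= kv.neighbor_vector(with_counter, 1)


class TestRigidMotionInvariance:
    def test_features_invariant_to_rotation_about_normal_and_xy_translation(self, table):
        rng = np.random.default_rng(3)
        st = random_cloud(rng, n=30)
        theta, shift = 0.77, np.array([4.0, -2.5, 0.0])
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        moved = StructureModel(
            st.positions.copy(), st.wt_aas.copy(), st.points @ R.T + shift,
            axis_point=R @ st.axis_point + shift, axis_dir=np.array([0.0, 0.0, 1.0]),
        )
        for pos in (1, 7, 23):
            assert kv.pore_axis_distance(moved, pos) == pytest.approx(
                kv.pore_axis_distance(st, pos), abs=1e-9
            )
            assert kv.membrane_burial(moved, pos) == pytest.approx(
                kv.membrane_burial(st, pos), abs=1e-12
            )
            assert kv.functional_density(
                moved, pos, table, "hydrophobicity", 6.5
            ) == pytest.approx(
                kv.functional_density(st, pos, table, "hydrophobicity", 6.5), abs=1e-9
            )
            assert kv.neighbor_vector(moved, pos) == pytest.approx(
                kv.neighbor_vector(st, pos), abs=1e-9
            )


class TestStructureIO:
    def test_synthetic_pdb_roundtrip(self, tmp_path, small_structure):
        from kvarpred.synthetic import write_structure_pdb

        path = tmp_path / "bundle.pdb"
        write_structure_pdb(small_structure, path)
        again = kv.read_structure(path)
        assert len(again) == len(small_structure)
        assert np.allclose(again.points, small_structure.points, atol=1e-3)
        assert list(again.wt_aas) == list(small_structure.wt_aas)

    def test_mmcif_reading_matches_pdb(self, tmp_path, small_structure):
        import gemmi

        from kvarpred.synthetic import write_structure_pdb

        pdb = tmp_path / "bundle.pdb"
        write_structure_pdb(small_structure, pdb)
        st = gemmi.read_structure(str(pdb))
        st.setup_entities()
        cif = tmp_path / "bundle.cif"
        st.make_mmcif_document().write_file(str(cif))
        from_pdb = kv.read_structure(pdb)
        from_cif = kv.read_structure(cif)
        assert np.allclose(from_pdb.points, from_cif.points, atol=1e-6)
        assert list(from_pdb.wt_aas) == list(from_cif.wt_aas)

    def test_duplicate_positions_rejected(self):
        with pytest.raises(StructureError):
            StructureModel(
                np.array([1, 1]), np.array(["A", "G"], dtype=object),
                np.zeros((2, 3)),
            )
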
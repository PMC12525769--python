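import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbsq.structure import (
    ChromophoreSite,
    build_eet_graph,
    coplanarity,
    harvest_chromophores,
    mass_center,
    min_intergroup_distance,
    pairwise_distances,
)
from pbsq.synth import default_toy_layout, make_toy_structure, toy_group_map


def site_at(center, site_id="s", group="g", masses=None):
    """A minimal site: atoms placed so the mass center is exactly `center`."""
    c = np.asarray(center, dtype=float)
    atoms = [
        ("C", c + np.array([1.0, 0, 0]), 12.0),
        ("C", c - np.array([1.0, 0, 0]), 12.0),
        ("C", c + np.array([0, 1.0, 0]), 12.0),
        ("C", c - np.array([0, 1.0, 0]), 12.0),
    ]
    if masses is not None:
        atoms = [(el, xyz, m) for (el, xyz, _), m in zip(atoms, masses)]
    return ChromophoreSite(site_id, "A", "CYC", 1, atoms, group=group)


class TestMassCenter:
    def test_equal_masses_midpoint(self):
        s = ChromophoreSite("s", "A", "CYC", 1,
                            [("C", np.zeros(3), 12.0), ("C", np.array([2.0, 0, 0]), 12.0)])
        assert np.allclose(s.mass_center, [1.0, 0, 0])

    def test_single_atom_identity(self):
        s = ChromophoreSite("s", "A", "CYC", 1, [("C", np.array([5.0, 5, 5]), 12.0)])
        assert np.allclose(s.mass_center, [5.0, 5, 5])

    def test_weighted_mean(self):
        s = ChromophoreSite("s", "A", "CYC", 1,
                            [("C", np.zeros(3), 12.0), ("X", np.array([3.0, 0, 0]), 24.0)])
        assert np.isclose(s.mass_center[0], 2.0)

    def test_zero_mass_errors(self):
        s = ChromophoreSite("s", "A", "CYC", 1, [("C", np.zeros(3), 12.0)])
        s.atoms = [("C", np.zeros(3), 0.0)]
        with pytest.raises(ValueError, match="mass"):
            mass_center(s)


class TestDistances:
    def test_pair_distance(self):
        d = pairwise_distances([site_at([0, 0, 0]), site_at([30.0, 0, 0])])
        assert np.isclose(d[0, 1], 30.0) and d[0, 0] == 0.0

    def test_single_site(self):
        assert pairwise_distances([site_at([1, 2, 3])]).shape == (1, 1)

    def test_pythagorean_triangle(self):
        sites = [site_at([0, 0, 0]), site_at([3.0, 0, 0]), site_at([3.0, 4.0, 0])]
        d = pairwise_distances(sites)
        assert sorted(np.round([d[0, 1], d[1, 2], d[0, 2]], 9)) == [3.0, 4.0, 5.0]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(*[st.floats(-100, 100) for _ in range(3)]), min_size=3, max_size=8))
    def test_triangle_inequality(self, centers):
        sites = [site_at(c, site_id=f"s{i}") for i, c in enumerate(centers)]
        d = pairwise_distances(sites)
        n = len(sites)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestEETGraph:
    def test_cutoff_boundary_inclusive(self):
        sites = [site_at([0, 0, 0], "a"), site_at([30.0, 0, 0], "b"), site_at([-40.0, 0, 0], "c")]
        g = build_eet_graph(sites, cutoff=35.0)
        assert g.n_edges == 1 and g.edges[0][:2] == ("a", "b")
        g_exact = build_eet_graph([site_at([0, 0, 0], "a"), site_at([35.0, 0, 0], "b")], cutoff=35.0)
        assert g_exact.n_edges == 1

    def test_zero_cutoff_no_edges(self):
        sites = [site_at([0, 0, 0], "a"), site_at([1.0, 0, 0], "b")]
        assert build_eet_graph(sites, cutoff=0.0).n_edges == 0

    def test_complete_graph_when_all_close(self):
        sites = [site_at([i * 2.0, 0, 0], f"s{i}") for i in range(5)]
        assert build_eet_graph(sites, cutoff=100.0).n_edges == 10

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.tuples(*[st.floats(-50, 50) for _ in range(3)]), min_size=2, max_size=10),
        st.floats(0, 60),
        st.floats(0, 60),
    )
    def test_edge_count_monotone_in_cutoff(self, centers, c1, c2):
        sites = [site_at(c, site_id=f"s{i}") for i, c in enumerate(centers)]
        lo, hi = sorted([c1, c2])
        assert build_eet_graph(sites, lo).n_edges <= build_eet_graph(sites, hi).n_edges


class TestMinIntergroupDistance:
    def test_min_by_hand(self):
        sites = [
            site_at([0, 0, 0], "a0", group="A"),
            site_at([27.0, 0, 0], "b0", group="B"),
            site_at([31.0, 0, 0], "b1", group="B"),
        ]
        d, pair = min_intergroup_distance(sites, "A", "B")
        assert np.isclose(d, 27.0) and pair == ("a0", "b0")

    def test_same_group_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            min_intergroup_distance([site_at([0, 0, 0], group="A")], "A", "A")

    def test_missing_group_named_in_error(self):
        with pytest.raises(ValueError, match="'B'"):
            min_intergroup_distance([site_at([0, 0, 0], group="A")], "A", "B")

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        sites = [
            site_at(rng.uniform(-60, 60, 3), f"s{i:02d}", group=("A" if i % 2 else "B"))
            for i in range(40)
        ]
        d, pair = min_intergroup_distance(sites, "A", "B")
        brute = min(
            (float(np.linalg.norm(sa.mass_center - sb.mass_center)), (sa.site_id, sb.site_id))
            for sa in sites if sa.group == "A"
            for sb in sites if sb.group == "B"
        )
        assert np.isclose(d, brute[0]) and pair == brute[1]


class TestRigidMotionInvariance:
    def test_distances_and_coplanarity_invariant(self):
        rng = np.random.default_rng(7)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.uniform(-50, 50, 3)

        layout = default_toy_layout()
        sites = [site_at(c, f"s{i}", group=g) for i, (g, _, c) in enumerate(layout)]
        moved = []
        for s in sites:
            atoms = [(el, q @ xyz + shift, m) for el, xyz, m in s.atoms]
            moved.append(ChromophoreSite(s.site_id, s.chain_id, s.residue_name,
                                         s.residue_number, atoms, group=s.group))
        d0 = pairwise_distances(sites)
        d1 = pairwise_distances(moved)
        assert np.allclose(d0, d1, atol=1e-9)

        dummy = _planar_bilin(displace_a=1.2, displace_d=-0.7)
        moved_dummy = ChromophoreSite(
            dummy.site_id, dummy.chain_id, dummy.residue_name, dummy.residue_number,
            [(el, q @ xyz + shift, m) for el, xyz, m in dummy.atoms],
        )
        rd = _ring_defs()
        g0 = coplanarity(dummy, rd)
        g1 = coplanarity(moved_dummy, rd)
        assert np.isclose(abs(g0.out_of_plane["A"]), abs(g1.out_of_plane["A"]), atol=1e-9)
        assert np.isclose(abs(g0.out_of_plane["D"]), abs(g1.out_of_plane["D"]), atol=1e-9)


def _planar_bilin(displace_a=0.0, displace_d=0.0):
    """Four triangles in the z=0 plane along x; A/D optionally lifted in z."""
    atoms = []
    for ri, (xc, dz) in enumerate([(-6.0, displace_a), (-2.0, 0.0), (2.0, 0.0), (6.0, displace_d)]):
        for ang in (0.0, 2.1, 4.2):
            atoms.append(("C", np.array([xc + np.cos(ang), np.sin(ang), dz]), 12.0))
    return ChromophoreSite("bilin", "A", "CYC", 1, atoms)


def _ring_defs():
    return {"A": [0, 1, 2], "B": [3, 4, 5], "C": [6, 7, 8], "D": [9, 10, 11]}


class TestCoplanarity:
    def test_all_rings_coplanar(self):
        g = coplanarity(_planar_bilin(), _ring_defs())
        assert np.isclose(g.out_of_plane["A"], 0.0, atol=1e-12)
        assert np.isclose(g.out_of_plane["D"], 0.0, atol=1e-12)
        assert np.isclose(np.linalg.norm(g.bc_normal), 1.0)

    def test_displaced_a_ring(self):
        g = coplanarity(_planar_bilin(displace_a=2.0), _ring_defs())
        assert np.isclose(abs(g.out_of_plane["A"]), 2.0, atol=1e-9)
        assert g.out_of_plane["A"] > 0  # sign convention: A displaces positively

    def test_opposite_sides(self):
        # PEB-like geometry: A and D on opposite sides of the B-C plane
        g = coplanarity(_planar_bilin(displace_a=1.5, displace_d=-1.5), _ring_defs())
        assert g.out_of_plane["A"] * g.out_of_plane["D"] < 0

    def test_too_few_ring_atoms_errors(self):
        rd = _ring_defs()
        rd["B"] = [3, 4]
        with pytest.raises(ValueError, match="ring"):
            coplanarity(_planar_bilin(), rd)

    def test_collinear_bc_errors(self):
        atoms = [("C", np.array([float(i), 0.0, 0.0]), 12.0) for i in range(12)]
        site = ChromophoreSite("bad", "A", "CYC", 1, atoms)
        with pytest.raises(ValueError, match="collinear|degenerate"):
            coplanarity(site, _ring_defs())


class TestHarvest:
    def test_toy_round_trip(self, tmp_path):
        layout = default_toy_layout()
        path = make_toy_structure(layout, str(tmp_path / "toy_pbs.pdb"))
        sites = harvest_chromophores(path, group_map=toy_group_map(layout))
        assert len(sites) == 12
        assert {s.group for s in sites} == {"core", "rod", "rx"}
        d, _ = min_intergroup_distance(sites, "rod", "core")
        assert np.isclose(d, 33.0, atol=1e-5)  # planted rod-core minimum

    def test_two_site_distance_round_trip(self, tmp_path):
        layout = [("a", "PCB", (0.0, 0.0, 0.0)), ("b", "PCB", (30.0, 0.0, 0.0))]
        path = make_toy_structure(layout, str(tmp_path / "pair.pdb"))
        sites = harvest_chromophores(path, group_map=toy_group_map(layout))
        d = pairwise_distances(sites)[0, 1]
        assert np.isclose(d, 30.0, atol=1e-6)

    def test_no_matches_warns_and_returns_empty(self, tmp_path):
        layout = [("a", "PCB", (0.0, 0.0, 0.0))]
        path = make_toy_structure(layout, str(tmp_path / "one.pdb"))
        with pytest.warns(UserWarning, match="matched"):
            sites = harvest_chromophores(path, ligand_map={"ZZZ": "PCB"})
        assert sites == []

    def test_unparseable_file_errors(self, tmp_path):
        bad = tmp_path / "junk.cif"
        bad.write_text("data_x\nloop_\nbroken")
        # gemmi may parse junk as an empty structure; either the format
        # error or the explicit empty-result warning must trigger
        import warnings

        with pytest.raises((ValueError, UserWarning), match="parse|matched"):
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                harvest_chromophores(str(bad))

    def test_bilin_types_from_ligand_map(self, tmp_path):
        layout = [("a", "PCB", (0.0, 0.0, 0.0)), ("a", "PEB", (40.0, 0.0, 0.0))]
        path = make_toy_structure(layout, str(tmp_path / "mix.pdb"))
        sites = harvest_chromophores(path)
        assert sorted(s.bilin_type for s in sites) == ["PCB", "PEB"]
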
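"""Differentiation rule engine: bands, load-case combination, state update."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fusesim.construct import CALLUS, box_mesh
from fusesim.errors import ParameterError
from fusesim.fem import StimulusField
from fusesim.materials import MaterialLibrary
from fusesim.regulation import (
    CallusTopology,
    Phenotype,
    RESORB,
    RuleThresholds,
    classify,
    combine_load_cases,
    element_mean_density,
    initial_tissue,
    update_state,
)


def brute_force_band(eps, p, r=RuleThresholds()):
    """Independently coded band evaluator (scalar, plain conditionals)."""
    if eps < r.eps_resorb_pct and abs(p) < r.p_resorb:
        return RESORB
    if eps <= r.eps_bone_pct and abs(p) <= r.p_bone:
        return int(Phenotype.BONE)
    if p > r.p_bone and eps <= r.eps_cart_pct:
        return int(Phenotype.CARTILAGE)
    return int(Phenotype.FIBROUS)


class TestClassify:
    @pytest.mark.parametrize(
        "eps,p,expected",
        [
            (0.05, 0.05, RESORB),        # below both resorption limits
            (0.0, 0.0, RESORB),          # unloaded element
            (0.5, 0.10, int(Phenotype.BONE)),
            (3.0, 1.0, int(Phenotype.CARTILAGE)),
            (20.0, 1.0, int(Phenotype.FIBROUS)),
            (0.1, 0.0, int(Phenotype.BONE)),     # eps boundary closed for bone
            (0.05, 0.15, int(Phenotype.BONE)),   # |p| = p_resorb not resorbing
            (0.05, -0.05, RESORB),               # tensile p uses magnitude
            (2.0, -1.0, int(Phenotype.FIBROUS)), # strong tension: not cartilage
        ],
    )
    def test_examples(self, eps, p, expected):
        assert classify(eps, p) == expected

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ParameterError):
            RuleThresholds(eps_resorb_pct=6.0)
        with pytest.raises(ParameterError):
            RuleThresholds(p_resorb=0.5, p_bone=0.15)

    @given(
        eps=st.floats(0, 25, allow_nan=False),
        p=st.floats(-2, 2, allow_nan=False),
    )
    @settings(deadline=None, max_examples=300)
    def test_total_and_matches_brute_force(self, eps, p):
        assert classify(eps, p) == brute_force_band(eps, p)

    def test_vectorized_matches_scalar_on_grid(self):
        eps = np.linspace(0, 20, 81)
        p = np.linspace(-1, 1, 41)
        E, P = np.meshgrid(eps, p)
        out = classify(E.ravel(), P.ravel())
        expected = np.array([brute_force_band(e, q) for e, q in zip(E.ravel(), P.ravel())])
        assert np.array_equal(out, expected)


class TestCombine:
    def field(self, eps, p):
        return StimulusField(np.asarray(eps, float), np.asarray(p, float))

    def test_single_case_identity(self):
        f = self.field([1.0, 0.2], [0.3, 0.1])
        out = combine_load_cases([f], [1.0])
        assert np.array_equal(out.eps_min_pct, f.eps_min_pct)
        assert np.array_equal(out.p_hyd, f.p_hyd)

    def test_identical_fields_any_duties(self):
        f = self.field([1.0, 0.2], [0.3, 0.1])
        out = combine_load_cases([f, f], [0.63, 0.37])
        assert np.allclose(out.eps_min_pct, f.eps_min_pct)
        assert np.allclose(out.p_hyd, f.p_hyd)

    def test_weighted_mean_63_37(self):
        a = self.field([1.0], [0.3])
        b = self.field([0.2], [0.1])
        out = combine_load_cases([a, b], [0.63, 0.37])
        assert out.eps_min_pct[0] == pytest.approx(0.704)
        assert out.p_hyd[0] == pytest.approx(0.226)

    def test_max_envelope_takes_larger_strain_case(self):
        a = self.field([1.0, 0.1], [0.3, 0.9])
        b = self.field([0.2, 0.5], [0.1, 0.2])
        out = combine_load_cases([a, b], [0.5, 0.5], mode="max")
        assert np.array_equal(out.eps_min_pct, [1.0, 0.5])
        assert np.array_equal(out.p_hyd, [0.3, 0.2])

    def test_errors(self):
        a = self.field([1.0], [0.3])
        with pytest.raises(ParameterError):
            combine_load_cases([a, a], [0.6, 0.6])
        with pytest.raises(ParameterError):
            combine_load_cases([a, self.field([1, 2], [1, 2])], [0.5, 0.5])


class TestUpdateState:
    @pytest.fixture()
    def mats(self):
        return MaterialLibrary()

    def test_no_cells_no_differentiation(self, small_mesh, mats):
        tissue = initial_tissue(small_mesh, mats)
        nc = tissue.phenotype.size
        targets = np.full(nc, int(Phenotype.BONE))
        cells = np.zeros(small_mesh.n_nodes)
        out = update_state(tissue, targets, cells, small_mesh, materials=mats)
        assert np.all(out.phenotype == int(Phenotype.GRANULATION))
        assert np.allclose(out.effective_E, 1.0)

    def test_full_cells_bone_forms_at_interface_only(self, small_mesh, mats):
        topo = CallusTopology(small_mesh)
        tissue = initial_tissue(small_mesh, mats)
        targets = np.full(tissue.phenotype.size, int(Phenotype.BONE))
        cells = np.ones(small_mesh.n_nodes)
        out = update_state(
            tissue, targets, cells, small_mesh, materials=mats, topology=topo
        )
        new_bone = out.phenotype == int(Phenotype.BONE)
        assert np.array_equal(new_bone, topo.touches_bone)
        assert np.allclose(out.effective_E[new_bone], 1000.0)
        assert np.allclose(out.effective_nu[new_bone], 0.325)

    def test_front_grows_by_face_adjacency(self, small_mesh, mats):
        """With all-bone targets the ossification front is exactly a BFS
        by face adjacency from the vertebral interfaces (graph oracle)."""
        topo = CallusTopology(small_mesh)
        tissue = initial_tissue(small_mesh, mats)
        targets = np.full(tissue.phenotype.size, int(Phenotype.BONE))
        cells = np.ones(small_mesh.n_nodes)

        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(tissue.phenotype.size))
        rows, cols = topo.adjacency.nonzero()
        g.add_edges_from(zip(rows.tolist(), cols.tolist()))
        seeds = np.flatnonzero(topo.touches_bone)
        dist = nx.multi_source_dijkstra_path_length(g, seeds.tolist(), weight=None)

        for k in range(1, 4):
            tissue = update_state(
                tissue, targets, cells, small_mesh, materials=mats, topology=topo
            )
            bone = np.flatnonzero(tissue.phenotype == int(Phenotype.BONE))
            expected = {e for e, d in dist.items() if d <= k - 1}
            assert set(bone.tolist()) == expected

    def test_front_rule_off_allows_interior_bone(self, small_mesh, mats):
        tissue = initial_tissue(small_mesh, mats)
        targets = np.full(tissue.phenotype.size, int(Phenotype.BONE))
        cells = np.ones(small_mesh.n_nodes)
        out = update_state(
            tissue, targets, cells, small_mesh, front_rule=False, materials=mats
        )
        assert np.all(out.phenotype == int(Phenotype.BONE))

    def test_resorption_reverts_bone_to_granulation(self, small_mesh, mats):
        tissue = initial_tissue(small_mesh, mats)
        tissue.phenotype[:] = int(Phenotype.BONE)
        targets = np.full(tissue.phenotype.size, RESORB)
        cells = np.ones(small_mesh.n_nodes)
        out = update_state(tissue, targets, cells, small_mesh, materials=mats)
        assert np.all(out.phenotype == int(Phenotype.GRANULATION))
        assert np.allclose(out.effective_E, 1.0)

    def test_rule_of_mixtures_half_density(self, small_mesh, mats):
        """n_bar = 0.5 bone element: E_eff = 0.5*1000 + 0.5*1 = 500.5 MPa."""
        tissue = initial_tissue(small_mesh, mats)
        targets = np.full(tissue.phenotype.size, int(Phenotype.BONE))
        cells = np.full(small_mesh.n_nodes, 0.5)
        out = update_state(
            tissue, targets, cells, small_mesh, front_rule=False, materials=mats
        )
        assert np.allclose(out.effective_E, 500.5)

    def test_phenotype_counts_conserved(self, small_mesh, mats):
        tissue = initial_tissue(small_mesh, mats)
        nc = tissue.phenotype.size
        rng = np.random.default_rng(7)
        targets = rng.choice(
            [RESORB, int(Phenotype.FIBROUS), int(Phenotype.CARTILAGE),
             int(Phenotype.BONE)],
            size=nc,
        )
        cells = rng.uniform(0, 1, small_mesh.n_nodes)
        out = update_state(tissue, targets, cells, small_mesh, materials=mats)
        counts = np.bincount(out.phenotype, minlength=4)
        assert counts.sum() == nc
        assert out.phenotype.size == nc

    def test_element_mean_density_is_node_average(self, small_mesh):
        cells = np.linspace(0, 1, small_mesh.n_nodes)
        nbar = element_mean_density(small_mesh, cells)
        callus = small_mesh.elements_of(CALLUS)
        manual = cells[small_mesh.tets[callus[5]]].mean()
        assert nbar[5] == pytest.approx(manual)
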
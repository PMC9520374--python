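import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathprobe import synth
from pathprobe.network import (
    MolecularNetwork,
    NetworkNode,
    SpectralEdge,
    build_network,
    entropy_similarity,
    filter_pathway_clusters,
    modified_cosine,
)
from pathprobe.screen import detect_modifications

from conftest import brute_force_modified_cosine, make_spectrum, random_spectrum


class TestModifiedCosine:
    def test_identical_spectra(self):
        s = make_spectrum(300.0, [(100.0, 10.0), (150.0, 20.0), (200.0, 5.0)])
        sim, matched = modified_cosine(s, s)
        assert sim == pytest.approx(1.0, abs=1e-12)
        assert matched == 3

    def test_disjoint_spectra(self):
        a = make_spectrum(300.0, [(100.0, 10.0)])
        b = make_spectrum(300.0, [(200.0, 10.0)])
        sim, matched = modified_cosine(a, b)
        assert sim == 0.0 and matched == 0

    def test_shifted_pairing(self):
        # all peaks of b moved up by the precursor difference: still a perfect match
        a = make_spectrum(300.0, [(100.0, 10.0), (150.0, 20.0)])
        b = make_spectrum(350.0, [(150.0, 10.0), (200.0, 20.0)])
        sim, matched = modified_cosine(b, a)
        assert sim == pytest.approx(1.0, abs=1e-12)
        assert matched == 2

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        grid = np.linspace(100, 250, 12)
        for _ in range(20):
            a = random_spectrum(rng, 5, mz_grid=grid)
            b = random_spectrum(rng, 5, mz_grid=grid)
            ab, _ = modified_cosine(a, b)
            ba, _ = modified_cosine(b, a)
            assert ab == pytest.approx(ba, abs=1e-9)

    def test_empty_spectrum_raises(self):
        with pytest.raises(ValueError):
            modified_cosine(make_spectrum(300.0, [(100.0, 1.0)]), _empty_like())
        with pytest.raises(ValueError):
            entropy_similarity(make_spectrum(300.0, [(100.0, 1.0)]), _empty_like())

    def test_three_peak_toy_matches_bruteforce(self):
        a = make_spectrum(310.0, [(100.0, 10.0), (150.0, 5.0), (200.0, 2.0)])
        b = make_spectrum(300.0, [(100.005, 8.0), (140.0, 5.0), (190.0, 2.0)])
        sim, _ = modified_cosine(a, b)
        assert sim == pytest.approx(brute_force_modified_cosine(a, b), abs=1e-9)

    def test_optimal_equals_bruteforce_on_random_small_spectra(self):
        rng = np.random.default_rng(42)
        grid = np.linspace(100, 200, 10)
        for _ in range(100):
            a = random_spectrum(rng, int(rng.integers(2, 7)), mz_grid=grid)
            b = random_spectrum(rng, int(rng.integers(2, 7)), mz_grid=grid)
            sim, _ = modified_cosine(a, b)
            assert sim == pytest.approx(brute_force_modified_cosine(a, b), abs=1e-9)

    def test_greedy_never_beats_optimal(self):
        rng = np.random.default_rng(7)
        grid = np.linspace(100, 200, 8)
        for _ in range(50):
            a = random_spectrum(rng, 5, mz_grid=grid)
            b = random_spectrum(rng, 5, mz_grid=grid)
            opt, _ = modified_cosine(a, b, assignment="optimal")
            greedy, _ = modified_cosine(a, b, assignment="greedy")
            assert greedy <= opt + 1e-12


def _empty_like():
    # bypass validation helper used by the raising test above
    s = make_spectrum(300.0, [(100.0, 1.0)])
    object.__setattr__(s, "peaks", ())
    return s


class TestEntropySimilarity:
    def test_identical_is_one(self):
        s = make_spectrum(300.0, [(100.0, 10.0), (150.0, 30.0)])
        assert entropy_similarity(s, s) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_single_peaks_is_zero(self):
        # closed form: S_A = S_B = 0, merged = ln 2 => 1 - 2 ln2 / ln4 = 0
        a = make_spectrum(300.0, [(100.0, 10.0)])
        b = make_spectrum(300.0, [(200.0, 10.0)])
        assert entropy_similarity(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(3)
        grid = np.linspace(100, 250, 15)
        for _ in range(30):
            a = random_spectrum(rng, 6, mz_grid=grid)
            b = random_spectrum(rng, 6, mz_grid=grid)
            ab = entropy_similarity(a, b)
            ba = entropy_similarity(b, a)
            assert 0.0 <= ab <= 1.0
            assert ab == pytest.approx(ba, abs=1e-9)

    def test_half_mixture_closed_form(self):
        # two single-peak spectra at the same m/z: merged == each => similarity 1
        a = make_spectrum(300.0, [(100.0, 5.0)])
        b = make_spectrum(300.0, [(100.005, 50.0)])
        assert entropy_similarity(a, b) == pytest.approx(1.0, abs=1e-9)


def _nodes_from(spectra, kind="experimental", registry=None):
    nodes = []
    for s in spectra:
        hits = tuple(detect_modifications(s, registry)) if registry is not None else ()
        nodes.append(NetworkNode(id=s.id, kind=kind, spectrum=s, hits=hits))
    return nodes


class TestBuildNetwork:
    def test_two_identical_spectra_single_edge(self):
        a = make_spectrum(300.0, [(100.0 + i * 10, 10.0) for i in range(7)], id="a")
        b = make_spectrum(300.5, [(100.0 + i * 10, 10.0) for i in range(7)], id="b")
        net = build_network(_nodes_from([a, b]))
        assert len(net.edges) == 1
        assert {net.edges[0].node_a, net.edges[0].node_b} == {"a", "b"}
        assert any(len(c) == 2 for c in net.components)

    def test_threshold_contract(self):
        a = make_spectrum(300.0, [(100.0 + i * 10, 10.0) for i in range(7)], id="a")
        b = make_spectrum(300.5, [(100.0 + i * 10, 10.0) for i in range(7)], id="b")

        def fake_sim(x, y):
            return 0.69, 7

        net = build_network(_nodes_from([a, b]), sim_fn=fake_sim)
        assert net.edges == []

    def test_min_matched_contract(self, registry):
        probes = synth.generate_probes(1, peaks_per_spectrum=8, seed=5)
        many, _, _ = synth.derive_modified(
            probes, registry, n_derived=1, shared_fragment_fraction=1.0, seed=5
        )
        few, _, _ = synth.derive_modified(
            probes, registry, n_derived=1, shared_fragment_fraction=0.25, seed=6
        )
        probe_node = NetworkNode(id="p", kind="probe", spectrum=probes.records[0].spectrum)
        net_many = build_network(
            [probe_node, NetworkNode(id="d", kind="experimental", spectrum=many[0])]
        )
        assert len(net_many.edges) == 1  # 9 shared fragments
        net_few = build_network(
            [probe_node, NetworkNode(id="d", kind="experimental", spectrum=few[0])]
        )
        assert net_few.edges == []  # 3 shared fragments < 6 matches

    def test_duplicate_nodes_merged(self):
        peaks = [(100.0 + i * 10, 10.0) for i in range(7)]
        a = make_spectrum(300.1000, peaks, id="a")
        b = make_spectrum(300.15, peaks, id="b")  # 0.05 Da away: kept
        c = make_spectrum(300.1001, peaks, id="c")  # within 0.01 Da of a: absorbed
        net = build_network(_nodes_from([a, b, c]))
        assert "c" in net.merged  # absorbed into a (same intensity, lexicographic)
        assert net.merged["c"] == "a"
        assert "c" not in net.nodes

    def test_unique_ids_required(self):
        s = make_spectrum(300.0, [(100.0, 1.0)], id="x")
        with pytest.raises(ValueError, match="unique"):
            build_network(_nodes_from([s, s]))

    def test_degree_cap(self):
        # star of identical spectra: every pair connects; cap degree at 3
        peaks = [(100.0 + i * 10, 10.0) for i in range(7)]
        spectra = [make_spectrum(300.0 + i, peaks, id=f"n{i}") for i in range(8)]
        net = build_network(_nodes_from(spectra), max_neighbors=3, max_component=500)
        degrees = {}
        for e in net.edges:
            degrees[e.node_a] = degrees.get(e.node_a, 0) + 1
            degrees[e.node_b] = degrees.get(e.node_b, 0) + 1
        assert degrees and max(degrees.values()) <= 3

    def test_component_cap(self):
        peaks = [(100.0 + i * 10, 10.0) for i in range(7)]
        spectra = [make_spectrum(300.0 + i, peaks, id=f"n{i:02d}") for i in range(12)]
        net = build_network(_nodes_from(spectra), max_component=4)
        assert all(len(c) <= 4 for c in net.components)

    def test_topology_contracts_on_random_networks(self, registry):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            grid = np.linspace(100, 300, 25)
            spectra = [
                random_spectrum(rng, 8, id=f"r{seed}-{i}", mz_grid=grid) for i in range(30)
            ]
            net = build_network(
                _nodes_from(spectra), threshold=0.2, min_matched=2, max_neighbors=4,
                max_component=6,
            )
            degrees: dict[str, int] = {}
            for e in net.edges:
                degrees[e.node_a] = degrees.get(e.node_a, 0) + 1
                degrees[e.node_b] = degrees.get(e.node_b, 0) + 1
            assert all(d <= 4 for d in degrees.values())
            assert all(len(c) <= 6 for c in net.components)

    def test_graphml_round_trip(self, tmp_path):
        import networkx as nx

        peaks = [(100.0 + i * 10, 10.0) for i in range(7)]
        spectra = [make_spectrum(300.0 + i, peaks, id=f"n{i}") for i in range(4)]
        net = build_network(_nodes_from(spectra))
        p = tmp_path / "net.graphml"
        net.to_graphml(p)
        g = nx.read_graphml(p)
        assert set(g.nodes) == set(net.nodes)
        assert g.number_of_edges() == len(net.edges)


class TestFilterPathwayClusters:
    def _network(self, registry, with_probe, specific):
        mod = registry["non-condensed coniferyl alcohol" if specific else "hexosylation"]
        mz = 500.0
        exp1 = make_spectrum(
            mz, [(mz - mod.mass, 150.0)] + [(100.0 + i * 10, 100.0) for i in range(6)], id="e1",
        )
        exp2 = make_spectrum(
            mz + 0.5,
            [(mz - mod.mass, 150.0)] + [(100.0 + i * 10, 100.0) for i in range(6)],
            id="e2",
        )
        nodes = _nodes_from([exp1, exp2], registry=registry)
        if with_probe:
            probe = make_spectrum(
                mz + 1.0, [(100.0 + i * 10, 100.0) for i in range(6)] + [(450.0, 10.0)], id="p1"
            )
            nodes.append(NetworkNode(id="p1", kind="probe", spectrum=probe))
        return build_network(nodes, threshold=0.5, min_matched=5)

    def test_probe_plus_modified_qualifies(self, registry):
        net = self._network(registry, with_probe=True, specific=False)
        clusters = filter_pathway_clusters(net, {"e1", "e2"})
        assert len(clusters) == 1
        assert clusters[0].qualification == "probe+modified"
        assert clusters[0].probe_members == {"p1"}

    def test_specific_modification_only_qualifies(self, registry):
        net = self._network(registry, with_probe=False, specific=True)
        clusters = filter_pathway_clusters(net, {"e1", "e2"})
        assert len(clusters) == 1
        assert clusters[0].qualification == "specific-modification-only"
        assert "non-condensed coniferyl alcohol" in clusters[0].specific_modifications

    def test_generic_only_without_probe_excluded(self, registry):
        net = self._network(registry, with_probe=False, specific=False)
        assert filter_pathway_clusters(net, {"e1", "e2"}) == []

    def test_lone_probe_does_not_qualify(self, registry):
        probe = make_spectrum(400.0, [(100.0, 1.0)], id="p1")
        net = build_network([NetworkNode(id="p1", kind="probe", spectrum=probe)])
        assert filter_pathway_clusters(net, set()) == []

    def test_adding_probe_is_monotone(self, registry):
        # a qualifying specific-only cluster still qualifies with a probe added
        net = self._network(registry, with_probe=True, specific=True)
        clusters = filter_pathway_clusters(net, {"e1", "e2"})
        assert len(clusters) == 1


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_modified_cosine_self_similarity_property(seed):
    rng = np.random.default_rng(seed)
    s = random_spectrum(rng, int(rng.integers(1, 10)), id="s")
    sim, matched = modified_cosine(s, s)
    assert sim == pytest.approx(1.0, abs=1e-9)
    assert matched == len(s)


@settings(max_examples=30, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_entropy_similarity_bounds_property(seed):
    rng = np.random.default_rng(seed)
    grid = np.linspace(100, 200, 12)
    a = random_spectrum(rng, int(rng.integers(1, 7)), mz_grid=grid)
    b = random_spectrum(rng, int(rng.integers(1, 7)), mz_grid=grid)
    sim = entropy_similarity(a, b)
    assert 0.0 <= sim <= 1.0
    assert sim == pytest.approx(entropy_similarity(b, a), abs=1e-9)
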
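"""Modified cosine, consensus clustering, network topology and exports."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from matchms import Spectrum as MatchmsSpectrum
from matchms.similarity import ModifiedCosine

from strainscope.network import (
    ConsensusSpectrum,
    ScoringParams,
    build_network,
    cluster_spectra,
    constellations,
    cosine_score,
    export_network,
    library_match,
)
from strainscope.spectra import Spectrum
from strainscope.synthetic import SimulationConfig, make_library, make_production, simulate_spectra


def _spec(mz, intensity, precursor=500.0, sid="s"):
    return Spectrum(id=sid, precursor_mz=precursor, mz=np.asarray(mz, float),
                    intensity=np.asarray(intensity, float))


def _optimal_assignment(a, b, p, shifted=True):
    """Exhaustive one-to-one matching oracle (small spectra only)."""
    wa = a.intensity ** p.intensity_power
    wa = wa / np.linalg.norm(wa)
    wb = b.intensity ** p.intensity_power
    wb = wb / np.linalg.norm(wb)
    delta = a.precursor_mz - b.precursor_mz
    pairs = []
    for i, mza in enumerate(a.mz):
        for j, mzb in enumerate(b.mz):
            if abs(mza - mzb) <= p.fragment_tol or (
                shifted and abs(mza - (mzb + delta)) <= p.fragment_tol
            ):
                pairs.append((i, j, wa[i] * wb[j]))

    best = 0.0
    def recurse(k, used_a, used_b, acc):
        nonlocal best
        best = max(best, acc)
        for idx in range(k, len(pairs)):
            i, j, prod = pairs[idx]
            if i not in used_a and j not in used_b:
                recurse(idx + 1, used_a | {i}, used_b | {j}, acc + prod)
    recurse(0, frozenset(), frozenset(), 0.0)
    return best


class TestCosineScore:
    def test_self_similarity_is_one(self):
        s = _spec([100.0, 150.0, 200.0], [1.0, 5.0, 2.0])
        score, matched = cosine_score(s, s)
        assert score == pytest.approx(1.0)
        assert matched == 3

    def test_disjoint_spectra_score_zero(self):
        a = _spec([100.0, 200.0], [1.0, 1.0], precursor=400.0)
        b = _spec([150.0, 250.0], [1.0, 1.0], precursor=400.0)
        assert cosine_score(a, b) == (0.0, 0)

    def test_two_peak_hand_computation(self):
        # equal intensities: each normalized weight is 1/sqrt(2); two matched
        # pairs contribute 1/2 each
        a = _spec([100.0, 200.0], [1.0, 1.0], precursor=300.0)
        b = _spec([100.0, 200.0], [1.0, 1.0], precursor=300.0)
        score, matched = cosine_score(a, b)
        assert score == pytest.approx(1.0)
        assert matched == 2
        half, _ = cosine_score(a, _spec([100.0, 500.0], [1.0, 1.0], precursor=300.0))
        assert half == pytest.approx(0.5)

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a = _spec(rng.uniform(100, 400, 5), rng.uniform(1, 10, 5), precursor=450.0)
        b = _spec(rng.uniform(100, 400, 6), rng.uniform(1, 10, 6), precursor=470.0)
        assert cosine_score(a, b) == cosine_score(b, a)

    def test_shifted_matching_links_modified_pairs(self):
        # b is a +14 Da homologue: shared fragment plus one precursor-shifted
        a = _spec([120.0, 250.0], [1.0, 1.0], precursor=300.0)
        b = _spec([120.0, 264.0], [1.0, 1.0], precursor=314.0)
        unshifted, _ = cosine_score(a, b, shifted=False)
        shifted, matched = cosine_score(a, b, shifted=True)
        assert shifted > unshifted
        assert shifted == pytest.approx(1.0) and matched == 2

    def test_empty_spectrum_rejected(self):
        a = _spec([100.0], [1.0])
        b = Spectrum(id="e", precursor_mz=100.0, mz=np.empty(0), intensity=np.empty(0))
        with pytest.raises(ValueError):
            cosine_score(a, b)

    def test_greedy_bounded_by_optimal_assignment(self):
        rng = np.random.default_rng(7)
        p = ScoringParams()
        for _ in range(200):
            n1, n2 = rng.integers(1, 7), rng.integers(1, 7)
            a = _spec(rng.uniform(100, 130, n1), rng.uniform(1, 10, n1),
                      precursor=float(rng.uniform(140, 160)))
            b = _spec(rng.uniform(100, 130, n2), rng.uniform(1, 10, n2),
                      precursor=float(rng.uniform(140, 160)))
            greedy, _ = cosine_score(a, b, p)
            optimal = _optimal_assignment(a, b, p)
            assert greedy <= optimal + 1e-12

    def test_greedy_equals_optimal_when_unambiguous(self):
        rng = np.random.default_rng(8)
        p = ScoringParams(fragment_tol=0.1)
        for _ in range(100):
            # widely separated peaks: every peak has at most one candidate partner
            base = np.sort(rng.choice(np.arange(100, 400, 5.0), size=5, replace=False))
            keep = rng.random(5) < 0.7
            a = _spec(base, rng.uniform(1, 10, 5), precursor=450.0)
            if not keep.any():
                continue
            b = _spec(base[keep] + rng.uniform(-0.05, 0.05, keep.sum()),
                      rng.uniform(1, 10, int(keep.sum())), precursor=450.0)
            greedy, _ = cosine_score(a, b, p)
            assert greedy == pytest.approx(_optimal_assignment(a, b, p), abs=1e-12)

    def test_agrees_with_matchms_modified_cosine(self):
        rng = np.random.default_rng(3)
        p = ScoringParams(fragment_tol=0.5, intensity_power=1.0)
        oracle = ModifiedCosine(tolerance=0.5)
        for _ in range(50):
            n1, n2 = int(rng.integers(3, 10)), int(rng.integers(3, 10))
            common = rng.uniform(100, 500, 3)
            mz1 = np.concatenate([rng.uniform(100, 500, n1), common])
            mz2 = np.concatenate([rng.uniform(100, 500, n2), common + rng.normal(0, 0.1, 3)])
            i1, i2 = rng.uniform(0.1, 1, n1 + 3), rng.uniform(0.1, 1, n2 + 3)
            p1, p2 = float(rng.uniform(400, 600)), float(rng.uniform(400, 600))
            a, b = _spec(mz1, i1, p1), _spec(mz2, i2, p2)
            ours, our_matched = cosine_score(a, b, p)
            res = oracle.pair(
                MatchmsSpectrum(mz=a.mz, intensities=a.intensity,
                                metadata={"precursor_mz": p1}, metadata_harmonization=False),
                MatchmsSpectrum(mz=b.mz, intensities=b.intensity,
                                metadata={"precursor_mz": p2}, metadata_harmonization=False),
            )
            assert ours == pytest.approx(float(res["score"]), abs=1e-9)
            assert our_matched == int(res["matches"])


class TestClusterSpectra:
    def _replicates(self, n, precursor=400.0):
        return [_spec([100.0, 150.0, 200.0], [1.0, 5.0, 2.0],
                      precursor=precursor, sid=f"r{i}") for i in range(n)]

    def test_four_identical_spectra_one_node(self, default_params):
        nodes = cluster_spectra(self._replicates(4), default_params)
        assert len(nodes) == 1
        assert nodes[0].size == 4

    def test_three_identical_spectra_discarded(self, default_params):
        assert cluster_spectra(self._replicates(3), default_params) == []

    def test_planted_compounds_recovered_one_node_each(self, small_sim, default_params):
        lib, prod, spectra = small_sim
        nodes = cluster_spectra(spectra, default_params)
        produced = {c.name for c in lib.compounds if (prod.values[c.name] > 0).any()}
        assert len(nodes) == len(produced)

    def test_consensus_peaks_sorted(self, small_sim, default_params):
        _, _, spectra = small_sim
        for node in cluster_spectra(spectra, default_params):
            assert (np.diff(node.mz) >= 0).all()


class TestBuildNetwork:
    def test_single_node_no_edges(self, small_sim, default_params):
        _, _, spectra = small_sim
        nodes = cluster_spectra(spectra, default_params)[:1]
        g = build_network(nodes, default_params)
        assert g.number_of_edges() == 0

    def test_identical_nodes_linked_at_one(self, default_params):
        n1 = ConsensusSpectrum("a", ["x"], 400.0, np.array([100.0, 200.0]),
                               np.array([1.0, 2.0]))
        n2 = ConsensusSpectrum("b", ["y"], 400.0, np.array([100.0, 200.0]),
                               np.array([1.0, 2.0]))
        g = build_network([n1, n2], default_params)
        assert g.number_of_edges() == 1
        assert g.edges["a", "b"]["cosine"] == pytest.approx(1.0)

    def test_disjoint_families_stay_unlinked(self, default_params):
        cfg = SimulationConfig(n_strains=3, compounds_per_group={"1": 4, "3": 4}, seed=13)
        lib = make_library(cfg)
        prod = make_production(lib, cfg=cfg)
        nodes = cluster_spectra(simulate_spectra(lib, prod, cfg), default_params)
        group_of = {n.id: min(lib.compounds, key=lambda c: abs(c.ion_mz - n.precursor_mz)).group
                    for n in nodes}
        g = build_network(nodes, default_params)
        for u, v in g.edges:
            assert group_of[u] == group_of[v]

    def test_raising_threshold_never_adds_edges(self, small_sim):
        _, _, spectra = small_sim
        counts = []
        for thr in (0.3, 0.5, 0.7, 0.9):
            p = ScoringParams(min_cosine=thr)
            nodes = cluster_spectra(spectra, ScoringParams())
            counts.append(build_network(nodes, p).number_of_edges())
        assert counts == sorted(counts, reverse=True)


class TestConstellations:
    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        assert [len(c) for c in constellations(g)] == [1] * 5

    def test_two_planted_families_two_constellations(self, default_params):
        cfg = SimulationConfig(n_strains=3, compounds_per_group={"1": 4, "3": 4}, seed=13)
        lib = make_library(cfg)
        prod = make_production(lib, cfg=cfg)
        nodes = cluster_spectra(simulate_spectra(lib, prod, cfg), default_params)
        g = build_network(nodes, default_params)
        assert len(constellations(g)) == 2

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(2, 30))
            g = nx.gnp_random_graph(n, float(rng.uniform(0, 0.3)),
                                    seed=int(rng.integers(2**31)))
            parent = list(range(n))
            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x
            for u, v in g.edges:
                parent[find(u)] = find(v)
            oracle = len({find(x) for x in range(n)})
            assert len(constellations(g)) == oracle


class TestLibraryMatch:
    def test_identical_entry_scores_one(self, default_params):
        s = _spec([100.0, 150.0, 200.0], [1.0, 5.0, 2.0], sid="node")
        entry = _spec([100.0, 150.0, 200.0], [1.0, 5.0, 2.0], sid="bagremycin A")
        hits = library_match(s, [entry], default_params)
        assert len(hits) == 1
        assert hits[0][0].id == "bagremycin A"
        assert hits[0][1] == pytest.approx(1.0)

    def test_single_shared_peak_never_hits(self, default_params):
        # one dominant shared peak gives a high cosine but only 1 matched peak
        node = _spec([100.0], [10.0])
        entry = _spec([100.0, 350.0], [10.0, 0.01])
        assert library_match(node, [entry], default_params) == []

    def test_agrees_with_exhaustive_scoring(self, default_params):
        rng = np.random.default_rng(23)
        library = [_spec(rng.uniform(100, 400, 5), rng.uniform(1, 10, 5),
                         precursor=400.0, sid=f"lib{i}") for i in range(20)]
        node = library[7]
        hits = library_match(node, library, default_params)
        expected = []
        for entry in library:
            sc, matched = cosine_score(node, entry, default_params, shifted=False)
            if sc >= default_params.library_min_score and matched >= default_params.library_min_matched:
                expected.append((entry.id, round(sc, 9)))
        assert sorted((h[0].id, round(h[1], 9)) for h in hits) == sorted(expected)

    def test_empty_library_rejected(self, default_params):
        with pytest.raises(ValueError):
            library_match(_spec([100.0], [1.0]), [], default_params)


class TestExport:
    def test_edge_table_round_trip(self, small_sim, default_params, tmp_path):
        _, _, spectra = small_sim
        nodes = cluster_spectra(spectra, default_params)
        g = build_network(nodes, default_params)
        paths = export_network(g, tmp_path / "net")
        edges = pd.read_csv(paths["edges"], sep="\t")
        got = {frozenset((r.source, r.target)) for r in edges.itertuples()}
        assert got == {frozenset(e) for e in g.edges}

    def test_graphml_loadable_by_standard_tool(self, small_sim, default_params, tmp_path):
        _, _, spectra = small_sim
        nodes = cluster_spectra(spectra, default_params)
        g = build_network(nodes, default_params)
        paths = export_network(g, tmp_path / "net")
        back = nx.read_graphml(paths["graphml"])
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}

    def test_empty_graph_exports_valid_files(self, tmp_path):
        g = nx.Graph()
        paths = export_network(g, tmp_path / "empty")
        assert nx.read_graphml(paths["graphml"]).number_of_nodes() == 0
        assert len(pd.read_csv(paths["edges"], sep="\t")) == 0
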
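"""Pairwise graph construction, topology and StromaBlocker against oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from scmtop.graph import (EdgeSet, GRAPH_LABELS, GRAPH_TYPES,
                          StromaBlockerConfig, assemble_cell_features,
                          build_all_graphs, build_pairwise_graph,
                          compute_stroma_blocker, compute_topology)
from scmtop.nuclei_io import CellType, NucleusSet
from scmtop.synthetic import (FieldConfig, PoissonProcess, ThomasProcess,
                              simulate_field)

from conftest import brute_force_pairwise_edges, make_nucleus, random_nucleus_set


class TestBuildPairwiseGraph:
    def test_single_cell_no_edges(self):
        ns = NucleusSet("s", [make_nucleus("a", 10, 10, CellType.TUMOR)])
        es = build_pairwise_graph(ns, CellType.TUMOR, CellType.TUMOR)
        assert len(es) == 0

    def test_pair_within_threshold(self):
        ns = NucleusSet("s", [make_nucleus("a", 10, 10, CellType.TUMOR),
                              make_nucleus("b", 90, 10, CellType.TUMOR)])
        es = build_pairwise_graph(ns, CellType.TUMOR, CellType.TUMOR)
        assert len(es) == 1
        assert es.edges[0][2] == pytest.approx(80.0)

    def test_pair_beyond_threshold(self):
        ns = NucleusSet("s", [make_nucleus("a", 10, 10, CellType.TUMOR),
                              make_nucleus("b", 130, 10, CellType.TUMOR)])
        es = build_pairwise_graph(ns, CellType.TUMOR, CellType.TUMOR)
        assert len(es) == 0

    def test_exact_threshold_deleted(self):
        ns = NucleusSet("s", [make_nucleus("a", 0, 10, CellType.TUMOR),
                              make_nucleus("b", 100, 10, CellType.TUMOR)])
        es = build_pairwise_graph(ns, CellType.TUMOR, CellType.TUMOR)
        assert len(es) == 0

    def test_unknown_type_rejected(self, rng):
        ns = random_nucleus_set(rng, 10)
        with pytest.raises(ValueError):
            build_pairwise_graph(ns, CellType.TUMOR, CellType.DEAD)

    @pytest.mark.parametrize("n", [50, 300])
    def test_matches_exhaustive_oracle(self, rng, n):
        ns = random_nucleus_set(rng, n, size_px=800)
        for label in GRAPH_LABELS:
            c1, c2 = GRAPH_TYPES[label]
            es = build_pairwise_graph(ns, c1, c2)
            got = {tuple(sorted((a, b))) for a, b, _ in es.edges}
            want = brute_force_pairwise_edges(ns, c1, c2, k=5, threshold=100.0)
            assert got == want, label

    def test_edge_invariants(self, rng):
        ns = random_nucleus_set(rng, 200, size_px=600)
        for es in build_all_graphs(ns).values():
            pairs = [(a, b) for a, b, _ in es.edges]
            assert all(a != b for a, b in pairs)
            assert len(set(pairs)) == len(pairs)
            assert all(d < 100.0 for _, _, d in es.edges)


class TestComputeTopology:
    def test_isolated_cell_sentinels(self):
        ns = NucleusSet("s", [make_nucleus("i1", 10, 10, CellType.INFLAMMATORY)])
        es = build_pairwise_graph(ns, CellType.INFLAMMATORY, CellType.INFLAMMATORY)
        topo = compute_topology(es, ns).loc["i1"]
        assert topo["Degrees"] == 0
        assert topo["Nsubgraph"] == 1
        assert topo["MinEdgeLength"] == 100.0
        assert topo["MeanEdgeLength"] == 100.0
        assert topo["Closeness"] == 0.0
        assert topo["ClusteringCoefficient"] == 0.0

    def test_triangle(self):
        ns = NucleusSet("s", [make_nucleus("a", 0, 0, CellType.TUMOR),
                              make_nucleus("b", 50, 0, CellType.TUMOR),
                              make_nucleus("c", 25, 40, CellType.TUMOR)])
        es = build_pairwise_graph(ns, CellType.TUMOR, CellType.TUMOR)
        topo = compute_topology(es, ns)
        assert (topo["Degrees"] == 2).all()
        assert (topo["Nsubgraph"] == 3).all()
        assert (topo["ClusteringCoefficient"] == 1.0).all()

    def test_path_centralities_match_networkx(self):
        # path a-b-c-d-e at 60-px spacing
        ns = NucleusSet("s", [make_nucleus(ch, 60 * i, 0, CellType.TUMOR)
                              for i, ch in enumerate("abcde")])
        es = build_pairwise_graph(ns, CellType.TUMOR, CellType.TUMOR, k=1)
        assert len(es) == 4
        topo = compute_topology(es, ns)
        g = nx.path_graph(["a", "b", "c", "d", "e"])
        betw = nx.betweenness_centrality(g, normalized=False)
        close = nx.closeness_centrality(g)
        ecc = nx.eccentricity(g)
        harm = nx.harmonic_centrality(g)
        for v in "abcde":
            assert topo.loc[v, "Betweenness"] == pytest.approx(betw[v])
            assert topo.loc[v, "Closeness"] == pytest.approx(close[v])
            assert topo.loc[v, "Eccentricity"] == ecc[v]
            assert topo.loc[v, "HarmonicCentrality"] == pytest.approx(harm[v] / 4)
        assert topo.loc["c", "Betweenness"] == 4.0
        assert topo.loc["c", "Betweenness_normed"] == pytest.approx(4 / 6)
        assert topo.loc["c", "Eccentricity_normed"] == pytest.approx(2 / 4)

    def test_heterotypic_graph_drops_clustering_coefficient(self, rng):
        ns = random_nucleus_set(rng, 60)
        es = build_pairwise_graph(ns, CellType.TUMOR, CellType.INFLAMMATORY)
        topo = compute_topology(es, ns)
        assert "ClusteringCoefficient" not in topo.columns

    def test_degrees_and_edge_length_consistency(self, rng):
        ns = random_nucleus_set(rng, 150, size_px=500)
        for es in build_all_graphs(ns).values():
            topo = compute_topology(es, ns)
            incident = {}
            for a, b, d in es.edges:
                incident.setdefault(a, []).append(d)
                incident.setdefault(b, []).append(d)
            for cid, row in topo.iterrows():
                assert row["Degrees"] == len(incident.get(cid, []))
                assert row["MinEdgeLength"] <= row["MeanEdgeLength"] + 1e-12
                assert row["MeanEdgeLength"] <= 100.0

    def test_clustered_field_denser_than_poisson(self):
        intensity = 800.0
        clustered = FieldConfig(
            size_um=800, seed=7, slide_id="thomas",
            processes={CellType.INFLAMMATORY: ThomasProcess(
                parent_intensity_per_mm2=intensity / 25, mean_offspring=25,
                sigma_um=8.0)})
        poisson = FieldConfig(
            size_um=800, seed=7, slide_id="pois",
            processes={CellType.INFLAMMATORY: PoissonProcess(intensity)})
        stats = {}
        for fc in (clustered, poisson):
            ns = simulate_field(fc).nucleus_set
            es = build_pairwise_graph(ns, CellType.INFLAMMATORY,
                                      CellType.INFLAMMATORY)
            topo = compute_topology(es, ns)
            stats[fc.slide_id] = (topo["Degrees"].mean(),
                                  topo["MinEdgeLength"].mean())
        assert stats["thomas"][0] > stats["pois"][0]
        assert stats["thomas"][1] < stats["pois"][1]


class TestStromaBlocker:
    def test_no_stroma_gives_zero(self):
        ns = NucleusSet("s", [make_nucleus("i1", 0, 0, CellType.INFLAMMATORY),
                              make_nucleus("t1", 50, 0, CellType.TUMOR)])
        assert compute_stroma_blocker(ns)["i1"] == 0.0

    def test_midpoint_stroma_counts_once(self):
        ns = NucleusSet("s", [make_nucleus("i1", 0, 0, CellType.INFLAMMATORY),
                              make_nucleus("t1", 60, 0, CellType.TUMOR),
                              make_nucleus("s1", 30, 0, CellType.STROMA)])
        assert compute_stroma_blocker(ns)["i1"] == 1.0

    def test_matches_geometric_oracle(self, rng):
        ns = random_nucleus_set(rng, 120, size_px=400)
        cfg = StromaBlockerConfig()
        got = compute_stroma_blocker(ns, cfg)
        inf = [n for n in ns if n.cell_type is CellType.INFLAMMATORY]
        tum = [n for n in ns if n.cell_type is CellType.TUMOR]
        stroma = np.array([n.centroid for n in ns
                           if n.cell_type is CellType.STROMA])
        for cell in inf:
            a = np.array(cell.centroid)
            dists = sorted((np.linalg.norm(np.array(t.centroid) - a), t.id,
                            np.array(t.centroid)) for t in tum)
            counts = []
            for d, _, b in dists[:cfg.k_tumor]:
                if d > cfg.radius_px:
                    continue
                c = 0
                for s in stroma:
                    ab = b - a
                    t = np.clip(np.dot(s - a, ab) / max(np.dot(ab, ab), 1e-12), 0, 1)
                    if np.linalg.norm(s - (a + t * ab)) <= cfg.corridor_halfwidth_px:
                        c += 1
                counts.append(c)
            want = float(np.mean(counts)) if counts else 0.0
            assert got[cell.id] == pytest.approx(want)


class TestAssembleCellFeatures:
    def test_column_membership_rule(self, rng):
        ns = random_nucleus_set(rng, 60)
        edge_sets = build_all_graphs(ns)
        morph = pd.DataFrame(
            {"Area": 30.0}, index=pd.Index(
                [n.id for n in ns], name="cell_id"))
        tables = assemble_cell_features(ns, edge_sets, morph)
        assert {"T-T_Degrees", "T-I_Degrees", "T-S_Degrees"} <= set(
            tables["tumor"].columns)
        assert not any(c.startswith("I-S") for c in tables["tumor"].columns)
        assert "StromaBlocker" in tables["inflammatory"].columns
        assert "StromaBlocker" not in tables["tumor"].columns
        assert not any(c.startswith("T-T") for c in tables["stroma"].columns)

    def test_one_cell_per_type(self):
        ns = NucleusSet("s", [make_nucleus("t", 0, 0, CellType.TUMOR),
                              make_nucleus("i", 50, 0, CellType.INFLAMMATORY),
                              make_nucleus("s", 0, 50, CellType.STROMA)])
        edge_sets = build_all_graphs(ns)
        morph = pd.DataFrame({"Area": [30.0, 30.0, 30.0]},
                             index=pd.Index(["t", "i", "s"], name="cell_id"))
        tables = assemble_cell_features(ns, edge_sets, morph)
        assert all(len(t) == 1 for t in tables.values())
        assert tables["tumor"].loc["t", "T-I_Degrees"] == 1

    def test_unknown_id_rejected(self, rng):
        ns = random_nucleus_set(rng, 10)
        edge_sets = build_all_graphs(ns)
        morph = pd.DataFrame({"Area": [1.0]},
                             index=pd.Index(["ghost"], name="cell_id"))
        with pytest.raises(ValueError, match="unknown"):
            assemble_cell_features(ns, edge_sets, morph)
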
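"""Spot tessellation, spatial correlation, Moran's I, MEM discovery, variation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from scmtop.nuclei_io import CellType, NucleusSet
from scmtop.spatial import (MODULE0, SpatialWeights, build_mem_model,
                            correlation_matrix, mem_variation, module_morans_i,
                            morans_i, occupied_grid, rook_weights, score_spots,
                            spatial_correlation, tessellate)
from scmtop.synthetic import CohortConfig, simulate_cohort

from conftest import (brute_force_morans_i, brute_force_spatial_corr,
                      make_nucleus)


def grid_weights(nrow, ncol):
    """Rook weights for a full nrow x ncol grid plus the matching index."""
    index = pd.MultiIndex.from_product([range(nrow), range(ncol)],
                                       names=["row", "col"])
    return rook_weights(index), index


class TestTessellate:
    def _ns(self, points_um, mpp=0.25):
        nuclei = [make_nucleus(str(i), x / mpp, y / mpp, CellType.TUMOR)
                  for i, (x, y) in enumerate(points_um)]
        return NucleusSet("s", nuclei, mpp=mpp)

    def test_floor_arithmetic(self):
        ns = self._ns([(10, 10), (790, 10)])
        labels = pd.Series({"0": "A", "1": "A"})
        sm = tessellate(ns, labels, spot_um=200)
        assert set(sm.counts.index) == {(0, 0), (0, 3)}
        assert (sm.counts["A"] == 1).all()

    def test_boundary_goes_to_higher_spot(self):
        ns = self._ns([(200.0, 10.0)])
        labels = pd.Series({"0": "A"})
        sm = tessellate(ns, labels, spot_um=200)
        assert list(sm.counts.index) == [(0, 1)]

    def test_count_conservation(self, rng):
        pts = rng.uniform(0, 1000, size=(300, 2))
        ns = self._ns([tuple(p) for p in pts])
        clusters = rng.choice(["A", "B", "C"], size=300)
        labels = pd.Series(clusters, index=[str(i) for i in range(300)])
        sm = tessellate(ns, labels, spot_um=200)
        for c in "ABC":
            assert sm.counts[c].sum() == (clusters == c).sum()
        assert sm.counts.to_numpy().sum() == 300

    def test_unlabelled_cell_rejected(self):
        ns = self._ns([(10, 10)])
        with pytest.raises(ValueError, match="without cluster label"):
            tessellate(ns, pd.Series(dtype=object), spot_um=200)


class TestSpatialStatistics:
    def test_checkerboard_morans_i(self):
        w, index = grid_weights(4, 4)
        x = np.array([(r + c) % 2 for r, c in index], dtype=float)
        got, degenerate = morans_i(x, w)
        assert not degenerate
        assert got == pytest.approx(-1.0, abs=1e-12)
        assert got == pytest.approx(brute_force_morans_i(x, w.matrix), abs=1e-12)

    def test_half_split_morans_i(self):
        w, index = grid_weights(4, 4)
        x = np.array([1.0 if c < 2 else 0.0 for _, c in index])
        got, _ = morans_i(x, w)
        assert got == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert got == pytest.approx(brute_force_morans_i(x, w.matrix), abs=1e-12)

    def test_constant_field_degenerate(self):
        w, _ = grid_weights(3, 3)
        got, degenerate = morans_i(np.ones(9), w)
        assert got == 0.0 and degenerate

    def test_bivariate_reduces_to_morans_i(self, rng):
        w, _ = grid_weights(5, 5)
        for _ in range(10):
            x = rng.uniform(size=25)
            c, _ = spatial_correlation(x, x, w)
            i, _ = morans_i(x, w)
            assert c == pytest.approx(i, abs=1e-10)

    def test_zero_variance_flagged(self, rng):
        w, _ = grid_weights(3, 3)
        c, degenerate = spatial_correlation(np.ones(9), rng.uniform(size=9), w)
        assert c == 0.0 and degenerate

    def test_matches_double_loop_oracle(self, rng):
        w, _ = grid_weights(4, 6)
        for _ in range(5):
            x = rng.poisson(5, size=24).astype(float)
            y = rng.poisson(3, size=24).astype(float)
            got, _ = spatial_correlation(x, y, w)
            assert got == pytest.approx(
                brute_force_spatial_corr(x, y, w.matrix), abs=1e-12)

    def test_rook_weights_symmetric_zero_diagonal(self):
        w, _ = grid_weights(4, 4)
        assert np.array_equal(w.matrix, w.matrix.T)
        assert np.all(np.diag(w.matrix) == 0)
        assert w.total == 48  # 24 undirected rook pairs


def planted_block_matrices(rng, n_samples=5):
    """Per-sample correlation matrices with two planted blocks {A,B},{C,D}."""
    clusters = ["A", "B", "C", "D"]
    out = []
    for _ in range(n_samples):
        m = np.full((4, 4), 0.0)
        m += rng.normal(scale=0.03, size=(4, 4))
        for i in range(4):
            m[i, i] = 1.0
        m[0, 1] = m[1, 0] = 0.8 + rng.normal(scale=0.05)
        m[2, 3] = m[3, 2] = 0.8 + rng.normal(scale=0.05)
        C = pd.DataFrame(m, index=clusters, columns=clusters)
        flags = pd.DataFrame(False, index=clusters, columns=clusters)
        out.append((C, flags))
    return out


class TestBuildMemModel:
    def test_planted_block_recovery(self, rng):
        mm = build_mem_model(planted_block_matrices(rng), n_modules=2)
        assert mm.module_of["A"] == mm.module_of["B"]
        assert mm.module_of["C"] == mm.module_of["D"]
        assert mm.module_of["A"] != mm.module_of["C"]

    def test_singleton_modules_at_max_cut(self, rng):
        mm = build_mem_model(planted_block_matrices(rng), n_modules=4)
        assert mm.n_modules == 4
        assert len(set(mm.module_of.values())) == 4

    def test_permutation_invariance(self, rng):
        mats = planted_block_matrices(rng)
        mm1 = build_mem_model(mats, n_modules=2)
        order = ["C", "A", "D", "B"]
        permuted = [(C.loc[order, order], f.loc[order, order]) for C, f in mats]
        mm2 = build_mem_model(permuted, n_modules=2)
        part1 = [sorted(mm1.module_clusters(m)) for m in mm1.module_names]
        part2 = [sorted(mm2.module_clusters(m)) for m in mm2.module_names]
        assert sorted(map(tuple, part1)) == sorted(map(tuple, part2))

    def test_degenerate_pair_everywhere_rejected(self, rng):
        mats = planted_block_matrices(rng, n_samples=2)
        for _, flags in mats:
            flags.loc["A", "B"] = True
            flags.loc["B", "A"] = True
        with pytest.raises(ValueError, match="degenerate"):
            build_mem_model(mats, n_modules=2)

    def test_mean_ignores_flagged_entries(self, rng):
        mats = planted_block_matrices(rng, n_samples=3)
        # corrupt one sample's A-B entry and flag it: mean must ignore it
        mats[0][0].loc["A", "B"] = 99.0
        mats[0][1].loc["A", "B"] = True
        mm = build_mem_model(mats, n_modules=2)
        others = [m.loc["A", "B"] for m, _ in mats[1:]]
        sym_ab = (np.mean(others) + np.mean([m.loc["B", "A"] for m, _ in mats])) / 2
        assert mm.mean_correlation.loc["A", "B"] == pytest.approx(sym_ab)


class TestScoreSpots:
    def _spot_matrix(self):
        counts = pd.DataFrame(
            {"A": [4, 0, 0], "B": [0, 6, 0], "C": [0, 2, 0]},
            index=pd.MultiIndex.from_tuples([(0, 0), (0, 1), (1, 0)],
                                            names=["row", "col"]))
        from scmtop.spatial import SpotMatrix
        return SpotMatrix("s", counts, spot_px=800.0, mpp=0.25)

    def _model(self, rng):
        mats = planted_block_matrices(rng)
        for C, f in mats:
            C.drop(index="D", columns="D", inplace=True)
            f.drop(index="D", columns="D", inplace=True)
        return build_mem_model(mats, n_modules=2)

    def test_empty_spot_gets_module0(self, rng):
        scored = score_spots(self._spot_matrix(), self._model(rng))
        assert scored.loc[(1, 0), "module"] == MODULE0

    def test_pure_spot_scores_one(self, rng):
        mm = self._model(rng)
        scored = score_spots(self._spot_matrix(), mm)
        mod_a = mm.module_of["A"]
        assert scored.loc[(0, 0), mod_a] == pytest.approx(1.0)
        assert scored.loc[(0, 0), "module"] == mod_a

    def test_scores_sum_to_one_on_nonempty_spots(self, rng):
        mm = self._model(rng)
        scored = score_spots(self._spot_matrix(), mm)
        nonempty = scored["n_cells"] > 0
        sums = scored.loc[nonempty, mm.module_names].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_unknown_cluster_rejected(self, rng):
        sm = self._spot_matrix()
        sm.counts["Z"] = 1
        with pytest.raises(ValueError, match="not in MEM model"):
            score_spots(sm, self._model(rng))


class TestMemVariation:
    def test_identical_proportions_zero_intra(self):
        idx = pd.Index(range(6))
        assignments = pd.Series(["M1"] * 3 + ["M2"] * 3, index=idx)
        props = pd.DataFrame({"tumor": [0.5] * 3 + [0.2] * 3}, index=idx)
        out = mem_variation(assignments, props)
        assert out.loc["tumor", "intra"] == pytest.approx(0.0)
        assert out.loc["tumor", "inter"] == pytest.approx(0.15)

    def test_equal_module_means_zero_inter(self):
        idx = pd.Index(range(4))
        assignments = pd.Series(["M1", "M1", "M2", "M2"], index=idx)
        props = pd.DataFrame({"tumor": [0.4, 0.6, 0.3, 0.7]}, index=idx)
        out = mem_variation(assignments, props)
        assert out.loc["tumor", "inter"] == pytest.approx(0.0)
        assert out.loc["tumor", "intra"] == pytest.approx(
            (np.std([0.4, 0.6]) + np.std([0.3, 0.7])) / 2)

    def test_matches_two_pass_oracle(self, rng):
        idx = pd.Index(range(40))
        assignments = pd.Series(rng.choice(["M1", "M2", "M3"], size=40), index=idx)
        props = pd.DataFrame({"t": rng.uniform(size=40)}, index=idx)
        out = mem_variation(assignments, props)
        mods = sorted(assignments.unique())
        sds = [props.loc[assignments == m, "t"].to_numpy().std() for m in mods]
        means = [props.loc[assignments == m, "t"].mean() for m in mods]
        assert out.loc["t", "intra"] == pytest.approx(np.mean(sds))
        assert out.loc["t", "inter"] == pytest.approx(np.std(means))

    def test_module0_excluded(self):
        idx = pd.Index(range(5))
        assignments = pd.Series(["M1", "M1", "M1", "M1", MODULE0], index=idx)
        props = pd.DataFrame({"t": [0.5, 0.5, 0.5, 0.5, 99.0]}, index=idx)
        out = mem_variation(assignments, props)
        assert out.loc["t", "intra"] == pytest.approx(0.0)


class TestPlantedColocalizationRecovery:
    def test_two_regime_mem_recovery_and_moran(self):
        cc = CohortConfig(
            n_samples=4, size_um=2000, region_um=500, seed=5,
            region_clusters={"reg1": ["A", "B"], "reg2": ["C", "D"]},
            archetypes={"E": {"reg1": 0.5, "reg2": 0.5}},
            cells_per_cluster_per_region=25, blob_sigma_um=60)
        cohort = simulate_cohort(cc)
        mats, spot_matrices = [], {}
        for sid, ns in cohort.slides.items():
            sm = tessellate(ns, cohort.cluster_labels[sid], spot_um=200,
                            clusters=cohort.clusters)
            spot_matrices[sid] = sm
            mats.append(correlation_matrix(sm))
        mm = build_mem_model(mats, n_modules=2)
        got = [mm.module_of[c] for c in ["A", "B", "C", "D"]]
        want = [cohort.cluster_kind[c] for c in ["A", "B", "C", "D"]]
        assert adjusted_rand_score(
            pd.factorize(pd.Series(got))[0], pd.factorize(pd.Series(want))[0]) == 1.0
        # planted regions produce spatially organized module-score fields
        morans = []
        for sid, sm in spot_matrices.items():
            scored = score_spots(sm, mm)
            morans.append(module_morans_i(scored, mm).max())
        assert np.nanmax(morans) > 0.3
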
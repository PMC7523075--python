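"""Bray-Curtis, NMDS, PerMANOVA, and PVCA against independent oracles."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

import plantcompart as pc
from plantcompart.beta import DissimilarityMatrix, _pseudo_f


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        assert pc.bray_curtis([3, 1, 0], [3, 1, 0]) == 0.0

    def test_disjoint_supports_one(self):
        assert pc.bray_curtis([3, 0, 2], [0, 4, 0]) == 1.0

    def test_hand_value(self):
        assert pc.bray_curtis([3, 1, 0], [1, 1, 2]) == pytest.approx(0.5)

    def test_subsampled_mean_matches_enumeration(self):
        # exact E[BC] at depth 3 by enumerating hypergeometric draws from
        # two 2-OTU samples with counts (2,2) and (3,1)
        x, y, depth = np.array([2, 2]), np.array([3, 1]), 3

        def draw_probs(col):
            total = col.sum()
            out = {}
            for k in range(max(0, depth - col[1]), min(col[0], depth) + 1):
                p = (
                    math.comb(col[0], k)
                    * math.comb(col[1], depth - k)
                    / math.comb(total, depth)
                )
                out[(k, depth - k)] = p
            return out

        expected = sum(
            pa * pb * pc.bray_curtis(a, b)
            for a, pa in draw_probs(x).items()
            for b, pb in draw_probs(y).items()
        )
        t = pc.OtuTable(
            np.column_stack([x, y]), otu_ids=["o1", "o2"],
            sample_ids=["s1", "s2"],
        )
        d = pc.iterative_bray_curtis(t, depth=3, iterations=4000, seed=5)
        # MC standard error of a mean of 4000 bounded-by-1 draws is < 0.008
        assert d.values[0, 1] == pytest.approx(expected, abs=0.025)

    def test_too_few_samples_errors(self):
        t = pc.OtuTable(np.array([[5]]), otu_ids=["o"], sample_ids=["s"])
        with pytest.raises(ValueError):
            pc.iterative_bray_curtis(t, depth=2, iterations=2)


class TestDissimilarityMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(["a", "b"], np.array([[0, 0.2], [0.4, 0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DissimilarityMatrix(["a", "b"], np.array([[0.1, 0.2], [0.2, 0.1]]))

    def test_tsv_round_trip(self, sim_dissimilarity, tmp_path):
        path = tmp_path / "d.tsv"
        sim_dissimilarity.write_tsv(path)
        back = DissimilarityMatrix.read_tsv(path)
        np.testing.assert_allclose(back.values, sim_dissimilarity.values,
                                   atol=1e-9)

    def test_phylip_round_trip(self, sim_dissimilarity, tmp_path):
        path = tmp_path / "d.phylip"
        sim_dissimilarity.write_phylip(path)
        back = DissimilarityMatrix.read_phylip(path)
        np.testing.assert_allclose(back.values, sim_dissimilarity.values,
                                   atol=1e-5)


def _dm_from_points(points, scale=1.0):
    d = pdist(np.asarray(points, dtype=float)) * scale
    ids = [f"p{i}" for i in range(len(points))]
    return DissimilarityMatrix(ids, squareform(d))


class TestNmds:
    def test_collinear_points_embed_in_1d(self):
        d = _dm_from_points([[0], [1], [2], [4]], scale=0.25)
        res = pc.nmds(d, k=1, restarts=8, seed=0)
        assert res.stress < 1e-6

    def test_unit_square_embeds_in_2d(self):
        d = _dm_from_points([[0, 0], [1, 0], [1, 1], [0, 1]], scale=0.5)
        res = pc.nmds(d, k=2, restarts=8, seed=0)
        assert res.stress < 1e-6

    def test_stress_trace_non_increasing(self, sim_dissimilarity):
        res = pc.nmds(sim_dissimilarity, k=2, restarts=4, seed=1)
        trace = res.stress_trace
        assert np.all(np.diff(trace) <= 1e-12)

    def test_k_too_large_errors(self):
        d = _dm_from_points([[0], [1], [2]], scale=0.25)
        with pytest.raises(ValueError):
            pc.nmds(d, k=3)


class TestAxisRSquared:
    def test_perfect_1d_embedding(self):
        d = _dm_from_points([[0], [1], [2], [4]], scale=0.25)
        res = pc.nmds(d, k=1, restarts=8, seed=0)
        assert res.axis_r2[0] == pytest.approx(1.0, abs=1e-6)

    def test_constant_axis_zero_with_warning(self):
        d = _dm_from_points([[0], [1], [2], [4]], scale=0.25)
        res = pc.nmds(d, k=1, restarts=4, seed=0)
        res.coordinates.iloc[:, 0] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            out = pc.axis_r_squared(d, res)
        assert out[0] == 0.0

    def test_matches_bruteforce_correlation(self, sim_dissimilarity):
        res = pc.nmds(sim_dissimilarity, k=2, restarts=4, seed=2)
        diss = sim_dissimilarity.condensed()
        for a in range(2):
            axis = res.coordinates.iloc[:, a].to_numpy()
            dist_a = pdist(axis[:, None])
            r_oracle = np.corrcoef(diss, dist_a)[0, 1] ** 2
            assert res.axis_r2[a] == pytest.approx(r_oracle, rel=1e-9)


def _naive_pseudo_f(dmat, labels):
    """Anderson's pseudo-F with explicit loops (independent of _pseudo_f)."""
    n = len(labels)
    ss_total = sum(
        dmat[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
    ) / n
    groups = sorted(set(labels))
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            dmat[i, j] ** 2
            for i, j in itertools.combinations(idx, 2)
        ) / len(idx)
    a = len(groups)
    if ss_within == 0:
        return np.inf
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def _two_group_toy(self):
        # 4 samples, within-group d = 0.1, between-group d = 0.9
        m = np.full((4, 4), 0.9)
        m[0, 1] = m[1, 0] = m[2, 3] = m[3, 2] = 0.1
        np.fill_diagonal(m, 0.0)
        return DissimilarityMatrix(list("wxyz"), m)

    def test_hand_pseudo_f(self):
        d = self._two_group_toy()
        res = pc.permanova(d, ["A", "A", "B", "B"], permutations="exact")
        assert res.pseudo_F == pytest.approx(161.0)
        assert (res.df_num, res.df_den) == (1, 2)

    def test_exact_p_one_third(self):
        d = self._two_group_toy()
        res = pc.permanova(d, ["A", "A", "B", "B"], permutations="exact")
        assert res.p_value == pytest.approx(1 / 3)

    def test_exact_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(8, 3))
        d = DissimilarityMatrix(
            [f"s{i}" for i in range(8)],
            squareform(pdist(pts) / (pdist(pts).max() * 1.01)),
        )
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 2
        res = pc.permanova(d, labels, permutations="exact")
        f_obs = _naive_pseudo_f(d.values, labels)
        perms = set(itertools.permutations(labels))
        hits = sum(
            _naive_pseudo_f(d.values, list(p)) >= f_obs - 1e-12 for p in perms
        )
        assert res.pseudo_F == pytest.approx(f_obs, rel=1e-10)
        assert res.p_value == pytest.approx(hits / len(perms), abs=1e-12)

    def test_statistic_matches_skbio(self, sim_dissimilarity, sim_table):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as skbio_permanova

        design = sim_table.design().loc[sim_dissimilarity.sample_ids]
        dm = skbio.DistanceMatrix(sim_dissimilarity.values,
                                  ids=sim_dissimilarity.sample_ids)
        theirs = skbio_permanova(dm, design["compartment"].to_numpy(),
                                 permutations=0)
        ours = pc.permanova(sim_dissimilarity, design["compartment"],
                            permutations=9, seed=0)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"],
                                              rel=1e-9)

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(40):
            pts = rng.normal(size=(10, 2))
            dd = pdist(pts)
            d = DissimilarityMatrix(
                [f"s{i}" for i in range(10)],
                squareform(dd / (dd.max() * 1.01)),
            )
            labels = rng.permutation(["A"] * 5 + ["B"] * 5)
            pvals.append(
                pc.permanova(d, labels, permutations=79,
                             seed=int(rng.integers(2**31))).p_value
            )
        # under the null, p < 0.25 for about a quarter of runs
        frac = np.mean(np.asarray(pvals) < 0.25)
        assert 0.05 < frac < 0.55

    def test_single_group_errors(self):
        d = self._two_group_toy()
        with pytest.raises(ValueError):
            pc.permanova(d, ["A"] * 4)


class TestAxisScoreTest:
    def test_shifted_groups_detected(self):
        d = _dm_from_points(np.linspace(0, 1, 12)[:, None], scale=0.9)
        res = pc.nmds(d, k=1, restarts=4, seed=0)
        scores = res.coordinates.iloc[:, 0].to_numpy()
        group = np.where(scores > np.median(scores), "hi", "lo")
        tab = pc.axis_score_test(res, 1, group)
        assert tab.loc["group", "p"] <= 0.001

    def test_axis_out_of_range_errors(self):
        d = _dm_from_points([[0], [1], [2], [4]], scale=0.25)
        res = pc.nmds(d, k=1, restarts=2, seed=0)
        with pytest.raises(ValueError):
            pc.axis_score_test(res, 2, ["a", "a", "b", "b"])


class TestPvca:
    def _design(self, sim_table):
        return sim_table.design()

    def test_sums_to_100(self, sim_dissimilarity, sim_table):
        design = self._design(sim_table).loc[sim_dissimilarity.sample_ids]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comps = pc.pvca(sim_dissimilarity, design, n_axes=3, seed=0,
                            restarts=2)
        assert comps.sum() == pytest.approx(100.0, abs=1e-6)
        assert (comps >= 0).all()

    def test_recovers_injected_compartment_effect(self, sim_table):
        design = self._design(sim_table)
        rng = np.random.default_rng(12)
        comp_means = design["compartment"].map(
            {"rhizosphere": 0.0, "root": 3.0, "nodule": 6.0, "leaf": 9.0}
        ).to_numpy()
        scores = pd.DataFrame(
            {
                "axis1": comp_means + rng.normal(0, 0.05, len(design)),
                "axis2": rng.normal(0, 1, len(design)),
                "axis3": rng.normal(0, 1, len(design)),
            },
            index=design.index,
        )
        comps = pc.pvca_from_scores(scores, [0.8, 0.15, 0.05], design)
        assert comps.sum() == pytest.approx(100.0, abs=1e-6)
        assert comps["compartment"] == comps.drop("residual").max()
        assert comps["compartment"] + comps["residual"] > 75

    def test_pure_noise_mostly_residual(self, sim_table):
        # on i.i.d. noise axes the residual component should dominate
        # (expectation ~92%); the mean over 10 replicate fits bounds MC error
        design = self._design(sim_table)
        rng = np.random.default_rng(3)
        residuals = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(10):
                scores = pd.DataFrame(
                    rng.normal(size=(len(design), 2)),
                    index=design.index, columns=["axis1", "axis2"],
                )
                comps = pc.pvca_from_scores(scores, [0.6, 0.4], design)
                residuals.append(comps["residual"])
        assert np.mean(residuals) > 85

    def test_reml_matches_lme4_oracle(self, sim_table):
        # percent components for one fixed noise draw, computed independently
        # with lme4 (REML) on the identical design and response
        from plantcompart.beta import PVCA_TERMS, _axis_variance_components

        design = sim_table.design()
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(design))
        comps = _axis_variance_components(y, design, PVCA_TERMS)
        pct = 100 * comps / comps.sum()
        expected = {
            "soil_origin": 4.489,
            "genotype": 0.0,
            "compartment": 0.0,
            "soil_origin:genotype": 0.0,
            "soil_origin:compartment": 0.0,
            "genotype:compartment": 2.075,
            "soil_origin:genotype:compartment": 25.982,
            "residual": 67.455,
        }
        for term, value in expected.items():
            assert pct[term] == pytest.approx(value, abs=0.05)
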
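"""Raup-Crick null model, Fisher comparisons, and co-occurrence metrics,
validated against exhaustive enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import plantcompart as pc
from plantcompart.assembly import _null_sim2, _null_sim4, _null_sim6


def _subset_probs(weights, richness):
    """Probability of each unordered subset under successive weighted draws
    without replacement (sums over all orderings)."""
    n = len(weights)
    out = {}
    for subset in itertools.combinations(range(n), richness):
        p = 0.0
        for order in itertools.permutations(subset):
            prob, remaining = 1.0, sum(weights)
            for idx in order:
                prob *= weights[idx] / remaining
                remaining -= weights[idx]
            p += prob
        out[frozenset(subset)] = p
    return out


def _beta_rc_exact(weights, sample_a, sample_b):
    """Exact beta_RC by enumerating both samples' null assemblages."""
    pa = _subset_probs(weights, len(sample_a))
    pb = _subset_probs(weights, len(sample_b))
    observed = len(set(sample_a) & set(sample_b))
    greater = ties = 0.0
    for sa, p1 in pa.items():
        for sb, p2 in pb.items():
            shared = len(sa & sb)
            if shared > observed:
                greater += p1 * p2
            elif shared == observed:
                ties += p1 * p2
    return 2 * (greater + 0.5 * ties) - 1


def _table_from_presence(presence, sample_names):
    return pc.OtuTable(
        np.asarray(presence, dtype=int),
        otu_ids=[f"o{i}" for i in range(len(presence))],
        sample_ids=sample_names,
    )


class TestRaupCrick:
    def test_two_species_hand_enumeration(self):
        # both samples = {species 0}, equal occurrence weights: the four
        # equally likely null outcomes give P(shared=1) = 1/2, so
        # percentile = 0 + 0.5*0.5 and beta_RC = -0.5
        # two balancing samples make both species' occurrence frequency 1/2
        counts = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        t = _table_from_presence(counts, ["s1", "s2", "s3", "s4"])
        res = pc.raup_crick(t, [("s1", "s2")], replicates=60_000, seed=0)
        assert res["beta_rc"].iloc[0] == pytest.approx(-0.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration(self, seed):
        # pools of <= 6 species, richness <= 3: Monte-Carlo at 1e5 replicates
        # should sit within 0.02 of the exact enumeration value
        rng = np.random.default_rng(seed)
        n_species, n_samples = 6, 5
        presence = (rng.random((n_species, n_samples)) < 0.5)
        # cap richness at 3 and forbid empty samples
        for j in range(n_samples):
            on = np.where(presence[:, j])[0]
            if len(on) > 3:
                presence[on[3:], j] = False
            if presence[:, j].sum() == 0:
                presence[rng.integers(n_species), j] = True
        t = _table_from_presence(presence, [f"s{i}" for i in range(n_samples)])
        res = pc.raup_crick(t, [("s0", "s1")], replicates=100_000, seed=seed)
        freq = presence.sum(axis=1)
        pool = np.where(freq > 0)[0]
        remap = {s: i for i, s in enumerate(pool)}
        weights = freq[pool].astype(float)
        sa = [remap[i] for i in np.where(presence[:, 0])[0]]
        sb = [remap[i] for i in np.where(presence[:, 1])[0]]
        exact = _beta_rc_exact(weights, sa, sb)
        assert res["beta_rc"].iloc[0] == pytest.approx(exact, abs=0.02)

    def test_bounded_and_classified(self, sim_table):
        design = sim_table.design()
        nod = design.index[design["compartment"] == "nodule"][:4]
        root = design.index[design["compartment"] == "root"][:4]
        pairs = list(zip(root, nod))
        res = pc.raup_crick(sim_table, pairs, replicates=200, seed=1)
        assert res["beta_rc"].between(-1, 1).all()
        assert (
            res["significant"] == (res["beta_rc"].abs() > 0.95)
        ).all()

    def test_empty_sample_errors(self):
        counts = np.array([[1, 0], [1, 0]])
        t = _table_from_presence(counts, ["s1", "s2"])
        with pytest.raises(ValueError, match="empty"):
            pc.raup_crick(t, [("s1", "s2")], replicates=10,
                          reference_samples=["s1"])


class TestFisherExact:
    def test_uniform_table(self):
        assert pc.fisher_exact([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_diagonal_two(self):
        # margins (2,2)x(2,2): tables with a=0,1,2 have probs 1/6, 4/6, 1/6
        assert pc.fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)

    def test_paper_style_rates_table(self):
        # 21/30 vs 8/30 significant pairs
        assert pc.fisher_exact([[21, 9], [8, 22]]) == pytest.approx(
            0.0017, abs=2e-4
        )

    def test_symmetry_under_swaps(self):
        t = np.array([[5, 2], [1, 7]])
        p = pc.fisher_exact(t)
        assert pc.fisher_exact(t[::-1]) == pytest.approx(p)
        assert pc.fisher_exact(t[:, ::-1]) == pytest.approx(p)
        assert pc.fisher_exact(t.T) == pytest.approx(p)

    def test_negative_entry_errors(self):
        with pytest.raises(ValueError):
            pc.fisher_exact([[1, -1], [1, 1]])

    def test_all_small_tables_match_enumeration(self):
        # every 2x2 table with total <= 12 vs the hypergeometric
        # point-probability oracle
        def oracle(t):
            r0, r1 = t[0][0] + t[0][1], t[1][0] + t[1][1]
            c0 = t[0][0] + t[1][0]
            n = r0 + r1
            def prob(a):
                return (
                    math.comb(r0, a) * math.comb(r1, c0 - a) / math.comb(n, c0)
                )
            p_obs = prob(t[0][0])
            return sum(
                prob(a)
                for a in range(max(0, c0 - r1), min(r0, c0) + 1)
                if prob(a) <= p_obs * (1 + 1e-9)
            )

        checked = 0
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if not 0 < a + b + c + d <= 12:
                continue
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            t = [[a, b], [c, d]]
            assert pc.fisher_exact(t) == pytest.approx(oracle(t), abs=1e-9)
            checked += 1
        assert checked > 200


class TestDeterministicAssemblyRates:
    def _results(self, flags):
        return pd.DataFrame({"significant": flags})

    def test_extreme_rates(self):
        a = self._results([True] * 10)
        b = self._results([False] * 10)
        ra, rb, p = pc.deterministic_assembly_rates(a, b)
        assert (ra, rb) == (1.0, 0.0)
        assert p == pc.fisher_exact([[10, 0], [0, 10]])

    def test_identical_rates_p_one(self):
        a = self._results([True, False] * 5)
        ra, rb, p = pc.deterministic_assembly_rates(a, a)
        assert ra == rb
        assert p == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pc.deterministic_assembly_rates(self._results([]), self._results([True]))


class TestComboMetric:
    def test_all_identical_columns(self):
        assert pc.combo_metric(np.ones((3, 5), dtype=bool)) == 1

    def test_hand_example(self):
        cols = np.array([[1, 0, 1], [0, 1, 0]])
        assert pc.combo_metric(cols) == 2

    def test_all_distinct(self):
        m = np.triu(np.ones((4, 4), dtype=bool))
        assert pc.combo_metric(m) == 4


class TestCooccurrenceNulls:
    def _presence(self, seed=0, shape=(8, 10), fill=0.4):
        rng = np.random.default_rng(seed)
        m = rng.random(shape) < fill
        m[:, m.sum(axis=0) == 0] = True
        return m

    def test_sim6_preserves_total_fill(self):
        m = self._presence()
        rng = np.random.default_rng(1)
        w = m.sum(axis=0).astype(float)
        for _ in range(20):
            null = _null_sim6(rng, m.shape, int(m.sum()), w)
            assert null.sum() == m.sum()

    def test_sim2_preserves_row_totals(self):
        m = self._presence()
        rng = np.random.default_rng(1)
        for _ in range(20):
            null = _null_sim2(rng, m)
            np.testing.assert_array_equal(null.sum(axis=1), m.sum(axis=1))

    def test_sim4_preserves_row_totals(self):
        m = self._presence()
        rng = np.random.default_rng(1)
        w = m.sum(axis=0).astype(float)
        for _ in range(20):
            null = _null_sim4(rng, m, w)
            np.testing.assert_array_equal(null.sum(axis=1), m.sum(axis=1))

    def test_self_consistency_z_near_zero(self):
        # a matrix drawn from the sim6 null itself should not look unusual
        rng = np.random.default_rng(5)
        base = self._presence(seed=5, shape=(6, 8), fill=0.5)
        w = base.sum(axis=0).astype(float)
        zs = []
        for i in range(12):
            drawn = _null_sim6(rng, base.shape, int(base.sum()), w)
            t = _table_from_presence(drawn, [f"s{j}" for j in range(8)])
            try:
                res = pc.cooccurrence_ses(t, iterations=400, seed=100 + i)
            except ValueError:
                continue  # a degenerate draw; skip
            zs.append(res["z_score"])
        assert len(zs) >= 6
        assert np.mean(np.abs(zs) < 2) >= 0.75

    def test_degenerate_null_errors(self):
        # 2 OTUs x 2 samples, fully filled: every sim6 null is identical
        t = _table_from_presence(np.ones((2, 2), dtype=int), ["s1", "s2"])
        with pytest.raises(ValueError, match="degenerate"):
            pc.cooccurrence_ses(t, iterations=50, seed=0)

    def test_unknown_algorithm_errors(self, sim_table):
        nod = sim_table.select_compartment("nodule")
        with pytest.raises(ValueError, match="algorithm"):
            pc.cooccurrence_ses(nod, algorithm="sim9", iterations=5, seed=0)
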
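import numpy as np
import pandas as pd
import pytest

import commresist as cr
from commresist.indices import _selection_weights
from conftest import random_count_table, random_std_env


class TestSelectCumulative:
    def test_exact_level_boundary(self):
        a = np.array([0.5, 0.3, 0.15, 0.05])
        assert cr.select_cumulative(a, 0.80).tolist() == [0, 1]

    def test_next_level_adds_one(self):
        a = np.array([0.5, 0.3, 0.15, 0.05])
        assert cr.select_cumulative(a, 0.85).tolist() == [0, 1, 2]

    def test_level_one_selects_all_present(self):
        a = np.array([0.5, 0.3, 0.0, 0.2])
        assert cr.select_cumulative(a, 1.0).tolist() == [0, 1, 3]

    def test_ties_broken_by_position(self):
        a = np.array([0.25, 0.25, 0.25, 0.25])
        assert cr.select_cumulative(a, 0.5).tolist() == [0, 1]

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="empty sample"):
            cr.select_cumulative(np.zeros(3), 0.8)


class TestSelectRandom:
    def test_forced_full_draw(self):
        a = np.array([0.2, 0.0, 0.5, 0.3])
        sels = cr.select_random(a, 3, 4, np.random.default_rng(0))
        for sel in sels:
            assert sel.tolist() == [0, 2, 3]

    def test_uniform_selection_frequencies(self):
        """n=1 draws hit each present OTU at the uniform rate (binomial 3-sigma)."""
        a = np.array([0.1, 0.2, 0.3, 0.4])
        reps = 4000
        sels = cr.select_random(a, 1, reps, np.random.default_rng(1))
        freq = np.bincount([s[0] for s in sels], minlength=4) / reps
        se = np.sqrt(0.25 * 0.75 / reps)
        assert np.all(np.abs(freq - 0.25) < 3 * se)

    def test_deterministic_under_seed(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        s1 = cr.select_random(a, 2, 5, np.random.default_rng(9))
        s2 = cr.select_random(a, 2, 5, np.random.default_rng(9))
        assert all((x == y).all() for x, y in zip(s1, s2))

    def test_richness_below_n_excluded(self):
        assert cr.select_random(np.array([0.5, 0.5, 0.0]), 3, 1,
                                np.random.default_rng(0)) is None


class TestCmtb:
    def _tb(self, values):
        ids = tuple(f"O{i}" for i in range(len(values)))
        return cr.ToleranceBreadths(ids, np.asarray(values, float),
                                    np.full(len(values), 2))

    def test_single_otu_returns_its_tb(self):
        tb = self._tb([2.5, 1.0])
        assert cr.cmtb(np.array([0.4, 0.0]), tb) == pytest.approx(2.5)

    def test_equal_weights_arithmetic_mean(self):
        tb = self._tb([2.0, 1.0, 3.0])
        assert cr.cmtb(np.array([0.2, 0.2, 0.2]), tb) == pytest.approx(2.0)

    def test_weighted_mean(self):
        tb = self._tb([2.0, 1.0])
        assert cr.cmtb(np.array([0.6, 0.4]), tb) == pytest.approx(1.6)

    def test_selection_renormalization_is_noop(self):
        tb = self._tb([2.0, 1.0, 5.0])
        a = np.array([0.6, 0.3, 0.1])
        selected = ["O0", "O1"]
        raw = cr.cmtb(a, tb, selected=selected)
        renorm = cr.cmtb(np.array([0.6, 0.3, 0.0]) / 0.9, tb, selected=selected)
        assert raw == pytest.approx(renorm)

    def test_empty_selection_errors(self):
        with pytest.raises(ValueError, match="empty selection"):
            cr.cmtb(np.zeros(2), self._tb([1.0, 2.0]))

    def test_bounded_by_selected_tb_range(self):
        rng = np.random.default_rng(31)
        tb = self._tb(rng.uniform(0, 5, size=10))
        a = rng.dirichlet(np.ones(10))
        val = cr.cmtb(a, tb)
        assert tb.tb.min() <= val <= tb.tb.max()


class TestResistancePotential:
    @pytest.mark.parametrize(
        "c,r,expected", [(0, 0, 0.0), (1, 1, np.sqrt(2)), (0.6, 0.8, 1.0)]
    )
    def test_known_values(self, c, r, expected):
        assert cr.resistance_potential(c, r) == pytest.approx(expected)

    def test_inputs_outside_unit_interval_rejected(self):
        for c, r in ((1.2, 0.5), (0.5, -0.1)):
            with pytest.raises(ValueError):
                cr.resistance_potential(c, r)


class TestComputeIndices:
    def _small(self):
        rng = np.random.default_rng(33)
        counts = random_count_table(rng, 20, 10)
        env = random_std_env(rng, 10, 3)
        return counts, env

    def test_matches_hand_chained_calls(self):
        counts, env = self._small()
        tb = cr.tolerance_breadth_all(counts, env)
        rel = cr.to_relative_abundance(counts)
        ra = cr.spearman_matrix(rel)
        out = cr.compute_indices(
            counts, env, cr.SelectionScheme.cumulative((1.0,)), tb=tb, ra=ra
        )
        for s, sid in enumerate(counts.sample_ids):
            a = rel.values[:, s]
            row = out[out.sample_id == sid].iloc[0]
            assert row.cmtb == pytest.approx(cr.cmtb(a, tb))
            assert row.cmra == pytest.approx(cr.cmra(a, ra))

    def test_level_one_equals_no_selection(self):
        counts, env = self._small()
        tb = cr.tolerance_breadth_all(counts, env)
        rel = cr.to_relative_abundance(counts)
        ra = cr.spearman_matrix(rel)
        w = np.array([_selection_weights(rel.values,
                                         cr.SelectionScheme.cumulative((1.0,)),
                                         1.0, s)[0]
                      for s in range(counts.n_samples)])
        np.testing.assert_allclose(w, rel.values.T)
        out = cr.compute_indices(counts, env,
                                 cr.SelectionScheme.cumulative((1.0,)), tb=tb, ra=ra)
        full_cmtb = rel.values.T @ tb.tb
        np.testing.assert_allclose(np.sort(out.cmtb), np.sort(full_cmtb))

    def test_standardized_indexes_attain_zero_and_one(self):
        counts, env = self._small()
        out = cr.compute_indices(counts, env, cr.SelectionScheme.cumulative((0.9,)))
        assert out.cmtb_stand.min() == 0 and out.cmtb_stand.max() == 1
        assert out.cmra_stand.min() == 0 and out.cmra_stand.max() == 1
        assert (out.resistance_potential <= np.sqrt(2) + 1e-12).all()
        np.testing.assert_allclose(
            out.resistance_potential,
            np.sqrt(out.cmtb_stand**2 + out.cmra_stand**2),
        )

    def test_degenerate_minmax_names_index(self):
        counts = cr.CountTable(
            ("O0", "O1"), ("S0", "S1", "S2"),
            np.array([[2, 2, 2], [2, 2, 2]]),
        )
        env = random_std_env(np.random.default_rng(34), 3, 2)
        with pytest.raises(ValueError, match="CMTB"):
            cr.compute_indices(counts, env, cr.SelectionScheme.cumulative((1.0,)))

    def test_replicate_mean_consistent_with_many_replicates(self, default_sim,
                                                            default_tb, default_ra):
        """100-replicate CMTB mean sits within 2 SE of a 10,000-replicate mean."""
        rel = cr.to_relative_abundance(default_sim.counts)
        s = 0
        a = rel.values[:, s]
        rng_small = np.random.default_rng(101)
        rng_big = np.random.default_rng(202)
        small = [cr.cmtb(self._mask(a, sel), default_tb)
                 for sel in self._draws(a, 300, 100, rng_small)]
        big = [cr.cmtb(self._mask(a, sel), default_tb)
               for sel in self._draws(a, 300, 10_000, rng_big)]
        small, big = np.array(small), np.array(big)
        se = small.std(ddof=1) / np.sqrt(len(small))
        assert abs(small.mean() - big.mean()) < 2 * se

    @staticmethod
    def _draws(a, n, reps, rng):
        return cr.select_random(a, n, reps, rng)

    @staticmethod
    def _mask(a, sel):
        out = np.zeros_like(a)
        out[sel] = a[sel]
        return out

    def test_random_scheme_deterministic_under_seed(self):
        counts, env = self._small()
        sch = cr.SelectionScheme.random((5,), replicates=10, seed=3)
        out1 = cr.compute_indices(counts, env, sch)
        out2 = cr.compute_indices(counts, env, sch)
        pd.testing.assert_frame_equal(out1, out2)


class TestMethodIndependence:
    def _indices(self):
        rows = []
        rng = np.random.default_rng(40)
        base = rng.normal(size=30)
        for level in (0.8, 0.9):
            noise = rng.normal(scale=0.05, size=30)
            for k in range(30):
                rows.append({"sample_id": f"S{k}", "scheme": "cumulative_abundance",
                             "level": level, "cmtb": base[k] + noise[k],
                             "cmra": -base[k] + noise[k]})
        return pd.DataFrame(rows)

    def test_self_comparison_is_unity(self):
        df = self._indices()
        dup = pd.concat([df[df.level == 0.8],
                         df[df.level == 0.8].assign(level=0.85)])
        out = cr.method_independence(dup, "cmtb")
        assert out.r.iloc[0] == pytest.approx(1.0)

    def test_invariant_to_common_sample_relabelling(self):
        df = self._indices()
        r1 = cr.method_independence(df, "cmtb").r.iloc[0]
        perm = {f"S{k}": f"T{(k * 7) % 30}" for k in range(30)}
        df2 = df.assign(sample_id=df.sample_id.map(perm))
        r2 = cr.method_independence(df2, "cmtb").r.iloc[0]
        assert r1 == pytest.approx(r2)

    def test_insufficient_overlap_reported_missing(self):
        df = self._indices()
        a = df[df.level == 0.8].iloc[:2]
        b = df[df.level == 0.9].iloc[:2]
        out = cr.method_independence(pd.concat([a, b]), "cmtb")
        assert np.isnan(out.r.iloc[0]) and out.n.iloc[0] == 2
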
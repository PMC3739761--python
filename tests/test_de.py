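"""Fold change, t-test, DE calling, Venn partitioning, top-fraction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import sciseq
from sciseq.containers import ValidationError
from sciseq.de import bh_adjust
from sciseq.simulate import SimulationConfig, simulate_study
from .conftest import make_study


def _study(ctr, d2):
    return make_study(
        values={
            **{f"c{i+1}": col for i, col in enumerate(np.asarray(ctr).T)},
            **{f"t{i+1}": col for i, col in enumerate(np.asarray(d2).T)},
        },
        stages={
            **{f"c{i+1}": "CTR" for i in range(np.asarray(ctr).shape[1])},
            **{f"t{i+1}": "D2" for i in range(np.asarray(d2).shape[1])},
        },
    )


class TestFoldChange:
    def test_simple_arithmetic(self):
        s = _study([[0.1, 0.1, 0.1]], [[0.4, 0.4, 0.4]])
        fc = sciseq.fold_change(s, ("D2", "CTR"))
        assert fc.loc["g1", "fold_change"] == pytest.approx(4.0)
        assert fc.loc["g1", "log2_fc"] == pytest.approx(2.0)

    def test_identical_stages_give_unity(self, two_stage_study):
        fc = sciseq.fold_change(two_stage_study, ("CTR", "CTR"))
        assert np.allclose(fc["fold_change"], 1.0)

    def test_floor_prevents_ratio_inflation(self):
        # raw 0.05 vs 0.4 floored at 0.1 -> FC 0.25, not 0.125
        s = _study([[0.4, 0.4]], [[0.05, 0.05]])
        floored = sciseq.floor_fpkm(s, 0.1)
        fc = sciseq.fold_change(floored, ("D2", "CTR"))
        assert fc.loc["g1", "fold_change"] == pytest.approx(0.25)

    def test_missing_stage_errors(self, two_stage_study):
        with pytest.raises(KeyError):
            sciseq.fold_change(two_stage_study, ("D7", "CTR"))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_reciprocal_contrasts_multiply_to_one(self, seed):
        rng = np.random.default_rng(seed)
        s = _study(rng.lognormal(1, 1, (8, 3)), rng.lognormal(1, 1, (8, 3)))
        a = sciseq.fold_change(s, ("D2", "CTR"))["fold_change"]
        b = sciseq.fold_change(s, ("CTR", "D2"))["fold_change"]
        assert np.allclose(a * b, 1.0, atol=1e-9)


class TestTTest:
    def test_identical_groups_give_p_one(self):
        s = _study([[1, 2, 3]], [[1, 2, 3]])
        p = sciseq.t_test(s, ("D2", "CTR"))
        assert p.iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_pooled_t(self):
        # groups (1,2,3) vs (2,3,4): t = -1.2247, df = 4, p ~ 0.2879
        s = _study([[2, 3, 4]], [[1, 2, 3]])
        p = sciseq.t_test(s, ("D2", "CTR"))
        t_expected = -1.0 / math.sqrt(1.0 * (1 / 3 + 1 / 3))
        p_expected = 2 * stats.t.sf(abs(t_expected), 4)
        assert t_expected == pytest.approx(-1.2247, abs=1e-4)
        assert p.iloc[0] == pytest.approx(p_expected, abs=1e-12)
        assert p.iloc[0] == pytest.approx(0.2879, abs=1e-4)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        a = rng.lognormal(0, 1, (50, 3))
        b = rng.lognormal(0, 1, (50, 3))
        s = _study(a, b)
        p = sciseq.t_test(s, ("D2", "CTR"))
        ref = stats.ttest_ind(b, a, axis=1, equal_var=True).pvalue
        assert np.allclose(p, ref, atol=1e-12)

    def test_zero_variance_degenerate_paths(self):
        s_eq = _study([[1.0, 1.0]], [[1.0, 1.0]])
        assert sciseq.t_test(s_eq, ("D2", "CTR")).iloc[0] == 1.0
        s_ne = _study([[1.0, 1.0]], [[2.0, 2.0]])
        with pytest.warns(UserWarning, match="zero variance"):
            assert sciseq.t_test(s_ne, ("D2", "CTR")).iloc[0] == 0.0

    def test_single_replicate_errors(self):
        s_single = make_study(
            values={"c1": [1.0], "t1": [2.0]},
            stages={"c1": "CTR", "t1": "D2"},
        )
        with pytest.raises(ValidationError):
            sciseq.t_test(s_single, ("D2", "CTR"))


class TestCallDe:
    def test_significance_rule(self):
        # strong fold change with tight replicates -> significant, up
        s = _study([[1.0, 1.1, 0.9]], [[4.0, 4.4, 3.6]])
        de = sciseq.call_de(s, ("D2", "CTR"))
        assert bool(de.loc["g1", "is_significant"])
        assert de.loc["g1", "direction"] == "up"

    def test_high_p_blocks_significance(self):
        # same mean fold change but replicates too noisy
        s = _study([[1.0, 1.0, 1.0]], [[0.2, 2.0, 9.8]])
        de = sciseq.call_de(s, ("D2", "CTR"))
        assert de.loc["g1", "fold_change"] > 2
        assert not bool(de.loc["g1", "is_significant"])

    def test_monotone_in_cutoffs(self):
        study, _ = simulate_study(SimulationConfig(n_genes=300, seed=5))
        floored = sciseq.floor_fpkm(study, 0.1)
        base = sciseq.call_de(floored, ("D2", "CTR"), fc_cutoff=2, p_cutoff=0.05)
        stricter_fc = sciseq.call_de(floored, ("D2", "CTR"), fc_cutoff=4, p_cutoff=0.05)
        stricter_p = sciseq.call_de(floored, ("D2", "CTR"), fc_cutoff=2, p_cutoff=0.01)
        b = set(base.index[base["is_significant"]])
        assert set(stricter_fc.index[stricter_fc["is_significant"]]) <= b
        assert set(stricter_p.index[stricter_p["is_significant"]]) <= b

    def test_bh_preserves_p_ordering(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestVenn:
    @staticmethod
    def _de_table(genes, up, down):
        df = pd.DataFrame(index=pd.Index(genes, name="gene"))
        df["direction"] = ["up" if g in up else "down" if g in down else "flat"
                           for g in genes]
        df["is_significant"] = [g in up or g in down for g in genes]
        return df

    def test_simple_set_algebra(self):
        genes = ["g1", "g2", "g3", "g4"]
        a = self._de_table(genes, up={"g1", "g2"}, down=set())
        b = self._de_table(genes, up={"g2", "g3"}, down=set())
        v = sciseq.venn_partition(a, b)
        assert v.shared_up == {"g2"}
        assert v.counts["up_union"] == 3
        assert v.counts["up_a"] + v.counts["up_b"] - v.counts["up_shared"] == 3

    def test_disjoint_sets(self):
        genes = ["g1", "g2"]
        a = self._de_table(genes, up={"g1"}, down=set())
        b = self._de_table(genes, up=set(), down={"g2"})
        v = sciseq.venn_partition(a, b)
        assert v.shared_up == set() and v.shared_down == set()

    def test_universe_mismatch_errors(self):
        a = self._de_table(["g1"], up=set(), down=set())
        b = self._de_table(["g2"], up=set(), down=set())
        with pytest.raises(ValidationError):
            sciseq.venn_partition(a, b)

    def test_counts_match_brute_force_on_random_tables(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(500)]
        for _ in range(20):
            lab_a = rng.choice(["up", "down", "flat"], 500, p=[0.2, 0.2, 0.6])
            lab_b = rng.choice(["up", "down", "flat"], 500, p=[0.2, 0.2, 0.6])
            a = self._de_table(
                genes,
                up={g for g, l in zip(genes, lab_a) if l == "up"},
                down={g for g, l in zip(genes, lab_a) if l == "down"},
            )
            b = self._de_table(
                genes,
                up={g for g, l in zip(genes, lab_b) if l == "up"},
                down={g for g, l in zip(genes, lab_b) if l == "down"},
            )
            v = sciseq.venn_partition(a, b)
            # brute force with plain loops
            for direction, la, lb in (("up", lab_a, lab_b), ("down", lab_a, lab_b)):
                sa = {g for g, l in zip(genes, la) if l == direction}
                sb = {g for g, l in zip(genes, lb) if l == direction}
                shared = sum(1 for g in genes if g in sa and g in sb)
                assert v.counts[f"{direction}_shared"] == shared
                assert v.counts[f"{direction}_union"] == len(sa) + len(sb) - shared


class TestTopFraction:
    @staticmethod
    def _random_de(rng, n):
        genes = [f"g{i:03d}" for i in range(n)]
        lfc = rng.normal(0, 2, n)
        sig = rng.random(n) < 0.5
        return pd.DataFrame(
            {
                "log2_fc": lfc,
                "fold_change": 2.0**lfc,
                "is_significant": sig,
                "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "flat")),
            },
            index=pd.Index(genes, name="gene"),
        )

    def test_fraction_of_twenty(self):
        rng = np.random.default_rng(0)
        de = self._random_de(rng, 200)
        up_sig = de[(de["is_significant"]) & (de["direction"] == "up")]
        top = sciseq.select_top_fraction(de, 0.1)
        assert len(top["up"]) == math.ceil(0.1 * len(up_sig))
        expected = set(up_sig.sort_values("log2_fc", ascending=False)
                       .index[: len(top["up"])])
        assert set(top["up"]) == expected

    def test_fraction_one_returns_all_significant(self):
        rng = np.random.default_rng(1)
        de = self._random_de(rng, 100)
        top = sciseq.select_top_fraction(de, 1.0)
        for direction in ("up", "down"):
            n = ((de["is_significant"]) & (de["direction"] == direction)).sum()
            assert len(top[direction]) == n

    def test_matches_brute_force_sort_and_slice(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            de = self._random_de(rng, int(rng.integers(10, 80)))
            frac = float(rng.uniform(0.05, 1.0))
            top = sciseq.select_top_fraction(de, frac)
            for direction, reverse in (("up", True), ("down", False)):
                rows = [
                    (float(r["log2_fc"]), g)
                    for g, r in de.iterrows()
                    if r["is_significant"] and r["direction"] == direction
                ]
                rows.sort(key=lambda x: (-x[0] if reverse else x[0], x[1]))
                n = math.ceil(frac * len(rows)) if rows else 0
                assert top[direction] == [g for _, g in rows[:n]]


def test_type_one_error_near_nominal_under_null():
    """Raw-scale pooled t keeps its size under the log-normal null."""
    cfg = SimulationConfig(
        n_genes=10000, seed=11, fraction_up=0, fraction_down=0,
        fraction_silent=0, replicates=(3, 3, 3),
    )
    study, _ = simulate_study(cfg)
    p = sciseq.t_test(sciseq.floor_fpkm(study, 0.1), ("D2", "CTR"))
    assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)
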
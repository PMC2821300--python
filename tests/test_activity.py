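import itertools
import logging
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import mirshift as m
from mirshift.activity import format_gene_count_rows

from conftest import rank_sum_oracle


class TestWilcoxonShiftTest:
    def test_unique_minimum_rank_sum(self):
        # targets hold ranks {1,2}; one of C(6,2)=15 assignments is as low
        assert m.wilcoxon_shift_test([1, 2], [3, 4, 5, 6]) == pytest.approx(
            1 / 15, abs=1e-15
        )

    def test_maximal_target_rank_gives_p_one(self):
        assert m.wilcoxon_shift_test([6], [1, 2, 3]) == 1.0

    def test_all_identical_values_degenerate(self, caplog):
        with caplog.at_level(logging.WARNING):
            p = m.wilcoxon_shift_test([2.0] * 3, [2.0] * 3)
        assert p == 1.0
        assert any("identical" in r.message for r in caplog.records)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            m.wilcoxon_shift_test([], [1.0])
        with pytest.raises(ValueError):
            m.wilcoxon_shift_test([1.0], [])

    def test_greater_alternative_mirrors_less(self):
        p_less = m.wilcoxon_shift_test([1, 2], [3, 4, 5, 6], alternative="less")
        p_greater = m.wilcoxon_shift_test([5, 6], [1, 2, 3, 4], alternative="greater")
        assert p_less == pytest.approx(p_greater, abs=1e-15)

    def test_exact_path_handles_cross_group_ties(self):
        p = m.wilcoxon_shift_test([1, 2, 2], [2, 3, 4])
        assert p == pytest.approx(rank_sum_oracle([1, 2, 2], [2, 3, 4]), abs=1e-12)

    @pytest.mark.parametrize("alternative", ["less", "greater"])
    def test_normal_approximation_matches_scipy(self, alternative):
        # Large-sample path: midranks, tie correction and continuity
        # correction agree with the reference asymptotic implementation.
        rng = np.random.default_rng(5)
        target = np.round(rng.normal(0, 1, 30), 1)
        background = np.round(rng.normal(0.3, 1, 60), 1)
        ours = m.wilcoxon_shift_test(target, background, alternative=alternative)
        ref = stats.mannwhitneyu(
            target, background, alternative=alternative,
            method="asymptotic", use_continuity=True,
        ).pvalue
        assert ours == pytest.approx(ref, rel=1e-10)

    @given(
        scale=st.sampled_from([1000.0, 0.001]),
        shift=st.floats(min_value=-5, max_value=5),
    )
    def test_rank_invariance_affine(self, scale, shift):
        target = [0.5, 1.5, 4.0]
        background = [1.0, 2.0, 3.0, 6.0, 8.0]
        base = m.wilcoxon_shift_test(target, background)
        transformed = m.wilcoxon_shift_test(
            [v * scale + shift * scale for v in target],
            [v * scale + shift * scale for v in background],
        )
        assert transformed == pytest.approx(base, abs=1e-12)


def _toy_screen(n_background=17, n_targets=3):
    """20-gene toy: family m1's targets sit below every background gene."""
    values = {f"B{i}": 10.0 + i for i in range(n_background)}
    values.update({f"T{i}": float(i + 1) for i in range(n_targets)})
    table = m.GeneExpressionTable("toy", values)
    per_mirna = {
        "m1": frozenset(f"T{i}" for i in range(n_targets)),
        "m2": frozenset(list(values)[:5]),
    }
    universe = frozenset(values)
    return table, m.ExpressedTargetSets("toy", per_mirna, universe)


class TestTestAllMirnas:
    def test_min_targets_is_strict(self):
        values = {f"G{i}": float(i) + 1.0 for i in range(120)}
        table = m.GeneExpressionTable("d", values)
        genes = sorted(values)
        ets = m.ExpressedTargetSets(
            "d",
            {"fifty": frozenset(genes[:50]), "fiftyone": frozenset(genes[:51])},
            frozenset(genes),
        )
        results = m.test_all_mirnas(table, ets, min_targets=50)
        assert [r.family_id for r in results] == ["fiftyone"]
        assert results[0].n_targets == 51

    def test_planted_family_has_minimum_p(self):
        table, ets = _toy_screen()
        results = m.test_all_mirnas(table, ets, min_targets=1)
        by_family = {r.family_id: r for r in results}
        assert by_family["m1"].p_value == min(r.p_value for r in results)

    def test_fully_separated_targets_exact_p(self):
        # 12 pooled values: the exact path applies, and with every target
        # below every background gene the p is 1/C(12,3)
        table, ets = _toy_screen(n_background=9)
        results = m.test_all_mirnas(table, ets, min_targets=1)
        by_family = {r.family_id: r for r in results}
        assert by_family["m1"].p_value == pytest.approx(
            1 / math.comb(12, 3), abs=1e-12
        )

    def test_average_target_signal_and_ordering(self):
        table, ets = _toy_screen()
        results = m.test_all_mirnas(table, ets, min_targets=1)
        for r in results:
            expected = np.mean([table.values[g] for g in ets.per_mirna[r.family_id]])
            assert r.avg_target_signal == pytest.approx(expected)
        signals = [r.avg_target_signal for r in results]
        assert signals == sorted(signals)

    def test_inclusive_background_contains_targets(self):
        table, ets = _toy_screen()
        p_ex = m.test_all_mirnas(table, ets, 1, "exclusive")[0].p_value
        p_in = m.test_all_mirnas(table, ets, 1, "inclusive")[0].p_value
        assert p_in != p_ex  # overlapping background dilutes the shift

    def test_tiny_universe_rejected(self):
        table = m.GeneExpressionTable("d", {"A": 1.0})
        ets = m.ExpressedTargetSets("d", {"m": frozenset({"A"})}, frozenset({"A"}))
        with pytest.raises(ValueError, match="universe"):
            m.test_all_mirnas(table, ets, min_targets=0)


class TestControlProfile:
    def test_profile_shape_and_determinism(self):
        table, ets = _toy_screen()
        a = m.control_profile(table, ets, seed=9, min_targets=1)
        b = m.control_profile(table, ets, seed=9, min_targets=1)
        assert a == b
        assert all(c.n_sets == 5 for c in a)  # five random sets by default
        assert {c.family_id for c in a} == set(ets.per_mirna)

    def test_identical_replicate_ps_give_zero_se(self):
        # one-gene families in a two-gene universe: every random set is one
        # of two genes, so with a single replicate the se must be zero
        table = m.GeneExpressionTable("d", {"A": 1.0, "B": 2.0})
        ets = m.ExpressedTargetSets(
            "d", {"m": frozenset({"A"})}, frozenset({"A", "B"})
        )
        profs = m.control_profile(table, ets, n_sets=1, seed=0, min_targets=0)
        assert profs[0].se_log10_p == 0.0


class TestFisherCombine:
    def test_single_p_identity(self):
        for p in (0.007, 0.5, 1.0):
            chi2, df, combined = m.fisher_combine([p])
            assert df == 2
            assert combined == pytest.approx(p, abs=1e-12)

    def test_two_dataset_closed_form(self):
        chi2, df, combined = m.fisher_combine([0.05, 0.05])
        assert df == 4
        x = -2 * (math.log(0.05) + math.log(0.05))
        assert chi2 == pytest.approx(x, abs=1e-9)
        assert combined == pytest.approx(math.exp(-x / 2) * (1 + x / 2), abs=1e-9)

    def test_uninformative_ps(self):
        chi2, df, combined = m.fisher_combine([1.0, 1.0, 1.0])
        assert chi2 == 0.0 and combined == 1.0

    def test_invalid_ps(self, caplog):
        with pytest.raises(ValueError):
            m.fisher_combine([1.2])
        with pytest.raises(ValueError):
            m.fisher_combine([])
        with caplog.at_level(logging.WARNING):
            _, _, combined = m.fisher_combine([0.0, 0.5])
        assert 0 < combined < 1e-100

    @given(
        ps=st.lists(
            st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=6
        ),
        idx=st.integers(min_value=0, max_value=5),
        factor=st.floats(min_value=0.01, max_value=0.999),
    )
    def test_monotone_in_each_p(self, ps, idx, factor):
        idx = idx % len(ps)
        smaller = list(ps)
        smaller[idx] = ps[idx] * factor
        assert m.fisher_combine(smaller)[2] <= m.fisher_combine(ps)[2] + 1e-15


class TestCombineAcrossDatasets:
    def _res(self, fam, ds, p, n=60):
        return m.ActivityResult(fam, ds, n, 1.0, p)

    def test_single_dataset_identity(self):
        combined = m.combine_across_datasets(
            {"P4": [self._res("m1", "d1", 0.03)]}
        )
        (r,) = combined
        assert r.combined_p == pytest.approx(0.03, abs=1e-12)
        assert r.df == 2 and r.significant

    def test_df_reflects_available_datasets(self):
        combined = m.combine_across_datasets(
            {
                "adult": [
                    self._res("m1", "d1", 0.2),
                    self._res("m1", "d2", 0.3),
                    self._res("m2", "d1", 0.5),
                ]
            }
        )
        by_fam = {r.family_id: r for r in combined}
        assert by_fam["m1"].df == 4  # passed the filter in 2 of the datasets
        assert by_fam["m2"].df == 2

    def test_all_ones_not_significant_and_sorted(self):
        combined = m.combine_across_datasets(
            {
                "P4": [
                    self._res("m1", "d1", 1.0),
                    self._res("m1", "d2", 1.0),
                    self._res("m2", "d1", 0.001),
                ]
            }
        )
        assert [r.family_id for r in combined] == ["m2", "m1"]
        m1 = combined[1]
        assert m1.combined_p == 1.0 and not m1.significant

    def test_benjamini_hochberg_extension(self):
        combined = m.combine_across_datasets(
            {"P4": [self._res("m1", "d1", 0.01), self._res("m2", "d1", 0.04)]},
            add_bh=True,
        )
        qs = [r.q_value for r in combined]
        assert qs == pytest.approx([0.02, 0.04])


class TestGeneRanking:
    def _combined(self, fams):
        return [
            m.CombinedActivityResult(f, "P4", (), 10.0, 2, 0.001, True)
            for f in fams
        ]

    @pytest.fixture
    def ets(self):
        return m.ExpressedTargetSets(
            "d",
            {
                "m1": frozenset({"G1", "G2"}),
                "m2": frozenset({"G1"}),
                "m3": frozenset({"G1", "G3"}),
            },
            frozenset({"G1", "G2", "G3"}),
        )

    def test_count_descending_then_alphabetical(self, ets):
        df = m.rank_genes_by_mirna_count(self._combined(["m1", "m2", "m3"]), ets)
        assert list(df.gene) == ["G1", "G2", "G3"]
        assert list(df.n_mirnas) == [3, 1, 1]

    def test_gene_list_restriction(self, ets):
        df = m.rank_genes_by_mirna_count(
            self._combined(["m1", "m2", "m3"]), ets, gene_list={"g3"}
        )
        assert format_gene_count_rows(df) == ["1: G3"]

    def test_only_significant_families_count(self, ets):
        combined = self._combined(["m1"]) + [
            m.CombinedActivityResult("m3", "P4", (), 0.1, 2, 0.9, False)
        ]
        df = m.rank_genes_by_mirna_count(combined, ets)
        assert list(df.gene) == ["G1", "G2"]

    def test_no_significant_families_warns(self, ets, caplog):
        with caplog.at_level(logging.WARNING):
            df = m.rank_genes_by_mirna_count([], ets)
        assert df.empty
        assert any("no significant" in r.message for r in caplog.records)


class TestRankInvariance:
    def test_monotone_transforms_preserve_all_ps(self):
        table, ets = _toy_screen()
        base = m.test_all_mirnas(table, ets, min_targets=1)
        for transform in (lambda v: v * 1000.0, lambda v: math.exp(v / 4.0)):
            warped = m.GeneExpressionTable(
                "toy", {g: transform(v) for g, v in table.values.items()}
            )
            res = m.test_all_mirnas(warped, ets, min_targets=1)
            assert [r.family_id for r in res] == [r.family_id for r in base]
            for a, b in zip(res, base):
                assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
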
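import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decaylens.models import ValidationError
from decaylens.overlap import (
    cross_period_status,
    expression_breadth,
    overlap_chisq,
    overlap_significance,
    sample_expression_matched,
    shared_degs,
    shared_period_degs,
)


class TestSharedDegs:
    def test_pairwise_intersection(self):
        out = shared_degs({"x": {"A", "B", "C"}, "y": {"B", "C", "D"}})
        assert out[("x", "y")] == 2

    def test_identical_sets(self):
        s = {"A", "B", "C"}
        assert shared_degs({"x": s, "y": set(s)})[("x", "y")] == 3

    def test_empty_triple_intersection(self):
        out = shared_degs(
            {"x": {"A", "B"}, "y": {"B", "C"}, "z": {"C", "A"}}
        )
        assert out[("x", "y", "z")] == 0

    def test_needs_two_sets(self):
        with pytest.raises(ValidationError):
            shared_degs({"x": {"A"}})


def test_shared_period_degs_requires_all_stages():
    deg = pd.DataFrame(
        {
            "gene": ["a", "b", "a", "c"],
            "period": "O",
            "stage": ["O1", "O1", "O2", "O2"],
            "cls": ["up", "up", "up", "up"],
        }
    )
    assert shared_period_degs(deg, "O", "up") == {"a"}


class TestExpressionMatching:
    def _setup(self, n_pool=5000, n_deg=200, seed=0):
        """DEG set drawn with probability weighted toward the
        low-expression tail (the structure the count simulator injects)."""
        rng = np.random.default_rng(seed)
        n = n_pool + n_deg
        genes = [f"g{i}" for i in range(n)]
        expr = pd.Series(rng.lognormal(2, 1.5, n), index=genes)
        rank = expr.rank().to_numpy() - 1
        w = np.exp(-4.0 * rank / (n - 1))
        chosen = rng.choice(n, size=n_deg, replace=False, p=w / w.sum())
        deg = {genes[i] for i in chosen}
        pool = set(genes) - deg
        return deg, pool, expr

    def test_control_size_equals_deg_size(self):
        deg, pool, expr = self._setup()
        ctrl = sample_expression_matched(deg, pool, expr, rng=1)
        assert len(ctrl.control_genes) == len(deg)

    def test_per_bin_histograms_match(self):
        deg, pool, expr = self._setup()
        ctrl = sample_expression_matched(deg, pool, expr, rng=1)
        if ctrl.fallback_moves == 0:
            deg_bins = sorted(ctrl.bin_of_gene[g] for g in deg)
            ctrl_bins = sorted(ctrl.bin_of_gene[g] for g in ctrl.control_genes)
            assert deg_bins == ctrl_bins

    def test_controls_disjoint_from_degs(self):
        deg, pool, expr = self._setup()
        ctrl = sample_expression_matched(deg, pool, expr, rng=2)
        assert not set(ctrl.control_genes) & deg

    def test_matching_quality_low_expression_tail(self):
        """Controls matched to a low-expression DEG set are statistically
        indistinguishable from it in expression (KS p > 0.1 in >= 95% of
        seeded runs)."""
        deg, pool, expr = self._setup(n_pool=10_000, n_deg=200)
        deg_vals = expr.reindex(sorted(deg)).to_numpy()
        ok = 0
        n_runs = 100
        for seed in range(n_runs):
            ctrl = sample_expression_matched(deg, pool, expr, rng=seed)
            ctrl_vals = expr.reindex(ctrl.control_genes).to_numpy()
            if stats.ks_2samp(deg_vals, ctrl_vals).pvalue > 0.1:
                ok += 1
        assert ok >= 0.95 * n_runs

    def test_pool_smaller_than_deg_set_rejected(self):
        expr = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(ValidationError, match="pool"):
            sample_expression_matched({"a", "b"}, {"c"}, expr)

    def test_same_seed_reproducible(self):
        deg, pool, expr = self._setup()
        c1 = sample_expression_matched(deg, pool, expr, rng=9)
        c2 = sample_expression_matched(deg, pool, expr, rng=9)
        assert c1.control_genes == c2.control_genes


class TestOverlapChisq:
    def test_hand_computed_value(self):
        chisq, _ = overlap_chisq([[10, 20], [20, 10]])
        assert chisq == pytest.approx(5.4, abs=1e-12)

    def test_equal_proportions(self):
        chisq, p = overlap_chisq([[5, 5], [5, 5]])
        assert chisq == 0.0
        assert p == 1.0

    def test_matches_scipy_with_correction(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            t = rng.integers(1, 80, (2, 2))
            chisq, p = overlap_chisq(t)
            ref = stats.chi2_contingency(t, correction=True)
            assert chisq == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_invariant_under_row_and_column_swaps(self):
        t = np.array([[12, 7], [3, 30]])
        base = overlap_chisq(t)[0]
        assert overlap_chisq(t[::-1])[0] == pytest.approx(base)
        assert overlap_chisq(t[:, ::-1])[0] == pytest.approx(base)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError, match="margin"):
            overlap_chisq([[0, 0], [5, 5]])


class TestOverlapSignificance:
    def _expr(self, genes, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.lognormal(0, 1, len(genes)), index=genes)

    def test_subset_overlap_extreme(self):
        genes = [f"g{i}" for i in range(2000)]
        a = set(genes[:50])
        b = set(genes[:100])  # A subset of B
        pool = set(genes[1000:])  # controls share nothing with B
        res = overlap_significance(a, b, pool, self._expr(genes), seed=1)
        assert res.observed_shared == 50
        assert res.pvalue < 1e-6
        assert res.quantile == 1.0

    def test_zero_resamples_rejected(self):
        with pytest.raises(ValidationError):
            overlap_significance({"a"}, {"b"}, {"c", "d"},
                                 pd.Series(1.0, index=list("abcd")),
                                 n_resamples=0)

    def test_same_seed_reproducible(self):
        genes = [f"g{i}" for i in range(500)]
        a, b = set(genes[:30]), set(genes[20:60])
        pool = set(genes[100:])
        expr = self._expr(genes)
        r1 = overlap_significance(a, b, pool, expr, seed=4)
        r2 = overlap_significance(a, b, pool, expr, seed=4)
        assert np.array_equal(r1.control_shared, r2.control_shared)
        assert r1.quantile_randomized == r2.quantile_randomized

    def test_null_quantile_uniform(self):
        """Randomized PIT quantile is U(0,1) when the DEG set is itself a
        random draw (KS p > 0.01 over 200 seeded runs)."""
        genes = [f"g{i}" for i in range(1500)]
        expr = self._expr(genes)
        qs = []
        for run in range(200):
            rng = np.random.default_rng(10_000 + run)
            a = set(rng.choice(genes, 80, replace=False))
            b = set(rng.choice(genes, 120, replace=False))
            pool = set(genes) - a
            res = overlap_significance(
                a, b, pool, expr, n_resamples=40, seed=run
            )
            qs.append(res.quantile_randomized)
        assert stats.kstest(qs, "uniform").pvalue > 0.01


class TestCrossPeriod:
    def _deg(self):
        rows = [
            ("a", "O", "O1", "up", 0.01, 2.0),
            ("a", "M", "UNA", "unchanged", 0.4, 1.05),
            ("a", "M", "ACT", "unchanged", 0.5, 1.02),
            ("b", "O", "O1", "up", 0.01, 2.0),
            ("b", "M", "UNA", "filtered", np.nan, np.nan),
            ("b", "M", "ACT", "filtered", np.nan, np.nan),
            ("c", "O", "O1", "down", 0.01, 0.5),
            ("c", "M", "UNA", "unchanged", 0.6, 1.0),
            ("c", "M", "ACT", "down", 0.01, 0.6),
        ]
        return pd.DataFrame(
            rows, columns=["gene", "period", "stage", "cls", "fdr", "fc"]
        )

    def test_unchanged_at_all_stages(self):
        assert cross_period_status(self._deg(), "a", "O", "M") == "unchanged"

    def test_filtered_everywhere_is_untested(self):
        assert cross_period_status(self._deg(), "b", "O", "M") == "untested"

    def test_deg_at_one_stage_takes_precedence(self):
        assert cross_period_status(self._deg(), "c", "O", "M") == "DEG"

    def test_non_deg_home_rejected(self):
        with pytest.raises(ValidationError):
            cross_period_status(self._deg(), "a", "M", "O")


def test_expression_breadth_counts_periods():
    sets = {"O": {"a", "b"}, "M": {"a"}, "E": {"c"}}
    assert expression_breadth("a", sets) == (2, ["O", "M"])
    assert expression_breadth("b", sets) == (1, ["O"])
    assert expression_breadth("zzz", sets)[0] == 0
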
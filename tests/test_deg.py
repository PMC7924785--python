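import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from decaylens.deg import (
    CountMatrix,
    bh_adjust,
    classify_genes,
    cpm,
    de_analysis,
    estimate_common_dispersion,
    filter_expressed,
    load_de_table,
    nb_test,
    pca_embed,
    tpm,
)
from decaylens.models import ValidationError

LIB = np.array([1e6])


class TestCpmTpm:
    def test_cpm_scales_by_library(self):
        counts = pd.DataFrame({"s1": [5, 15, 80]})
        out = cpm(counts)
        assert list(out["s1"]) == [50000, 150000, 800000]

    def test_cpm_zero_gene_stays_zero_and_columns_conserve(self):
        counts = pd.DataFrame({"s1": [0, 10], "s2": [0, 4]})
        out = cpm(counts)
        assert (out.iloc[0] == 0).all()
        assert np.allclose(out.sum(axis=0), 1e6, rtol=1e-6)

    def test_cpm_zero_library_names_sample(self):
        counts = pd.DataFrame({"good": [1], "empty": [0]})
        with pytest.raises(ValidationError, match="empty"):
            cpm(counts)

    def test_tpm_length_normalization(self):
        counts = pd.DataFrame({"s": [10, 10]}, index=["a", "b"])
        lengths = pd.Series([1000, 2000], index=["a", "b"])
        out = tpm(counts, lengths)
        assert out.loc["a", "s"] == pytest.approx(666666.67, abs=0.01)
        assert out.loc["b", "s"] == pytest.approx(333333.33, abs=0.01)

    def test_tpm_equal_lengths_proportional_to_cpm(self):
        counts = pd.DataFrame({"s": [3, 7, 10]}, index=list("abc"))
        lengths = pd.Series([500, 500, 500], index=list("abc"))
        assert np.allclose(tpm(counts, lengths), cpm(counts))

    def test_tpm_single_expressed_gene(self):
        counts = pd.DataFrame({"s": [9, 0]}, index=["a", "b"])
        lengths = pd.Series([100, 200], index=["a", "b"])
        assert tpm(counts, lengths).loc["a", "s"] == pytest.approx(1e6)

    def test_tpm_missing_length_drops_gene_with_warning(self):
        counts = pd.DataFrame({"s": [3, 7]}, index=["a", "b"])
        lengths = pd.Series([100.0], index=["a"])
        with pytest.warns(UserWarning, match="without a length"):
            out = tpm(counts, lengths)
        assert list(out.index) == ["a"]


class TestFilterExpressed:
    def _cm(self, gene_counts, filler=10_000):
        # six one-period libraries; filler gene fixes each library at 1e5
        # total so cpm = count x 10
        samples = [f"s{i}" for i in range(6)]
        counts = pd.DataFrame(
            {s: [gene_counts[i], filler - gene_counts[i]]
             for i, s in enumerate(samples)},
            index=["target", "filler"],
        )
        design = pd.DataFrame(
            {
                "genotype": ["WT"] * 3 + ["mut"] * 3,
                "period": "O",
                "stage": "O1",
                "replicate": [1, 2, 3] * 2,
            },
            index=pd.Index(samples, name="sample"),
        )
        return CountMatrix(counts, design)

    def test_exactly_threshold_in_three_libraries_passes(self):
        # cpm exactly 10 in exactly 3 of 6 libraries
        cm = self._cm([1, 1, 1, 0, 0, 0])
        assert "target" in filter_expressed(cm, "O")

    def test_two_qualifying_libraries_fail(self):
        cm = self._cm([1, 1, 0, 0, 0, 0])
        assert "target" not in filter_expressed(cm, "O")

    def test_all_zero_gene_fails(self):
        cm = self._cm([0] * 6)
        assert "target" not in filter_expressed(cm, "O")

    def test_too_few_libraries_error(self):
        cm = self._cm([1] * 6)
        with pytest.raises(ValidationError, match="libraries"):
            filter_expressed(cm, "O", min_libraries=7)


class TestNbTest:
    def test_poisson_limit_matches_exact_binomial(self):
        # equal libraries, sums (10, 0): two-sided p = 2 x 0.5^10
        _, p = nb_test([10], [0], LIB, LIB, dispersion=0.0)
        assert p == pytest.approx(2 * 0.5**10, rel=1e-12)

    def test_identical_groups_null(self):
        log2fc, p = nb_test([5, 5, 5], [5, 5, 5], np.ones(3), np.ones(3), 0.05)
        assert log2fc == 0.0
        assert p >= 0.999

    def test_fold_change_pseudocount(self):
        log2fc, _ = nb_test([30], [60], LIB, LIB, 0.0)
        assert log2fc == pytest.approx(np.log2(60.5 / 30.5), rel=1e-12)

    def test_both_groups_zero(self):
        log2fc, p = nb_test([0, 0], [0, 0], np.ones(2), np.ones(2), 0.1)
        assert (log2fc, p) == (0.0, 1.0)

    @pytest.mark.parametrize("dispersion", [0.0, 0.05, 0.3])
    def test_swap_symmetry(self, dispersion):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 50, 3)
        b = rng.integers(0, 50, 3)
        lib = np.full(3, 1e5)
        fc_ab, p_ab = nb_test(a, b, lib, lib, dispersion)
        fc_ba, p_ba = nb_test(b, a, lib, lib, dispersion)
        assert fc_ab == pytest.approx(-fc_ba, rel=1e-12)
        assert p_ab == p_ba

    def test_dispersion_estimator_recovers_truth(self):
        rng = np.random.default_rng(1)
        d = 0.1
        mean = rng.lognormal(np.log(300), 0.8, 3000)
        lib = np.full(4, 1e6)
        a = rng.negative_binomial(1 / d, 1 / (1 + mean[:, None] * d), (3000, 4))
        b = rng.negative_binomial(1 / d, 1 / (1 + mean[:, None] * d), (3000, 4))
        dhat = estimate_common_dispersion(
            a.astype(float), b.astype(float), lib, lib
        )
        assert dhat == pytest.approx(d, rel=0.3)


class TestBhAdjust:
    @staticmethod
    def _bh_oracle(p):
        """Definitional step-up: fdr_i = min over thresholds t >= p_i of
        n t / #(p <= t), evaluated at observed p-values."""
        p = np.asarray(p, float)
        n = len(p)
        out = np.empty(n)
        for i in range(n):
            ts = p[p >= p[i]]
            out[i] = min(
                1.0, min(n * t / (p <= t).sum() for t in ts)
            )
        return out

    def test_hand_example(self):
        assert np.allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == 0.3

    def test_matches_definitional_oracle_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            assert np.allclose(bh_adjust(p), self._bh_oracle(p), atol=1e-12)

    def test_matches_statsmodels_on_long_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = rng.uniform(size=500)
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_fdr_at_least_p(self, p):
        assert np.all(bh_adjust(p) >= np.asarray(p) - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestClassify:
    @pytest.mark.parametrize(
        "fdr,fc,expected",
        [
            (0.03, 1.6, "up"),
            (0.03, 0.5, "down"),
            (0.2, 1.1, "unchanged"),
            (0.2, 1.5, "other"),
            (0.2, 0.7, "other"),
            (0.05, 1.1, "other"),  # boundary FDR is neither DEG nor unchanged
        ],
    )
    def test_rules(self, fdr, fc, expected):
        assert classify_genes([fdr], [fc])[0] == expected

    @given(
        st.floats(0, 1),
        st.floats(0.01, 10),
    )
    def test_partition_exhaustive_and_exclusive(self, fdr, fc):
        label = classify_genes([fdr], [fc])[0]
        assert label in ("up", "down", "unchanged", "other")


class TestPca:
    def _cm(self, counts):
        samples = list(counts.columns)
        design = pd.DataFrame(
            {
                "genotype": "WT",
                "period": "O",
                "stage": "O1",
                "replicate": range(1, len(samples) + 1),
            },
            index=pd.Index(samples, name="sample"),
        )
        return CountMatrix(counts, design)

    def test_identical_samples_zero_distance(self):
        counts = pd.DataFrame({"s1": [5, 10, 3], "s2": [5, 10, 3]})
        with pytest.warns(UserWarning):
            coords, _ = pca_embed(self._cm(counts))
        assert np.allclose(coords.loc["s1"], coords.loc["s2"])

    def test_duplicating_samples_preserves_subspace(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 1000, (200, 6)),
            columns=[f"s{i}" for i in range(6)],
        )
        doubled = pd.concat(
            [counts, counts.add_suffix("_dup", axis=1)], axis=1
        )
        with pytest.warns(UserWarning):
            c1, _ = pca_embed(self._cm(counts))
        with pytest.warns(UserWarning):
            c2, _ = pca_embed(self._cm(doubled))
        # principal angles between the two sample-score planes, computed
        # from the embedded original samples
        a = np.linalg.qr(c1.to_numpy())[0]
        b = np.linalg.qr(c2.to_numpy()[: len(c1)])[0]
        sv = np.linalg.svd(a.T @ b, compute_uv=False)
        assert np.allclose(sv, 1.0, atol=1e-8)

    def test_variance_explained_bounded(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 500, (100, 5)), columns=list("abcde")
        )
        with pytest.warns(UserWarning):
            _, var = pca_embed(self._cm(counts))
        assert 0 <= var.sum() <= 1 + 1e-12


class TestDeAnalysis:
    def test_null_simulation_type_one_error(self, small_dataset):
        """With no true effect the exact test rejects near nominal rate."""
        cm = small_dataset["cm"]
        labels = small_dataset["labels"]
        deg = de_analysis(cm, "O")
        null_genes = labels.index[labels["fc_O"] == 1.0]
        sub = deg[deg["gene"].isin(null_genes) & (deg["cls"] != "filtered")]
        frac = (sub["pvalue"] < 0.05).mean()
        assert 0.005 < frac < 0.12

    def test_stabilized_genes_called_up(self, small_dataset):
        cm = small_dataset["cm"]
        labels = small_dataset["labels"]
        deg = de_analysis(cm, "M")
        stab = labels.index[
            labels["stabilized"] & (labels["stabilized_period"] == "M")
        ]
        up = set(deg.loc[deg["cls"] == "up", "gene"])
        assert len(stab) >= 3
        assert np.mean([g in up for g in stab]) > 0.7

    def test_round_trip_external_table(self, small_dataset, tmp_path):
        deg = de_analysis(small_dataset["cm"], "O")
        path = tmp_path / "de.tsv"
        deg.to_csv(path, sep="\t", index=False)
        back = load_de_table(path)
        assert list(back["cls"]) == list(deg["cls"])
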
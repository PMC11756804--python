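import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from cernapipe import LayerThresholds, bh_adjust, classify_direction, ddct, nb_test, size_factors
from cernapipe.synthetic import simulate_counts

GROUPS = ["mcao"] * 5 + ["sham"] * 5


def _counts(array, samples=None):
    array = np.asarray(array)
    cols = samples or [f"s{i}" for i in range(array.shape[1])]
    return pd.DataFrame(array, index=[f"f{i}" for i in range(array.shape[0])], columns=cols)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        sf = size_factors(_counts([[5, 5], [9, 9], [2, 2]]))
        assert np.allclose(sf, 1.0)

    def test_doubled_column_gives_sqrt2_factors(self):
        # col B = 2 x col A: ratios to the per-feature geometric mean are
        # 1/sqrt(2) and sqrt(2) for every feature, hence the medians too
        sf = size_factors(_counts([[4, 8], [10, 20], [7, 14]]))
        assert np.allclose(sf, [2 ** -0.5, 2 ** 0.5])

    def test_single_feature_hand_computation(self):
        # geometric mean of (4, 9) is 6 -> factors (4/6, 9/6)
        sf = size_factors(_counts([[4, 9]]))
        assert np.allclose(sf, [2 / 3, 3 / 2])

    def test_matches_pydeseq2_median_of_ratios(self):
        pydeseq2_pp = pytest.importorskip("pydeseq2.preprocessing")
        rng = np.random.default_rng(3)
        mat = _counts(rng.poisson(50, (40, 6)) + 1)
        ours = size_factors(mat)
        _, theirs = pydeseq2_pp.deseq2_norm(mat.T.to_numpy())
        assert np.allclose(ours.to_numpy(), theirs)

    def test_no_common_positive_feature_errors_with_fallback_hint(self):
        mat = _counts([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(mat)
        sf = size_factors(mat, fallback="pseudo_reference")
        assert np.all(sf > 0)


class TestBH:
    def test_step_up_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert np.allclose(bh_adjust([0.03]), [0.03])
        assert bh_adjust([]).size == 0

    def test_matches_statsmodels_on_random_pvalues(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 500)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])

    def test_fdr_dominates_p_and_is_rank_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.beta(0.5, 3, 200)
        fdr = bh_adjust(p)
        assert np.all(fdr >= p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(fdr[order]) >= 0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestNBTest:
    def test_fold_change_pseudocount_arithmetic(self):
        # size factors are 1 by construction (per-feature ratios are
        # symmetric around 1), group means 10 vs 40 -> log2(40.5/10.5)
        mat = _counts(
            [[10, 10, 40, 40], [40, 40, 10, 10], [20, 20, 20, 20]],
            samples=["a", "b", "c", "d"],
        )
        de = nb_test(mat, ["sham", "sham", "mcao", "mcao"], "mcao", "sham")
        assert de.loc[0, "log2fc"] == pytest.approx(np.log2(40.5 / 10.5))
        assert de.loc[1, "log2fc"] == pytest.approx(-np.log2(40.5 / 10.5))

    def test_identical_groups_give_zero_log2fc(self):
        rng = np.random.default_rng(2)
        block = rng.poisson(30, (50, 5))
        mat = _counts(np.hstack([block, block]), samples=[f"s{i}" for i in range(10)])
        de = nb_test(mat, GROUPS, "mcao", "sham")
        assert np.allclose(de["log2fc"], 0.0)

    def test_swapping_group_labels_negates_log2fc_keeps_p(self):
        counts, _ = simulate_counts(
            n_features={"lncrna": 10, "mirna": 10, "mrna": 300}, de_fraction=0.1, seed=4
        )
        mat = counts["mrna"]
        a = nb_test(mat, GROUPS, "mcao", "sham")
        b = nb_test(mat, GROUPS, "sham", "mcao")
        assert np.allclose(a["log2fc"], -b["log2fc"])
        assert np.allclose(a["pvalue"], b["pvalue"])

    def test_all_zero_feature_kept_with_null_result(self):
        mat = _counts(np.vstack([np.zeros(10), np.full(10, 20.0)]),
                      samples=[f"s{i}" for i in range(10)])
        de = nb_test(mat, GROUPS, "mcao", "sham")
        row = de[de["feature_id"] == "f0"].iloc[0]
        assert row["pvalue"] == 1.0 and row["fdr"] == 1.0 and row["direction"] == "ns"
        assert bool(row["all_zero"])

    def test_fdr_never_below_p(self):
        counts, _ = simulate_counts(
            n_features={"lncrna": 10, "mirna": 10, "mrna": 400}, de_fraction=0.05, seed=5
        )
        de = nb_test(counts["mrna"], GROUPS, "mcao", "sham")
        assert np.all(de["fdr"] >= de["pvalue"] - 1e-12)

    @pytest.mark.parametrize("dispersion", [0.02, 0.05, 0.1])
    def test_null_type_i_error_within_binomial_ci(self, dispersion):
        # 2000 null features at alpha 0.05: 99% binomial CI is
        # 0.05 +/- 2.576*sqrt(0.05*0.95/2000) = [0.0374, 0.0626]
        counts, _ = simulate_counts(
            n_features={"lncrna": 10, "mirna": 10, "mrna": 2000},
            de_fraction=0.0, dispersion=dispersion, seed=21,
        )
        de = nb_test(counts["mrna"], GROUPS, "mcao", "sham")
        rate = float((de["pvalue"] < 0.05).mean())
        assert 0.0374 <= rate <= 0.0626

    def test_planted_log2fc_recovered_within_tolerance(self):
        # planted |log2FC| = 2 at n=5/group, dispersion 0.1: the mean
        # estimate over planted features must sit within +/- 0.15
        counts, truth = simulate_counts(
            n_features={"lncrna": 10, "mirna": 10, "mrna": 2000},
            de_fraction=0.1, effect=2.0, dispersion=0.1,
            n_triplet_mirnas=0, seed=6,
        )
        de = nb_test(counts["mrna"], GROUPS, "mcao", "sham").set_index("feature_id")
        signed = [
            de.loc[f, "log2fc"] * np.sign(lfc)
            for f, lfc in truth.lfc["mrna"].items()
        ]
        assert abs(float(np.mean(signed)) - 2.0) <= 0.15


class TestClassifyDirection:
    def _records(self, lfc, p=0.001, fdr=0.005):
        n = len(lfc)
        return pd.DataFrame(
            {"feature_id": [f"f{i}" for i in range(n)], "log2fc": lfc,
             "pvalue": [p] * n, "fdr": [fdr] * n}
        )

    def test_inclusive_vs_strict_magnitude(self):
        rec = self._records([1.0, -1.0, 0.5])
        inclusive = LayerThresholds(log2fc_min=1.0, inclusive=True, fdr_max=0.01, p_max=0.05)
        strict = LayerThresholds(log2fc_min=1.0, inclusive=False, fdr_max=0.01, p_max=0.05)
        _, (up_i, down_i) = classify_direction(rec, inclusive)
        _, (up_s, down_s) = classify_direction(rec, strict)
        assert (up_i, down_i) == (1, 1) and (up_s, down_s) == (0, 0)

    def test_significance_gates(self):
        rec = self._records([3.0, 3.0])
        rec.loc[1, "fdr"] = 0.02  # fails FDR < 0.01
        thr = LayerThresholds(log2fc_min=1.0, inclusive=True, fdr_max=0.01, p_max=0.05)
        out, (up, down) = classify_direction(rec, thr)
        assert up == 1 and down == 0 and out.loc[1, "direction"] == "ns"

    def test_no_raw_p_gate_when_disabled(self):
        rec = self._records([3.0], p=0.2, fdr=0.01)
        thr = LayerThresholds(log2fc_min=1.0, inclusive=False, fdr_max=0.05, p_max=None)
        _, (up, _) = classify_direction(rec, thr)
        assert up == 1

    def test_empty_input(self):
        thr = LayerThresholds()
        _, counts = classify_direction(self._records([]), thr)
        assert counts == (0, 0)


class TestDdct:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ((20, 20, 20, 20), 1.0),  # all equal
            ((19, 20, 20, 20), 2.0),  # ddCt = -1
            ((20, 18, 24, 18), 16.0),  # ddCt = 2 - 6 = -4
        ],
    )
    def test_known_values(self, cts, expected):
        assert ddct(*cts) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            ddct(float("nan"), 20, 20, 20)
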
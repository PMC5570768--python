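import numpy as np
import pandas as pd
import pytest

from metabatch import (BatchResult, average_pcorr, call_significant,
                       combined_ci, combined_se, integrate_batches,
                       sign_consistency, sus_data)

BATCH_COLS = ["pcorr_batch1", "pcorr_batch2", "pcorr_batch3"]


class TestSignConsistency:
    @pytest.mark.parametrize("values,expected", [
        ((-0.560, -0.527, -0.652), True),    # all negative
        ((0.324, -0.106, -0.045), False),    # mixed signs
        ((0.0, 0.1, 0.2), False),            # zero has no sign
        ((0.3, 0.3, 0.3), True),
    ])
    def test_triplets(self, values, expected):
        mask = sign_consistency(np.array(values)[:, None])
        assert bool(mask.iloc[0]) is expected

    def test_missing_entries_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            sign_consistency(np.array([[0.1, np.nan], [0.2, 0.3]]))

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError):
            sign_consistency(np.array([[0.1, 0.2]]))


class TestAveragePcorr:
    def test_reference_rows(self, sle_pcorr, sle_table):
        mask = sign_consistency(sle_pcorr)
        avg = average_pcorr(sle_pcorr, mask)
        assert abs(avg.loc["2-Oxoisocaproic acid"] - (-0.5797)) < 5e-4
        assert abs(avg.loc["Ornithine"] - 0.3377) < 5e-4
        assert np.isnan(avg.loc["Alanine"])  # inconsistent -> undefined

    def test_identical_values_mean_is_value(self):
        M = np.full((3, 2), 0.42)
        mask = sign_consistency(M)
        avg = average_pcorr(M, mask)
        np.testing.assert_allclose(avg, 0.42)


class TestCombinedSe:
    def test_rms_of_equal_values_is_value(self):
        se = combined_se(np.full((3, 4), 0.2))
        np.testing.assert_allclose(se, 0.2)

    def test_hand_value(self):
        se = combined_se(np.array([[0.1], [0.2], [0.2]]))
        assert abs(se.iloc[0] - 0.17321) < 1e-5

    def test_zeros(self):
        np.testing.assert_allclose(combined_se(np.zeros((3, 2))), 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            combined_se(np.array([[0.1], [-0.2], [0.2]]))


class TestCombinedCi:
    def test_three_sevenfold_batches_multiplier(self):
        # N_total = 21 CV groups, df = 18
        assert abs(combined_ci(1.0, 21, 3) - 2.1009) < 1e-4

    def test_zero_se(self):
        assert combined_ci(0.0, 21, 3) == 0.0

    def test_multiplier_decreases_with_n_total(self):
        assert combined_ci(1.0, 30, 3) < combined_ci(1.0, 21, 3)

    def test_insufficient_groups_rejected(self):
        with pytest.raises(ValueError):
            combined_ci(1.0, 3, 3)


class TestCallSignificant:
    @pytest.mark.parametrize("avg,ci,expected", [
        (-0.336, 0.258, True),     # tryptophan-like
        (0.298, 0.304, False),     # xylose-like, CI wins
        (0.0, 0.2, False),
    ])
    def test_threshold(self, avg, ci, expected):
        sig = call_significant(pd.Series([avg]), pd.Series([ci]))
        assert bool(sig.iloc[0]) is expected


class TestSusData:
    def test_identical_profiles_r2_one(self, sle_pcorr):
        d = sus_data(sle_pcorr["pcorr_batch1"], sle_pcorr["pcorr_batch1"])
        assert abs(d.r_squared - 1.0) < 1e-12
        assert d.same_direction.all()

    def test_reference_batch_pairs(self, sle_pcorr):
        r12 = sus_data(sle_pcorr["pcorr_batch1"], sle_pcorr["pcorr_batch2"]).r_squared
        r13 = sus_data(sle_pcorr["pcorr_batch1"], sle_pcorr["pcorr_batch3"]).r_squared
        r23 = sus_data(sle_pcorr["pcorr_batch2"], sle_pcorr["pcorr_batch3"]).r_squared
        assert abs(r12 - 0.454) < 0.01
        assert abs(r13 - 0.177) < 0.01
        assert abs(r23 - 0.055) < 0.01

    def test_orthogonal_vectors_r2_zero(self):
        a = pd.Series([1.0, -1.0, 1.0, -1.0])
        b = pd.Series([1.0, 1.0, -1.0, -1.0])
        assert sus_data(a, b).r_squared < 1e-12

    def test_zero_variance_rejected(self):
        a = pd.Series([0.3, 0.3, 0.3])
        with pytest.raises(ValueError, match="zero-variance"):
            sus_data(a, pd.Series([0.1, 0.2, 0.3]))

    def test_restricted_to_shared_metabolites(self):
        a = pd.Series([0.1, 0.4, -0.2, 0.5], index=list("abcd"))
        b = pd.Series([0.2, 0.3, -0.1], index=list("abc"))
        d = sus_data(a, b)
        assert list(d.pairs.index) == list("abc")


def _results_from_table(sle_table, with_se=False):
    out = []
    for i, col in enumerate(BATCH_COLS, start=1):
        se = pd.Series(0.1, index=sle_table.index) if with_se else None
        out.append(BatchResult(batch_id=i, pcorr=sle_table[col],
                               jackknife_se=se,
                               n_cv_groups=7 if with_se else None))
    return out


class TestIntegrateBatches:
    def test_reference_counts_and_averages(self, sle_table):
        profile = integrate_batches(_results_from_table(sle_table))
        assert int(profile.sign_consistent.sum()) == 42
        printed = sle_table["avg_pcorr"].dropna()
        recomputed = profile.avg_pcorr.loc[printed.index]
        assert (recomputed - printed).abs().max() < 1e-3

    def test_reference_significance_with_printed_ci(self, sle_table):
        profile = integrate_batches(_results_from_table(sle_table))
        sig = call_significant(profile.avg_pcorr, sle_table["avg_ci"])
        assert int(sig.sum()) == 3
        assert set(sle_table.index[sig]) == {
            "2-Oxoisocaproic acid", "Ornithine", "Tryptophan"}

    def test_permutation_invariant_in_batch_order(self, sle_table):
        res = _results_from_table(sle_table, with_se=True)
        p1 = integrate_batches(res)
        p2 = integrate_batches(res[::-1])
        pd.testing.assert_series_equal(p1.sign_consistent, p2.sign_consistent)
        pd.testing.assert_series_equal(p1.avg_pcorr, p2.avg_pcorr)
        pd.testing.assert_series_equal(p1.significant, p2.significant)

    def test_identical_batches_average_is_batch(self, sle_pcorr):
        col = sle_pcorr["pcorr_batch1"]
        res = [BatchResult(batch_id=i, pcorr=col) for i in (1, 2, 3)]
        profile = integrate_batches(res)
        nonzero = col != 0
        pd.testing.assert_series_equal(profile.sign_consistent, nonzero,
                                       check_names=False)
        np.testing.assert_allclose(profile.avg_pcorr[nonzero], col[nonzero])

    def test_metabolite_mismatch_lists_difference(self, sle_pcorr):
        a = BatchResult(batch_id=1, pcorr=sle_pcorr["pcorr_batch1"])
        b_pcorr = sle_pcorr["pcorr_batch2"].rename(index={"Ornithine": "Weird"})
        b = BatchResult(batch_id=2, pcorr=b_pcorr)
        with pytest.raises(ValueError, match="Ornithine"):
            integrate_batches([a, b])

    def test_unanimous_batch_significance_implies_consistency(self):
        # if every batch flags metabolite k significant with a common sign,
        # then k must be sign-consistent
        rng = np.random.default_rng(11)
        for _ in range(50):
            P = rng.uniform(-1, 1, size=(30, 3))
            SE = rng.uniform(0.01, 0.3, size=(30, 3))
            res = [BatchResult(batch_id=b, pcorr=pd.Series(P[:, b]),
                               jackknife_se=pd.Series(SE[:, b]), n_cv_groups=7)
                   for b in range(3)]
            per_batch_sig = np.column_stack([r.significant for r in res])
            common_sign = (np.sign(P) == np.sign(P[:, [0]])).all(axis=1) \
                & (P != 0).all(axis=1)
            unanimous = per_batch_sig.all(axis=1) & common_sign
            profile = integrate_batches(res)
            assert profile.sign_consistent[unanimous].all()

    def test_round_trip_through_flat_table(self, sle_table, tmp_path):
        res = _results_from_table(sle_table, with_se=True)
        profile = integrate_batches(res)
        path = tmp_path / "profile.csv"
        profile.to_frame().to_csv(path, index_label="metabolite_id")
        back = pd.read_csv(path, index_col="metabolite_id")
        want = profile.to_frame()
        np.testing.assert_allclose(back["avg_pcorr"], want["avg_pcorr"])
        np.testing.assert_allclose(back["se_avg"], want["se_avg"])
        np.testing.assert_allclose(back["avg_ci"], want["avg_ci"])
        assert (back["sign_consistent"] == want["sign_consistent"]).all()
        assert (back["significant"] == want["significant"]).all()

    def test_significant_implies_consistent_and_summary(self, sle_table):
        res = _results_from_table(sle_table, with_se=True)
        profile = integrate_batches(res)
        assert (profile.significant[~profile.sign_consistent] == False).all()  # noqa: E712
        s = profile.summary()
        assert s["n_metabolites"] == 73 and s["n_batches"] == 3
        assert s["n_total_cv_groups"] == 21

    def test_two_batches_allowed_one_rejected(self, sle_pcorr):
        res = [BatchResult(batch_id=i, pcorr=sle_pcorr[c])
               for i, c in enumerate(BATCH_COLS[:2], 1)]
        integrate_batches(res)  # fine
        with pytest.raises(ValueError):
            integrate_batches(res[:1])
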
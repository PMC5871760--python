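"""Unit and property tests for the four differential-interaction methods."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aidlicense import bioid
from aidlicense.bioid import (
    BioidParams,
    bh_adjust,
    call_fold,
    call_maz,
    call_nb,
    call_normz,
    consensus,
    fold_enrichment,
    normalize_to_birA,
    run_bioid,
)

from conftest import make_matrix


# ---------------------------------------------------------------- normalise
class TestNormalize:
    def test_direct_division(self):
        m = make_matrix({"BIRA": [4, 2], "P": [12, 10]}, ["WT", "MUT1"])
        nm = normalize_to_birA(m)
        assert nm.values.loc["P", "WT.1"] == 3.0
        assert nm.values.loc["P", "MUT1.1"] == 5.0

    def test_birA_row_is_one(self, small_matrix):
        nm = normalize_to_birA(small_matrix)
        assert (nm.values.loc["BIRA"] == 1.0).all()

    def test_scale_invariance_per_sample(self, small_matrix):
        nm1 = normalize_to_birA(small_matrix)
        scaled = small_matrix.counts.copy()
        scaled["WT.1"] *= 2
        m2 = make_matrix(
            {p: list(scaled.loc[p]) for p in scaled.index},
            list(small_matrix.samples["bait"]),
        )
        nm2 = normalize_to_birA(m2)
        pd.testing.assert_frame_equal(nm1.values, nm2.values)

    def test_idempotent(self, small_matrix):
        nm = normalize_to_birA(small_matrix)
        nm2 = normalize_to_birA(nm)
        pd.testing.assert_frame_equal(nm.values, nm2.values)

    def test_zero_birA_names_sample(self):
        m = make_matrix({"BIRA": [4, 0], "P": [1, 1]}, ["WT", "MUT1"])
        with pytest.raises(ValueError, match="MUT1.1"):
            normalize_to_birA(m)


# ------------------------------------------------------------------- fold
class TestFold:
    def test_mean_ratio(self):
        m = make_matrix(
            {"BIRA": [1, 1, 1, 1], "P": [2, 4, 1, 1]},
            ["WT", "WT", "MUT1", "MUT1"],
        )
        f = fold_enrichment(normalize_to_birA(m), "WT", "MUT1", pseudocount=0)
        assert f.loc["P"] == pytest.approx(3.0)

    def test_identical_baits_give_one(self, small_matrix):
        nm = normalize_to_birA(small_matrix)
        f = fold_enrichment(nm, "WT", "WT")
        assert np.allclose(f, 1.0)

    @given(st.floats(1e-3, 10.0))
    def test_reciprocal_product_is_one(self, pseudocount):
        m = make_matrix(
            {"BIRA": [2, 3, 4, 5], "P": [7, 1, 9, 2], "Q": [0, 0, 3, 8]},
            ["WT", "WT", "MUT1", "MUT1"],
        )
        nm = normalize_to_birA(m)
        ab = fold_enrichment(nm, "WT", "MUT1", pseudocount)
        ba = fold_enrichment(nm, "MUT1", "WT", pseudocount)
        assert np.allclose(ab * ba, 1.0)

    def test_unknown_bait_errors(self, small_matrix):
        nm = normalize_to_birA(small_matrix)
        with pytest.raises(ValueError, match="bait"):
            fold_enrichment(nm, "WT", "XX")

    @pytest.mark.parametrize(
        "f1,f2,fa2,expected",
        [
            (5.0, 3.0, 6.0, True),  # passes both mutants and the A2 filter
            (2.4, 10.0, 10.0, False),  # fails one mutant
            (2.5, 2.5, 5.0, True),  # thresholds are inclusive ("at least")
            (10.0, 10.0, 4.9, False),  # fails the A2 specificity filter
        ],
    )
    def test_call_fold_joint_rule(self, f1, f2, fa2, expected):
        idx = pd.Index(["P"])
        tab = call_fold(
            pd.Series([f1], index=idx),
            pd.Series([f2], index=idx),
            pd.Series([fa2], index=idx),
        )
        assert bool(tab.loc["P", "called"]) is expected


# ------------------------------------------------------------------ normz
class TestNormz:
    def test_hand_computed_z_with_sample_sd(self):
        out = call_normz(pd.Series([1.0, 1.0, 1.0, 1.0, 6.0]))
        assert out["z"].iloc[-1] == pytest.approx(4 / np.sqrt(5), abs=1e-12)
        assert not out["flagged"].any()

    def test_constant_vector_degenerate(self):
        with pytest.warns(UserWarning, match="zero standard deviation"):
            out = call_normz(pd.Series([2.0, 2.0, 2.0, 2.0]))
        assert (out["z"] == 0).all()
        assert not out["flagged"].any()

    @given(
        st.lists(st.floats(-20, 20), min_size=4, max_size=40).filter(
            lambda xs: np.std(xs) > 1e-6
        )
    )
    def test_standardisation_identity(self, xs):
        out = call_normz(pd.Series(xs))
        assert out["z"].mean() == pytest.approx(0.0, abs=1e-9)
        assert out["z"].std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            call_normz(pd.Series([1.0, 2.0]))


# -------------------------------------------------------------------- maz
def brute_force_window(intensities: np.ndarray, i: int, w: int) -> set[int]:
    """All-pairs distance sort; ties broken by original order."""
    pairs = sorted(
        range(len(intensities)),
        key=lambda j: (abs(intensities[j] - intensities[i]), j),
    )
    return set(pairs[:w])


class TestMaz:
    def test_window_floor(self, rng):
        r = pd.Series(rng.normal(size=20))
        inten = pd.Series(rng.normal(size=20))
        # ceil(0.10 * 20) = 2 < min_window -> the floor of 5 must apply;
        # verify via the limiting case: identical to brute force with w=5
        out = call_maz(r, inten, window_frac=0.10, min_window=5)
        w5 = brute_force_window(inten.to_numpy(), 0, 5)
        win = r.to_numpy()[sorted(w5)]
        expected = (r.iloc[0] - win.mean()) / win.std(ddof=1)
        assert out["local_z"].iloc[0] == pytest.approx(expected)

    def test_full_window_equals_global_z(self, rng):
        r = pd.Series(rng.normal(size=37))
        inten = pd.Series(rng.normal(size=37))
        maz = call_maz(r, inten, window_frac=1.0)
        normz = call_normz(r)
        assert np.allclose(maz["local_z"], normz["z"], atol=1e-12)

    def test_nearest_window_matches_brute_force(self, rng):
        n = 200
        inten = rng.normal(size=n)
        for i in range(n):
            fast = set(bioid._nearest_window(inten, i, 20).tolist())
            assert fast == brute_force_window(inten, i, 20)

    def test_too_few_preys(self):
        with pytest.raises(ValueError):
            call_maz(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]))

    def test_zero_local_sd_warns(self):
        r = pd.Series([1.0] * 6 + [5.0])
        inten = pd.Series(np.arange(7.0))
        with pytest.warns(UserWarning, match="local standard deviation"):
            out = call_maz(r, inten, window_frac=0.5)
        assert out["local_z"].iloc[0] == 0.0


# --------------------------------------------------------------------- nb
class TestNbTest:
    def test_identical_counts_null_identity(self):
        m = make_matrix(
            {"BIRA": [100] * 6, "P": [30] * 6, "Q": [12] * 6},
            ["WT", "WT", "WT", "MUT1", "MUT1", "MUT2"],
        )
        out = call_nb(m)
        assert out.loc["P", "log2_fold_wt_over_mut"] == pytest.approx(0, abs=1e-6)
        assert out.loc["P", "wald_p"] == pytest.approx(1.0, abs=1e-6)
        assert not out["flagged"].any()

    def test_all_zero_rows_untested(self):
        m = make_matrix(
            {"BIRA": [100] * 6, "P": [30, 28, 33, 31, 29, 30], "Z": [0] * 6},
            ["WT", "WT", "WT", "MUT1", "MUT1", "MUT2"],
        )
        out = call_nb(m)
        assert not out.loc["Z", "tested"]
        assert np.isnan(out.loc["Z", "wald_p"])
        assert out.loc["P", "tested"]

    def test_needs_two_samples_per_condition(self):
        m = make_matrix(
            {"BIRA": [100] * 3, "P": [30, 28, 33]}, ["WT", "MUT1", "MUT2"]
        )
        with pytest.raises(ValueError, match="2 samples"):
            call_nb(m)

    def test_recovers_large_planted_reduction(self, rng):
        baits = ["WT"] * 3 + ["MUT1", "MUT1", "MUT2"]
        counts = {"BIRA": [150] * 6}
        for i in range(60):
            counts[f"N{i:02d}"] = list(rng.poisson(40, size=6))
        counts["HIT"] = list(rng.poisson([400, 400, 400, 50, 50, 50]))
        m = make_matrix(counts, baits)
        out = call_nb(m)
        assert out.loc["HIT", "flagged"]
        assert out.loc["HIT", "log2_fold_wt_over_mut"] == pytest.approx(3.0, abs=0.7)

    def test_dispersion_parameterisation_matches_generator(self, rng):
        # variance = mu + alpha * mu^2 with alpha = 0.2 at mu = 100
        r = 1 / 0.2
        draws = rng.negative_binomial(r, r / (r + 100.0), size=200_000)
        assert draws.mean() == pytest.approx(100.0, rel=0.02)
        assert draws.var() == pytest.approx(100 + 0.2 * 100**2, rel=0.05)


def test_bh_step_up_hand_check():
    adj = bh_adjust([0.001, 0.01, 0.02, 0.9])
    assert np.allclose(adj, [0.004, 0.02, 0.02 * 4 / 3, 0.9], atol=1e-12)


# -------------------------------------------------------------- consensus
class TestConsensus:
    @staticmethod
    def _tables(idx, fold_called, nz1, nz2, mz1, mz2, nb_flag):
        mk = lambda flags, col: pd.DataFrame({col: flags}, index=idx)
        return dict(
            fold=mk(fold_called, "called"),
            normz_mut1=mk(nz1, "flagged"),
            normz_mut2=mk(nz2, "flagged"),
            maz_mut1=mk(mz1, "flagged"),
            maz_mut2=mk(mz2, "flagged"),
            nb=mk(nb_flag, "flagged"),
        )

    def test_two_methods_reach_core(self):
        idx = pd.Index(["P"])
        t = self._tables(idx, [True], [True], [True], [False], [False], [False])
        out = consensus(t["fold"], t["normz_mut1"], t["normz_mut2"],
                        t["maz_mut1"], t["maz_mut2"], t["nb"])
        assert out.loc["P", "n_methods"] == 2
        assert out.loc["P", "in_core"] and out.loc["P", "in_union"]

    def test_single_mutant_flag_is_not_a_call(self):
        idx = pd.Index(["P"])
        t = self._tables(idx, [False], [True], [False], [False], [False], [False])
        out = consensus(t["fold"], t["normz_mut1"], t["normz_mut2"],
                        t["maz_mut1"], t["maz_mut2"], t["nb"])
        assert out.loc["P", "n_methods"] == 0
        assert not out.loc["P", "in_union"]

    def test_empty_calls_empty_sets(self):
        idx = pd.Index(["P", "Q"])
        f = [False, False]
        t = self._tables(idx, f, f, f, f, f, f)
        out = consensus(t["fold"], t["normz_mut1"], t["normz_mut2"],
                        t["maz_mut1"], t["maz_mut2"], t["nb"])
        assert not out["in_union"].any() and not out["in_core"].any()

    def test_mismatched_universe_errors(self):
        t = self._tables(pd.Index(["P"]), [True], [True], [True], [True],
                         [True], [True])
        other = pd.DataFrame({"flagged": [True]}, index=pd.Index(["Q"]))
        with pytest.raises(ValueError, match="universe"):
            consensus(t["fold"], t["normz_mut1"], t["normz_mut2"],
                      t["maz_mut1"], t["maz_mut2"], other)

    def test_core_subset_of_union(self, small_matrix):
        out = run_bioid(small_matrix, BioidParams())
        cons = out["consensus"]
        assert (cons["in_core"] <= cons["in_union"]).all()
        assert cons["in_union"].sum() <= len(cons)
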
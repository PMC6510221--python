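import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from assemblyscope import (
    classify_pair,
    classify_pairs,
    env_difference_matrix,
    mantel,
    pairwise_regression,
    process_fractions,
)
from assemblyscope.processes import PROCESS_LABELS


class TestClassifyPair:
    @pytest.mark.parametrize(
        "bnti,rc,expected",
        [
            (2.5, 0.1, "variable_selection"),
            (-3.0, 0.0, "homogeneous_selection"),
            (0.5, 0.99, "dispersal_limitation"),
            (1.0, -0.99, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated"),
            # boundaries are strict inequalities -> undominated
            (2.0, 0.0, "undominated"),
            (-2.0, 0.0, "undominated"),
            (0.0, 0.95, "undominated"),
            (0.0, -0.95, "undominated"),
        ],
    )
    def test_threshold_rules(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    @settings(max_examples=500, derandomize=True)
    @given(
        st.floats(-6, 6, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
    )
    def test_partition_exactly_one_label(self, bnti, rc):
        assert classify_pair(bnti, rc) in PROCESS_LABELS

    def test_undefined_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(float("nan"), 0.0)
        with pytest.raises(ValueError):
            classify_pair(0.0, 1.5)


def make_results(vals):
    rows = []
    for (i, j), (b, r) in vals.items():
        rows.append({"sample_i": i, "sample_j": j, "bnti": b, "rc_bray": r})
    df = pd.DataFrame(rows)
    bn = df[["sample_i", "sample_j", "bnti"]]
    rc = df[["sample_i", "sample_j", "rc_bray"]]
    return bn, rc


class TestProcessFractions:
    def test_counts_and_undefined_bookkeeping(self):
        bn, rc = make_results(
            {
                ("a", "b"): (3.0, 0.0),
                ("a", "c"): (-3.0, 0.0),
                ("b", "c"): (0.0, 0.99),
                ("a", "d"): (np.nan, 0.0),
                ("b", "d"): (3.0, 0.0),
                ("c", "d"): (3.0, 0.0),
            }
        )
        meta = pd.DataFrame({"group": ["g"] * 4}, index=list("abcd"))
        cl = classify_pairs(bn, rc)
        fr = process_fractions(cl, meta)
        row = fr.iloc[0]
        assert row["n_pairs"] == 5 and row["n_undefined"] == 1
        assert row["variable_selection"] == pytest.approx(3 / 5)
        assert row["homogeneous_selection"] == pytest.approx(1 / 5)
        assert row["dispersal_limitation"] == pytest.approx(1 / 5)
        total = sum(row[label] for label in PROCESS_LABELS)
        assert total == pytest.approx(1.0)

    def test_between_group_pairs_excluded(self):
        bn, rc = make_results(
            {("a", "b"): (3.0, 0.0), ("a", "c"): (0.0, 0.0), ("b", "c"): (0.0, 0.0)}
        )
        meta = pd.DataFrame({"group": ["x", "x", "y"]}, index=list("abc"))
        fr = process_fractions(classify_pairs(bn, rc), meta)
        assert list(fr["group"]) == ["x"]
        assert fr.iloc[0]["n_pairs"] == 1


class TestEnvDifferenceMatrix:
    def test_hand_values(self):
        meta = pd.DataFrame({"group": ["g"] * 3, "pH": [1.0, 2.0, 4.0]},
                            index=list("abc"))
        dm = env_difference_matrix(meta, "pH")
        assert dm["a", "b"] == pytest.approx(1.0)
        assert dm["a", "c"] == pytest.approx(3.0)
        assert dm["b", "c"] == pytest.approx(2.0)

    def test_constant_variable_all_zero(self):
        meta = pd.DataFrame({"group": ["g"] * 3, "v": [2.0, 2.0, 2.0]},
                            index=list("abc"))
        assert np.allclose(env_difference_matrix(meta, "v").data, 0.0)

    def test_missing_values_drop_samples(self):
        meta = pd.DataFrame({"group": ["g"] * 3, "v": [1.0, np.nan, 2.0]},
                            index=list("abc"))
        dm = env_difference_matrix(meta, "v")
        assert set(dm.ids) == {"a", "c"}

    def test_all_missing_rejected(self):
        meta = pd.DataFrame({"group": ["g"], "v": [np.nan]}, index=["a"])
        with pytest.raises(ValueError):
            env_difference_matrix(meta, "v")


def random_distance_matrix(rng, n, ids=None):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return DistanceMatrix(m, ids=ids or [f"s{i}" for i in range(n)])


class TestMantel:
    def test_perfect_correlation(self, rng):
        a = random_distance_matrix(rng, 5)
        r, _ = mantel(a, a, permutations=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self, rng):
        a = random_distance_matrix(rng, 5)
        flipped = np.where(np.eye(5, dtype=bool), 0.0, a.data.max() - a.data)
        b = DistanceMatrix(flipped, ids=a.ids)
        r, _ = mantel(a, b, permutations=99, seed=0)
        assert r == pytest.approx(-1.0)

    def test_p_matches_full_enumeration(self, rng):
        a = random_distance_matrix(rng, 4)
        b = random_distance_matrix(rng, 4, ids=list(a.ids))
        va = squareform(a.data, checks=False)
        r_obs = stats.pearsonr(va, squareform(b.data, checks=False))[0]
        count = 0
        perms = list(itertools.permutations(range(4)))
        for p in perms:
            vp = squareform(b.data[np.ix_(p, p)], checks=False)
            if stats.pearsonr(va, vp)[0] >= r_obs:
                count += 1
        p_exact = count / len(perms)
        n_perm = 4999
        _, p_hat = mantel(a, b, permutations=n_perm, seed=77)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert p_hat == pytest.approx(p_exact, abs=max(3 * se, 2 / n_perm))

    def test_agrees_with_scikit_bio_statistic(self, rng):
        import skbio.stats.distance as skd

        a = random_distance_matrix(rng, 6)
        b = random_distance_matrix(rng, 6, ids=list(a.ids))
        r_ours, _ = mantel(a, b, permutations=9, seed=0)
        r_skb, _, _ = skd.mantel(a, b, method="pearson", permutations=0)
        assert r_ours == pytest.approx(r_skb)

    def test_rescaling_invariance(self, rng):
        a = random_distance_matrix(rng, 5)
        b = random_distance_matrix(rng, 5, ids=list(a.ids))
        scaled = DistanceMatrix(3.5 * b.data, ids=b.ids)
        r1, p1 = mantel(a, b, permutations=99, seed=3)
        r2, p2 = mantel(a, scaled, permutations=99, seed=3)
        assert r1 == pytest.approx(r2)
        assert p1 == pytest.approx(p2)

    def test_constant_matrix_rejected(self):
        a = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValueError):
            mantel(a, a, permutations=9, seed=0)


class TestPairwiseRegression:
    def test_exact_linear_relation(self, rng):
        x = random_distance_matrix(rng, 5)
        y = DistanceMatrix(2.0 * x.data, ids=x.ids)
        fit = pairwise_regression(x, y, permutations=99, seed=0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_underdetermined_rejected(self, rng):
        x = random_distance_matrix(rng, 2)
        with pytest.raises(ValueError):
            pairwise_regression(x, x, permutations=9, seed=0)

    def test_zero_variance_predictor_rejected(self, rng):
        x = DistanceMatrix(np.where(np.eye(4, dtype=bool), 0.0, 1.0),
                           ids=list("abcd"))
        y = random_distance_matrix(rng, 4, ids=list("abcd"))
        with pytest.raises(ValueError):
            pairwise_regression(x, y, permutations=9, seed=0)

    def test_null_p_values_roughly_uniform(self):
        # y unrelated to x: permutation p over independent datasets should
        # not concentrate near 0 (calibration sanity at light n)
        ps = []
        for s in range(30):
            rng = np.random.default_rng(1000 + s)
            x = random_distance_matrix(rng, 7)
            y = random_distance_matrix(rng, 7, ids=list(x.ids))
            ps.append(pairwise_regression(x, y, permutations=99, seed=s).p_permutation)
        assert 0.2 <= np.mean(ps) <= 0.8
        assert (np.array(ps) < 0.05).mean() <= 0.2
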
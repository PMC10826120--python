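"""Entropy, mutual information, interaction information and the T statistic.

Every estimator is checked against an independent brute-force log-sum
oracle written here in the plainest possible form.
"""

import itertools
import math

import numpy as np
import pytest

from epitrio import (
    StratifiedCounts,
    entropy,
    info_gain,
    interaction_information,
    lambda_variance,
    mutual_information,
    test_statistic as tig_statistic,
)


# ---------------------------------------------------------------- oracles
def oracle_entropy(counts):
    total = sum(counts)
    return -sum(c / total * math.log(c / total) for c in counts if c > 0)


def oracle_mi(table):
    table = np.asarray(table, float)
    n = table.sum()
    px = table.sum(axis=1) / n
    py = table.sum(axis=0) / n
    s = 0.0
    for i, j in itertools.product(range(table.shape[0]), range(table.shape[1])):
        p = table[i, j] / n
        if p > 0:
            s += p * math.log(p / (px[i] * py[j]))
    return s


def oracle_ii(joint3):
    """I(X;Y) - I(X;Y|Z), each term by direct summation."""
    f = np.asarray(joint3, float)
    n = f.sum()
    ixy = oracle_mi(f.sum(axis=2))
    ixy_given_z = 0.0
    for k in range(f.shape[2]):
        slab = f[:, :, k]
        if slab.sum() > 0:
            ixy_given_z += slab.sum() / n * oracle_mi(slab)
    return ixy - ixy_given_z


# ---------------------------------------------------------------- entropy/MI
def test_entropy_closed_forms():
    assert entropy(np.array([5, 5, 5])) == pytest.approx(math.log(3), abs=1e-12)
    assert entropy(np.array([0, 9, 0])) == 0.0
    expected = math.log(6) - (2 * math.log(2) + 3 * math.log(3)) / 6
    assert entropy(np.array([1, 2, 3])) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(1.011404, abs=5e-7)


def test_entropy_rejects_empty_table():
    with pytest.raises(ValueError, match="all-zero"):
        entropy(np.zeros(3))


def test_mi_zero_for_product_tables_and_h_for_diagonal():
    margins = np.array([4, 6, 10])
    product = np.outer(margins, margins)
    assert mutual_information(product) == pytest.approx(0.0, abs=1e-12)
    diag = np.diag([3, 5, 7])
    assert mutual_information(diag) == pytest.approx(
        entropy(np.array([3, 5, 7])), abs=1e-12
    )


def test_estimators_match_oracles_on_random_tables():
    rng = np.random.default_rng(21)
    for _ in range(200):
        t2 = rng.integers(0, 50, size=(3, 3))
        t2[0, 0] += 1
        assert mutual_information(t2) == pytest.approx(oracle_mi(t2), abs=1e-12)
        assert mutual_information(t2) >= -1e-12
        assert mutual_information(t2.T) == pytest.approx(
            mutual_information(t2), abs=1e-12
        )
        t3 = rng.integers(0, 30, size=(3, 3, 3))
        t3[0, 0, 0] += 1
        assert interaction_information(t3) == pytest.approx(oracle_ii(t3), abs=1e-12)


def test_interaction_information_is_exchangeable():
    rng = np.random.default_rng(22)
    t3 = rng.integers(1, 20, size=(3, 3, 3)).astype(float)
    ref = interaction_information(t3)
    for perm in itertools.permutations(range(3)):
        assert interaction_information(np.transpose(t3, perm)) == pytest.approx(
            ref, abs=1e-12
        )


def test_xor_table_scores_minus_log2():
    """Classic synergy: Z = X xor Y gives interaction information -ln 2."""
    xor = np.zeros((3, 3, 3))
    for x, y in itertools.product(range(2), range(2)):
        xor[x, y, x ^ y] = 25
    assert interaction_information(xor) == pytest.approx(-math.log(2), abs=1e-12)


def test_independent_margins_score_zero():
    a = np.array([2, 3, 5], float)
    joint = np.einsum("i,j,k->ijk", a, a, a)
    assert interaction_information(joint) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------- info gain
def _sc(case, ctrl, k=2):
    ids = tuple("abc"[:k])
    return StratifiedCounts(ids, case, ctrl)


def test_gain_zero_for_identical_strata_and_antisymmetric():
    rng = np.random.default_rng(23)
    t = rng.integers(1, 30, size=(3, 3, 3))
    assert info_gain(_sc(t, t, k=3)) == pytest.approx(0.0, abs=1e-12)
    u = rng.integers(1, 30, size=(3, 3, 3))
    assert info_gain(_sc(t, u, k=3)) == pytest.approx(
        -info_gain(_sc(u, t, k=3)), abs=1e-12
    )


def test_pooled_reference_mode():
    rng = np.random.default_rng(24)
    case = rng.integers(1, 30, size=(3, 3))
    ctrl = rng.integers(1, 30, size=(3, 3))
    sc = _sc(case, ctrl)
    expected = mutual_information(case) - mutual_information(case + ctrl)
    assert info_gain(sc, reference="pooled") == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------- Lambda & T
class TestLambda:
    def test_doubling_counts_halves_lambda(self):
        rng = np.random.default_rng(25)
        case = rng.integers(1, 40, size=(3, 3))
        ctrl = rng.integers(1, 40, size=(3, 3))
        for mode in ("null", "stratum"):
            lam1 = lambda_variance(_sc(case, ctrl), weights=mode)
            lam2 = lambda_variance(_sc(2 * case, 2 * ctrl), weights=mode)
            assert lam2 == pytest.approx(lam1 / 2, abs=1e-9)

    def test_degenerate_strata_hit_floor(self):
        case = np.zeros((3, 3))
        case[1, 1] = 50
        lam = lambda_variance(_sc(case, case))
        assert lam == pytest.approx(1e-12)

    def test_within_factor_two_of_bootstrap_variance(self):
        """Empirical check: Lambda tracks the resampling variance of the gain."""
        rng = np.random.default_rng(123)
        case = np.array([[30, 20, 10], [15, 40, 25], [10, 20, 30]])
        ctrl = np.array([[25, 25, 15], [20, 30, 20], [15, 25, 25]])
        pc, qc = case / case.sum(), ctrl / ctrl.sum()
        gains = []
        for _ in range(500):
            cb = rng.multinomial(case.sum(), pc.ravel()).reshape(3, 3)
            qb = rng.multinomial(ctrl.sum(), qc.ravel()).reshape(3, 3)
            gains.append(info_gain(_sc(cb, qb)))
        emp = np.var(gains)
        for mode in ("null", "stratum"):
            lam = lambda_variance(_sc(case, ctrl), weights=mode)
            assert emp / 2 < lam < emp * 2


class TestTestStatistic:
    def test_zero_gain_gives_p_one(self):
        t, p = tig_statistic(0.0, 1e-3)
        assert t == 0.0 and p == 1.0

    @pytest.mark.parametrize(
        "t_val,printed_p",
        [(8.25, 0.004), (7.47, 0.006), (8.53, 0.003), (6.74, 0.009)],
    )
    def test_chi_square_mapping_reproduces_published_pvalues(self, t_val, printed_p):
        """T referred to chi-square(1 df) matches the published triplet tables."""
        _, p = tig_statistic(math.sqrt(t_val), 1.0)
        assert round(p, 3) == printed_p

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            tig_statistic(0.1, 0.0)


def test_gain_scale_invariance_of_t():
    """T is invariant to expressing counts at a different sampling depth."""
    rng = np.random.default_rng(26)
    case = rng.integers(5, 40, size=(3, 3, 3))
    ctrl = rng.integers(5, 40, size=(3, 3, 3))
    sc = _sc(case, ctrl, k=3)
    g1, l1 = info_gain(sc), lambda_variance(sc)
    t1, _ = tig_statistic(g1, l1)
    assert t1 >= 0
    assert (t1 == 0) == (g1 == 0)
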
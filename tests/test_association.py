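import itertools
import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clrnet import (
    METHODS,
    association_matrix,
    kendall,
    mic,
    mutual_information,
    pearson,
    spearman,
    theil_sen_assoc,
    weighted_rank,
)

from conftest import random_expression

CORRELATION_FNS = {
    "pearson": pearson,
    "spearman": spearman,
    "kendall": kendall,
    "theil_sen": theil_sen_assoc,
    "weighted_rank": weighted_rank,
}

SCALAR_FNS = {**CORRELATION_FNS, "mutual_information": mutual_information, "mic": mic}


# ---------------------------------------------------------------------------
# hand-computed values


@pytest.mark.parametrize(
    "fn,x,y,expected",
    [
        (pearson, (1, 2, 3), (1, 2, 3), 1.0),
        (pearson, (1, 2, 3), (3, 2, 1), -1.0),
        (pearson, (1, 2, 3), (1, 3, 2), 0.5),
        (spearman, (1, 2, 3), (1, 3, 2), 0.5),
        (kendall, (1, 2, 3), (1, 3, 2), 1.0 / 3.0),
        (kendall, (1, 2, 3, 4), (1, 2, 3, 4), 1.0),
        (kendall, (1, 2, 3, 4), (4, 3, 2, 1), -1.0),
    ],
)
def test_hand_computed_correlations(fn, x, y, expected):
    assert fn(np.array(x, float), np.array(y, float)) == pytest.approx(expected)


def test_spearman_is_rank_invariant_under_exp():
    x = np.array([0.2, 1.4, 2.1, 3.3, 4.0])
    assert spearman(x, np.exp(x)) == pytest.approx(1.0)


@pytest.mark.parametrize("fn", list(CORRELATION_FNS.values()))
def test_zero_variance_profile_scores_zero(fn):
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert fn(x, np.full(4, 7.0)) == 0.0


@pytest.mark.parametrize("fn", list(SCALAR_FNS.values()))
def test_length_mismatch_is_hard_error(fn):
    with pytest.raises(ValueError, match="mismatch"):
        fn(np.arange(4.0), np.arange(5.0))


# ---------------------------------------------------------------------------
# Theil–Sen association vs brute-force slope enumeration


def _theil_sen_oracle(x, y):
    def std(v):
        sd = statistics.pstdev(v)
        return None if sd == 0 else [(t - statistics.fmean(v)) / sd for t in v]

    xs, ys = std(list(x)), std(list(y))
    if xs is None or ys is None:
        return 0.0

    def med_slope(a, b):
        slopes = [
            (b[j] - b[i]) / (a[j] - a[i])
            for i, j in itertools.combinations(range(len(a)), 2)
            if a[j] != a[i]
        ]
        return statistics.median(slopes) if slopes else None

    b_yx = med_slope(xs, ys)
    b_xy = med_slope(ys, xs)
    if b_yx is None or b_xy is None or b_yx * b_xy <= 0:
        return 0.0
    return math.copysign(min(1.0, math.sqrt(b_yx * b_xy)), b_yx)


def test_theil_sen_affine_relationship():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    assert theil_sen_assoc(x, 2 * x + 1) == pytest.approx(1.0)
    assert theil_sen_assoc(x, -x) == pytest.approx(-1.0)


def test_theil_sen_matches_exhaustive_slope_oracle(rng):
    for _ in range(60):
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        assert theil_sen_assoc(x, y) == pytest.approx(_theil_sen_oracle(x, y), abs=1e-12)


# ---------------------------------------------------------------------------
# weighted rank


def _weighted_rank_oracle(x, y):
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    m = len(x)
    w = [((m - a + 1) + (m - b + 1)) / 2 for a, b in zip(rx, ry)]
    ws = sum(w)
    mx = sum(wi * a for wi, a in zip(w, rx)) / ws
    my = sum(wi * b for wi, b in zip(w, ry)) / ws
    cov = sum(wi * (a - mx) * (b - my) for wi, a, b in zip(w, rx, ry))
    vx = sum(wi * (a - mx) ** 2 for wi, a in zip(w, rx))
    vy = sum(wi * (b - my) ** 2 for wi, b in zip(w, ry))
    return cov / math.sqrt(vx * vy)


def test_weighted_rank_perfect_agreement_and_reversal():
    x = np.array([3.0, 1.0, 4.0, 1.5, 5.0])
    assert weighted_rank(x, x * 2 + 1) == pytest.approx(1.0)
    assert weighted_rank(x, -x) == pytest.approx(-1.0)


def test_weighted_rank_matches_first_principles_oracle(rng):
    for _ in range(40):
        x = rng.standard_normal(5)
        y = rng.standard_normal(5)
        assert weighted_rank(x, y) == pytest.approx(_weighted_rank_oracle(x, y))


def test_weighted_rank_custom_weight_vector():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 3.0, 2.0, 4.0])
    # uniform weights reduce to plain Spearman
    assert weighted_rank(x, y, weights=np.ones(4)) == pytest.approx(spearman(x, y))


# ---------------------------------------------------------------------------
# mutual information


def test_mi_diagonal_two_bins_is_one_bit():
    x = np.array([1.0, 1.0, 2.0, 2.0])
    assert mutual_information(x, x, bins=2) == pytest.approx(1.0)


def test_mi_with_constant_profile_is_zero():
    x = np.arange(8.0)
    assert mutual_information(x, np.full(8, 3.0)) == 0.0


def test_mi_information_inequality(rng):
    def entropy(ix, bins):
        p = np.bincount(ix, minlength=bins) / len(ix)
        p = p[p > 0]
        return -(p * np.log2(p)).sum()

    from clrnet.association import _bin_indices

    for _ in range(30):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        bins = 5
        miv = mutual_information(x, y, bins=bins)
        hx = entropy(_bin_indices(x, bins), bins)
        hy = entropy(_bin_indices(y, bins), bins)
        assert -1e-12 <= miv <= min(hx, hy) + 1e-12


# ---------------------------------------------------------------------------
# MIC


def _mic_exhaustive_oracle(x, y, alpha=0.6):
    """Enumerate every grid placement with a·b ≤ B; the true optimum."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = len(x)
    B = max(m**alpha, 4.0)
    best = 0.0

    def cut_positions(v, parts):
        u = np.unique(v)
        gaps = [(u[i] + u[i + 1]) / 2 for i in range(len(u) - 1)]
        return itertools.combinations(gaps, parts - 1)

    for a in range(2, int(B) + 1):
        for b in range(2, int(B) // a + 1):
            for cx in cut_positions(x, a):
                ix = np.searchsorted(np.array(cx), x)
                for cy in cut_positions(y, b):
                    iy = np.searchsorted(np.array(cy), y)
                    joint = np.zeros((a, b))
                    np.add.at(joint, (ix, iy), 1.0)
                    joint /= m
                    px, py = joint.sum(1), joint.sum(0)
                    nz = joint > 0
                    info = float(
                        (joint[nz] * np.log2(joint[nz] / (px[:, None] * py[None, :])[nz])).sum()
                    )
                    best = max(best, info / np.log2(min(a, b)))
    return min(best, 1.0)


def test_mic_noiseless_monotone_relationship_is_one():
    x = np.linspace(0.0, 1.0, 100)
    assert mic(x, x**3 + x) == pytest.approx(1.0, abs=0.05)


def test_mic_constant_profile_is_zero():
    assert mic(np.arange(12.0), np.full(12, 1.0)) == 0.0


def test_mic_equals_exhaustive_oracle_on_structured_m12():
    # noiseless functional patterns: the optimal grid equipartitions an axis,
    # so the DP search attains the exhaustive optimum exactly
    x = np.arange(12.0)
    for y in (x, -x, np.repeat([0.0, 1.0], 6), np.tile([0.0, 1.0], 6)):
        assert mic(x, y) == pytest.approx(_mic_exhaustive_oracle(x, y), abs=1e-9)


def test_mic_never_exceeds_exhaustive_oracle(rng):
    # the DP restricts one axis to an equipartition, so it can only
    # undershoot the enumerate-everything optimum
    for _ in range(12):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        assert mic(x, y) <= _mic_exhaustive_oracle(x, y) + 1e-9


def test_mic_bounds(rng):
    for _ in range(20):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        assert 0.0 <= mic(x, y) <= 1.0


# ---------------------------------------------------------------------------
# matrix assembly


def test_association_matrix_composes_pairwise_calls(small_matrix):
    am = association_matrix(small_matrix, "pearson")
    v = small_matrix.values
    for i in range(6):
        for j in range(i + 1, 6):
            assert am.scores[i, j] == pytest.approx(pearson(v[i], v[j]), abs=1e-12)
    assert np.array_equal(am.scores, am.scores.T)
    assert np.all(np.diag(am.scores) == 0.0)


def test_association_matrix_unknown_method_lists_valid_names(small_matrix):
    with pytest.raises(ValueError, match="pearson.*spearman"):
        association_matrix(small_matrix, "nope")


@pytest.mark.parametrize("method", sorted(METHODS))
def test_association_matrix_permutation_equivariance(method, rng):
    m = random_expression(7, 15, seed=5)
    am = association_matrix(m, method)
    perm = rng.permutation(7)
    from clrnet import ExpressionMatrix

    pm = ExpressionMatrix(
        [m.gene_ids[i] for i in perm], m.sample_ids, m.values[perm]
    )
    pam = association_matrix(pm, method)
    np.testing.assert_allclose(pam.scores, am.scores[np.ix_(perm, perm)], atol=1e-12)


@pytest.mark.parametrize("method", ["spearman", "kendall", "weighted_rank", "mic"])
def test_rank_methods_invariant_under_increasing_transform(method, rng):
    m = random_expression(5, 20, seed=9)
    from clrnet import ExpressionMatrix

    tm = ExpressionMatrix(m.gene_ids, m.sample_ids, np.exp(m.values))
    np.testing.assert_allclose(
        association_matrix(tm, method).scores,
        association_matrix(m, method).scores,
        atol=1e-9,
    )


def test_pearson_consistency_on_bivariate_normal():
    rho = 0.6
    rng = np.random.default_rng(77)
    cov = [[1.0, rho], [rho, 1.0]]
    xy = rng.multivariate_normal([0, 0], cov, size=5000)
    assert abs(pearson(xy[:, 0], xy[:, 1]) - rho) < 0.05


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(
            st.floats(-50, 50, allow_nan=False), st.floats(-50, 50, allow_nan=False)
        ),
        min_size=5,
        max_size=25,
    )
)
def test_every_estimator_is_symmetric_and_bounded(data):
    x = np.array([a for a, _ in data])
    y = np.array([b for _, b in data])
    for name, fn in SCALAR_FNS.items():
        sxy, syx = fn(x, y), fn(y, x)
        assert sxy == pytest.approx(syx, abs=1e-9), name
        if name == "mutual_information":
            assert sxy >= -1e-12
        elif name == "mic":
            assert 0.0 <= sxy <= 1.0
        else:
            assert -1.0 <= sxy <= 1.0
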
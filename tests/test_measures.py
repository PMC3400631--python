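"""Dependency measures: baselines, the BIC-difference score, batch driver."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbomm import (
    FitConfig,
    UndefinedCorrelationError,
    dbomm,
    euclidean,
    kendall_tau,
    loglik_ratio,
    mi_from_contingency,
    mutual_information,
    pair_dependency,
    pearson,
    score_all_pairs,
)
from dbomm.gmm import n_free_params
from dbomm.simulate import make_pair


# ---------------------------------------------------------------- baselines

@pytest.mark.parametrize(
    "x,y,expected",
    [
        ((0, 0), (3, 4), 5.0),
        ((1, 2, 3), (1, 2, 3), 0.0),
        ((1, 2, 3), (2, 4, 1), 3.0),  # sqrt(1 + 4 + 4)
    ],
)
def test_euclidean(x, y, expected):
    assert euclidean(x, y) == pytest.approx(expected, abs=1e-12)


def test_euclidean_length_mismatch():
    with pytest.raises(ValueError):
        euclidean([1, 2], [1, 2, 3])


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ((1, 2, 3, 7), (3, 5, 7, 15), 1.0),       # y = 2x + 1
        ((1, 2, 3), (-1, -2, -3), -1.0),
        ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),
    ],
)
def test_pearson(x, y, expected):
    assert pearson(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_constant_profile_is_error():
    with pytest.raises(UndefinedCorrelationError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ((1, 2, 3), (1, 2, 3), 1.0),
        ((1, 2, 3), (3, 2, 1), -1.0),
        ((1, 2, 3), (1, 3, 2), 1.0 / 3.0),  # 2 concordant, 1 discordant pair
    ],
)
def test_kendall_tau(x, y, expected):
    assert kendall_tau(x, y) == pytest.approx(expected, abs=1e-12)


def test_kendall_all_tied_is_error():
    with pytest.raises(UndefinedCorrelationError):
        kendall_tau([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


# ------------------------------------------------------- mutual information

def test_mi_identical_binary_is_entropy():
    x = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
    assert mutual_information(x, x, bins=2) == pytest.approx(math.log(2), abs=1e-12)


def test_mi_product_table_is_zero():
    table = np.outer([3, 7, 2], [5, 1, 4])
    assert mi_from_contingency(table) == pytest.approx(0.0, abs=1e-12)


def test_mi_known_table():
    # brute-force value of [[4,1],[1,4]]: 0.8·ln1.6 + 0.2·ln0.4
    expected = 0.8 * math.log(1.6) + 0.2 * math.log(0.4)
    assert mi_from_contingency([[4, 1], [1, 4]]) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.192745, abs=1e-6)


def test_mi_constant_profile_is_zero():
    x = np.full(20, 5.0)
    y = np.arange(20.0)
    assert mutual_information(x, y) == 0.0


def _mi_brute_force(table):
    table = np.asarray(table, dtype=float)
    n = table.sum()
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    mi = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            p = table[i, j] / n
            if p > 0:
                mi += p * math.log(p / (row[i] * col[j]))
    return mi


@settings(derandomize=True, max_examples=100)
@given(
    st.lists(
        st.lists(st.integers(min_value=0, max_value=30), min_size=2, max_size=6),
        min_size=2,
        max_size=6,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1 and sum(map(sum, rows)) > 0)
)
def test_mi_matches_brute_force_double_sum(rows):
    table = np.array(rows, dtype=float)
    assert mi_from_contingency(table) == pytest.approx(
        _mi_brute_force(table), abs=1e-12
    )


# ----------------------------------------------------------- model-based

G1 = FitConfig(g_min=1, g_max=1)


@pytest.mark.parametrize("n,seed", [(20, 0), (100, 1), (500, 2)])
def test_dbomm_single_component_closed_form(n, seed):
    """With G forced to 1 the score is −n·ln(1−r̂²) − ln n."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = 0.6 * x + 0.8 * rng.standard_normal(n)
    r = np.corrcoef(x, y)[0, 1]
    expected = -n * math.log(1 - r * r) - math.log(n)
    assert dbomm(x, y, G1) == pytest.approx(expected, rel=1e-6)


def test_llr_single_component_closed_form():
    rng = np.random.default_rng(3)
    n = 200
    x = rng.standard_normal(n)
    y = 0.5 * x + rng.standard_normal(n)
    r = np.corrcoef(x, y)[0, 1]
    assert loglik_ratio(x, y, G1) == pytest.approx(-(n / 2) * math.log(1 - r * r), rel=1e-6)


def test_dbomm_llr_identity(fast_config):
    """dbomm == 2·llr − Δk·ln n under the shared fits."""
    rng = np.random.default_rng(4)
    x = rng.standard_normal(80)
    y = np.concatenate([x[:40] * 0.9, rng.standard_normal(40)])
    dep = pair_dependency(x, y, fast_config)
    dk = (
        dep.joint.n_params - dep.marginal_x.n_params - dep.marginal_y.n_params
    )
    assert dep.dbomm == pytest.approx(2 * dep.llr - dk * math.log(80), abs=1e-9)


def test_dbomm_symmetric_bit_exact(fast_config):
    x, y = make_pair("dependent", 60, 2, 0.7, seed=5)
    assert dbomm(x, y, fast_config) == dbomm(y, x, fast_config)


def test_llr_small_for_independent_gaussians():
    """G=1 llr is a half chi-square(1): rarely above 5."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        if loglik_ratio(x, y, G1) < 5.0:
            hits += 1
    assert hits >= 19


def test_dependent_pairs_score_above_independent(fast_config):
    dep, ind = [], []
    for i in range(25):
        x, y = make_pair("dependent", 100, 3, 0.8, seed=i)
        dep.append(dbomm(x, y, fast_config))
        x, y = make_pair("independent", 100, 3, 0.8, seed=1000 + i)
        ind.append(dbomm(x, y, fast_config))
    assert np.median(dep) > np.median(ind)
    assert np.mean(dep) > np.mean(ind) + 50


# ------------------------------------------------------------ batch driver

def test_score_all_pairs_delegates(small_expr):
    out = score_all_pairs(small_expr, [("g0", "g1")], "euc")
    assert out.scores[0] == pytest.approx(
        euclidean(small_expr.row("g0"), small_expr.row("g1"))
    )
    assert out.higher_is_dependent is False


def test_score_all_pairs_rejects_duplicates(small_expr):
    with pytest.raises(ValueError):
        score_all_pairs(small_expr, [("g0", "g1"), ("g1", "g0")], "euc")


def test_score_all_pairs_unknown_gene(small_expr):
    with pytest.raises(KeyError, match="nope"):
        score_all_pairs(small_expr, [("g0", "nope")], "euc")


def test_score_all_pairs_deterministic_and_order_independent(small_expr, fast_config):
    pairs = [(f"g{i}", f"g{j}") for i in range(5) for j in range(i + 1, 5)]
    a = score_all_pairs(small_expr, pairs, "dbomm", config=fast_config)
    b = score_all_pairs(small_expr, pairs, "dbomm", config=fast_config)
    assert np.array_equal(a.scores, b.scores)
    shuffled = pairs[::-1]
    c = score_all_pairs(small_expr, shuffled, "dbomm", config=fast_config)
    lookup = dict(zip([tuple(sorted(p)) for p in c.pairs], c.scores))
    for p, s in zip(a.pairs, a.scores):
        assert lookup[tuple(sorted(p))] == s


def test_correlation_transforms(small_expr):
    raw = score_all_pairs(small_expr, [("g2", "g3")], "cor")
    absd = score_all_pairs(small_expr, [("g2", "g3")], "cor", transform="abs")
    assert absd.scores[0] == pytest.approx(abs(raw.scores[0]))
    assert absd.higher_is_dependent is True


def test_dbomm_rank_stable_under_missing_conditions(fast_config):
    """Dropping 5% of conditions barely reorders a 20-pair score panel."""
    from scipy import stats

    pairs = []
    for i in range(10):
        pairs.append(make_pair("dependent", 100, 3, 0.8, seed=i))
        pairs.append(make_pair("independent", 100, 3, 0.8, seed=100 + i))
    rng = np.random.default_rng(0)
    keep = rng.choice(100, size=95, replace=False)
    full = [dbomm(x, y, fast_config) for x, y in pairs]
    sub = [dbomm(x[keep], y[keep], fast_config) for x, y in pairs]
    rho = stats.spearmanr(full, sub).statistic
    assert rho >= 0.8
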
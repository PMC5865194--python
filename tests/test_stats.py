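"""Spearman/S identities, exact Mann-Whitney, forest contrasts and calibration helpers."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from antcomp.stats import (
    evenness_contrast,
    forest_contrast,
    mann_whitney,
    rho_from_s,
    site_permutation_test,
    spearman,
)

# permutation of 1..17 built from disjoint swaps at distances 13,3,2,1,1:
# sum of squared rank differences = 2*(169+9+4+1+1) = 368
PERM_S368 = [14, 5, 3, 4, 2, 8, 7, 6, 10, 9, 12, 11, 13, 1, 15, 16, 17]


def test_identical_vectors_rho_one_s_zero():
    r = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
    assert r.rho == pytest.approx(1.0)
    assert r.S == 0.0


def test_reversed_ranks_n4_rho_minus_one():
    r = spearman([1, 2, 3, 4], [4, 3, 2, 1])
    assert r.S == 20.0
    assert r.rho == pytest.approx(-1.0)


def test_s368_n17_gives_rho_055():
    x = list(range(1, 18))
    r = spearman(x, PERM_S368)
    assert r.S == 368.0
    assert not r.ties
    assert round(r.rho, 2) == 0.55
    assert r.rho == pytest.approx(rho_from_s(368, 17))
    assert r.p < 0.05  # significant at the scale the design uses


def test_rho_from_s_no_ties_identity():
    rng = np.random.default_rng(0)
    for n in (5, 9, 14):
        y = rng.permutation(n) + 1
        x = np.arange(1, n + 1)
        r = spearman(x, y)
        assert r.rho == pytest.approx(rho_from_s(r.S, n))


@given(
    st.integers(4, 9).flatmap(
        lambda n: st.tuples(
            st.lists(st.floats(-50, 50), min_size=n, max_size=n),
            st.lists(st.floats(-50, 50), min_size=n, max_size=n),
        )
    )
)
@settings(deadline=None, derandomize=True, max_examples=30)
def test_spearman_equals_pearson_of_fractional_ranks(xy):
    x, y = xy
    from scipy.stats import rankdata
    rx, ry = rankdata(x), rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        assert spearman(x, y).degenerate
        return
    r = spearman(x, y)
    assert r.rho == pytest.approx(float(np.corrcoef(rx, ry)[0, 1]))
    assert r.S == pytest.approx(((rx - ry) ** 2).sum())


def test_exact_spearman_p_for_n3():
    # 6 permutations; |rho| >= 1 for exactly the 2 monotone ones
    r = spearman([1, 2, 3], [1, 2, 3])
    assert r.method == "exact"
    assert r.p == pytest.approx(2 / 6)


def test_constant_vector_flagged_degenerate():
    r = spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert r.degenerate and math.isnan(r.rho)


# ----------------------------------------------------------------- mann-whitney

def exact_mw_p(a, b):
    """Brute-force two-sided exact p: enumerate all C(n+m, n) group assignments."""
    from scipy.stats import rankdata
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = rankdata(pooled)
    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n * (n + 1) / 2
    u_obs = u_of(range(n))
    u_big = max(u_obs, n * m - u_obs)
    count = total = 0
    for comb in itertools.combinations(range(n + m), n):
        u = u_of(comb)
        total += 1
        if max(u, n * m - u) >= u_big - 1e-9:
            count += 1
    # matches the doubled one-tail definition of the exact test
    one_tail = sum(1 for comb in itertools.combinations(range(n + m), n)
                   if u_of(comb) >= u_big - 1e-9) / total
    return min(1.0, 2 * one_tail)


def test_identical_samples_p_near_one():
    r = mann_whitney([1.0, 2.5, 3.5, 4.0], [1.5, 2.0, 3.0, 4.5])
    assert r.p > 0.5


def test_complete_separation_smallest_attainable_p():
    r = mann_whitney([1, 2, 3], [10, 11, 12])
    assert r.statistic == 0.0
    assert r.p == pytest.approx(2 / 20)  # 2 / C(6,3): the two extreme assignments
    assert r.effect_direction == "b"


@pytest.mark.parametrize("seed", range(10))
def test_exact_p_matches_enumeration_fuzzed_n4(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=4)
    b = rng.normal(loc=rng.uniform(-1, 1), size=4)
    r = mann_whitney(a, b)
    assert r.method == "mann-whitney-exact"
    assert r.p == pytest.approx(exact_mw_p(a, b), abs=1e-12)


@pytest.mark.parametrize("n_a,n_b", [(3, 3), (3, 5), (5, 6), (6, 6)])
def test_exact_p_matches_enumeration_small_sizes(n_a, n_b):
    rng = np.random.default_rng(n_a * 10 + n_b)
    a, b = rng.normal(size=n_a), rng.normal(size=n_b)
    assert mann_whitney(a, b).p == pytest.approx(exact_mw_p(a, b), abs=1e-12)


def test_large_or_tied_samples_use_tie_corrected_normal():
    rng = np.random.default_rng(1)
    a = rng.integers(0, 4, size=20).astype(float)
    b = rng.integers(1, 5, size=20).astype(float)
    r = mann_whitney(a, b)
    assert r.method == "mann-whitney-asymptotic"
    assert 0 <= r.p <= 1


# --------------------------------------------------------------- forest contrast

def sim_forest(seed, site_sd=0.3, noise_sd=1.0, effect=0.0, n_sites=10, n_cards=9, family="continuous"):
    rng = np.random.default_rng(seed)
    rows = []
    for forest in ("primary", "logged"):
        shift = effect if forest == "primary" else 0.0
        for site in range(1, n_sites + 1):
            s = rng.normal(0, site_sd)
            for _ in range(n_cards):
                base = shift + s + rng.normal(0, noise_sd)
                if family == "count":
                    val = rng.poisson(math.exp(0.5 + base / 2))
                elif family == "binary":
                    val = float(rng.random() < 1 / (1 + math.exp(-base)))
                else:
                    val = base
                rows.append({"value": val, "forest": forest, "site": site})
    return pd.DataFrame(rows)


@pytest.mark.parametrize("family", ["continuous", "count", "binary"])
def test_direction_follows_forest_means(family):
    df = sim_forest(seed=0, effect=2.0, family=family)
    r = forest_contrast(df, family=family)
    assert r.effect_direction == "primary"
    assert r.p < 0.05


def test_doubling_counts_flips_direction():
    df = sim_forest(seed=3, family="count")
    df2 = df.copy()
    df2.loc[df2["forest"] == "logged", "value"] *= 2
    r = forest_contrast(df2, family="count")
    assert r.effect_direction == "logged"


def test_contrast_requires_both_forests_and_sites():
    df = sim_forest(seed=0)
    with pytest.raises(ValueError):
        forest_contrast(df[df["forest"] == "primary"], family="continuous")
    tiny = df[df["site"] <= 1]
    with pytest.raises(ValueError, match="2 sites"):
        forest_contrast(tiny, family="continuous")


def test_permutation_and_model_p_agree_in_rank_order():
    effects = [0.0, 0.8, 2.0]
    p_model, p_perm = [], []
    for e in effects:
        df = sim_forest(seed=11, effect=e)
        p_model.append(forest_contrast(df, family="continuous").p)
        p_perm.append(site_permutation_test(df, n_permutations=2000, seed=5).p)
    assert p_model == sorted(p_model, reverse=True)
    assert p_perm == sorted(p_perm, reverse=True)


def test_permutation_test_is_seed_deterministic():
    df = sim_forest(seed=2, effect=0.5)
    r1 = site_permutation_test(df, n_permutations=500, seed=7)
    r2 = site_permutation_test(df, n_permutations=500, seed=7)
    assert r1.p == r2.p


# ------------------------------------------------------------ evenness contrast

def test_constant_offset_recovered_by_linear_model():
    rng = np.random.default_rng(4)
    delta = 0.4
    df = pd.DataFrame(
        {
            "H_prime": np.concatenate([rng.normal(1.8, 0.2, 60), rng.normal(1.8 + delta, 0.2, 60)]),
            "forest": ["logged"] * 60 + ["primary"] * 60,
        }
    )
    r = evenness_contrast(df)
    est = r.group_means["primary"] - r.group_means["logged"]
    assert est == pytest.approx(delta, abs=0.15)
    assert r.effect_direction == "primary"


def test_null_evenness_p_large_on_average():
    ps = []
    rng = np.random.default_rng(8)
    for _ in range(40):
        df = pd.DataFrame(
            {
                "H_prime": rng.normal(2.0, 0.3, 80),
                "forest": ["primary"] * 40 + ["logged"] * 40,
            }
        )
        ps.append(evenness_contrast(df).p)
    assert np.mean(ps) > 0.35  # uniform-null mean is 0.5


def test_degenerate_constant_H_flagged():
    df = pd.DataFrame({"H_prime": [0.0] * 20, "forest": ["primary"] * 10 + ["logged"] * 10})
    r = evenness_contrast(df)
    assert not r.converged and "degenerate" in r.note


def test_evenness_needs_three_units_per_forest():
    df = pd.DataFrame({"H_prime": [1, 2, 3, 4], "forest": ["primary"] * 2 + ["logged"] * 2})
    with pytest.raises(ValueError):
        evenness_contrast(df)
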
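"""Scoring, pairwise matrices, score change and card metrics — with brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from antcomp import aggression as agg
from antcomp.dataset import EVENTS_COLUMNS

from conftest import random_events, tiny_dataset


# -------------------------------------------------------------------- classify

@pytest.mark.parametrize(
    "roles, category, scores",
    [
        (("neutral", "neutral"), "neutral", (1, 1)),
        (("aggressive", "submissive"), "competitive", (2, 0)),
        (("submissive", "aggressive"), "competitive", (0, 2)),
        (("aggressive", "aggressive"), "competitive", (2, 2)),
    ],
)
def test_classify_mapping(roles, category, scores):
    cat, sa, sb = agg.classify(*roles)
    assert (cat, sa, sb) == (category, *scores)


def test_classify_events_matches_scalar_classify():
    ev = random_events(seed=0, n_events=30)
    out = agg.classify_events(ev)
    for _, row in out.iterrows():
        cat, sa, sb = agg.classify(row["role_a"], row["role_b"])
        assert (row["category"], row["score_a"], row["score_b"]) == (cat, sa, sb)


# ---------------------------------------------------------- aggression matrix

def naive_matrix(classified: pd.DataFrame, min_partners: int):
    """Independent recomputation with explicit loops."""
    partners: dict[str, set] = {}
    for _, r in classified.iterrows():
        partners.setdefault(r["genus_a"], set()).add(r["genus_b"])
        partners.setdefault(r["genus_b"], set()).add(r["genus_a"])
    retained = sorted(g for g, p in partners.items() if len(p) >= min_partners)
    means, ns = {}, {}
    for i in retained:
        for j in retained:
            scores = []
            for _, r in classified.iterrows():
                if r["genus_a"] == i and r["genus_b"] == j:
                    scores.append(r["score_a"])
                elif r["genus_b"] == i and r["genus_a"] == j:
                    scores.append(r["score_b"])
            if scores:
                means[(i, j)] = sum(scores) / len(scores)
                ns[(i, j)] = len(scores)
    return retained, means, ns


def events_frame(rows):
    df = pd.DataFrame(
        [("p-cam", 1.0, a, b, ra, rb) for a, b, ra, rb in rows], columns=EVENTS_COLUMNS
    )
    return agg.classify_events(df)


def test_three_partner_genus_excluded_by_default_filter():
    rows = [("X", p, "aggressive", "submissive") for p in ("A", "B", "C")]
    for i, a in enumerate("ABCD"):
        for b in "ABCD"[i + 1:]:
            rows.append((a, b, "neutral", "neutral"))
    rows += [("X", "A", "neutral", "neutral")]  # X still has 3 distinct partners
    rows += [("D", "E", "neutral", "neutral")]  # D's 4th partner; E has only 1
    m = agg.aggression_matrix(events_frame(rows), "primary")
    assert "X" not in m.genera and "E" not in m.genera
    assert set("ABCD") <= set(m.genera)
    # A has partners B, C, D and X -> 4 distinct, retained
    assert m.partner_count["A"] == 4


def test_pairwise_mean_is_arithmetic_mean_of_scores():
    rows = [
        ("A", "B", "aggressive", "submissive"),
        ("A", "B", "aggressive", "submissive"),
        ("A", "B", "neutral", "neutral"),
    ]
    m = agg.aggression_matrix(events_frame(rows), "primary", min_partners=1)
    assert m.mean.loc["A", "B"] == pytest.approx(5 / 3)
    assert m.mean.loc["B", "A"] == pytest.approx(1 / 3)
    assert m.n.loc["A", "B"] == 3 == m.n.loc["B", "A"]


@pytest.mark.parametrize("seed", range(8))
def test_matrix_matches_naive_recomputation_on_fuzzed_events(seed):
    classified = agg.classify_events(random_events(seed, n_events=60, n_genera=7))
    for min_partners in (1, 3, 4):
        m = agg.aggression_matrix(classified, "primary", min_partners)
        retained, means, ns = naive_matrix(classified, min_partners)
        assert m.genera == retained
        for i in retained:
            for j in retained:
                if (i, j) in means:
                    assert m.mean.loc[i, j] == pytest.approx(means[(i, j)])
                    assert m.n.loc[i, j] == ns[(i, j)]
                else:
                    assert np.isnan(m.mean.loc[i, j])
                    assert m.n.loc[i, j] == 0


def test_filter_monotonicity():
    classified = agg.classify_events(random_events(3, n_events=80, n_genera=8))
    prev = None
    for mp in (1, 2, 3, 4, 5, 6):
        genera = set(agg.aggression_matrix(classified, "primary", mp).genera)
        if prev is not None:
            assert genera <= prev
        prev = genera


def test_n_matrix_symmetric_and_score_complementarity(rewired_dataset):
    classified = agg.classify_events(rewired_dataset.events_with_units("primary"))
    m = agg.aggression_matrix(classified, "primary")
    pd.testing.assert_frame_equal(m.n, m.n.T, check_names=False)
    # the generator never produces mutual aggression, so means are complementary
    both = m.mean.notna() & m.mean.T.notna()
    s = (m.mean + m.mean.T)[both]
    assert np.allclose(s.to_numpy()[both.to_numpy()], 2.0)


def test_empty_events_give_empty_matrix_with_warning():
    m = agg.aggression_matrix(agg.classify_events(pd.DataFrame(columns=EVENTS_COLUMNS)), "primary")
    assert m.genera == []
    assert m.warnings


# ---------------------------------------------------------------- score change

def matrix_from_cells(cells, genera, forest="primary"):
    mean = pd.DataFrame(np.nan, index=genera, columns=genera, dtype=float)
    n = pd.DataFrame(0, index=genera, columns=genera, dtype="int64")
    for (i, j), (mu, k) in cells.items():
        mean.loc[i, j] = mu
        n.loc[i, j] = k
        n.loc[j, i] = k
    return agg.AggressionMatrix(
        forest=forest, genera=list(genera), mean=mean, n=n,
        partner_count=pd.Series(1, index=list(genera)), min_partners=4,
    )


def test_identical_matrices_give_zero_change():
    cells = {("A", "B"): (1.5, 5), ("B", "A"): (0.5, 5), ("A", "C"): (2.0, 4), ("C", "A"): (0.0, 4)}
    mp = matrix_from_cells(cells, ["A", "B", "C"])
    ml = matrix_from_cells(cells, ["A", "B", "C"], "logged")
    ch = agg.score_change(mp, ml)
    defined = ch.delta.notna().to_numpy()
    assert defined.sum() == 4
    assert (ch.delta.to_numpy()[defined] == 0).all()
    assert ch.weighted_mean_delta["A"] == 0.0


def test_weighted_mean_of_plus1_w3_minus1_w1_is_half():
    # deltas +1 (pooled n=3) and -1 (pooled n=1) -> (3-1)/4 = +0.5
    mp = matrix_from_cells(
        {("A", "B"): (0.5, 2), ("A", "C"): (1.5, 1)}, ["A", "B", "C"]
    )
    ml = matrix_from_cells(
        {("A", "B"): (1.5, 1), ("A", "C"): (0.5, 0)}, ["A", "B", "C"], "logged"
    )
    ch = agg.score_change(mp, ml, min_pair_n=0)
    assert ch.delta.loc["A", "B"] == 1.0 and ch.delta.loc["A", "C"] == -1.0
    assert ch.weighted_mean_delta["A"] == pytest.approx(0.5)


def test_min_pair_n_applies_to_each_forest_separately():
    mp = matrix_from_cells({("A", "B"): (1.0, 5), ("A", "C"): (1.0, 2)}, ["A", "B", "C"])
    ml = matrix_from_cells({("A", "B"): (1.5, 2), ("A", "C"): (1.5, 5)}, ["A", "B", "C"], "logged")
    ch = agg.score_change(mp, ml, min_pair_n=3)
    assert ch.delta.isna().all().all()  # every cell fails in one forest


def test_disjoint_genus_sets_rejected():
    mp = matrix_from_cells({("A", "B"): (1.0, 5)}, ["A", "B"])
    ml = matrix_from_cells({("C", "D"): (1.0, 5)}, ["C", "D"], "logged")
    with pytest.raises(ValueError, match="disjoint"):
        agg.score_change(mp, ml)


@pytest.mark.parametrize("seed", range(6))
def test_weighted_means_match_naive_loop(seed):
    rng = np.random.default_rng(seed)
    genera = list("ABCDE")
    def random_matrix(forest):
        cells = {}
        for i in genera:
            for j in genera:
                if i != j and rng.random() < 0.7:
                    cells[(i, j)] = (float(rng.uniform(0, 2)), int(rng.integers(0, 8)))
        return matrix_from_cells(cells, genera, forest)
    mp, ml = random_matrix("primary"), random_matrix("logged")
    # symmetrise n (matrix_from_cells last-write wins; enforce invariant)
    sym = np.minimum(mp.n.to_numpy(), mp.n.to_numpy().T)
    mp.n.iloc[:, :] = sym
    sym = np.minimum(ml.n.to_numpy(), ml.n.to_numpy().T)
    ml.n.iloc[:, :] = sym
    for weighting in ("pooled", "min"):
        ch = agg.score_change(mp, ml, min_pair_n=2, weighting=weighting)
        for i in genera:
            num = den = 0.0
            for j in genera:
                if i == j:
                    continue
                n_p, n_l = mp.n.loc[i, j], ml.n.loc[i, j]
                if n_p >= 2 and n_l >= 2 and not np.isnan(mp.mean.loc[i, j]) and not np.isnan(ml.mean.loc[i, j]):
                    w = n_p + n_l if weighting == "pooled" else min(n_p, n_l)
                    num += w * (ml.mean.loc[i, j] - mp.mean.loc[i, j])
                    den += w
            if den > 0:
                assert ch.weighted_mean_delta[i] == pytest.approx(num / den)
            else:
                assert np.isnan(ch.weighted_mean_delta[i])


# ----------------------------------------------------------------- card metrics

def test_card_metrics_forced_arithmetic():
    events = [("p-cam", float(t), "Aa", "Bb", "aggressive", "submissive") for t in range(4)]
    events += [("p-cam", 10.0, "Aa", "Bb", "neutral", "neutral")]
    presences = [("p-cam", "Aa", 60), ("p-cam", "Bb", 40)]
    ds = tiny_dataset(events=events, presences=presences)
    cm = agg.card_metrics(ds, "primary")
    row = cm[cm["unit_id"] == "p-cam"].iloc[0]
    assert row["n_competitive"] == 4 and row["n_neutral"] == 1
    assert row["rate"] == pytest.approx(0.1)  # 4 / 40 min
    assert row["per_capita"] == pytest.approx(4 / 100)
    assert row["proportion_competitive"] == pytest.approx(0.8)


def test_card_with_no_interactions_has_zero_rate_and_missing_proportion():
    ds = tiny_dataset(presences=[("p-cam", "Aa", 50)])
    cm = agg.card_metrics(ds, "primary")
    row = cm[cm["unit_id"] == "p-cam"].iloc[0]
    assert row["rate"] == 0.0 and row["per_capita"] == 0.0
    assert np.isnan(row["proportion_competitive"])


def test_per_capita_missing_without_ants_and_numerator_modes():
    events = [("p-cam", 1.0, "Aa", "Bb", "neutral", "neutral"),
              ("p-cam", 2.0, "Aa", "Bb", "aggressive", "submissive")]
    ds = tiny_dataset(events=events)
    cm = agg.card_metrics(ds, "primary")
    assert np.isnan(cm[cm["unit_id"] == "p-cam"]["per_capita"].iloc[0])
    ds2 = tiny_dataset(events=events, presences=[("p-cam", "Aa", 10)])
    comp_mode = agg.card_metrics(ds2, "primary")
    all_mode = agg.card_metrics(ds2, "primary", per_capita_numerator="all")
    assert comp_mode[comp_mode["unit_id"] == "p-cam"]["per_capita"].iloc[0] == pytest.approx(0.1)
    assert all_mode[all_mode["unit_id"] == "p-cam"]["per_capita"].iloc[0] == pytest.approx(0.2)


def test_card_competitive_counts_conserve_forest_total(rewired_dataset):
    for forest in ("primary", "logged"):
        cm = agg.card_metrics(rewired_dataset, forest)
        classified = agg.classify_events(rewired_dataset.events_with_units(forest))
        assert cm["n_competitive"].sum() == (classified["category"] == "competitive").sum()
        assert len(cm) == 90  # all cards present, even empty ones


# ----------------------------------------------------------- interaction totals

def test_totals_partition_identity():
    ev = agg.classify_events(random_events(5, n_events=50))
    ev["forest"] = "primary"
    totals = agg.interaction_totals(ev)
    for _, row in totals.iterrows():
        assert row["n_total"] == row["n_competitive"] + row["n_neutral"]


def test_totals_empty_event_list_all_zero():
    totals = agg.interaction_totals(agg.classify_events(pd.DataFrame(columns=EVENTS_COLUMNS)))
    row = totals[totals["stratum"] == "overall"].iloc[0]
    assert (row[["n_total", "n_competitive", "n_neutral"]] == 0).all()
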
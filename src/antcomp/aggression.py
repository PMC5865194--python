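"""Aggression scoring, pairwise score matrices and per-card metrics.

Every genus-genus interaction gets a per-participant aggression score:
0 = submissive, 1 = neutral, 2 = aggressive.  An interaction is *neutral*
iff both participants were neutral; any aggression makes it *competitive*
(including mutual aggression, which real footage can contain even though a
clean dominance encounter has one aggressor and one submissive).

From scored events the module builds forest-specific pairwise mean-score
matrices over the genera that interacted with more than three other genera,
the between-forest score-change matrix (cells need at least ``min_pair_n``
events in each forest), sample-size-weighted per-genus mean changes, and
per-card competitive-interaction rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import Dataset, SESSION_MINUTES

__all__ = [
    "SCORE",
    "classify",
    "classify_events",
    "AggressionMatrix",
    "aggression_matrix",
    "ScoreChange",
    "score_change",
    "card_metrics",
    "interaction_totals",
    "genus_weighted_mean_scores",
]

SCORE = {"submissive": 0, "neutral": 1, "aggressive": 2}

#: Strictly-more-than-three-partners filter: keep genera seen interacting
#: with at least this many distinct other genera.
DEFAULT_MIN_PARTNERS = 4
#: A score-change cell needs at least this many events in each forest.
DEFAULT_MIN_PAIR_N = 3


def classify(role_a: str, role_b: str) -> tuple[str, int, int]:
    """Classify one interaction and score both participants.

    Returns ``(category, score_a, score_b)`` with category ``neutral`` iff
    both roles are neutral, else ``competitive``.
    """
    category = "neutral" if (role_a == "neutral" and role_b == "neutral") else "competitive"
    return category, SCORE[role_a], SCORE[role_b]


def classify_events(events: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`classify` over an events table.

    Adds ``category``, ``score_a`` and ``score_b`` columns; the input frame
    is not modified.
    """
    out = events.copy()
    if len(out) == 0:
        out["category"] = pd.Series(dtype=object)
        out["score_a"] = pd.Series(dtype="int64")
        out["score_b"] = pd.Series(dtype="int64")
        return out
    out["category"] = np.where(
        (out["role_a"] == "neutral") & (out["role_b"] == "neutral"), "neutral", "competitive"
    )
    out["score_a"] = out["role_a"].map(SCORE).astype("int64")
    out["score_b"] = out["role_b"].map(SCORE).astype("int64")
    return out


@dataclass
class AggressionMatrix:
    """Per-forest pairwise mean aggression scores with sample sizes.

    ``mean.loc[i, j]`` is the mean score genus *i* received over all its
    events against genus *j* (NaN when the pair was never observed);
    ``n.loc[i, j] == n.loc[j, i]`` is the event count for the pair.
    ``partner_count`` counts distinct interaction partners per retained
    genus, computed before the partner filter was applied.
    """

    forest: str
    genera: list[str]
    mean: pd.DataFrame
    n: pd.DataFrame
    partner_count: pd.Series
    min_partners: int
    warnings: list[str] = field(default_factory=list)


def _directed_scores(classified: pd.DataFrame) -> pd.DataFrame:
    """Long table with one row per (focal genus, partner genus, score)."""
    fwd = classified[["genus_a", "genus_b", "score_a"]].rename(
        columns={"genus_a": "genus", "genus_b": "partner", "score_a": "score"}
    )
    rev = classified[["genus_b", "genus_a", "score_b"]].rename(
        columns={"genus_b": "genus", "genus_a": "partner", "score_b": "score"}
    )
    return pd.concat([fwd, rev], ignore_index=True)


def aggression_matrix(
    classified_events: pd.DataFrame,
    forest: str,
    min_partners: int = DEFAULT_MIN_PARTNERS,
) -> AggressionMatrix:
    """Pairwise mean-score matrix for one forest's classified events.

    ``classified_events`` must already be restricted to the forest's camera
    events (see :meth:`antcomp.dataset.Dataset.events_with_units`) and carry
    the ``score_a``/``score_b`` columns from :func:`classify_events`.

    Genera are retained when they interacted with at least ``min_partners``
    distinct other genera (the default, 4, keeps genera with more than three
    partners); matrix cells cover retained-by-retained pairs only, with
    means over every event between the pair.
    """
    warnings = []
    if len(classified_events) == 0:
        warnings.append(f"{forest}: no events; empty matrix")
        empty = pd.DataFrame(dtype=float)
        return AggressionMatrix(
            forest=forest, genera=[], mean=empty, n=empty.astype("int64", errors="ignore"),
            partner_count=pd.Series(dtype="int64"), min_partners=min_partners, warnings=warnings,
        )
    directed = _directed_scores(classified_events)
    partners_all = directed.groupby("genus")["partner"].nunique()
    retained = sorted(partners_all.index[partners_all >= min_partners])
    sub = directed[directed["genus"].isin(retained) & directed["partner"].isin(retained)]

    mean = pd.DataFrame(np.nan, index=retained, columns=retained, dtype=float)
    n = pd.DataFrame(0, index=retained, columns=retained, dtype="int64")
    if len(sub):
        grp = sub.groupby(["genus", "partner"])["score"]
        mean_long = grp.mean()
        n_long = grp.size()
        for (g, p), v in mean_long.items():
            mean.loc[g, p] = v
        for (g, p), c in n_long.items():
            n.loc[g, p] = int(c)
    return AggressionMatrix(
        forest=forest,
        genera=list(retained),
        mean=mean,
        n=n,
        partner_count=partners_all.loc[retained].astype("int64"),
        min_partners=min_partners,
        warnings=warnings,
    )


@dataclass
class ScoreChange:
    """Between-forest aggression-score change over a shared genus set.

    ``delta.loc[i, j] = mean_logged[i, j] - mean_primary[i, j]`` where both
    forests have at least ``min_pair_n`` events for the pair, NaN elsewhere.
    ``weighted_mean_delta[i]`` averages row *i*'s defined deltas with
    weights ``w[i, j]`` (pooled pair sample sizes by default).
    """

    genera: list[str]
    delta: pd.DataFrame
    n_primary: pd.DataFrame
    n_logged: pd.DataFrame
    weighted_mean_delta: pd.Series
    min_pair_n: int
    weighting: str


def score_change(
    matrix_primary: AggressionMatrix,
    matrix_logged: AggressionMatrix,
    min_pair_n: int = DEFAULT_MIN_PAIR_N,
    weighting: str = "pooled",
) -> ScoreChange:
    """Score-change matrix and sample-size-weighted per-genus mean change.

    ``weighting`` selects the cell weights for the per-genus mean:
    ``"pooled"`` uses ``n_primary + n_logged`` (default), ``"min"`` uses
    ``min(n_primary, n_logged)``.
    """
    if weighting not in {"pooled", "min"}:
        raise ValueError(f"unknown weighting {weighting!r}")
    shared = sorted(set(matrix_primary.genera) & set(matrix_logged.genera))
    if not shared:
        raise ValueError("matrices have disjoint genus sets")
    mp = matrix_primary.mean.loc[shared, shared]
    ml = matrix_logged.mean.loc[shared, shared]
    np_ = matrix_primary.n.loc[shared, shared]
    nl = matrix_logged.n.loc[shared, shared]
    ok = (np_ >= min_pair_n) & (nl >= min_pair_n) & mp.notna() & ml.notna()
    delta = (ml - mp).where(ok)
    if weighting == "pooled":
        w = (np_ + nl).where(ok)
    else:
        w = np.minimum(np_, nl).where(ok)
    num = (delta * w).sum(axis=1, skipna=True)
    den = w.sum(axis=1, skipna=True)
    weighted = num.where(den > 0) / den.where(den > 0)
    return ScoreChange(
        genera=shared,
        delta=delta,
        n_primary=np_,
        n_logged=nl,
        weighted_mean_delta=weighted,
        min_pair_n=min_pair_n,
        weighting=weighting,
    )


def genus_weighted_mean_scores(matrix: AggressionMatrix) -> pd.Series:
    """Sample-size-weighted mean aggression score per genus.

    ``sum_j n[i,j] * mean[i,j] / sum_j n[i,j]`` — a genus's overall position
    in the observed dominance order of its forest.
    """
    if not matrix.genera:
        return pd.Series(dtype=float)
    w = matrix.n.where(matrix.mean.notna())
    num = (matrix.mean * w).sum(axis=1, skipna=True)
    den = w.sum(axis=1, skipna=True)
    return num.where(den > 0) / den.where(den > 0)


def card_metrics(
    dataset: Dataset,
    forest: str,
    per_capita_numerator: str = "competitive",
) -> pd.DataFrame:
    """Per-bait-card interaction metrics for one forest.

    One row per camera unit — including cards with no interactions, so that
    forest means average over all cards.  ``rate`` is competitive
    interactions per minute (count / 40); the raw per-session count is in
    ``n_per_session``.  ``per_capita`` divides by total ant abundance on the
    card (NaN when no ants were recorded); its numerator is competitive
    interactions by default, or all interactions with
    ``per_capita_numerator="all"``.  ``proportion_competitive`` is NaN for
    cards with no interactions at all.
    """
    if per_capita_numerator not in {"competitive", "all"}:
        raise ValueError(f"unknown per_capita_numerator {per_capita_numerator!r}")
    cards = dataset.camera_units(forest)
    ev = classify_events(dataset.events_with_units(forest))
    counts = (
        ev.groupby(["unit_id", "category"]).size().unstack(fill_value=0)
        if len(ev)
        else pd.DataFrame()
    )
    pres = dataset.presences[dataset.presences["unit_id"].isin(set(cards["unit_id"]))]
    ants = pres.groupby("unit_id")["abundance"].sum()

    out = cards[["unit_id", "site", "grid"]].copy().reset_index(drop=True)
    out["n_competitive"] = out["unit_id"].map(
        counts["competitive"] if "competitive" in counts else pd.Series(dtype=int)
    ).fillna(0).astype(int)
    out["n_neutral"] = out["unit_id"].map(
        counts["neutral"] if "neutral" in counts else pd.Series(dtype=int)
    ).fillna(0).astype(int)
    out["n_total_ants"] = out["unit_id"].map(ants).fillna(0).astype(int)
    out["n_per_session"] = out["n_competitive"]
    out["rate"] = out["n_competitive"] / SESSION_MINUTES
    numerator = (
        out["n_competitive"]
        if per_capita_numerator == "competitive"
        else out["n_competitive"] + out["n_neutral"]
    )
    out["per_capita"] = np.where(
        out["n_total_ants"] > 0, numerator / out["n_total_ants"].replace(0, np.nan), np.nan
    )
    total = out["n_competitive"] + out["n_neutral"]
    out["proportion_competitive"] = np.where(total > 0, out["n_competitive"] / total.replace(0, np.nan), np.nan)
    out["forest"] = forest
    return out


def interaction_totals(classified_events: pd.DataFrame) -> pd.DataFrame:
    """Interaction counts (total / competitive / neutral) per forest and overall.

    ``classified_events`` should carry a ``forest`` column (from
    :meth:`Dataset.events_with_units`) and the ``category`` column; counts
    always satisfy ``n_total = n_competitive + n_neutral`` per stratum.
    """
    rows = []
    if len(classified_events) and "forest" in classified_events.columns:
        for forest, grp in classified_events.groupby("forest"):
            rows.append(
                {
                    "stratum": forest,
                    "n_total": len(grp),
                    "n_competitive": int((grp["category"] == "competitive").sum()),
                    "n_neutral": int((grp["category"] == "neutral").sum()),
                }
            )
    n = len(classified_events)
    n_comp = int((classified_events["category"] == "competitive").sum()) if n else 0
    rows.append(
        {"stratum": "overall", "n_total": n, "n_competitive": n_comp, "n_neutral": n - n_comp}
    )
    return pd.DataFrame(rows, columns=["stratum", "n_total", "n_competitive", "n_neutral"])
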
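"""Community-composition metrics.

Occupancy (fraction of analysed sampling units a genus was recorded in, out
of 120 per forest in the canonical design), per-unit and mean genus
richness, Shannon diversity H' in nats, genus overlap between two
collections, and between-forest rank-occupancy comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy, rankdata

from .dataset import Dataset
from . import stats as _stats

__all__ = [
    "occupancy_table",
    "mean_richness",
    "shannon",
    "shannon_by_forest",
    "genus_overlap",
    "rank_occupancy_change",
    "OverlapSummary",
    "DiversityResult",
]

ANALYSED_METHODS = ("litter", "camera")


def _round_half_up_1dp(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class OverlapSummary:
    """Partition of a pooled genus list into shared and exclusive subsets."""

    n_total: int
    n_shared: int
    n_exclusive_a: int
    n_exclusive_b: int
    pct_shared: float
    pct_exclusive_a: float
    pct_exclusive_b: float


@dataclass
class DiversityResult:
    forest: str
    H_prime: float
    richness: int
    mean_richness: Optional[float] = None
    per_unit: Optional[pd.DataFrame] = None  # unit_id, richness (and H_prime in unit mode)
    level: str = "pooled"


def occupancy_table(
    dataset: Dataset,
    forest: str,
    methods: Iterable[str] = ANALYSED_METHODS,
) -> pd.DataFrame:
    """Occupancy of every genus observed in ``forest``, ranked.

    The denominator is the number of analysed units in that forest (litter +
    camera; human-observed cards never count).  Duplicate presence rows
    within a unit count once — presence is a set.  Rank 1 is the highest
    occupancy; ties get fractional (average) ranks.
    """
    units = dataset.units[
        (dataset.units["forest"] == forest) & dataset.units["method"].isin(list(methods))
    ]
    n_units = len(units)
    if n_units == 0:
        raise ValueError(f"no analysed units in forest {forest!r}")
    pres = dataset.presences[dataset.presences["unit_id"].isin(set(units["unit_id"]))]
    occ = (
        pres[["unit_id", "genus"]]
        .drop_duplicates()
        .groupby("genus", sort=True)
        .size()
        .rename("n_occupied")
        .reset_index()
    )
    occ["forest"] = forest
    occ["n_units"] = n_units
    occ["occupancy"] = occ["n_occupied"] / n_units
    occ["rank"] = rankdata(-occ["occupancy"].to_numpy(), method="average")
    occ = occ.sort_values(["rank", "genus"], kind="mergesort").reset_index(drop=True)
    return occ[["genus", "forest", "n_occupied", "n_units", "occupancy", "rank"]]


def mean_richness(dataset: Dataset, forest: str) -> DiversityResult:
    """Mean per-unit genus richness over all analysed units of a forest.

    Units with no presence records contribute richness 0; the mean is over
    all analysed units, not just occupied ones.  The per-unit vector is
    returned for downstream model fitting.
    """
    units = dataset.analysed_units(forest)
    if len(units) == 0:
        raise ValueError(f"no analysed units in forest {forest!r}")
    pres = dataset.presences[dataset.presences["unit_id"].isin(set(units["unit_id"]))]
    counts = (
        pres[["unit_id", "genus"]].drop_duplicates().groupby("unit_id").size().rename("richness")
    )
    per_unit = units[["unit_id", "site", "grid", "method"]].copy()
    per_unit["richness"] = per_unit["unit_id"].map(counts).fillna(0).astype(int)
    pooled = pres.groupby("genus")["abundance"].sum()
    return DiversityResult(
        forest=forest,
        H_prime=shannon(pooled.to_numpy()) if len(pooled) else 0.0,
        richness=int(pres["genus"].nunique()),
        mean_richness=float(per_unit["richness"].mean()),
        per_unit=per_unit.reset_index(drop=True),
        level="pooled",
    )


def shannon(counts: Sequence[float]) -> float:
    """Shannon diversity H' = -sum p_i ln p_i (nats) of an abundance vector.

    Zeros are ignored; an all-zero (or empty) vector raises ``ValueError``.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or not (arr > 0).any():
        raise ValueError("shannon requires at least one positive count")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return float(entropy(arr[arr > 0]))


def shannon_by_forest(dataset: Dataset, forest: str, level: str = "pooled") -> DiversityResult:
    """Shannon diversity for one forest.

    ``level="pooled"`` computes H' on abundance pooled over all analysed
    units; ``level="unit"`` computes H' per unit (0 for units with fewer
    than two genera) and reports the mean, returning the per-unit vector.
    """
    units = dataset.analysed_units(forest)
    if len(units) == 0:
        raise ValueError(f"no analysed units in forest {forest!r}")
    pres = dataset.presences[dataset.presences["unit_id"].isin(set(units["unit_id"]))].copy()
    pres["abundance"] = pd.to_numeric(pres["abundance"])
    richness = int(pres["genus"].nunique())
    if level == "pooled":
        pooled = pres.groupby("genus")["abundance"].sum()
        h = shannon(pooled.to_numpy()) if len(pooled) else 0.0
        return DiversityResult(forest=forest, H_prime=h, richness=richness, level="pooled")
    if level != "unit":
        raise ValueError(f"unknown level {level!r}")
    per_unit = units[["unit_id", "site", "grid", "method"]].copy()
    h_by_unit = {}
    for uid, grp in pres.groupby("unit_id"):
        counts = grp.groupby("genus")["abundance"].sum().to_numpy()
        h_by_unit[uid] = shannon(counts) if (counts > 0).any() else 0.0
    per_unit["H_prime"] = per_unit["unit_id"].map(h_by_unit).fillna(0.0)
    return DiversityResult(
        forest=forest,
        H_prime=float(per_unit["H_prime"].mean()),
        richness=richness,
        per_unit=per_unit.reset_index(drop=True),
        level="unit",
    )


def genus_overlap(genera_a: set[str], genera_b: set[str]) -> OverlapSummary:
    """Shared / exclusive partition of two genus sets, percentages to 1 dp.

    ``n_shared + n_exclusive_a + n_exclusive_b = n_total`` always; each
    percentage is ``100 * count / n_total`` rounded half-up to one decimal.
    """
    a, b = set(genera_a), set(genera_b)
    if not a or not b:
        raise ValueError("both genus sets must be non-empty")
    shared = a & b
    only_a = a - b
    only_b = b - a
    total = len(a | b)
    return OverlapSummary(
        n_total=total,
        n_shared=len(shared),
        n_exclusive_a=len(only_a),
        n_exclusive_b=len(only_b),
        pct_shared=_round_half_up_1dp(100.0 * len(shared) / total),
        pct_exclusive_a=_round_half_up_1dp(100.0 * len(only_a) / total),
        pct_exclusive_b=_round_half_up_1dp(100.0 * len(only_b) / total),
    )


def rank_occupancy_change(
    table_primary: pd.DataFrame,
    table_logged: pd.DataFrame,
    genera: Optional[set[str]] = None,
) -> tuple[pd.DataFrame, "_stats.CorrelationResult", list[str]]:
    """Paired rank-occupancy comparison between forests for a genus subset.

    Ranks are recomputed within the compared subset (fractional ranking) so
    the two rank vectors are directly comparable, and the Spearman
    correlation of the paired ranks is computed by the stats module.  Genera
    missing from either table are excluded with a warning.

    Returns ``(table, correlation, warnings)`` where the table has one row
    per genus: rank_primary, rank_logged, occupancy in each forest, and
    ``delta_occupancy = occupancy_logged - occupancy_primary``.
    """
    tp = table_primary.set_index("genus")
    tl = table_logged.set_index("genus")
    if genera is None:
        genera = set(tp.index) & set(tl.index)
    warnings = []
    usable = []
    for g in sorted(genera):
        if g not in tp.index or g not in tl.index:
            warnings.append(f"genus {g!r} missing from one forest; excluded")
        else:
            usable.append(g)
    if len(usable) < 2:
        raise ValueError("need at least two genera present in both forests")
    occ_p = tp.loc[usable, "occupancy"].to_numpy(dtype=float)
    occ_l = tl.loc[usable, "occupancy"].to_numpy(dtype=float)
    out = pd.DataFrame(
        {
            "genus": usable,
            "rank_primary": rankdata(-occ_p, method="average"),
            "rank_logged": rankdata(-occ_l, method="average"),
            "occupancy_primary": occ_p,
            "occupancy_logged": occ_l,
            "delta_occupancy": occ_l - occ_p,
        }
    )
    corr = _stats.spearman(out["rank_primary"].to_numpy(), out["rank_logged"].to_numpy())
    return out.sort_values("rank_primary", kind="mergesort").reset_index(drop=True), corr, warnings
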
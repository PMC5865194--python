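"""Synthetic bait-card surveys with a latent dominance hierarchy.

The generator emulates the logical structure of a two-forest litter-ant
survey: per forest, 10 sites x 3 grids, each grid contributing one pooled
leaf-litter unit and three 40-minute camera bait-card sessions (30 litter +
90 camera = 120 analysed units per forest).

Generative model
----------------
For genus ``g`` in forest ``f``:

* litter presence per pooled bag:  Bernoulli(``p_litter[g, f]``)
* camera-card presence:            Bernoulli(1 - exp(-``lambda_arrival[g, f]``))
  (a genus is seen iff at least one Poisson arrival occurs in the session)
* abundance given presence:        1 + Poisson(``mu_abundance[g, f]``)
* first arrival time:              Uniform(0, 40) minutes; arrival order is
  the rank of those times within the card

For each unordered pair of co-present genera ``(i, j)`` on a card the number
of encounters is Poisson(``eta``) (optionally scaled by the smaller of the
two abundances).  An encounter is neutral/neutral with probability
``p_neutral``; otherwise genus ``i`` is the aggressor with probability
``logistic(beta * (d[i, f] - d[j, f]))``, the other participant submissive.
Dominance values ``d`` are the latent hierarchy; a habitat shuffle of ``d``
re-wires who dominates whom without touching occupancy parameters.

Mutual aggression is never generated — every competitive encounter has
exactly one aggressor and one submissive — although the I/O layer accepts
mutual-aggression rows from real footage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import rankdata

from .dataset import (
    ARRIVALS_COLUMNS,
    Dataset,
    EVENTS_COLUMNS,
    FORESTS,
    GENERA_COLUMNS,
    N_CAMERA_POINTS_PER_GRID,
    N_GRIDS_PER_SITE,
    N_SITES_PER_FOREST,
    PRESENCES_COLUMNS,
    SESSION_MINUTES,
    TIME_SLOTS,
    UNITS_COLUMNS,
    unit_id,
)

__all__ = [
    "SyntheticParams",
    "Scenario",
    "generate_dataset",
    "shuffle_hierarchy",
    "reference_scenarios",
    "community_params",
]


@dataclass
class SyntheticParams:
    """Parameters of the generative model.

    Per-genus, per-forest arrays are DataFrames indexed by genus name with
    one column per forest (``primary``, ``logged``).
    """

    genera: tuple[str, ...]
    p_litter: pd.DataFrame        # Bernoulli presence probability per pooled bag
    lambda_arrival: pd.DataFrame  # Poisson arrival rate per 40-min card
    mu_abundance: pd.DataFrame    # mean extra workers per arriving genus
    dominance: pd.DataFrame       # latent dominance value d[g, f]
    beta: float = 2.0             # dominance-contrast slope of the logistic outcome
    p_neutral: float = 0.735      # probability an encounter is neutral
    eta: float = 0.15             # encounters per co-present pair per card
    seed: int = 0
    encounters_scale_with_abundance: bool = False
    size_class: Optional[pd.Series] = None

    def validate(self) -> "SyntheticParams":
        names = pd.Index(self.genera)
        if len(names) == 0:
            raise ValueError("at least one genus required")
        if names.has_duplicates or (names.astype(str).str.len() == 0).any():
            raise ValueError("genus names must be unique and non-empty")
        for label, df in (
            ("p_litter", self.p_litter),
            ("lambda_arrival", self.lambda_arrival),
            ("mu_abundance", self.mu_abundance),
            ("dominance", self.dominance),
        ):
            if not names.isin(df.index).all() or not set(FORESTS) <= set(df.columns):
                raise ValueError(f"{label} must be indexed by every genus with columns {FORESTS}")
            vals = df.loc[list(names), list(FORESTS)].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ValueError(f"{label} contains non-finite values")
        if ((self.p_litter < 0) | (self.p_litter > 1)).to_numpy().any():
            raise ValueError("p_litter must lie in [0, 1]")
        if (self.lambda_arrival < 0).to_numpy().any():
            raise ValueError("lambda_arrival must be >= 0")
        if (self.mu_abundance <= 0).to_numpy().any():
            raise ValueError("mu_abundance must be > 0")
        if not (self.beta > 0):
            raise ValueError("beta must be > 0")
        if not (0.0 <= self.p_neutral <= 1.0):
            raise ValueError("p_neutral must lie in [0, 1]")
        if not (self.eta >= 0):
            raise ValueError("eta must be >= 0")
        return self


@dataclass
class Scenario:
    name: str
    params: SyntheticParams
    description: str


def _canonical_units() -> pd.DataFrame:
    """Unit table for the canonical two-forest design (no human-observed cards)."""
    rows = []
    for forest in FORESTS:
        for site in range(1, N_SITES_PER_FOREST + 1):
            for grid in range(1, N_GRIDS_PER_SITE + 1):
                slot = TIME_SLOTS[grid - 1]
                rows.append(
                    {
                        "unit_id": unit_id(forest, site, grid, "litter"),
                        "forest": forest,
                        "site": site,
                        "grid": grid,
                        "method": "litter",
                        "time_slot": slot,
                        "point_index": pd.NA,
                    }
                )
                for point in range(1, N_CAMERA_POINTS_PER_GRID + 1):
                    rows.append(
                        {
                            "unit_id": unit_id(forest, site, grid, "camera", point),
                            "forest": forest,
                            "site": site,
                            "grid": grid,
                            "method": "camera",
                            "time_slot": slot,
                            "point_index": point,
                        }
                    )
    units = pd.DataFrame(rows, columns=UNITS_COLUMNS)
    units["point_index"] = units["point_index"].astype("Int64")
    return units


def generate_dataset(params: SyntheticParams) -> Dataset:
    """Sample one complete survey dataset from the generative model.

    Deterministic: identical ``params`` (including ``seed``) give a
    bit-identical dataset.  Each sampling unit draws from its own RNG
    sub-stream spawned from the master seed, so regenerating a subset of
    units reproduces them exactly.
    """
    params.validate()
    genera = list(params.genera)
    n = len(genera)
    units = _canonical_units()

    root = np.random.SeedSequence(params.seed)
    children = root.spawn(len(units))

    p_litter = {f: params.p_litter.loc[genera, f].to_numpy(dtype=float) for f in FORESTS}
    lam = {f: params.lambda_arrival.loc[genera, f].to_numpy(dtype=float) for f in FORESTS}
    mu = {f: params.mu_abundance.loc[genera, f].to_numpy(dtype=float) for f in FORESTS}
    dom = {f: params.dominance.loc[genera, f].to_numpy(dtype=float) for f in FORESTS}

    presence_rows: list[tuple] = []
    arrival_rows: list[tuple] = []
    event_rows: list[tuple] = []

    for (_, unit), child in zip(units.iterrows(), children):
        rng = np.random.default_rng(child)
        uid, forest, method = unit["unit_id"], unit["forest"], unit["method"]
        if method == "litter":
            present = rng.random(n) < p_litter[forest]
            for gi in np.flatnonzero(present):
                presence_rows.append((uid, genera[gi], 1))
            continue

        # camera bait card
        present = rng.random(n) < -np.expm1(-lam[forest])
        idx = np.flatnonzero(present)
        if idx.size == 0:
            continue
        abundance = 1 + rng.poisson(mu[forest][idx])
        times = rng.uniform(0.0, SESSION_MINUTES, size=idx.size)
        order = rankdata(times, method="ordinal").astype(int)
        for k, gi in enumerate(idx):
            presence_rows.append((uid, genera[gi], int(abundance[k])))
            arrival_rows.append((uid, genera[gi], float(times[k]), int(order[k])))

        d_f = dom[forest]
        for a in range(idx.size):
            for b in range(a + 1, idx.size):
                gi, gj = idx[a], idx[b]
                rate = params.eta
                if params.encounters_scale_with_abundance:
                    rate = params.eta * min(abundance[a], abundance[b])
                n_enc = rng.poisson(rate)
                for _ in range(n_enc):
                    t = float(rng.uniform(0.0, SESSION_MINUTES))
                    if rng.random() < params.p_neutral:
                        roles = ("neutral", "neutral")
                    elif rng.random() < expit(params.beta * (d_f[gi] - d_f[gj])):
                        roles = ("aggressive", "submissive")
                    else:
                        roles = ("submissive", "aggressive")
                    event_rows.append((uid, t, genera[gi], genera[gj], roles[0], roles[1]))

    presences = pd.DataFrame(presence_rows, columns=PRESENCES_COLUMNS)
    arrivals = pd.DataFrame(arrival_rows, columns=ARRIVALS_COLUMNS)
    events = pd.DataFrame(event_rows, columns=EVENTS_COLUMNS)
    if presences.empty:
        presences = presences.astype({"abundance": "int64"}, errors="ignore")
    genera_table = pd.DataFrame(
        {
            "genus": genera,
            "size_class": (
                params.size_class.reindex(genera).to_numpy()
                if params.size_class is not None
                else [pd.NA] * n
            ),
        },
        columns=GENERA_COLUMNS,
    )
    return Dataset(
        units=units,
        presences=presences,
        arrivals=arrivals,
        events=events,
        genera=genera_table,
    ).validate()


def shuffle_hierarchy(params: SyntheticParams, k: int, seed: int) -> SyntheticParams:
    """Re-wire the logged-forest hierarchy by permuting ``k`` dominance values.

    The logged column is reset to the primary column, then ``k`` randomly
    chosen genera have their dominance values permuted among themselves with
    a non-identity permutation (for ``k = 2`` this is exactly one swap).
    Occupancy, arrival and abundance parameters are untouched, as is the
    primary-forest hierarchy.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (a permutation of fewer than 2 values is a no-op)")
    if k > len(params.genera):
        raise ValueError(f"k={k} exceeds the number of genera ({len(params.genera)})")
    rng = np.random.default_rng(seed)
    genera = list(params.genera)
    chosen = rng.choice(len(genera), size=k, replace=False)
    perm = rng.permutation(k)
    while np.array_equal(perm, np.arange(k)):
        perm = rng.permutation(k)
    dominance = params.dominance.copy()
    d_logged = dominance.loc[genera, "primary"].to_numpy(dtype=float).copy()
    d_logged[chosen] = d_logged[chosen[perm]]
    dominance.loc[genera, "logged"] = d_logged
    return dataclasses.replace(params, dominance=dominance)


# --------------------------------------------------------------------------
# Reference community and named scenarios
# --------------------------------------------------------------------------

# 54 ground-dwelling Bornean litter-ant genera.  19 occur in both litter and
# bait-card samples, 3 only at baits, 32 only in litter — matching the
# collection-method split typical of combined Winkler + bait surveys.
GENERA_BOTH = (
    "Odontoponera", "Pheidole", "Lophomyrmex", "Nylanderia", "Diacamma",
    "Acanthomyrmex", "Pheidologeton", "Myrmicaria", "Polyrhachis", "Camponotus",
    "Odontomachus", "Oecophylla", "Crematogaster", "Dolichoderus", "Technomyrmex",
    "Tapinoma", "Monomorium", "Leptogenys", "Anoplolepis",
)
GENERA_BAIT_ONLY = ("Anochetus", "Tetraponera", "Philidris")
GENERA_LITTER_ONLY = (
    "Hypoponera", "Strumigenys", "Carebara", "Pachycondyla", "Ponera",
    "Pristomyrmex", "Recurvidris", "Gnamptogenys", "Mystrium", "Proceratium",
    "Discothyrea", "Platythyrea", "Centromyrmex", "Cryptopone", "Myrmoteras",
    "Paratrechina", "Pseudolasius", "Acropyga", "Euprenolepis", "Echinopla",
    "Meranoplus", "Myrmecina", "Vollenhovia", "Calyptomyrmex", "Dacetinops",
    "Lordomyrma", "Mayriella", "Rhoptromyrmex", "Cerapachys", "Aenictus",
    "Dorylus", "Tetramorium",
)
ALL_GENERA = GENERA_BOTH + GENERA_BAIT_ONLY + GENERA_LITTER_ONLY
INTERACTING_GENERA = GENERA_BOTH + GENERA_BAIT_ONLY  # the 22 bait-visiting genera

_LARGE_GENERA = {"Odontomachus", "Oecophylla", "Diacamma", "Polyrhachis", "Camponotus", "Leptogenys", "Platythyrea", "Pachycondyla"}
_MEDIUM_GENERA = {"Odontoponera", "Myrmicaria", "Dolichoderus", "Anoplolepis", "Gnamptogenys", "Anochetus", "Tetraponera", "Centromyrmex", "Echinopla", "Cerapachys", "Dorylus", "Mystrium"}


def _per_forest_frame(genera, primary, logged) -> pd.DataFrame:
    return pd.DataFrame({"primary": primary, "logged": logged}, index=list(genera))


def community_params(seed: int = 42, dense_interactions: bool = False) -> SyntheticParams:
    """Build field-realistic parameters for the 54-genus reference community.

    Default (sparse) mode mirrors the observed scale of a real survey: most
    genera rare, a handful of dominant recruiters common, roughly
    three-quarters of encounters neutral, and fewer bait visits in logged
    than in primary forest.

    ``dense_interactions`` switches to a densely sampled design used for
    parameter-recovery checks: the 17 most frequent bait-visiting genera get
    high arrival and encounter rates (>= 30 expected encounters per frequent
    pair over 90 cards) and an evenly spread dominance ladder; the other
    bait genera are dropped from the cards.
    """
    rng = np.random.default_rng(seed)
    genera = ALL_GENERA
    n = len(genera)
    is_litter = np.array([g not in GENERA_BAIT_ONLY for g in genera])
    is_bait = np.array([g in INTERACTING_GENERA for g in genera])

    # Litter occupancy: right-skewed, most genera occupy few bags.
    p_lit_primary = np.where(is_litter, rng.beta(0.8, 3.5, size=n), 0.0)
    p_lit_primary = np.clip(p_lit_primary, 0.0, 0.9)
    p_lit_logged = np.clip(p_lit_primary * rng.lognormal(-0.15, 0.6, size=n), 0.0, 0.9)

    # Bait-card arrival rates: log-normal, more activity in primary forest.
    lam_primary = np.where(is_bait, np.clip(rng.lognormal(np.log(0.35), 1.0, size=n), 0.02, 3.0), 0.0)
    lam_logged = lam_primary * rng.lognormal(-0.45, 0.5, size=n)

    # Habitat exclusives: some genera never recorded in one forest.
    litter_only_idx = np.flatnonzero(~is_bait)
    excl_primary = rng.choice(litter_only_idx, size=10, replace=False)
    remaining = np.setdiff1d(litter_only_idx, excl_primary)
    excl_logged = rng.choice(remaining, size=7, replace=False)
    p_lit_logged[excl_primary] = 0.0
    lam_logged[excl_primary] = 0.0
    p_lit_primary[excl_logged] = 0.0
    lam_primary[excl_logged] = 0.0
    # exclusives get a floor so they are actually observed somewhere
    p_lit_primary[excl_primary] = np.maximum(p_lit_primary[excl_primary], 0.15)
    p_lit_logged[excl_logged] = np.maximum(p_lit_logged[excl_logged], 0.15)

    mu = np.clip(rng.lognormal(np.log(3.0), 1.0, size=n), 0.2, 30.0)
    d_primary = np.where(is_bait, rng.normal(0.0, 1.0, size=n), 0.0)

    p_neutral, eta, beta = 0.735, 0.15, 2.0
    if dense_interactions:
        # keep the 17 highest-rate bait genera, spread their dominance evenly
        bait_idx = np.flatnonzero(is_bait)
        keep = bait_idx[np.argsort(lam_primary[bait_idx])[::-1][:17]]
        drop = np.setdiff1d(bait_idx, keep)
        lam_primary[keep] = 2.0
        lam_logged[keep] = 2.0
        lam_primary[drop] = 0.0
        lam_logged[drop] = 0.0
        ladder = np.linspace(-2.0, 2.0, 17)
        d_primary[keep] = rng.permutation(ladder)
        p_neutral, eta = 0.5, 0.5

    size_class = pd.Series(
        ["large" if g in _LARGE_GENERA else "medium" if g in _MEDIUM_GENERA else "small" for g in genera],
        index=list(genera),
    )
    return SyntheticParams(
        genera=genera,
        p_litter=_per_forest_frame(genera, p_lit_primary, p_lit_logged),
        lambda_arrival=_per_forest_frame(genera, lam_primary, lam_logged),
        mu_abundance=_per_forest_frame(genera, mu, mu),
        dominance=_per_forest_frame(genera, d_primary, d_primary.copy()),
        beta=beta,
        p_neutral=p_neutral,
        eta=eta,
        seed=seed,
        size_class=size_class,
    ).validate()


def _expected_occupancy(params: SyntheticParams, forest: str) -> pd.Series:
    """Expected fraction of the 120 analysed units occupied, per genus."""
    p_lit = params.p_litter[forest]
    p_cam = 1.0 - np.exp(-params.lambda_arrival[forest])
    return (30.0 * p_lit + 90.0 * p_cam) / 120.0


def reference_scenarios(seed: int = 42) -> list[Scenario]:
    """The three named study scenarios, reproducible given ``seed``.

    ``null``
        the hierarchy is identical in both forests; occupancy still changes.
    ``intuitive``
        dominance change is positively coupled to occupancy change —
        genera that gain ground also climb the hierarchy.
    ``rewired``
        densely sampled 17-genus design whose logged hierarchy is a random
        permutation of the primary one, independent of occupancy change.
    """
    ss = np.random.SeedSequence(seed)
    sub = [int(s) for s in ss.generate_state(4) % (2**31)]

    null = community_params(seed=sub[0])
    scenarios = [
        Scenario("null", null, "identical dominance hierarchy in both forests"),
    ]

    intuitive = community_params(seed=sub[1])
    d_occ = _expected_occupancy(intuitive, "logged") - _expected_occupancy(intuitive, "primary")
    interacting = [g for g in intuitive.genera if g in INTERACTING_GENERA]
    shift = rankdata(d_occ.loc[interacting].to_numpy())
    shift = (shift - shift.mean()) / shift.std()
    dominance = intuitive.dominance.copy()
    dominance.loc[interacting, "logged"] = dominance.loc[interacting, "primary"] + 1.5 * shift
    intuitive = dataclasses.replace(intuitive, dominance=dominance)
    scenarios.append(
        Scenario("intuitive", intuitive, "dominance change rank-coupled to occupancy change")
    )

    rewired = community_params(seed=sub[2], dense_interactions=True)
    active = [g for g in rewired.genera if rewired.lambda_arrival.loc[g, "primary"] > 0]
    # permute the whole active (17-genus) hierarchy in the logged forest only
    rng = np.random.default_rng(sub[3])
    perm = rng.permutation(len(active))
    while np.array_equal(perm, np.arange(len(active))):  # pragma: no cover
        perm = rng.permutation(len(active))
    dominance = rewired.dominance.copy()
    d_active = dominance.loc[active, "primary"].to_numpy(dtype=float)
    dominance.loc[active, "logged"] = d_active[perm]
    rewired = dataclasses.replace(rewired, dominance=dominance)
    scenarios.append(
        Scenario("rewired", rewired, "logged hierarchy is a shuffle of the primary one")
    )
    return scenarios
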
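"""Core data model for bait-card ant community surveys.

The sampling design this package analyses pairs two collection methods at
each forest site: pooled leaf-litter extractions (Winkler bags, one pooled
bag per 3-point grid column) and baited paper cards filmed for 40 minutes.
Each *sampling unit* is either one pooled litter bag or one camera bait-card
session; these units are the atoms for occupancy and richness. A third
method — human-observed bait cards used to build a reference collection —
is representable via the ``human`` method tag but is excluded from every
analysis by default.

Four tables describe a dataset:

``units``
    one row per sampling unit (forest, site, grid, method, time slot, point).
``presences``
    one row per (unit, genus) with a positive abundance; absence is encoded
    by absence of a row, never by a zero.
``arrivals``
    camera units only: first-arrival time (minutes into the 40-min session)
    and within-card arrival order for each genus that visited.
``events``
    camera units only: one row per observed genus–genus interaction with a
    behavioural role (aggressive / neutral / submissive) per participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

FORESTS = ("primary", "logged")
METHODS = ("litter", "camera", "human")
TIME_SLOTS = ("0800", "1200", "1600")
ROLES = ("aggressive", "neutral", "submissive")

#: Role pairs accepted at ingestion.  ``aggressive/aggressive`` (mutual
#: aggression) is accepted for losslessness even though the behavioural
#: taxonomy names only one aggressor and one submissive per competitive
#: encounter; classification policy lives in :mod:`antcomp.aggression`.
VALID_ROLE_PAIRS = frozenset(
    {
        ("neutral", "neutral"),
        ("aggressive", "submissive"),
        ("submissive", "aggressive"),
        ("aggressive", "aggressive"),
    }
)

SESSION_MINUTES = 40.0

# Canonical design constants: 10 sites per forest, 3 grids per site, one
# pooled litter unit per grid and 3 camera bait cards per grid, giving
# 30 litter + 90 camera = 120 analysed units per forest.
N_SITES_PER_FOREST = 10
N_GRIDS_PER_SITE = 3
N_CAMERA_POINTS_PER_GRID = 3
N_LITTER_UNITS_PER_FOREST = N_SITES_PER_FOREST * N_GRIDS_PER_SITE
N_CAMERA_UNITS_PER_FOREST = (
    N_SITES_PER_FOREST * N_GRIDS_PER_SITE * N_CAMERA_POINTS_PER_GRID
)
N_ANALYSED_UNITS_PER_FOREST = N_LITTER_UNITS_PER_FOREST + N_CAMERA_UNITS_PER_FOREST

UNITS_COLUMNS = ["unit_id", "forest", "site", "grid", "method", "time_slot", "point_index"]
PRESENCES_COLUMNS = ["unit_id", "genus", "abundance"]
ARRIVALS_COLUMNS = ["unit_id", "genus", "first_arrival_time", "arrival_order"]
EVENTS_COLUMNS = ["unit_id", "time", "genus_a", "genus_b", "role_a", "role_b"]
GENERA_COLUMNS = ["genus", "size_class"]

SIZE_CLASSES = ("small", "medium", "large")


class SchemaError(ValueError):
    """A table is missing a required column or has an invalid dtype."""


class ReferentialError(ValueError):
    """A row references a unit or genus that does not exist (or has the wrong method)."""


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class Dataset:
    """Validated container for one survey's tables.

    Construct via :func:`antcomp.io.read_dataset`,
    :func:`antcomp.synthetic.generate_dataset`, or directly from data frames
    followed by :meth:`validate`.
    """

    units: pd.DataFrame
    presences: pd.DataFrame
    arrivals: pd.DataFrame
    events: pd.DataFrame
    genera: Optional[pd.DataFrame] = None

    # ------------------------------------------------------------------ build
    @classmethod
    def empty(cls) -> "Dataset":
        return cls(
            units=_empty(UNITS_COLUMNS),
            presences=_empty(PRESENCES_COLUMNS),
            arrivals=_empty(ARRIVALS_COLUMNS),
            events=_empty(EVENTS_COLUMNS),
        )

    # --------------------------------------------------------------- validate
    def validate(self) -> "Dataset":
        """Check schema, value domains and referential closure.

        Returns ``self`` so it can be chained.  Raises :class:`SchemaError`,
        :class:`ReferentialError` or :class:`ValueError` (with the offending
        row number where applicable) on the first violation found.
        """
        for name, df, cols in (
            ("units", self.units, UNITS_COLUMNS),
            ("presences", self.presences, PRESENCES_COLUMNS),
            ("arrivals", self.arrivals, ARRIVALS_COLUMNS),
            ("events", self.events, EVENTS_COLUMNS),
        ):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SchemaError(f"{name} table missing column(s): {', '.join(missing)}")
        if self.genera is not None:
            missing = [c for c in GENERA_COLUMNS if c not in self.genera.columns]
            if missing:
                raise SchemaError(f"genera table missing column(s): {', '.join(missing)}")
            names = self.genera["genus"]
            if names.duplicated().any() or (names.astype(str).str.len() == 0).any():
                raise ValueError("genus names must be unique and non-empty")
            bad = ~self.genera["size_class"].isin(SIZE_CLASSES) & self.genera["size_class"].notna()
            if bad.any():
                raise ValueError(
                    f"genera row {int(np.flatnonzero(bad)[0])}: size_class outside {SIZE_CLASSES}"
                )

        self._validate_units()
        self._validate_presences()
        self._validate_arrivals()
        self._validate_events()
        return self

    def _validate_units(self) -> None:
        u = self.units
        if u["unit_id"].duplicated().any():
            dup = u.loc[u["unit_id"].duplicated(), "unit_id"].iloc[0]
            raise ValueError(f"duplicate unit_id {dup!r}")
        for col, domain in (("forest", FORESTS), ("method", METHODS), ("time_slot", TIME_SLOTS)):
            bad = ~u[col].astype(str).isin(domain)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(f"units row {i}: {col}={u[col].iloc[i]!r} outside {domain}")
        for col in ("site", "grid"):
            if len(u) and (pd.to_numeric(u[col], errors="coerce").fillna(-1) < 1).any():
                raise ValueError(f"units: {col} must be a positive integer")

    def _validate_presences(self) -> None:
        p = self.presences
        if len(p):
            ab = pd.to_numeric(p["abundance"], errors="coerce")
            bad = ~(ab >= 1)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(f"presences row {i}: abundance must be >= 1 (absence is absence of record)")
        self._check_unit_refs(p, "presences")

    def _validate_arrivals(self) -> None:
        a = self.arrivals
        if len(a):
            t = pd.to_numeric(a["first_arrival_time"], errors="coerce")
            bad = ~((t >= 0) & (t <= SESSION_MINUTES))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(f"arrivals row {i}: first_arrival_time outside [0, {SESSION_MINUTES}]")
            order = pd.to_numeric(a["arrival_order"], errors="coerce")
            if (~(order >= 1)).any():
                raise ValueError("arrivals: arrival_order must be a positive integer")
        self._check_unit_refs(a, "arrivals", camera_only=True)

    def _validate_events(self) -> None:
        e = self.events
        if len(e):
            t = pd.to_numeric(e["time"], errors="coerce")
            bad = ~((t >= 0) & (t <= SESSION_MINUTES))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(f"events row {i}: time outside [0, {SESSION_MINUTES}]")
            same = e["genus_a"].astype(str) == e["genus_b"].astype(str)
            if same.any():
                i = int(np.flatnonzero(same)[0])
                raise ValueError(f"events row {i}: genus_a equals genus_b ({e['genus_a'].iloc[i]!r})")
            for col in ("role_a", "role_b"):
                bad = ~e[col].astype(str).isin(ROLES)
                if bad.any():
                    i = int(np.flatnonzero(bad)[0])
                    raise ValueError(f"events row {i}: {col}={e[col].iloc[i]!r} outside {ROLES}")
            pairs = list(zip(e["role_a"].astype(str), e["role_b"].astype(str)))
            bad_pairs = [i for i, pr in enumerate(pairs) if pr not in VALID_ROLE_PAIRS]
            if bad_pairs:
                i = bad_pairs[0]
                raise ValueError(
                    f"events row {i}: role pair {pairs[i]} is not a valid combination"
                )
        self._check_unit_refs(e, "events", camera_only=True)

    def _check_unit_refs(self, df: pd.DataFrame, name: str, camera_only: bool = False) -> None:
        if not len(df):
            return
        known = set(self.units["unit_id"])
        dangling = ~df["unit_id"].isin(known)
        if dangling.any():
            i = int(np.flatnonzero(dangling)[0])
            raise ReferentialError(f"{name} row {i}: unknown unit_id {df['unit_id'].iloc[i]!r}")
        if camera_only:
            cams = set(self.units.loc[self.units["method"] == "camera", "unit_id"])
            bad = ~df["unit_id"].isin(cams)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ReferentialError(
                    f"{name} row {i}: unit {df['unit_id'].iloc[i]!r} is not a camera unit"
                )

    # ---------------------------------------------------------------- queries
    def analysed_units(self, forest: Optional[str] = None) -> pd.DataFrame:
        """Units entering analyses: litter and camera, never human-observed cards."""
        u = self.units[self.units["method"].isin(["litter", "camera"])]
        if forest is not None:
            u = u[u["forest"] == forest]
        return u

    def camera_units(self, forest: Optional[str] = None) -> pd.DataFrame:
        u = self.units[self.units["method"] == "camera"]
        if forest is not None:
            u = u[u["forest"] == forest]
        return u

    def genus_set(
        self,
        forest: Optional[str] = None,
        methods: Iterable[str] = ("litter", "camera"),
    ) -> set[str]:
        """Genera recorded present in the selected units (presence table only)."""
        units = self.units[self.units["method"].isin(list(methods))]
        if forest is not None:
            units = units[units["forest"] == forest]
        keep = self.presences["unit_id"].isin(set(units["unit_id"]))
        return set(self.presences.loc[keep, "genus"].astype(str))

    def events_with_units(self, forest: Optional[str] = None) -> pd.DataFrame:
        """Events joined to their unit's forest/site/grid columns."""
        merged = self.events.merge(
            self.units[["unit_id", "forest", "site", "grid", "method"]],
            on="unit_id",
            how="left",
        )
        if forest is not None:
            merged = merged[merged["forest"] == forest]
        return merged.reset_index(drop=True)


def unit_id(forest: str, site: int, grid: int, method: str, point_index: Optional[int] = None) -> str:
    """Canonical unit identifier, e.g. ``primary-s03-g2-camera-1`` or ``logged-s10-g1-litter``."""
    base = f"{forest}-s{site:02d}-g{grid}-{method}"
    return base if point_index is None else f"{base}-{point_index}"
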
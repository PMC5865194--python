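"""Reading, writing and design-checking of survey tables.

The on-disk representation is four (optionally five) CSV files in one
directory — ``units.csv``, ``presences.csv``, ``arrivals.csv``,
``interactions.csv`` and an optional ``genera.csv`` — comma-separated,
UTF-8, header row, ``.`` decimal.  A YAML (or dict) config can remap file
names, the delimiter, and per-table column names, so the same reader can
ingest a deposited dataset whose headers differ from the canonical schema.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd
import yaml

from .dataset import (
    ARRIVALS_COLUMNS,
    Dataset,
    EVENTS_COLUMNS,
    GENERA_COLUMNS,
    N_ANALYSED_UNITS_PER_FOREST,
    N_CAMERA_UNITS_PER_FOREST,
    N_GRIDS_PER_SITE,
    N_LITTER_UNITS_PER_FOREST,
    N_SITES_PER_FOREST,
    PRESENCES_COLUMNS,
    SESSION_MINUTES,
    SchemaError,
    UNITS_COLUMNS,
)

DEFAULT_FILES = {
    "units": "units.csv",
    "presences": "presences.csv",
    "arrivals": "arrivals.csv",
    "events": "interactions.csv",
    "genera": "genera.csv",
}

_TABLE_COLUMNS = {
    "units": UNITS_COLUMNS,
    "presences": PRESENCES_COLUMNS,
    "arrivals": ARRIVALS_COLUMNS,
    "events": EVENTS_COLUMNS,
    "genera": GENERA_COLUMNS,
}

# Nullable Int64 keeps point_index round-trippable for litter rows (blank cell).
_DTYPES = {
    "units": {"site": "int64", "grid": "int64", "point_index": "Int64"},
    "presences": {"abundance": "int64"},
    "arrivals": {"first_arrival_time": "float64", "arrival_order": "int64"},
    "events": {"time": "float64"},
}

ConfigLike = Union[None, Mapping, str, Path]


def _load_config(config: ConfigLike) -> dict:
    if config is None:
        return {}
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def read_dataset(in_dir: Union[str, Path], config: ConfigLike = None) -> Dataset:
    """Read and validate a dataset from a directory of CSV files.

    Parameters
    ----------
    in_dir
        Directory holding the table files.
    config
        Optional dict or YAML path with keys ``delimiter`` (default ``,``),
        ``files`` (table → file name) and ``columns`` (table → {canonical
        column → file column}).

    Raises :class:`antcomp.dataset.SchemaError` naming the missing column,
    :class:`antcomp.dataset.ReferentialError` for dangling references (e.g.
    an interaction recorded against a litter unit), and ``ValueError`` with
    the row number for value-domain violations.
    """
    cfg = _load_config(config)
    delimiter = cfg.get("delimiter", ",")
    files = {**DEFAULT_FILES, **cfg.get("files", {})}
    colmaps = cfg.get("columns", {})
    in_dir = Path(in_dir)

    tables: dict[str, Optional[pd.DataFrame]] = {}
    for table, cols in _TABLE_COLUMNS.items():
        path = in_dir / files[table]
        if table == "genera" and not path.exists():
            tables[table] = None
            continue
        if not path.exists():
            raise FileNotFoundError(f"missing table file: {path}")
        df = pd.read_csv(path, sep=delimiter, dtype=object, keep_default_na=True)
        rename = {v: k for k, v in colmaps.get(table, {}).items()}
        if rename:
            df = df.rename(columns=rename)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{files[table]}: missing column(s): {', '.join(missing)}")
        df = df[cols]
        for col, dtype in _DTYPES.get(table, {}).items():
            try:
                df[col] = df[col].astype("float64").astype(dtype) if dtype != "float64" else df[col].astype(dtype)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{files[table]}: column {col!r} not parseable as {dtype}: {exc}") from exc
        tables[table] = df

    ds = Dataset(
        units=tables["units"],
        presences=tables["presences"],
        arrivals=tables["arrivals"],
        events=tables["events"],
        genera=tables["genera"],
    )
    return ds.validate()


def write_dataset(dataset: Dataset, out_dir: Union[str, Path], config: ConfigLike = None) -> dict[str, Path]:
    """Write a dataset as CSV files with stable column order.

    ``read_dataset(write_dataset(ds)) == ds`` field-by-field.  Returns the
    mapping table name → written path.
    """
    cfg = _load_config(config)
    delimiter = cfg.get("delimiter", ",")
    files = {**DEFAULT_FILES, **cfg.get("files", {})}
    out_dir = Path(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    written: dict[str, Path] = {}
    frames = {
        "units": dataset.units,
        "presences": dataset.presences,
        "arrivals": dataset.arrivals,
        "events": dataset.events,
    }
    if dataset.genera is not None:
        frames["genera"] = dataset.genera
    for table, df in frames.items():
        path = out_dir / files[table]
        df[_TABLE_COLUMNS[table]].to_csv(path, sep=delimiter, index=False)
        written[table] = path
    return written


def validate_design(dataset: Dataset) -> list[str]:
    """Report deviations from the canonical sampling design as warnings.

    The canonical design per forest: 10 sites, 3 grids per site, 30 pooled
    litter units, 90 camera bait-card units (120 analysed units), sessions
    confined to 40 minutes.  Deviations are reported, never raised — partial
    datasets are legitimate inputs.
    """
    warnings: list[str] = []
    units = dataset.units
    for forest in sorted(units["forest"].astype(str).unique()):
        fu = units[units["forest"] == forest]
        n_sites = fu["site"].nunique()
        if n_sites != N_SITES_PER_FOREST:
            warnings.append(f"{forest}: {n_sites} sites (expected {N_SITES_PER_FOREST})")
        for site, su in fu.groupby("site"):
            n_grids = su["grid"].nunique()
            if n_grids != N_GRIDS_PER_SITE:
                warnings.append(f"{forest} site {site}: {n_grids} grids (expected {N_GRIDS_PER_SITE})")
        n_litter = (fu["method"] == "litter").sum()
        if n_litter != N_LITTER_UNITS_PER_FOREST:
            warnings.append(
                f"{forest}: {n_litter} litter units (expected {N_LITTER_UNITS_PER_FOREST})"
            )
        n_camera = (fu["method"] == "camera").sum()
        if n_camera != N_CAMERA_UNITS_PER_FOREST:
            warnings.append(
                f"{forest}: {n_camera} camera units (expected {N_CAMERA_UNITS_PER_FOREST})"
            )
        n_analysed = len(dataset.analysed_units(forest))
        if n_analysed != N_ANALYSED_UNITS_PER_FOREST:
            warnings.append(
                f"{forest}: {n_analysed} analysed units (expected {N_ANALYSED_UNITS_PER_FOREST})"
            )
    for name, df, col in (("arrivals", dataset.arrivals, "first_arrival_time"), ("events", dataset.events, "time")):
        if len(df):
            t = pd.to_numeric(df[col], errors="coerce")
            n_late = int((t > SESSION_MINUTES).sum())
            if n_late:
                warnings.append(f"{name}: {n_late} rows with {col} beyond {SESSION_MINUTES} min")
    return warnings
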
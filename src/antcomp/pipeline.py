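"""End-to-end orchestration: simulate/load -> composition -> aggression -> network -> stats.

Every stage writes plain files into the output directory so any stage can be
re-run or audited in isolation; ``report.json`` ties a run together (config
echo, seed, software version, stage outputs, warnings).  Identical config +
seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import aggression as agg
from . import composition as comp
from . import network as net
from . import stats as st
from .dataset import Dataset, FORESTS
from .io import read_dataset, validate_design, write_dataset
from .synthetic import generate_dataset, reference_scenarios

logger = logging.getLogger("antcomp")

__all__ = ["RunConfig", "RunReport", "run_all", "make_paper_tables", "load_config"]


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    mode: str = "scenario"              # "scenario" | "files"
    scenario: str = "null"
    in_dir: Optional[str] = None        # files mode: directory of CSVs
    io_config: Optional[str] = None     # files mode: optional column-mapping YAML
    out_dir: str = "antcomp-out"
    seed: int = 42
    min_partners: int = agg.DEFAULT_MIN_PARTNERS
    min_pair_n: int = agg.DEFAULT_MIN_PAIR_N
    weighting: str = "pooled"           # "pooled" | "min"
    per_capita_numerator: str = "competitive"
    shannon_level: str = "pooled"       # "pooled" | "unit"
    network_view: str = "per-direction"  # "per-direction" | "net"

    def validate(self) -> "RunConfig":
        if self.mode not in {"scenario", "files"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.in_dir:
            raise ValueError("files mode requires in_dir")
        for name in ("min_partners", "min_pair_n"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        return self


def load_config(path: Union[str, Path], **overrides) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw).validate()


@dataclass
class RunReport:
    config: dict
    seed: int
    version: str
    dataset_summary: dict
    outputs: dict
    warnings: list = field(default_factory=list)
    stats: dict = field(default_factory=dict)


def _get_dataset(config: RunConfig) -> tuple[Dataset, list[str]]:
    warnings: list[str] = []
    if config.mode == "files":
        ds = read_dataset(config.in_dir, config.io_config)
    else:
        scenarios = {s.name: s for s in reference_scenarios(seed=config.seed)}
        if config.scenario not in scenarios:
            raise ValueError(f"unknown scenario {config.scenario!r}; have {sorted(scenarios)}")
        ds = generate_dataset(scenarios[config.scenario].params)
    warnings.extend(validate_design(ds))
    return ds, warnings


def _dataset_summary(ds: Dataset) -> dict:
    ev = agg.classify_events(ds.events_with_units())
    summary: dict = {
        "n_units": int(len(ds.units)),
        "n_genera": int(ds.presences["genus"].nunique()),
        "n_events": int(len(ds.events)),
    }
    for forest in sorted(ds.units["forest"].astype(str).unique()):
        fe = ev[ev["forest"] == forest] if len(ev) else ev
        summary[forest] = {
            "n_units": int((ds.units["forest"] == forest).sum()),
            "n_genera": len(ds.genus_set(forest)),
            "n_events": int(len(fe)),
            "n_competitive": int((fe["category"] == "competitive").sum()) if len(fe) else 0,
        }
    return summary


def run_all(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write every stage's outputs.

    Raises on the first failing stage, leaving earlier outputs in place.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    logger.info("stage: dataset (%s mode)", config.mode)
    ds, warnings = _get_dataset(config)
    written = write_dataset(ds, out / "dataset")
    outputs["dataset"] = {k: str(v) for k, v in written.items()}

    forests = sorted(set(ds.units["forest"].astype(str)) & set(FORESTS))

    # ---------------------------------------------------------- composition
    logger.info("stage: composition")
    occ_tables = {f: comp.occupancy_table(ds, f) for f in forests}
    occ_all = pd.concat(occ_tables.values(), ignore_index=True)
    occ_all.to_csv(out / "occupancy.csv", index=False)
    outputs["occupancy"] = str(out / "occupancy.csv")

    diversity_rows = []
    richness = {}
    shannon_units = {}
    for f in forests:
        r = comp.mean_richness(ds, f)
        richness[f] = r
        h = comp.shannon_by_forest(ds, f, level=config.shannon_level)
        diversity_rows.append(
            {
                "forest": f,
                "mean_richness": r.mean_richness,
                "richness_total": r.richness,
                "H_prime": h.H_prime,
                "shannon_level": h.level,
            }
        )
        shannon_units[f] = comp.shannon_by_forest(ds, f, level="unit").per_unit
    pd.DataFrame(diversity_rows).to_csv(out / "diversity.csv", index=False)
    outputs["diversity"] = str(out / "diversity.csv")

    overlap = None
    if len(forests) == 2:
        overlap = comp.genus_overlap(ds.genus_set("primary"), ds.genus_set("logged"))
        (out / "overlap.json").write_text(json.dumps(asdict(overlap), indent=2), encoding="utf-8")
        outputs["overlap"] = str(out / "overlap.json")

    # ------------------------------------------------------------ aggression
    logger.info("stage: aggression")
    classified = agg.classify_events(ds.events_with_units())
    matrices = {}
    for f in forests:
        m = agg.aggression_matrix(classified[classified["forest"] == f], f, config.min_partners)
        matrices[f] = m
        warnings.extend(m.warnings)
        long = (
            m.mean.stack(future_stack=True)
            .rename("mean_score")
            .to_frame()
            .join(m.n.stack(future_stack=True).rename("n"))
            .reset_index(names=["genus_i", "genus_j"])
        )
        long = long[long["n"] > 0]
        long.to_csv(out / f"aggression_{f}.csv", index=False)
        outputs[f"aggression_{f}"] = str(out / f"aggression_{f}.csv")

    change = None
    if len(forests) == 2 and matrices["primary"].genera and matrices["logged"].genera:
        try:
            change = agg.score_change(
                matrices["primary"], matrices["logged"], config.min_pair_n, config.weighting
            )
        except ValueError as exc:
            warnings.append(f"score_change skipped: {exc}")
    if change is not None:
        rows = change.delta.stack(future_stack=True).rename("delta").to_frame()
        rows = rows.join(change.n_primary.stack(future_stack=True).rename("n_primary"))
        rows = rows.join(change.n_logged.stack(future_stack=True).rename("n_logged"))
        rows = rows.reset_index(names=["genus_i", "genus_j"])
        rows.to_csv(out / "score_change.csv", index=False)
        change.weighted_mean_delta.rename("weighted_mean_delta").to_frame().reset_index(
            names="genus"
        ).to_csv(out / "weighted_mean_delta.csv", index=False)
        outputs["score_change"] = str(out / "score_change.csv")
        outputs["weighted_mean_delta"] = str(out / "weighted_mean_delta.csv")

    cards = pd.concat(
        [agg.card_metrics(ds, f, config.per_capita_numerator) for f in forests],
        ignore_index=True,
    )
    cards.to_csv(out / "card_metrics.csv", index=False)
    outputs["card_metrics"] = str(out / "card_metrics.csv")

    totals = agg.interaction_totals(classified)
    totals.to_csv(out / "interaction_totals.csv", index=False)
    outputs["interaction_totals"] = str(out / "interaction_totals.csv")

    # --------------------------------------------------------------- network
    logger.info("stage: network")
    networks = {}
    for f in forests:
        g = net.build_network(classified[classified["forest"] == f], f)
        if config.network_view == "net":
            g = net.net_view(g)
        networks[f] = g
        net.export_network(g, out / f"network_{f}.graphml", "graphml")
        net.export_network(g, out / f"edges_{f}.tsv", "edgelist")
        outputs[f"network_{f}"] = str(out / f"network_{f}.graphml")
        outputs[f"edges_{f}"] = str(out / f"edges_{f}.tsv")
    if len(forests) == 2:
        diff = net.diff_networks(networks["primary"], networks["logged"])
        (out / "network_diff.json").write_text(
            json.dumps(
                {
                    "edges_lost": sorted(map(list, diff.edges_lost)),
                    "edges_gained": sorted(map(list, diff.edges_gained)),
                    "nodes_gained": sorted(diff.nodes_gained),
                    "nodes_lost": sorted(diff.nodes_lost),
                },
                indent=2,
            ),
            encoding="utf-8",
        )
        outputs["network_diff"] = str(out / "network_diff.json")

    # ----------------------------------------------------------------- stats
    logger.info("stage: stats")
    stats_report: dict = {"settings": {"seed": config.seed}}
    if len(forests) == 2:
        stats_report.update(
            _run_stats(ds, config, occ_tables, matrices, change, richness, shannon_units, cards)
        )
    (out / "stats_report.json").write_text(
        json.dumps(stats_report, indent=2, default=_json_default), encoding="utf-8"
    )
    outputs["stats_report"] = str(out / "stats_report.json")

    report = RunReport(
        config=asdict(config),
        seed=config.seed,
        version=__version__,
        dataset_summary=_dataset_summary(ds),
        outputs=outputs,
        warnings=warnings,
        stats=stats_report,
    )
    (out / "report.json").write_text(
        json.dumps(asdict(report), indent=2, default=_json_default), encoding="utf-8"
    )
    make_paper_tables(out)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if dataclasses.is_dataclass(obj):
        return asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _test_to_dict(t: st.TestResult) -> dict:
    return asdict(t)


def _corr_to_dict(c: st.CorrelationResult) -> dict:
    return asdict(c)


def _run_stats(ds, config, occ_tables, matrices, change, richness, shannon_units, cards) -> dict:
    report: dict = {}

    # rank-occupancy comparison over genera retained in both forests' matrices
    shared = set(matrices["primary"].genera) & set(matrices["logged"].genera)
    if len(shared) >= 3:
        table, corr, warn = comp.rank_occupancy_change(
            occ_tables["primary"], occ_tables["logged"], shared
        )
        report["rank_occupancy_spearman"] = _corr_to_dict(corr)
        report["rank_occupancy_warnings"] = warn

    # richness: quasi-Poisson count contrast on per-unit richness
    rich = pd.concat(
        [richness[f].per_unit.assign(forest=f) for f in ("primary", "logged")], ignore_index=True
    )
    try:
        report["richness_contrast"] = _test_to_dict(
            st.forest_contrast(rich, family="count", value_col="richness", seed=config.seed)
        )
    except ValueError as exc:
        report["richness_contrast"] = {"skipped": str(exc)}

    # evenness: linear model on per-unit Shannon H'
    h_units = pd.concat(
        [shannon_units[f].assign(forest=f) for f in ("primary", "logged")], ignore_index=True
    )
    try:
        report["evenness_contrast"] = _test_to_dict(st.evenness_contrast(h_units))
    except ValueError as exc:
        report["evenness_contrast"] = {"skipped": str(exc)}

    # event category (competitive=1 / neutral=0): binomial contrast
    classified = agg.classify_events(ds.events_with_units())
    if len(classified):
        binary = classified.assign(value=(classified["category"] == "competitive").astype(float))
        try:
            report["category_contrast"] = _test_to_dict(
                st.forest_contrast(binary, family="binary", seed=config.seed)
            )
        except ValueError as exc:
            report["category_contrast"] = {"skipped": str(exc)}

    # per-card rate / per-capita / proportion contrasts
    for metric in ("rate", "per_capita", "proportion_competitive"):
        try:
            report[f"{metric}_contrast"] = _test_to_dict(
                st.forest_contrast(cards, family="continuous", value_col=metric, seed=config.seed)
            )
        except ValueError as exc:
            report[f"{metric}_contrast"] = {"skipped": str(exc)}

    # Mann-Whitney on per-site neutral vs competitive counts within each forest
    for f in ("primary", "logged"):
        fc = cards[cards["forest"] == f]
        per_site = fc.groupby("site")[["n_neutral", "n_competitive"]].sum()
        if len(per_site) >= 2:
            report[f"neutral_vs_competitive_mw_{f}"] = _test_to_dict(
                st.mann_whitney(per_site["n_neutral"], per_site["n_competitive"])
            )

    # aggression change vs occupancy change (the re-wiring question)
    if change is not None and len(change.genera) >= 3:
        table, _, _ = comp.rank_occupancy_change(
            occ_tables["primary"], occ_tables["logged"], set(change.genera)
        )
        wmd = change.weighted_mean_delta.rename("weighted_mean_delta").to_frame().reset_index()
        wmd.columns = ["genus", "weighted_mean_delta"]
        merged = table.merge(wmd, on="genus").dropna(subset=["weighted_mean_delta"])
        if len(merged) >= 3:
            corr = st.spearman(
                merged["weighted_mean_delta"].to_numpy(), merged["delta_occupancy"].to_numpy()
            )
            report["aggression_vs_occupancy_spearman"] = _corr_to_dict(corr)
            report["aggression_vs_occupancy_n"] = int(len(merged))
    return report


def make_paper_tables(out_dir: Union[str, Path]) -> dict[str, Path]:
    """Figure-shaped CSV tables regenerated from a completed run's outputs.

    ``table_rank_occupancy.csv`` (rank-occupancy pairs), ``table_pairwise_change.csv``
    (one row per ordered genus pair: delta + per-forest n), ``table_genus_change.csv``
    (per-genus weighted mean change) and ``table_change_vs_occupancy.csv``
    (change-vs-occupancy pairs).  Regeneration from the same run directory is
    idempotent.
    """
    out = Path(out_dir)
    made: dict[str, Path] = {}

    occ_path = out / "occupancy.csv"
    change_path = out / "score_change.csv"
    wmd_path = out / "weighted_mean_delta.csv"

    if occ_path.exists():
        occ = pd.read_csv(occ_path)
        if set(occ["forest"]) >= {"primary", "logged"}:
            p = occ[occ["forest"] == "primary"][["genus", "occupancy", "rank"]]
            l = occ[occ["forest"] == "logged"][["genus", "occupancy", "rank"]]
            t = p.merge(l, on="genus", suffixes=("_primary", "_logged"))
            t["delta_occupancy"] = t["occupancy_logged"] - t["occupancy_primary"]
            t = t.sort_values("rank_primary", kind="mergesort").reset_index(drop=True)
            path = out / "table_rank_occupancy.csv"
            t.to_csv(path, index=False)
            made["rank_occupancy"] = path

    if change_path.exists():
        ch = pd.read_csv(change_path)
        ch = ch.dropna(subset=["delta"]).copy()
        ch["n_pooled"] = ch["n_primary"] + ch["n_logged"]
        path = out / "table_pairwise_change.csv"
        ch[["genus_i", "genus_j", "delta", "n_primary", "n_logged", "n_pooled"]].to_csv(
            path, index=False
        )
        made["pairwise_change"] = path

    if wmd_path.exists():
        wmd = pd.read_csv(wmd_path).dropna(subset=["weighted_mean_delta"])
        path = out / "table_genus_change.csv"
        wmd.to_csv(path, index=False)
        made["genus_change"] = path
        if "rank_occupancy" in made:
            t = pd.read_csv(made["rank_occupancy"])
            merged = wmd.merge(t[["genus", "delta_occupancy"]], on="genus")
            path = out / "table_change_vs_occupancy.csv"
            merged.to_csv(path, index=False)
            made["change_vs_occupancy"] = path
    return made
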
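"""End-to-end orchestration: simulate/load → quantify → classify →
differential abundance → evenness → enrichment + network statistics.

A run is driven by a single JSON config; the same config and seed
regenerate every output byte-identically. Stage outputs are written as
TSVs under the run directory plus a machine-readable ``report.json``.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import differential, diversity, io, network, quant, synthetic
from .errors import SchemaError, ValidationError

logger = logging.getLogger("metabotyper")

DEFAULT_THRESHOLDS = {
    "q": 0.05,
    "effect": 2.0,
    "min_gap": 10.0,
    "lambda": 0.5,
    "p": 0.05,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    Exactly one of ``simulate`` (generator specs) or ``inputs`` (paths to
    existing TSVs) supplies the data. ``thresholds`` override the printed
    defaults (q < 0.05, effect ≥ 2, min_gap 10, λ = 0.5, p < 0.05).
    """

    out_dir: Path
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    thresholds: dict = field(default_factory=dict)
    substrate_initial: float = synthetic.SUBSTRATE_INITIAL_UM
    blacklist: tuple[str, ...] = ()
    evenness: dict | None = None  # {"gene": feature_id, "gene_category": ..., "taxon": ..., ...}

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValidationError("config needs exactly one of 'simulate' or 'inputs'")
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        for key, value in self.thresholds.items():
            if not value > 0:
                raise ValidationError(f"threshold {key!r} must be positive")
        self.out_dir = Path(self.out_dir)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ValidationError("config requires 'out_dir'")
        kwargs = dict(raw)
        kwargs["blacklist"] = tuple(kwargs.get("blacklist", ()))
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(io.read_json(path))


def _simulate_inputs(cfg: RunConfig) -> dict:
    """Generate every configured input table; returns in-memory tables + truth."""
    sim = cfg.simulate or {}
    seed = cfg.seed
    cohort = synthetic.CohortSpec(seed=seed, **sim.get("cohort", {}))
    timecourse, tc_truth = synthetic.simulate_turnover(cohort)
    cal_cfg = sim.get("calibration", {})
    cal_tables = []
    for i, m in enumerate(("SN-38", "SN-38G")):
        cal_tables.append(
            synthetic.simulate_calibration(
                cal_cfg.get("levels", [0.0, 1.0, 10.0, 50.0, 100.0]),
                slope=cal_cfg.get("slope", cohort.response_slope),
                intercept=cal_cfg.get("intercept", 0.0),
                noise_sd=cal_cfg.get("noise_sd", 0.0),
                seed=seed + 1000 + i,
                metabolite=m,
            )
        )
    calibration = pd.concat(cal_tables, ignore_index=True)

    sample_ids = sorted(tc_truth["labels"])
    group_labels = tuple(1 if tc_truth["labels"][s] == "high" else 0 for s in sample_ids)
    features: dict[str, pd.DataFrame] = {}
    truth: dict[str, Any] = {"cohort": tc_truth, "features": {}}

    reactions = None
    rspec = None
    if "reactions" in sim:
        rspec = synthetic.ReactionSpec(seed=seed + 3000, **sim["reactions"])
        reactions, rtruth = synthetic.simulate_reactions(rspec)
        truth["reactions"] = rtruth

    for j, (category, fspec) in enumerate(sorted(sim.get("features", {}).items())):
        fspec = dict(fspec)
        planted = fspec.pop("planted", ())
        ids = None
        if category == "KO" and rspec is not None:
            # KO ids must match the reaction enzymes for the network stage;
            # "peripheral" plants the fold change on the chain-end enzymes
            ids = synthetic.enzyme_ids(rspec)
            fspec.setdefault("n_features", len(ids))
            if fspec["n_features"] != len(ids):
                raise ValidationError(
                    "features.KO.n_features must equal the simulated enzyme count"
                )
            if planted == "peripheral" or (
                planted and planted[0] == "peripheral"
            ):
                fold = 4.0 if planted == "peripheral" else float(planted[1])
                planted = [(i, fold) for i in synthetic.peripheral_indices(rspec)]
        planted = tuple((int(f), float(x)) for f, x in planted)
        spec = synthetic.FeatureTableSpec(
            group_labels=group_labels,
            planted=planted,
            seed=seed + 2000 + j,
            category=category,
            **fspec,
        )
        features[category], ftruth = synthetic.simulate_feature_table(spec, sample_ids, ids)
        truth["features"][category] = ftruth
    return {
        "timecourse": timecourse,
        "calibration": calibration,
        "features": features,
        "reactions": reactions,
        "labels": None,
        "truth": truth,
    }


def _load_inputs(cfg: RunConfig) -> dict:
    paths = cfg.inputs or {}
    data: dict[str, Any] = {"truth": None, "labels": None, "reactions": None}
    data["timecourse"] = io.read_timecourse(paths["timecourse"]) if "timecourse" in paths else None
    data["calibration"] = io.read_calibration(paths["calibration"]) if "calibration" in paths else None
    data["features"] = {
        cat: io.read_feature_table(p) for cat, p in paths.get("features", {}).items()
    }
    if "reactions" in paths:
        data["reactions"] = io.read_reactions(paths["reactions"])
    if "labels" in paths:
        data["labels"] = io.read_labels(paths["labels"])
    return data


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages and write outputs + report JSON.

    Returns the report dict. Any stage failure raises with the stage name
    prepended; no partial report is written in that case.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": _package_version(),
        "seed": config.seed,
        "thresholds": config.thresholds,
        "config": {
            "out_dir": str(config.out_dir),
            "seed": config.seed,
            "simulate": config.simulate,
            "inputs": config.inputs,
            "thresholds": config.thresholds,
            "substrate_initial": config.substrate_initial,
            "blacklist": list(config.blacklist),
            "evenness": config.evenness,
        },
        "stages": {},
    }
    stage = "inputs"
    try:
        data = _simulate_inputs(config) if config.simulate else _load_inputs(config)
        if config.simulate:
            io.write_tsv(data["timecourse"], out / "timecourse.tsv")
            io.write_tsv(data["calibration"], out / "calibration.tsv")
            for cat, table in data["features"].items():
                io.write_tsv(table.reset_index(), out / f"features_{cat}.tsv")
            if data["reactions"] is not None:
                io.write_tsv(data["reactions"], out / "reactions.tsv")
            io.write_json(data["truth"], out / "truth.json")

        labels = data["labels"]
        if data["timecourse"] is not None:
            stage = "quant"
            t0 = time.perf_counter()
            if data["calibration"] is None:
                raise ValidationError("quant stage needs a calibration table")
            curves = {
                "sn38": quant.fit_calibration(data["calibration"], "SN-38"),
                "sn38g": quant.fit_calibration(data["calibration"], "SN-38G"),
            }
            qtable = quant.quantify(data["timecourse"], curves)
            io.write_tsv(qtable, out / "quant.tsv")
            percents = quant.percent_formation(qtable, config.substrate_initial)

            stage = "classify"
            assignment = quant.classify_metabotype(
                percents, min_gap=config.thresholds["min_gap"]
            )
            io.write_tsv(assignment.assignments, out / "metabotype.tsv")
            labels = assignment.labels
            report["stages"]["classify"] = {
                "n_low": assignment.n_low,
                "n_high": assignment.n_high,
                "split_gap": assignment.split_gap,
                "threshold": assignment.threshold,
            }
            logger.info("quant+classify done in %.2fs", time.perf_counter() - t0)

        if data["features"] and labels is None:
            raise ValidationError(
                "feature analysis needs metabotype labels (from a time course or a labels table)"
            )

        diff_results: dict[str, pd.DataFrame] = {}
        for cat, table in sorted(data["features"].items()):
            stage = f"differential[{cat}]"
            res = differential.differential_features(
                table,
                labels,
                q_threshold=config.thresholds["q"],
                effect_threshold=config.thresholds["effect"],
                lam=config.thresholds["lambda"],
            )
            diff_results[cat] = res
            io.write_tsv(res.reset_index().rename(columns={"index": "feature_id"}),
                         out / f"differential_{cat}.tsv")
            report["stages"].setdefault("differential", {})[cat] = {
                "n_features": int(len(res)),
                "n_significant": int(res["significant"].sum()),
                "pi0": res.attrs["pi0"],
            }

        stage = "evenness"
        if config.evenness:
            ev = config.evenness
            gene_vec = data["features"][ev.get("gene_category", "BG")].loc[ev["gene"]]
            taxon_vec = data["features"][ev.get("taxon_category", "taxon")].loc[ev["taxon"]]
            gene_res, taxon_res, delta = diversity.evenness_contrast(
                gene_vec.to_numpy(), taxon_vec.to_numpy(), ev["gene"], ev["taxon"]
            )
            rows = [
                {"entity": r.entity, "ed": r.ed, "s": r.s, "d": r.d}
                for r in (gene_res, taxon_res)
            ]
            io.write_tsv(pd.DataFrame(rows), out / "evenness.tsv")
            report["stages"]["evenness"] = {
                "ed_gene": gene_res.ed,
                "ed_taxon": taxon_res.ed,
                "delta": delta,
            }
        if "taxon" in data["features"]:
            summary = diversity.taxon_summary(data["features"]["taxon"])
            io.write_tsv(
                summary.rename("mean_relative_abundance_pct").reset_index(),
                out / "taxon_summary.tsv",
            )
            report["stages"]["taxon_summary"] = {
                "top_taxon": str(summary.index[0]),
                "top_mean_pct": float(summary.iloc[0]),
            }

        if data["reactions"] is not None:
            stage = "enrichment"
            enrich_cat = "KO" if "KO" in data["features"] else None
            if enrich_cat is None:
                raise ValidationError("enrichment stage needs a 'KO' feature table")
            ko = data["features"][enrich_cat]
            enr = network.enrichment_table(ko, labels)
            io.write_tsv(
                enr.reset_index().rename(columns={"index": "enzyme_id"}),
                out / "enrichment.tsv",
            )

            stage = "network"
            g = network.build_network(data["reactions"], config.blacklist)
            bt = network.betweenness(g)
            edges = pd.DataFrame(
                [
                    {"source": u, "target": v, "compounds": ";".join(d["compounds"])}
                    for u, v, d in sorted(g.edges(data=True))
                ]
            )
            io.write_tsv(edges, out / "network_edges.tsv")
            _write_graphml(g, out / "network.graphml")
            tiers = network.centrality_tiers(bt)
            tier_table = pd.DataFrame(
                {
                    "enzyme_id": tiers.tiers.index,
                    "betweenness": tiers.scores.loc[tiers.tiers.index].to_numpy(),
                    "tier": tiers.tiers.to_numpy(),
                }
            )
            io.write_tsv(tier_table, out / "centrality_tiers.tsv")

            stage = "network_stats"
            common = [e for e in enr.index if e in bt]
            if not common:
                raise ValidationError(
                    "no overlap between KO feature ids and reaction enzyme ids"
                )
            flags = enr.loc[common, "associated"]
            scores = pd.Series({e: bt[e] for e in common})
            stats_out: dict[str, Any] = {
                "n_enzymes": len(common),
                "n_associated": int(flags.sum()),
                "tier_sizes": {t: len(tiers.members(t)) for t in network.TIERS},
            }
            if 0 < int(flags.sum()) < len(common):
                w, p = network.compare_centrality(scores, flags)
                stats_out["wilcoxon"] = {"W": w, "p": p, "significant": p < config.thresholds["p"]}
                stats_out["tier_enrichment"] = network.tier_enrichment(
                    tiers.tiers.loc[common], flags
                )
            degrees = pd.Series(dict(g.degree()), dtype=float).loc[common]
            for feat_name, feat in (("betweenness", scores), ("degree", degrees)):
                try:
                    rho, p = network.score_topology_correlation(
                        enr.loc[common, "da_score"].to_numpy(), feat.to_numpy()
                    )
                    stats_out[f"spearman_{feat_name}"] = {"rho": rho, "p": p}
                except Exception:  # zero rank variance on degenerate inputs
                    stats_out[f"spearman_{feat_name}"] = None
            report["stages"]["network"] = stats_out
            io.write_json(stats_out, out / "network_stats.json")
    except Exception as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    io.write_json(report, out / "report.json")
    return report


def _write_graphml(g, path) -> None:
    import networkx as nx

    h = g.copy()
    for _, _, d in h.edges(data=True):
        d["compounds"] = ";".join(d["compounds"])
    nx.write_graphml(h, path)


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("metabotyper")
    except PackageNotFoundError:
        return "unknown"


def validate_tables(paths: Mapping[str, Any]) -> dict:
    """Schema, sign and ID-consistency checks over a set of input TSVs.

    ``paths`` uses the same layout as ``RunConfig.inputs``. Returns
    ``{"errors": [...], "warnings": [...]}``; unreadable files raise.
    """
    errors: list[str] = []
    warnings_: list[str] = []

    def check(fn, path):
        try:
            return fn(path)
        except FileNotFoundError:
            raise
        except SchemaError as exc:
            errors.append(str(exc))
            return None

    tc = check(io.read_timecourse, paths["timecourse"]) if "timecourse" in paths else None
    if tc is not None:
        for col in ("area_sn38", "area_sn38g", "area_istd"):
            bad = tc.index[tc[col] < 0]
            for i in bad:
                errors.append(f"timecourse: negative {col} at row {i}")
        for ind, sub in tc.groupby("individual"):
            if 0 not in set(sub["timepoint_min"]):
                errors.append(f"timecourse: individual {ind} missing timepoint 0")
    if "calibration" in paths:
        check(io.read_calibration, paths["calibration"])
    labels = check(io.read_labels, paths["labels"]) if "labels" in paths else None
    for cat, fpath in paths.get("features", {}).items():
        table = check(io.read_feature_table, fpath)
        if table is None:
            continue
        neg = np.argwhere(table.to_numpy() < 0)
        for i, j in neg:
            errors.append(
                f"features[{cat}]: negative abundance at ({table.index[i]}, {table.columns[j]})"
            )
        if table.index.duplicated().any():
            errors.append(f"features[{cat}]: duplicate feature ids")
        if labels is not None:
            missing = [s for s in table.columns if s not in labels.index]
            if missing:
                errors.append(f"features[{cat}]: samples missing from labels: {missing}")
    if "reactions" in paths:
        rt = check(io.read_reactions, paths["reactions"])
        if rt is not None and rt["enzyme_id"].duplicated().any():
            errors.append("reactions: duplicate enzyme ids")
    return {"errors": errors, "warnings": warnings_}


def setup_logging(out_dir: Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(Path(out_dir) / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
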
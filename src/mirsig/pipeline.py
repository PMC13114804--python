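"""End-to-end orchestration: ingest -> curate -> classify -> consensus ->
partition -> enrichment -> prioritization -> networks -> reports.

A single configuration mapping names every threshold and rule; identical
config + seed produces byte-identical run manifests.  Inputs are either
real top-table files (two cohorts per disease, two diseases) or the
synthetic study preset.  Every stage's counts land in a machine-readable
manifest, and each tabular output is written as TSV with its SHA-256
recorded for determinism checks.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .consensus import (direction_stratify, partition_signatures,
                        strict_intersection, vote_consensus, write_partition,
                        write_signature)
from .deg_classification import (ThresholdConfig, significant_sets,
                                 top_ranked, volcano_table)
from .errors import ConfigError, PipelineStageError
from .network import (build_bipartite, degree_hubs, export_cytoscape,
                      select_network_mirnas)
from .ora import enrich_signature
from .prioritization import categorize_bias, membership_matrix, shortlist
from .symbol_curation import curate, write_audit
from .synthetic_data import (default_spec, degree_rank, fdr_rank,
                             generate_study, generate_target_library,
                             truth_recovery_report)
from .target_library import (build_universe, read_gmt, restrict_library,
                             write_gmt, write_universe)
from .toptable_io import read_toptable, write_toptable

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "thresholds": {"fdr_max": 0.05, "abs_lfc_min": 1.0},
    "alpha": 0.05,
    "min_set_size": 5,
    "k_min": 3,
    "K_min": 5,
    "per_category_top": 10,
    "network": {"fallback_top": 10},
    "rules": {},  # disease -> "strict" | "vote"
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return cfg


def _merge_config(config: Mapping) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in config.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunResult:
    outdir: Path
    manifest: dict

    @property
    def manifest_path(self) -> Path:
        return self.outdir / "manifest.json"


def run_pipeline(config: Mapping, outdir: str | Path,
                 seed: int | None = None) -> RunResult:
    """Execute the full analysis described by ``config`` into ``outdir``.

    ``seed`` overrides ``config["seed"]``.  On stage failure a partial
    manifest naming the failed stage is written before the error is
    re-raised as :class:`PipelineStageError`.
    """
    cfg = _merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config": cfg,
        "seed": cfg["seed"],
        "versions": {"mirsig": __version__},
        "stages": {},
        "outputs": {},
    }
    stage = "configure"

    def fail(exc: BaseException) -> PipelineStageError:
        manifest["failed_stage"] = stage
        _write_manifest(manifest, outdir)
        return PipelineStageError(stage, exc)

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)

    try:
        thresholds = ThresholdConfig(**cfg["thresholds"])

        # ---- stage: ingest ----------------------------------------------
        stage = "ingest"
        synthetic = "synthetic" in cfg
        truth = None
        lib = None
        if synthetic:
            preset = cfg["synthetic"].get("preset", "default")
            if preset != "default":
                raise ConfigError(f"unknown synthetic preset {preset!r}")
            spec = default_spec(seed=cfg["seed"])
            study = generate_study(spec)
            truth = study.truth
            tables_by_disease = study.tables
            lib, hub_manifest = generate_target_library(spec, truth)
            rules = {"CLL": "strict", "MM": "vote"} | cfg.get("rules", {})
            emit("truth.tsv", truth.to_csv)
            emit("hub_manifest.tsv",
                 lambda p: hub_manifest.to_csv(p, sep="\t", index=False))
        else:
            diseases_cfg = cfg.get("diseases")
            if not diseases_cfg:
                raise ConfigError(
                    "config needs either a 'synthetic' preset or 'diseases' "
                    "with cohort paths"
                )
            tables_by_disease = {}
            for disease, dcfg in diseases_cfg.items():
                cohorts = dcfg.get("cohorts", [])
                if len(cohorts) != 2:
                    raise ConfigError(
                        f"{disease}: exactly two cohorts required, "
                        f"got {len(cohorts)}"
                    )
                pair = tuple(
                    read_toptable(
                        c["path"],
                        column_map=c.get("column_map"),
                        dataset_id=c.get("dataset_id", ""),
                        disease=disease,
                    )
                    for c in cohorts
                )
                tables_by_disease[disease] = pair
            rules = {d: dcfg.get("rule", "strict")
                     for d, dcfg in diseases_cfg.items()}
            lib_path = cfg.get("library")
            if not lib_path:
                raise ConfigError("config lacks a 'library' GMT path")
            lib = read_gmt(lib_path)
        disease_names = list(tables_by_disease)
        if len(disease_names) < 2:
            raise ConfigError("two diseases required for partitioning")

        # ---- stage: curate ----------------------------------------------
        stage = "curate"
        curated: dict[str, tuple] = {}
        reports = []
        for disease, pair in tables_by_disease.items():
            out_pair = []
            for table in pair:
                ct, report = curate(table)
                out_pair.append(ct)
                reports.append(report)
                emit(f"toptable_{ct.dataset_id}.tsv",
                     lambda p, t=ct: write_toptable(t, p))
            curated[disease] = tuple(out_pair)
        emit("curation_audit.tsv", lambda p: write_audit(reports, p))
        manifest["stages"]["curate"] = {
            r.dataset_id: {"n_input": r.n_input, "n_output": r.n_output}
            for r in reports
        }

        # ---- stage: classify --------------------------------------------
        stage = "classify"
        counts = {}
        for disease, pair in curated.items():
            for table in pair:
                sets = significant_sets(table, thresholds)
                n_up, n_down, total = sets.counts
                counts[table.dataset_id] = {
                    "up": n_up, "down": n_down, "total": total,
                }
                vdf = volcano_table(table, thresholds)
                emit(f"volcano_{table.dataset_id}.tsv",
                     lambda p, v=vdf: v.to_csv(p, sep="\t", index=False))
                mode = ("significant_only" if total >= 20
                        else "fdr_rank_fallback")
                blocks = top_ranked(table, 10, mode=mode,
                                    thresholds=thresholds)
                emit(f"top_genes_{table.dataset_id}.tsv",
                     lambda p, b=blocks: b["combined"].to_csv(
                         p, sep="\t", index=False))
        manifest["stages"]["classify"] = counts

        # ---- stage: consensus -------------------------------------------
        stage = "consensus"
        signatures = {}
        for disease, (t1, t2) in curated.items():
            rule = rules.get(disease, "strict")
            if rule == "strict":
                sig = strict_intersection(t1, t2, thresholds)
            elif rule == "vote":
                sig = vote_consensus(t1, t2, thresholds)
            else:
                raise ConfigError(f"{disease}: unknown rule {rule!r}")
            signatures[disease] = sig
            emit(f"consensus_{disease}.tsv",
                 lambda p, s=sig: write_signature(s, p))
        manifest["stages"]["consensus"] = {
            d: {"rule": s.rule, "n_members": len(s)}
            for d, s in signatures.items()
        }

        # ---- stage: partition -------------------------------------------
        stage = "partition"
        a, b = disease_names[0], disease_names[1]
        partition = partition_signatures(signatures[a], signatures[b])
        stratified = direction_stratify(partition, cfg["min_set_size"])
        emit("partition.tsv", lambda p: write_partition(partition, p))
        manifest["stages"]["partition"] = partition.sizes()
        manifest["stages"]["stratify"] = {
            name: {"n": len(s), "underpowered": s.underpowered}
            for name, s in stratified.items()
        }

        # ---- stage: universe/library ------------------------------------
        stage = "library"
        all_tables = [t for pair in curated.values() for t in pair]
        universe = build_universe(all_tables)
        restricted = restrict_library(lib, universe)
        emit("universe.txt", lambda p: write_universe(universe, p))
        emit("library_restricted.gmt", lambda p: write_gmt(restricted, p))
        manifest["stages"]["library"] = {
            "universe_n": universe.n,
            "n_regulons": len(restricted),
        }

        # ---- stage: enrichment ------------------------------------------
        stage = "enrichment"
        results = {}
        for name, sset in stratified.items():
            res = enrich_signature(
                sset.symbols, restricted, universe,
                alpha=cfg["alpha"], k_min=cfg["k_min"], K_min=cfg["K_min"],
            )
            results[name] = res
            emit(f"enrichment_{name}.tsv",
                 lambda p, r=res: r.to_csv(p, sep="\t", index=False))
        manifest["stages"]["enrichment"] = {
            name: {"n_tested": len(r),
                   "n_significant": int(r["significant"].sum())
                   if len(r) else 0}
            for name, r in results.items()
        }

        # ---- stage: prioritize ------------------------------------------
        stage = "prioritize"
        roles = {name: s.role for name, s in stratified.items()}
        calls = categorize_bias(results, roles, alpha=cfg["alpha"],
                                labels=(a, b))
        top = shortlist(calls, cfg["per_category_top"])
        matrix = membership_matrix(results, alpha=cfg["alpha"])
        emit("bias_calls.tsv",
             lambda p: calls.to_csv(p, sep="\t", index=False))
        emit("shortlist.tsv", lambda p: top.to_csv(p, sep="\t", index=False))
        emit("membership_matrix.tsv", lambda p: matrix.to_csv(p, sep="\t"))
        manifest["stages"]["prioritize"] = (
            calls["category"].value_counts().to_dict() if len(calls) else {}
        )

        # ---- stage: network ---------------------------------------------
        stage = "network"
        net_counts = {}
        hub_tables = {}
        for name, sset in stratified.items():
            res = results[name]
            retained = select_network_mirnas(
                res, alpha=cfg["alpha"],
                fallback_top=cfg["network"]["fallback_top"],
            )
            net = build_bipartite(retained, sset, restricted)
            mirna_hubs, gene_hubs = degree_hubs(net)
            hub_tables[name] = mirna_hubs
            edge_path, node_path = export_cytoscape(net, outdir / f"net_{name}")
            for p in (edge_path, node_path):
                manifest["outputs"][p.name] = _sha256(p)
            emit(f"hubs_mirna_{name}.tsv",
                 lambda p, h=mirna_hubs: h.to_csv(p, sep="\t", index=False))
            net_counts[name] = {
                "n_mirnas": len(mirna_hubs),
                "n_genes": len(gene_hubs),
                "n_edges": net.number_of_edges(),
            }
        manifest["stages"]["network"] = net_counts

        # ---- stage: recovery (synthetic only) ---------------------------
        if truth is not None:
            stage = "recovery"
            hub_ranks = {}
            for hub in spec.library.hubs:
                dz, direction = hub.program
                sig_name = f"{dz}_specific_{direction}"
                if sig_name in results and len(results[sig_name]):
                    hub_ranks[f"{hub.mirna}_fdr_rank"] = fdr_rank(
                        results[sig_name], hub.mirna)
                if sig_name in hub_tables:
                    hub_ranks[f"{hub.mirna}_degree_rank"] = degree_rank(
                        hub_tables[sig_name], hub.mirna)
            recovery = truth_recovery_report(
                signatures, partition, truth, hub_ranks=hub_ranks,
            )
            manifest["stages"]["recovery"] = recovery

        stage = "finalize"
        _write_manifest(manifest, outdir)
        return RunResult(outdir=outdir, manifest=manifest)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context re-raise
        raise fail(exc) from exc


def _write_manifest(manifest: dict, outdir: Path) -> Path:
    path = outdir / "manifest.json"

    def default(obj):
        if isinstance(obj, (pd.Timestamp,)):
            return str(obj)
        if hasattr(obj, "item"):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=default) + "\n"
    )
    return path
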
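"""End-to-end orchestration of the screening stages from one config.

The stage order mirrors the study workflow: annotation cataloguing →
preprocessing with QC → differential-expression screening (per dataset)
→ cross-dataset overlap → cis-window search → trans co-expression →
gene-set enrichment → RBP motif scan.  Stages whose inputs are not
configured are skipped; a failing stage halts the run with a message
naming the stage, and every artifact written before the failure is
preserved.

Every published threshold is a named config key carrying its study value
as the default (FDR < 0.20, fold ≥ 2, p < 0.01, 10-kb window,
|rho| ≥ 0.8 with p < 0.05, count ≥ 2 with EASE ≤ 0.1, relative score
≥ 0.8).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from lncarray import annotation as ann_mod
from lncarray import cis as cis_mod
from lncarray import de as de_mod
from lncarray import enrichment as enr_mod
from lncarray import overlap as ovl_mod
from lncarray import preprocess as pre_mod
from lncarray import trans as trans_mod
from lncarray.errors import LncArrayError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DatasetConfig:
    id: str
    probes: Path
    design: Path


@dataclass
class PipelineConfig:
    outdir: Path
    datasets: list[DatasetConfig]
    seed: int = 0
    annotation_csv: Path | None = None
    gene_map: str = "catalog"                   # or "identity"
    thresholds: de_mod.DEThresholds = field(default_factory=de_mod.DEThresholds)
    qc_limits: pre_mod.QCLimits = field(default_factory=pre_mod.QCLimits)
    cis_cfg: cis_mod.CisConfig = field(default_factory=cis_mod.CisConfig)
    lncrna_intervals: Path | None = None
    gene_intervals: Path | None = None
    trans_cfg: trans_mod.TransConfig = field(default_factory=trans_mod.TransConfig)
    enrichment_filters: enr_mod.EnrichmentFilters = field(
        default_factory=enr_mod.EnrichmentFilters)
    gmt: Path | None = None
    fasta: Path | None = None
    pwms: Path | None = None
    rbp_threshold: float = 0.8

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw: dict[str, Any] = yaml.safe_load(path.read_text()) or {}
        base = path.parent

        def resolve(p: str | None) -> Path | None:
            return None if p is None else (base / p)

        datasets = [
            DatasetConfig(id=d["id"], probes=base / d["probes"],
                          design=base / d["design"])
            for d in raw.get("datasets", [])
        ]
        if not datasets:
            raise ValidationError("config defines no datasets")
        th = raw.get("thresholds", {})
        qc = raw.get("qc", {})
        cis_raw = raw.get("cis", {})
        trans_raw = raw.get("trans", {})
        enr_raw = raw.get("enrichment", {})
        rbp_raw = raw.get("rbp", {})
        return cls(
            outdir=base / raw.get("outdir", "results"),
            datasets=datasets,
            seed=int(raw.get("seed", 0)),
            annotation_csv=resolve(raw.get("annotation")),
            gene_map=raw.get("gene_map", "catalog"),
            thresholds=de_mod.DEThresholds(
                fdr_max=float(th.get("fdr_max", 0.20)),
                fold_min=float(th.get("fold_min", 2.0)),
                p_max=float(th.get("p_max", 0.01)),
            ),
            qc_limits=pre_mod.QCLimits(
                nuse_fence=float(qc.get("nuse_fence", 1.5)),
                rle_fence=float(qc.get("rle_fence", 1.5)),
            ),
            cis_cfg=cis_mod.CisConfig(window=int(cis_raw.get("window", 10_000))),
            lncrna_intervals=resolve(cis_raw.get("lncrnas")),
            gene_intervals=resolve(cis_raw.get("genes")),
            trans_cfg=trans_mod.TransConfig(
                rho_min=float(trans_raw.get("rho_min", 0.8)),
                p_max=float(trans_raw.get("p_max", 0.05)),
            ),
            enrichment_filters=enr_mod.EnrichmentFilters(
                count_min=int(enr_raw.get("count_min", 2)),
                ease_max=float(enr_raw.get("ease_max", 0.1)),
            ),
            gmt=resolve(enr_raw.get("gmt")),
            fasta=resolve(rbp_raw.get("fasta")),
            pwms=resolve(rbp_raw.get("pwms")),
            rbp_threshold=float(rbp_raw.get("threshold", 0.8)),
        )


class StageError(LncArrayError):
    """A pipeline stage failed; earlier artifacts are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute every configured stage; returns a result bundle of paths
    and in-memory tables, and writes ``run_log.json`` describing what ran."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict[str, Any]] = []
    bundle: dict[str, Any] = {"outdir": out}

    def stage(name: str, **meta: Any):
        logger.info("stage %s %s", name, meta)
        log.append({"stage": name, **meta})

    def flush_log() -> None:
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str) + "\n")

    try:
        catalog = None
        if cfg.annotation_csv is not None:
            stage("annotate", input=str(cfg.annotation_csv))
            catalog, _ = ann_mod.catalog_from_csv(cfg.annotation_csv)
            catalog.write(out / "catalog.tsv", out / "catalog_venn.json")
            bundle["catalog"] = catalog

        de_tables: dict[str, pd.DataFrame] = {}
        gene_tables: dict[str, pd.DataFrame] = {}
        expr_by_ds: dict[str, pre_mod.ProbesetExpressionMatrix] = {}
        for ds in cfg.datasets:
            stage("preprocess", dataset=ds.id, probes=str(ds.probes))
            m = pre_mod.read_probe_tsv(ds.probes, ds.design)
            expr, report = pre_mod.preprocess_and_qc(m, cfg.qc_limits)
            expr.write_tsv(out / f"expression_{ds.id}.tsv")
            report.write(out / f"qc_{ds.id}.tsv", out / f"qc_{ds.id}.json")
            expr_by_ds[ds.id] = expr
            bundle[f"qc_{ds.id}"] = report

            stage("de", dataset=ds.id, fdr_max=cfg.thresholds.fdr_max,
                  fold_min=cfg.thresholds.fold_min, p_max=cfg.thresholds.p_max)
            de_table = de_mod.screen_de(expr, cfg.thresholds)
            de_table.to_csv(out / f"de_{ds.id}.tsv", sep="\t", index=False)
            de_tables[ds.id] = de_table
            dendro = de_mod.average_linkage_cluster(expr)
            (out / f"dendrogram_{ds.id}.nwk").write_text(dendro.to_newick() + "\n")

            if cfg.gene_map == "catalog":
                if catalog is None:
                    raise ValidationError("gene_map=catalog requires an annotation CSV")
                gmap = catalog.gene_map()
            else:
                gmap = {p: p for p in de_table["probe_set_id"]}
            gene_tables[ds.id] = ovl_mod.collapse_to_genes(de_table, gmap, ds.id)
            gene_tables[ds.id].to_csv(out / f"genes_{ds.id}.tsv", sep="\t", index=False)
        bundle["de"] = de_tables
        bundle["genes"] = gene_tables

        if len(cfg.datasets) >= 2:
            a, b = cfg.datasets[0].id, cfg.datasets[1].id
            stage("overlap", datasets=[a, b])
            shared = ovl_mod.intersect_shared(gene_tables[a], gene_tables[b])
            shared.to_csv(out / "shared_lncrnas.tsv", sep="\t", index=False)
            bundle["shared"] = shared

        if cfg.lncrna_intervals is not None and cfg.gene_intervals is not None:
            stage("cis", window=cfg.cis_cfg.window)
            lncs = cis_mod.read_interval_tsv(cfg.lncrna_intervals)
            genes = cis_mod.read_interval_tsv(cfg.gene_intervals)
            cis_table = cis_mod.find_cis_targets(lncs, genes, cfg.cis_cfg)
            cis_table.to_csv(out / "cis_targets.tsv", sep="\t", index=False)
            bundle["cis"] = cis_table

        trans_tables: dict[str, pd.DataFrame] = {}
        for ds in cfg.datasets:
            de_table = de_tables[ds.id]
            called = de_table.loc[de_table["direction"] != de_mod.NO_CALL,
                                  "probe_set_id"]
            if called.empty:
                continue
            stage("trans", dataset=ds.id, rho_min=cfg.trans_cfg.rho_min,
                  p_max=cfg.trans_cfg.p_max)
            frame = expr_by_ds[ds.id].to_frame()
            lnc_rows = frame.loc[frame.index.isin(set(called))]
            gene_rows = frame.loc[~frame.index.isin(set(called))]
            table, tallies = trans_mod.find_trans_targets(
                lnc_rows, gene_rows, cfg.trans_cfg)
            table.to_csv(out / f"trans_{ds.id}.tsv", sep="\t", index=False)
            (out / f"trans_{ds.id}_tallies.json").write_text(
                json.dumps(tallies, indent=2) + "\n")
            trans_tables[ds.id] = table
        bundle["trans"] = trans_tables

        if cfg.gmt is not None:
            stage("enrich", count_min=cfg.enrichment_filters.count_min,
                  ease_max=cfg.enrichment_filters.ease_max)
            sets = enr_mod.parse_gmt(cfg.gmt)
            background = set().union(*(s.members for s in sets))
            enr_by_ds: dict[str, pd.DataFrame] = {}
            for ds in cfg.datasets:
                query: set[str] = set()
                if "cis" in bundle:
                    query |= {g for g in bundle["cis"]["gene_name"] if g}
                if ds.id in trans_tables:
                    query |= set(trans_tables[ds.id]["gene_probe_id"])
                query = {enr_mod._norm_symbol(q) for q in query} & background
                if not query:
                    continue
                table = enr_mod.enrich(query, background, sets,
                                       cfg.enrichment_filters)
                table.to_csv(out / f"enrichment_{ds.id}.tsv", sep="\t", index=False)
                enr_by_ds[ds.id] = table
            if len(enr_by_ds) >= 2:
                ids = list(enr_by_ds)
                shared_t = enr_mod.shared_terms(enr_by_ds[ids[0]], enr_by_ds[ids[1]])
                shared_t.to_csv(out / "enrichment_shared.tsv", sep="\t", index=False)
            bundle["enrichment"] = enr_by_ds

        if cfg.fasta is not None and cfg.pwms is not None:
            stage("scan", threshold=cfg.rbp_threshold)
            pwms = enr_mod.parse_pwm_file(cfg.pwms)
            seqs = enr_mod.read_fasta(cfg.fasta)
            hits, per_seq, shared_prot = enr_mod.scan_rbp(pwms, seqs,
                                                          cfg.rbp_threshold)
            hits.to_csv(out / "rbp_hits.tsv", sep="\t", index=False)
            (out / "rbp_proteins.json").write_text(json.dumps(
                {"per_lncrna": {k: sorted(v) for k, v in per_seq.items()},
                 "shared_by_all": sorted(shared_prot)}, indent=2) + "\n")
            bundle["rbp"] = hits
    except StageError:
        flush_log()
        raise
    except Exception as exc:                       # noqa: BLE001
        flush_log()
        current = log[-1]["stage"] if log else "setup"
        raise StageError(current, exc) from exc
    stage("done")
    flush_log()
    return bundle
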
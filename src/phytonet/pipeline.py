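"""End-to-end pipeline: screen -> network -> disease -> tissues -> enrichment.

One declarative YAML config drives the full workflow; every stage also
exists as a standalone CLI subcommand.  All per-stage outputs are
written to the output directory and a machine-readable ``summary.json``
records the attrition counts at every stage (inputs, screened, removed,
network sizes, profiled/unprofiled genes, tested/significant sets) —
exactly the bookkeeping a screening study reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .adme import AdmeThresholds, drop_targetless, filter_compounds
from .core import (
    ConfigurationError,
    GeneSet,
    PhytonetError,
    read_compound_table,
    read_gene_list,
    read_gmt,
    read_expression_matrix,
    read_interaction_table,
    write_compound_table,
    write_network,
)
from .enrichment import EnrichmentThresholds, enrich, rows_to_frame
from .network import build_ct_network, degree_table, restrict_to_disease, summarize
from .tissue import RULE_ABOVE_MEAN, RULE_ARGMAX, organ_counts

import pandas as pd

logger = logging.getLogger("phytonet.pipeline")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(PhytonetError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    compounds: Path
    interactions: Path
    outdir: Path
    disease: Path | None = None
    expression: Path | None = None
    annotation: Path | None = None
    background: Path | None = None
    whitelist: Path | None = None
    adme: AdmeThresholds = field(default_factory=AdmeThresholds)
    enrichment: EnrichmentThresholds = field(default_factory=EnrichmentThresholds)
    tissue_rule: str = RULE_ABOVE_MEAN
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("compounds", "interactions"):
            p = Path(getattr(self, name))
            setattr(self, name, p)
            if not p.exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        for name in ("disease", "expression", "annotation", "background", "whitelist"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise ConfigurationError(f"{name} path does not exist: {p}")
        self.outdir = Path(self.outdir)
        if self.tissue_rule not in (RULE_ABOVE_MEAN, RULE_ARGMAX):
            raise ConfigurationError(f"unknown tissue rule {self.tissue_rule!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        adme = AdmeThresholds(**raw.pop("adme", {}))
        enr = EnrichmentThresholds(**raw.pop("enrichment", {}))
        try:
            return cls(adme=adme, enrichment=enr, **raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from None

    def echo(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Path):
                v = str(v)
            elif dataclasses.is_dataclass(v):
                v = dataclasses.asdict(v)
            out[f.name] = v
        return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every configured stage in order and return the run summary.

    Optional inputs (disease set, expression matrix, annotation GMT)
    skip their stage with a logged notice; any stage failure aborts with
    a stage-named error, retaining the outputs already written.
    """
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "versions": {"phytonet": __version__},
        "config": cfg.echo(),
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": {},
    }

    # --- screen ------------------------------------------------------------
    try:
        table = read_compound_table(cfg.compounds)
        whitelist = (
            set(read_gene_list(cfg.whitelist).genes) if cfg.whitelist else set()
        )
        filtered, audit = filter_compounds(table, cfg.adme, whitelist)
        write_compound_table(filtered, outdir / "filtered.tsv")
        pd.DataFrame(audit.to_rows()).to_csv(outdir / "audit.tsv", sep="\t", index=False)
        interactions = read_interaction_table(cfg.interactions)
        retained, removed = drop_targetless(filtered, interactions)
        summary["stages"]["screen"] = {
            "input_compounds": len(table),
            "passed_thresholds": len(audit.passed),
            "failed_thresholds": len(audit.failed),
            "whitelisted_in": len(audit.whitelisted_in),
            "filtered_compounds": len(filtered),
            "targetless_removed": len(removed),
            "retained_compounds": len(retained),
        }
    except PhytonetError as exc:
        raise PipelineStageError("screen", exc)

    # --- compound-target network -------------------------------------------
    try:
        net = build_ct_network(retained, interactions)
        write_network(net, outdir / "ct.graphml", "graphml")
        write_network(net, outdir / "ct.sif", "sif")
        degree_table(net).to_csv(outdir / "degrees.tsv", sep="\t", index=False)
        s = summarize(net)
        summary["stages"]["ct_network"] = dataclasses.asdict(s)
    except PhytonetError as exc:
        raise PipelineStageError("ct_network", exc)

    # --- disease restriction -----------------------------------------------
    disease_net = None
    if cfg.disease is None:
        logger.info("no disease gene set configured; skipping disease restriction")
        summary["stages"]["disease_network"] = "skipped"
    else:
        try:
            disease = read_gene_list(cfg.disease, set_id="disease")
            disease_net = restrict_to_disease(net, disease)
            write_network(disease_net, outdir / "ctd.graphml", "graphml")
            write_network(disease_net, outdir / "ctd.sif", "sif")
            degree_table(disease_net).to_csv(
                outdir / "degrees_ctd.tsv", sep="\t", index=False
            )
            summary["stages"]["disease_network"] = {
                "disease_genes": len(disease.genes),
                "n_compounds": len(disease_net.compound_nodes),
                "n_targets": len(disease_net.target_nodes),
                "n_edges": disease_net.n_edges,
            }
        except PhytonetError as exc:
            raise PipelineStageError("disease_network", exc)

    query_targets = (disease_net or net).target_nodes

    # --- tissue location ----------------------------------------------------
    if cfg.expression is None:
        logger.info("no expression matrix configured; skipping tissue location")
        summary["stages"]["tissue_location"] = "skipped"
    else:
        try:
            expr = read_expression_matrix(cfg.expression)
            loc = organ_counts(expr, net.target_nodes, rule=cfg.tissue_rule)
            pd.DataFrame(
                {
                    "gene": list(loc.located_tissues),
                    "primary_tissue": [
                        loc.primary_tissue[g] or "" for g in loc.located_tissues
                    ],
                    "located_tissues": [
                        ",".join(sorted(loc.located_tissues[g]))
                        for g in loc.located_tissues
                    ],
                }
            ).to_csv(outdir / "locations.tsv", sep="\t", index=False)
            pd.DataFrame(
                {"tissue": list(loc.counts), "located_genes": list(loc.counts.values())}
            ).to_csv(outdir / "organ_counts.tsv", sep="\t", index=False)
            summary["stages"]["tissue_location"] = {
                "rule": loc.rule,
                "profiled": len(loc.profiled),
                "unprofiled": len(loc.unprofiled),
            }
        except PhytonetError as exc:
            raise PipelineStageError("tissue_location", exc)

    # --- enrichment ----------------------------------------------------------
    if cfg.annotation is None:
        logger.info("no annotation collection configured; skipping enrichment")
        summary["stages"]["enrichment"] = "skipped"
    else:
        try:
            collection = read_gmt(cfg.annotation)
            if cfg.background is not None:
                collection.background = read_gene_list(cfg.background, "background")
            rows = enrich(
                GeneSet("query", frozenset(query_targets)),
                collection,
                cfg.enrichment,
            )
            rows_to_frame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            summary["stages"]["enrichment"] = {
                "tested_sets": len(collection.sets),
                "reported_sets": len(rows),
                "significant_sets": sum(r.significant for r in rows),
            }
        except PhytonetError as exc:
            raise PipelineStageError("enrichment", exc)

    summary["finished"] = datetime.now(timezone.utc).isoformat()
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
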
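"""End-to-end orchestration: load -> call -> build -> score -> partition ->
degree stats -> m-core -> enrichment -> export, from one validated config.

The run writes every artifact under one output directory and returns a
machine-readable summary whose counts are all recomputable from the emitted
files.  Analyses whose inputs are absent (e.g. no TF library) are skipped
with a log notice and marked in the summary.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .degree import fit_power_law, plot_ccdf, reverse_cumulative
from .enrichment import hypergeometric_ora, results_frame, term_overlap, tf_binding_frequency
from .io import (
    read_drug_target_table,
    read_gmt,
    read_signature_table,
    write_gene_scores,
    write_gmt,
    write_graphml,
)
from .mcore import core_profile, cores_as_gene_sets, peel_decomposition
from .network import (
    TARGET,
    SENSITIVE,
    build_layer,
    compute_gene_scores,
    merge_layers,
    partition_genes,
    sample_drug_subnetwork,
)
from .signatures import SignatureCallingConfig, call_signatures

logger = logging.getLogger(__name__)

_version = "0.1.0"


class CallingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    adjusted_p_threshold: float = Field(0.05, gt=0, le=1)
    fc_upper: float = Field(2.0, gt=1)
    fc_lower: float = Field(0.5, gt=0, lt=1)
    adjust_method: Literal["benjamini-hochberg", "none"] = "benjamini-hochberg"
    adjust_scope: Literal["per-drug", "global"] = "per-drug"

    def to_config(self) -> SignatureCallingConfig:
        return SignatureCallingConfig(**self.model_dump())


class SamplingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    drug_fraction: float = Field(gt=0, le=1)
    seed: int


class MCoreSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    strict: bool = False
    largest_component_only: bool = False
    min_genes: int = Field(50, ge=1)  # layers smaller than this are not decomposed


class OraSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    libraries: list[str] = Field(default_factory=list)
    fdr_threshold: float = Field(0.05, gt=0, le=1)


class PipelineConfig(BaseModel):
    """Validated run configuration (strict schema: unknown keys are rejected)."""

    model_config = ConfigDict(extra="forbid")

    target_table: str
    target_dialect: Literal["two-column-tsv", "gmt"] = "two-column-tsv"
    signature_tables: list[str] = Field(min_length=1)
    calling: CallingSection = Field(default_factory=CallingSection)
    sampling: SamplingSection | None = None
    mcore: MCoreSection = Field(default_factory=MCoreSection)
    ora: OraSection = Field(default_factory=OraSection)
    tf_library: str | None = None
    output_dir: str = "dgnet-run"
    plots: bool = False

    @model_validator(mode="after")
    def _paths_exist(self) -> "PipelineConfig":
        missing = [
            p
            for p in [
                self.target_table,
                *self.signature_tables,
                *self.ora.libraries,
                *( [self.tf_library] if self.tf_library else [] ),
            ]
            if not Path(p).exists()
        ]
        if missing:
            raise ValueError(f"input paths do not exist: {missing}")
        return self


class RunSummary(BaseModel):
    """Counts and provenance for one landscape run; every count is
    recomputable from the emitted artifacts."""

    n_drugs: dict[str, int]
    n_genes: dict[str, int]
    n_edges: dict[str, int]
    partition_sizes: dict[str, int]
    kdtn_range: tuple[int, int]
    kdsn_range: tuple[int, int]
    m_max: dict[str, int]
    skipped: list[str]
    version: str
    config: dict[str, Any]
    started_at: str
    artifacts: dict[str, str]


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse + validate a YAML/JSON config, reporting every violation at once."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as err:
        lines = [
            f"{'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ValueError(f"{path}: invalid config:\n  " + "\n  ".join(lines)) from err


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_landscape(config: PipelineConfig) -> RunSummary:
    """Run every analysis whose inputs are present and write all artifacts."""
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    skipped: list[str] = []
    artifacts: dict[str, str] = {}

    def _stage(name: str):
        logger.info("stage: %s", name)
        return name

    try:
        stage = _stage("load")
        targets = read_drug_target_table(config.target_table, config.target_dialect)
        sig_tables = [read_signature_table(p) for p in config.signature_tables]

        stage = _stage("call")
        calling = config.calling.to_config()
        called_pairs: set[tuple[str, str]] = set()
        for table in sig_tables:
            called_pairs |= call_signatures(table, calling).pairs

        stage = _stage("build")
        dtn = build_layer(targets.pairs, TARGET)
        dsn = build_layer(called_pairs, SENSITIVE)
        merged = merge_layers(dtn, dsn)
        if config.sampling is not None:
            merged = sample_drug_subnetwork(
                merged, config.sampling.drug_fraction, config.sampling.seed
            )
            dtn = merged.layer_view(TARGET)
            dsn = merged.layer_view(SENSITIVE)

        stage = _stage("score")
        scores = compute_gene_scores(merged)
        partition = partition_genes(scores)
        artifacts["scores"] = str(outdir / "gene_scores.tsv")
        write_gene_scores(scores, artifacts["scores"], partition)
        artifacts["partition"] = str(outdir / "partition.gmt")
        sets = {k: v for k, v in zip(("DTG", "DSG", "DTSG"),
                                     (partition.dtg, partition.dsg, partition.dtsg)) if v}
        if sets:
            write_gmt(sets, artifacts["partition"])
        artifacts["network"] = str(outdir / "network.graphml")
        write_graphml(merged, artifacts["network"], partition)

        stage = _stage("distributions")
        fit_rows = []
        for layer, net in ((TARGET, dtn), (SENSITIVE, dsn)):
            degrees = [
                scores.kdtn[g] if layer == TARGET else scores.kdsn[g]
                for g in net.genes
            ]
            degrees = [d for d in degrees if d >= 1]
            if not degrees:
                skipped.append(f"distributions:{layer}")
                continue
            curve = reverse_cumulative(degrees)
            pd.DataFrame(curve.as_table(), columns=["k", "ccdf"]).to_csv(
                outdir / f"ccdf_{layer}.tsv", sep="\t", index=False
            )
            artifacts[f"ccdf_{layer}"] = str(outdir / f"ccdf_{layer}.tsv")
            try:
                fit = fit_power_law(degrees, xmin="auto")
                fit_rows.append(
                    {"layer": layer, "alpha": fit.alpha, "xmin": fit.xmin,
                     "n_tail": fit.n_tail, "ks_distance": fit.ks_distance}
                )
            except ValueError as err:
                logger.warning("power-law fit skipped for %s: %s", layer, err)
                skipped.append(f"powerlaw:{layer}")
            if config.plots:
                plot_ccdf({layer: curve}, str(outdir / f"ccdf_{layer}.png"))
        if fit_rows:
            artifacts["powerlaw_fits"] = str(outdir / "powerlaw_fits.tsv")
            pd.DataFrame(fit_rows).to_csv(artifacts["powerlaw_fits"], sep="\t", index=False)

        stage = _stage("mcore")
        m_max: dict[str, int] = {}
        for layer, net in ((TARGET, dtn), (SENSITIVE, dsn)):
            if len(net.genes) <= config.mcore.min_genes:
                skipped.append(f"mcore:{layer}")
                continue
            dec = peel_decomposition(
                net, strict=config.mcore.strict,
                largest_component_only=config.mcore.largest_component_only,
            )
            m_max[layer] = dec.m_max
            core_profile(dec).to_csv(outdir / f"mcore_profile_{layer}.tsv", sep="\t", index=False)
            write_gmt(cores_as_gene_sets(dec), outdir / f"mcore_{layer}.gmt")
            artifacts[f"mcore_profile_{layer}"] = str(outdir / f"mcore_profile_{layer}.tsv")
            artifacts[f"mcore_{layer}"] = str(outdir / f"mcore_{layer}.gmt")

        stage = _stage("enrichment")
        universe = {g for g in scores.genes if scores.kdtn[g] or scores.kdsn[g]}
        gene_sets = {"DTG": partition.dtg, "DSG": partition.dsg, "DTSG": partition.dtsg}
        if config.ora.libraries:
            for lib_path in config.ora.libraries:
                library = read_gmt(lib_path)
                sig_terms: dict[str, list[str]] = {}
                for set_name, members in gene_sets.items():
                    if not members:
                        continue
                    results = hypergeometric_ora(
                        members, universe, library, config.ora.fdr_threshold
                    )
                    out = outdir / f"ora_{library.name}_{set_name}.tsv"
                    results_frame(results).to_csv(out, sep="\t", index=False)
                    artifacts[f"ora_{library.name}_{set_name}"] = str(out)
                    sig_terms[set_name] = [r.term for r in results]
                if len(sig_terms) >= 2:
                    table, overlap_counts = term_overlap(sig_terms)
                    out = outdir / f"term_overlap_{library.name}.tsv"
                    table.to_csv(out, sep="\t", index=False)
                    artifacts[f"term_overlap_{library.name}"] = str(out)
                    (outdir / f"term_overlap_{library.name}.json").write_text(
                        json.dumps(overlap_counts, indent=1) + "\n", encoding="utf-8"
                    )
        else:
            skipped.append("enrichment")
            logger.info("enrichment skipped: no libraries configured")

        stage = _stage("tf")
        if config.tf_library:
            tf_lib = read_gmt(config.tf_library)
            rows = []
            for set_name, members in gene_sets.items():
                if not members:
                    continue
                summary = tf_binding_frequency(members, tf_lib)
                rows.append(
                    {"set": set_name, "mean_tfs_per_gene": summary.mean_tfs_per_gene,
                     "n_tfs": len(summary.tf_set), "n_genes": len(members)}
                )
            artifacts["tf_frequency"] = str(outdir / "tf_frequency.tsv")
            pd.DataFrame(rows).to_csv(artifacts["tf_frequency"], sep="\t", index=False)
        else:
            skipped.append("tf")
            logger.info("TF analysis skipped: no TF library configured")
    except Exception as err:  # noqa: BLE001 - re-raise with the stage name
        raise StageError(f"stage '{stage}' failed: {err}") from err

    kdtn_vals = [v for v in scores.kdtn.values() if v >= 1] or [0]
    kdsn_vals = [v for v in scores.kdsn.values() if v >= 1] or [0]
    summary = RunSummary(
        n_drugs={
            "target": len(dtn.drugs), "sensitive": len(dsn.drugs),
            "merged": len(merged.drugs),
        },
        n_genes={
            "target": len(dtn.genes), "sensitive": len(dsn.genes),
            "merged": len(merged.genes),
        },
        n_edges={
            "target": len(dtn.edges), "sensitive": len(dsn.edges),
            "merged": len(merged.edges),
        },
        partition_sizes=partition.sizes(),
        kdtn_range=(min(kdtn_vals), max(kdtn_vals)),
        kdsn_range=(min(kdsn_vals), max(kdsn_vals)),
        m_max=m_max,
        skipped=sorted(skipped),
        version=_version,
        config=config.model_dump(),
        started_at=started,
        artifacts=artifacts,
    )
    summary_path = outdir / "summary.json"
    summary_path.write_text(summary.model_dump_json(indent=1) + "\n", encoding="utf-8")
    logger.info("run complete: %s", summary_path)
    return summary
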
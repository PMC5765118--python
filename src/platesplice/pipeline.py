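"""End-to-end pipeline: simulate -> quantify -> test -> database -> match -> integrate.

One structured config drives every stage; all randomness derives from the
root seed, so a rerun with the same config reproduces identical TSVs (the
manifest records a checksum per output).  Stages communicate only through
their declared files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation_io, diff_stats, integrate, ir_quant, junction_db, peptide_match
from .annotation_io import QuantTable, read_quant_table, write_tsv
from .synthetic_data import SimulationConfig, simulate_dataset

log = logging.getLogger("platesplice")


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "platesplice_out"
    simulation: dict = field(default_factory=dict)
    ir_filter: dict = field(default_factory=dict)
    diff: dict = field(default_factory=dict)
    flank: int = 75
    strandedness: str = "reverse"
    il_equivalent: bool = False
    inputs: dict | None = None  # optional pre-existing inputs instead of simulation

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)

    def filter_params(self) -> ir_quant.IRFilterParams:
        return ir_quant.IRFilterParams(**self.ir_filter)

    def diff_config(self, stage: int) -> diff_stats.DiffTestConfig:
        seed = derive_seed(self.seed, stage)
        return diff_stats.DiffTestConfig(seed=seed, **self.diff)


def derive_seed(root_seed: int, stage: int) -> int:
    """Per-stage seed derived from the root seed (stable, < 2**31)."""
    state = np.random.SeedSequence([root_seed, stage]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    if config.inputs is not None:
        missing = [str(v) for k, v in _flatten_inputs(config.inputs)
                   if not Path(v).exists()]
        if missing:
            raise FileNotFoundError(f"missing pipeline inputs: {missing}")

    # --- stage 1: inputs -------------------------------------------------
    if config.inputs is None:
        log.info("simulate: writing synthetic dataset")
        dataset = simulate_dataset(config.sim_config(), out / "sim")
        genome_path = dataset.paths["genome"]
        gtf_path = dataset.paths["gtf"]
        sam_paths = {k: str(v) for k, v in dataset.paths["sam"].items()}
        proteins_path = dataset.paths["proteins"]
        peptides_path = dataset.paths["peptides"]
        map_path = dataset.paths["protein_gene_map"]
    else:
        genome_path = config.inputs["genome"]
        gtf_path = config.inputs["gtf"]
        sam_paths = dict(config.inputs["sam"])
        proteins_path = config.inputs["proteins"]
        peptides_path = config.inputs["peptides"]
        map_path = config.inputs["protein_gene_map"]

    genome = annotation_io.read_genome(genome_path)
    annotation = annotation_io.read_annotation(gtf_path)
    groups = annotation_io.groups_from_sample_ids(sam_paths)
    stimuli = sorted(set(groups.values()) - {"CTRL"})
    params = config.filter_params()

    # --- stage 2: IR quantification --------------------------------------
    log.info("ir-quant: %d samples", len(sam_paths))
    ir_long = ir_quant.compute_ir_matrix(
        sam_paths, annotation, params, strandedness=config.strandedness)
    outputs["ir_matrix"] = out / "ir_matrix.tsv"
    write_tsv(ir_long, outputs["ir_matrix"])
    ir_wide = ir_quant.pivot_ir(ir_long)
    intron_to_gene = dict(zip(ir_long["intron_id"], ir_long["gene_id"]))

    retained: dict[str, set[str]] = {}
    for group in ["CTRL"] + stimuli:
        retained[group] = ir_quant.filter_retained(ir_wide, params, group, groups)
        path = out / f"retained_{group}.tsv"
        write_tsv(pd.DataFrame({"intron_id": sorted(retained[group])}), path)
        outputs[f"retained_{group}"] = path

    # --- stage 3: differential IR ----------------------------------------
    diff_ir: dict[str, pd.DataFrame] = {}
    for k, stim in enumerate(stimuli):
        log.info("diff-ir: %s vs CTRL", stim)
        cfg = config.diff_config(10 + k)
        diff_ir[stim] = diff_stats.call_differential_introns(
            ir_wide, groups, cfg, stim, retained=retained["CTRL"] | retained[stim])
        outputs[f"diff_ir_{stim}"] = out / f"diff_ir_{stim}.tsv"
        write_tsv(diff_ir[stim], outputs[f"diff_ir_{stim}"])
        hist = diff_stats.introns_per_gene_summary(diff_ir[stim], intron_to_gene)
        outputs[f"introns_per_gene_{stim}"] = out / f"introns_per_gene_{stim}.tsv"
        write_tsv(hist, outputs[f"introns_per_gene_{stim}"])

    # --- stage 4: transcript expression ----------------------------------
    log.info("expression: counting gene fragments")
    counts = pd.DataFrame({
        s: ir_quant.gene_read_counts(p, annotation, strandedness=config.strandedness)
        for s, p in sam_paths.items()})
    outputs["gene_counts"] = out / "gene_counts.tsv"
    write_tsv(counts.rename_axis("gene_id").reset_index(), outputs["gene_counts"])
    lengths = ir_quant.gene_exon_lengths(annotation)
    expression: dict[str, pd.DataFrame] = {}
    for k, stim in enumerate(stimuli):
        cfg = config.diff_config(20 + k)
        expression[stim] = integrate.transcript_expression(
            counts, lengths, groups, cfg, stim)
        outputs[f"expression_{stim}"] = out / f"expression_{stim}.tsv"
        write_tsv(expression[stim], outputs[f"expression_{stim}"])

    # --- stage 5: differential proteins ----------------------------------
    protein_table = read_quant_table(proteins_path)
    diff_protein: dict[str, pd.DataFrame] = {}
    for k, stim in enumerate(stimuli):
        log.info("diff-protein: %s vs CTRL", stim)
        cfg = config.diff_config(30 + k)
        diff_protein[stim] = diff_stats.call_differential_proteins(
            protein_table, cfg, stim)
        outputs[f"diff_protein_{stim}"] = out / f"diff_protein_{stim}.tsv"
        write_tsv(diff_protein[stim], outputs[f"diff_protein_{stim}"])

    if {"COLL", "TRAP"} <= set(stimuli):
        part = integrate.partition_stimulus_sets(
            diff_protein["COLL"], diff_protein["TRAP"])
        rows = ([{"feature_id": f, "set": "coll_only"} for f in sorted(part.coll_only)]
                + [{"feature_id": f, "set": "trap_only"} for f in sorted(part.trap_only)]
                + [{"feature_id": f, "set": "common"} for f in sorted(part.common)])
        outputs["partition"] = out / "partition.tsv"
        write_tsv(pd.DataFrame(rows, columns=["feature_id", "set"]), outputs["partition"])
        outputs["partition_direction"] = out / "partition_direction.tsv"
        write_tsv(pd.DataFrame([part.common_direction]), outputs["partition_direction"])

    # --- stage 6: junction database ---------------------------------------
    log.info("junction-db: retained introns in CTRL")
    introns = {i.intron_id: i for i in
               (iv for g in annotation.genes for iv in annotation_io.derive_introns(g))}
    ctrl_retained = [introns[i] for i in sorted(retained["CTRL"]) if i in introns]
    sites, entries = junction_db.build_junction_database(
        genome, annotation, ctrl_retained, flank=config.flank)
    outputs["junctions"] = out / "junctions.fasta"
    junction_db.write_junction_fasta(entries, sites, outputs["junctions"])
    junction_to_gene = {s.junction_id: s.gene_id for s in sites}

    # --- stage 7: peptide matching ----------------------------------------
    peptide_df = peptide_match.read_peptide_table(peptides_path)
    matches = peptide_match.match_peptides(
        list(peptide_df["peptide_seq"]), entries, il_equivalent=config.il_equivalent)
    pep_groups = annotation_io.groups_from_sample_ids(
        peptide_match.peptide_sample_columns(peptide_df))
    junction_quant: dict[str, pd.DataFrame] = {}
    for k, stim in enumerate(stimuli):
        log.info("match-peptides: %s vs CTRL", stim)
        cfg = config.diff_config(40 + k)
        junction_quant[stim] = peptide_match.quantify_junction_peptides(
            matches, peptide_df, pep_groups, cfg, stim,
            junction_ids=[s.junction_id for s in sites])
        outputs[f"junction_peptides_{stim}"] = out / f"junction_peptides_{stim}.tsv"
        write_tsv(junction_quant[stim], outputs[f"junction_peptides_{stim}"])

    # --- stage 8: integration ---------------------------------------------
    mapping = pd.read_csv(map_path, sep="\t")
    protein_to_gene = dict(zip(mapping["protein_id"], mapping["gene_id"]))
    for k, stim in enumerate(stimuli):
        cfg = config.diff_config(50 + k)
        scatter = integrate.protein_mrna_scatter(
            diff_protein[stim], expression[stim], protein_to_gene, cfg)
        outputs[f"scatter_{stim}"] = out / f"scatter_{stim}.tsv"
        write_tsv(scatter, outputs[f"scatter_{stim}"])
    validation = integrate.build_validation_table(
        diff_ir, diff_protein, junction_quant, protein_to_gene,
        junction_to_gene, intron_to_gene)
    outputs["validation"] = out / "validation.tsv"
    write_tsv(validation, outputs["validation"])

    manifest = {
        "seed": config.seed,
        "outputs": {k: {"path": str(p), "sha256": _sha256(Path(p))}
                    for k, p in outputs.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("run-all complete: %d outputs", len(outputs))
    return manifest


def _flatten_inputs(inputs: dict):
    for k, v in inputs.items():
        if isinstance(v, dict):
            yield from ((f"{k}.{k2}", v2) for k2, v2 in v.items())
        else:
            yield k, v
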
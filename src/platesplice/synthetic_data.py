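"""Synthetic platelet activation dataset with known ground truth.

The generator emulates the study design the pipeline was built for: three
resting (CTRL) and three treated replicates per stimulus (COLL, TRAP), a
toy genome of independent single-transcript genes with 2-4 exons,
strand-specific single-end alignments in which each intron's balance of
purely intronic coverage versus exact junction-spanning reads follows a
known true IR ratio, TMT-like log-normal protein intensities with planted
fold-changes, and junction-spanning peptides (taken verbatim from the
package's own three-frame junction translations) whose abundance rises in
treated samples.

Per intron and sample, ``depth_per_gene`` coverage units are split
binomially: K ~ Binomial(C, true_IR) units become uniform intronic
pre-mRNA coverage (reads may straddle the intron/exon boundaries so the
median per-base depth is an unbiased K) and the remaining C - K become
junction reads whose alignment gap equals the intron exactly.  The
estimated IR ratio K/(K + (C-K)) is then a binomial proportion estimate of
the true IR.  Spliced exonic reads are placed within single exons so they
never alias a splice junction.

All randomness flows from one root seed through ``numpy`` SeedSequence
spawning; a fixed seed reproduces byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .annotation_io import (
    Annotation,
    AuxFeature,
    GeneModel,
    GenomeSequence,
    IntronInterval,
    derive_introns,
    write_annotation,
    write_genome,
    write_tsv,
)
from .junction_db import extract_spliced_window, junctions_from_introns, translate_frame

_AA_BACKGROUND = "ACDEFGHIKMNPQRSTVWY"  # L left out so I/L folding stays trivial


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters of the simulated experiment.

    Defaults mirror the emulated design: triplicates per condition, two
    stimuli, ~60x per-intron coverage, removal effects of delta IR = -0.4
    planted on retained (high-baseline) introns, |log2FC| = 1 protein
    effects with 0.1 log2 replicate noise.
    """

    seed: int = 0
    n_genes: int = 120
    exon_len: tuple[int, int] = (80, 130)
    intron_len: tuple[int, int] = (90, 160)
    read_len: int = 50
    depth_per_gene: int = 60
    exonic_fragments_per_gene: int = 60
    n_replicates: int = 3
    stimuli: tuple[str, ...] = ("COLL", "TRAP")
    ir_ctrl: tuple[float, float] = (2.0, 5.0)  # Beta(a, b) baseline IR
    removal_base_range: tuple[float, float] = (0.5, 0.85)
    n_removal: dict = field(default_factory=lambda: {"COLL": 16, "TRAP": 12})
    n_removal_shared: int = 5
    removal_delta: float = -0.4
    planted_removal: dict | None = None  # intron_id -> {stimulus: delta}
    planted_protein_fc: dict | None = None  # protein_id -> {stimulus: log2fc}
    planted_protein_lfc: float = 1.0
    n_extra_protein_fc: dict = field(default_factory=lambda: {"COLL": 10, "TRAP": 6})
    n_extra_protein_shared: int = 5
    noise_sd: float = 0.1
    junction_peptide_rate: float = 0.8
    peptide_len: int = 10
    n_background_peptides: int = 80
    flank: int = 75
    snorna_rate: float = 0.05
    strandedness: str = "reverse"
    base_intensity_log2: float = 10.0
    intensity_spread_log2: float = 1.5
    contig_pad: int = 80

    def __post_init__(self) -> None:
        if self.intron_len[0] < self.read_len:
            raise ConfigError("minimum intron length must be >= read_len")
        if self.exon_len[0] < self.read_len:
            raise ConfigError("minimum exon length must be >= read_len")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")

    @property
    def conditions(self) -> tuple[str, ...]:
        return ("CTRL",) + tuple(self.stimuli)

    def samples(self) -> list[str]:
        return [f"{cond}_{r + 1}" for cond in self.conditions
                for r in range(self.n_replicates)]

    def groups(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.samples()}


@dataclass
class GroundTruth:
    """Planted truth: per-intron IR by condition, protein log2FCs, gene flags."""

    ir: pd.DataFrame        # index intron_id; gene_id + one column per condition
    planted: dict           # intron_id -> {stimulus: delta}
    protein_fc: dict        # protein_id -> {stimulus: log2fc}
    genes: pd.DataFrame     # gene_id, stimulus, spliced_and_translated, intron_id, peptide_seq

    def removal_introns(self, stimulus: str) -> set[str]:
        return {i for i, d in self.planted.items() if stimulus in d}


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def simulate_genome_and_annotation(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GenomeSequence, Annotation]:
    """One contig per gene; 2-4 exons; i.i.d. uniform ACGT sequence."""
    genome: GenomeSequence = {}
    genes: list[GeneModel] = []
    aux: list[AuxFeature] = []
    bases = np.array(list("ACGT"))
    for i in range(config.n_genes):
        gene_id = f"g{i:04d}"
        contig = f"c_{gene_id}"
        n_exons = int(rng.integers(2, 5))
        exon_lens = rng.integers(config.exon_len[0], config.exon_len[1] + 1, n_exons)
        intron_lens = rng.integers(
            config.intron_len[0], config.intron_len[1] + 1, n_exons - 1)
        strand = str(rng.choice(["+", "-"]))
        pos = config.contig_pad
        exons: list[tuple[int, int]] = []
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        total = pos + config.contig_pad
        genome[contig] = "".join(rng.choice(bases, total))
        genes.append(GeneModel(gene_id, contig, strand, [("t1", exons)]))
        # occasionally drop a snoRNA inside an intron: exercises the
        # exclusion mask of the measurable region
        for j in range(n_exons - 1):
            if rng.random() < config.snorna_rate:
                s = exons[j][1] + int(intron_lens[j]) // 2 - 10
                aux.append(AuxFeature(
                    "snoRNA", contig, s, s + 20, strand,
                    {"gene_id": f"sno_{gene_id}_{j}"}))
    return genome, Annotation(genes=genes, aux_features=aux)


def all_introns(annotation: Annotation) -> list[IntronInterval]:
    out: list[IntronInterval] = []
    for gene in annotation.genes:
        out.extend(derive_introns(gene))
    return out


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def plant_truth(
    config: SimulationConfig,
    genome: GenomeSequence,
    annotation: Annotation,
    rng: np.random.Generator,
) -> GroundTruth:
    """Draw baseline IR ratios and plant removal/protein/peptide effects.

    Removal effects are planted on one intron per selected gene, and those
    introns get high baseline IR (they model retained introns of immature
    transcripts); a ``junction_peptide_rate`` fraction of removal genes are
    additionally flagged spliced-and-translated: they receive a +1 log2FC
    protein effect and emit one junction-spanning peptide whose sequence is
    read off the package's own junction translation.
    """
    introns = all_introns(annotation)
    intron_ids = [i.intron_id for i in introns]
    by_id = {i.intron_id: i for i in introns}
    gene_of = {i.intron_id: i.gene_id for i in introns}

    a, b = config.ir_ctrl
    base = rng.beta(a, b, len(introns))

    if config.planted_removal is not None:
        planted = {k: dict(v) for k, v in config.planted_removal.items()}
    else:
        planted = _sample_removals(config, introns, rng)

    lo, hi = config.removal_base_range
    idx = {iid: k for k, iid in enumerate(intron_ids)}
    for iid in planted:
        base[idx[iid]] = rng.uniform(lo, hi)

    ir = pd.DataFrame({"gene_id": [gene_of[i] for i in intron_ids]},
                      index=pd.Index(intron_ids, name="intron_id"))
    ir["CTRL"] = base
    for stim in config.stimuli:
        theta = base.copy()
        for iid, deltas in planted.items():
            if stim in deltas:
                theta[idx[iid]] = np.clip(base[idx[iid]] + deltas[stim], 0.01, 0.99)
        ir[stim] = theta

    # proteins: one per gene
    if config.planted_protein_fc is not None:
        protein_fc = {k: dict(v) for k, v in config.planted_protein_fc.items()}
        gene_rows: list[dict] = []
    else:
        protein_fc, gene_rows = _plant_proteins_and_peptides(
            config, genome, annotation, planted, by_id, rng)

    genes_df = pd.DataFrame(
        gene_rows, columns=["gene_id", "stimulus", "spliced_and_translated",
                            "intron_id", "peptide_seq"])
    return GroundTruth(ir=ir, planted=planted, protein_fc=protein_fc, genes=genes_df)


def _sample_removals(config, introns, rng) -> dict[str, dict[str, float]]:
    by_gene: dict[str, list] = {}
    for i in introns:
        by_gene.setdefault(i.gene_id, []).append(i)
    gene_ids = sorted(by_gene)
    need_unique = config.n_removal_shared + sum(
        max(0, config.n_removal[s] - config.n_removal_shared) for s in config.stimuli)
    if need_unique > len(gene_ids):
        raise ConfigError("not enough genes for the requested removal events")
    chosen = list(rng.choice(gene_ids, size=need_unique, replace=False))
    shared = chosen[: config.n_removal_shared]
    rest = chosen[config.n_removal_shared:]
    planted: dict[str, dict[str, float]] = {}

    def plant(gene_id: str, stims: tuple[str, ...]) -> None:
        intron = by_gene[gene_id][int(rng.integers(len(by_gene[gene_id])))]
        planted[intron.intron_id] = {s: config.removal_delta for s in stims}

    for g in shared:
        plant(g, tuple(config.stimuli))
    pos = 0
    for stim in config.stimuli:
        extra = max(0, config.n_removal[stim] - config.n_removal_shared)
        for g in rest[pos:pos + extra]:
            plant(g, (stim,))
        pos += extra
    return planted


def _plant_proteins_and_peptides(config, genome, annotation, planted, by_id, rng):
    protein_fc: dict[str, dict[str, float]] = {}
    gene_rows: list[dict] = []
    removal_genes: dict[str, dict] = {}
    for iid, deltas in sorted(planted.items()):
        removal_genes.setdefault(by_id[iid].gene_id,
                                 {"intron": by_id[iid], "stims": set()})
        removal_genes[by_id[iid].gene_id]["stims"] |= set(deltas)

    for gene_id in sorted(removal_genes):
        info = removal_genes[gene_id]
        if rng.random() >= config.junction_peptide_rate:
            continue
        protein_fc[f"P_{gene_id}"] = {
            s: config.planted_protein_lfc for s in sorted(info["stims"])}
        peptide = _junction_peptide(
            genome, annotation, info["intron"], config.flank, config.peptide_len)
        for stim in sorted(info["stims"]):
            gene_rows.append({
                "gene_id": gene_id, "stimulus": stim,
                "spliced_and_translated": True,
                "intron_id": info["intron"].intron_id,
                "peptide_seq": peptide or ""})

    # extra modulated proteins on genes without removal effects
    free = sorted(set(g.gene_id for g in annotation.genes) - set(removal_genes))
    n_shared = config.n_extra_protein_shared
    need = n_shared + sum(
        max(0, config.n_extra_protein_fc[s] - n_shared) for s in config.stimuli)
    extra = list(rng.choice(free, size=min(need, len(free)), replace=False))
    pos = 0
    for g in extra[:n_shared]:
        sign = -1.0 if rng.random() < 0.75 else 1.0  # mostly joint down-regulation
        protein_fc[f"P_{g}"] = {
            s: sign * config.planted_protein_lfc for s in config.stimuli}
    pos = n_shared
    for stim in config.stimuli:
        k = max(0, config.n_extra_protein_fc[stim] - n_shared)
        for g in extra[pos:pos + k]:
            sign = -1.0 if rng.random() < 0.5 else 1.0
            protein_fc[f"P_{g}"] = {stim: sign * config.planted_protein_lfc}
        pos += k
    return protein_fc, gene_rows


def _junction_peptide(genome, annotation, intron, flank, pep_len) -> str | None:
    """A stop-free junction-spanning peptide from the gene's own translation."""
    (site,) = junctions_from_introns([intron], annotation)
    window = extract_spliced_window(genome, annotation, site, flank=flank)
    L = window.L
    for frame in (0, 1, 2):
        aa = translate_frame(window.spliced_seq, frame)
        center = (L - frame) // 3
        for jitter in (0, -1, 1, -2, 2, -3, 3):
            a = center - pep_len // 2 + jitter
            if a < 0 or a + pep_len > len(aa):
                continue
            nt_start, nt_end = frame + 3 * a, frame + 3 * (a + pep_len)
            if not (nt_start < L < nt_end):
                continue
            pep = aa[a:a + pep_len]
            if "*" not in pep and "X" not in pep:
                return pep
    return None


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def simulate_alignments(
    config: SimulationConfig,
    genome: GenomeSequence,
    annotation: Annotation,
    truth: GroundTruth,
    sample: str,
    condition: str,
    rng: np.random.Generator,
    path,
) -> None:
    """Write one sample's SAM: exonic, intronic and junction reads.

    Junction reads carry a gap matching the intron exactly; intronic reads
    give uniform per-base pre-mRNA coverage; read orientation encodes the
    gene strand under the configured library protocol.
    """
    L = config.read_len
    header = pysam.AlignmentHeader.from_references(
        list(genome), [len(genome[c]) for c in genome])
    tid = {c: k for k, c in enumerate(genome)}
    serial = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for gene in annotation.genes:
            seq = genome[gene.contig]
            exons = gene.transcripts[0][1]
            is_reverse = _read_is_reverse(gene.strand, config.strandedness, rng)

            def emit(pos: int, cigar: str, read_seq: str) -> None:
                nonlocal serial
                a = pysam.AlignedSegment(header)
                a.query_name = f"{sample}:{gene.gene_id}:{serial}"
                serial += 1
                a.reference_id = tid[gene.contig]
                a.reference_start = pos
                a.cigarstring = cigar
                a.mapping_quality = 60
                a.query_sequence = read_seq
                a.flag = 16 if is_reverse() else 0
                out.write(a)

            # spliced exonic reads, fully inside single exons
            n_exonic = int(rng.poisson(config.exonic_fragments_per_gene))
            weights = np.array([e - s - L + 1 for s, e in exons], dtype=float)
            weights /= weights.sum()
            for _ in range(n_exonic):
                ei = int(rng.choice(len(exons), p=weights))
                s, e = exons[ei]
                pos = int(rng.integers(s, e - L + 1))
                emit(pos, f"{L}M", seq[pos:pos + L])

            for intron in derive_introns(gene):
                theta = float(truth.ir.loc[intron.intron_id, condition])
                C = config.depth_per_gene
                K = int(rng.binomial(C, theta))
                n_junction = C - K
                M = intron.end - intron.start
                for _ in range(n_junction):
                    a_len = int(rng.integers(1, L))
                    pos = intron.start - a_len
                    read_seq = (seq[pos:intron.start]
                                + seq[intron.end:intron.end + (L - a_len)])
                    emit(pos, f"{a_len}M{M}N{L - a_len}M", read_seq)
                n_intronic = int(round(K * (M + L - 1) / L))
                if n_intronic:
                    starts = rng.integers(
                        intron.start - (L - 1), intron.end, n_intronic)
                    for pos in starts:
                        pos = int(pos)
                        emit(pos, f"{L}M", seq[pos:pos + L])


def _read_is_reverse(gene_strand: str, strandedness: str, rng):
    if strandedness == "reverse":
        flag = gene_strand == "+"
        return lambda: flag
    if strandedness == "forward":
        flag = gene_strand == "-"
        return lambda: flag
    return lambda: bool(rng.random() < 0.5)


def simulate_ir_matrix(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Count-level fast path: IR ratios drawn directly from the binomial model.

    Statistically equivalent to quantifying the simulated alignments (each
    sample's ratio is K/C with K ~ Binomial(depth, true IR)) but without
    read placement; used for large calibration sweeps.
    """
    C = config.depth_per_gene
    data = {}
    for cond in config.conditions:
        theta = truth.ir[cond].to_numpy()
        for r in range(config.n_replicates):
            K = rng.binomial(C, theta)
            data[f"{cond}_{r + 1}"] = K / C
    return pd.DataFrame(data, index=truth.ir.index)


# ---------------------------------------------------------------------------
# protein / peptide tables
# ---------------------------------------------------------------------------

def simulate_protein_and_peptide_tables(
    config: SimulationConfig,
    annotation: Annotation,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TMT-like protein intensities and a peptide table with planted effects.

    intensity = 2^(base + log2FC[group] + N(0, noise_sd)); planted junction
    peptides follow the same model around a peptide-level baseline, so their
    abundance tracks the planted splicing events.
    """
    samples = config.samples()
    groups = config.groups()
    proteins = [f"P_{g.gene_id}" for g in annotation.genes]
    gene_of = {f"P_{g.gene_id}": g.gene_id for g in annotation.genes}
    base = rng.normal(config.base_intensity_log2, config.intensity_spread_log2,
                      len(proteins))
    prot = {}
    for s in samples:
        lfc = np.array([truth.protein_fc.get(p, {}).get(groups[s], 0.0)
                        for p in proteins])
        noise = (rng.normal(0.0, config.noise_sd, len(proteins))
                 if config.noise_sd > 0 else 0.0)
        prot[s] = np.power(2.0, base + lfc + noise)
    protein_df = pd.DataFrame(prot, index=pd.Index(proteins, name="protein_id"))

    rows = []
    planted_peps = truth.genes[truth.genes["peptide_seq"] != ""]
    for pep, sub in planted_peps.groupby("peptide_seq"):
        stims = set(sub["stimulus"])
        gene_id = sub["gene_id"].iloc[0]
        pb = rng.normal(config.base_intensity_log2 - 2, config.intensity_spread_log2)
        row = {"peptide_seq": pep, "protein_id": f"P_{gene_id}"}
        for s in samples:
            lfc = config.planted_protein_lfc if groups[s] in stims else 0.0
            noise = (rng.normal(0.0, config.noise_sd)
                     if config.noise_sd > 0 else 0.0)
            row[s] = float(np.power(2.0, pb + lfc + noise))
        rows.append(row)
    for k in range(config.n_background_peptides):
        pep = "".join(rng.choice(list(_AA_BACKGROUND), 12))
        pb = rng.normal(config.base_intensity_log2 - 2, config.intensity_spread_log2)
        row = {"peptide_seq": pep, "protein_id": ""}
        for s in samples:
            noise = (rng.normal(0.0, config.noise_sd)
                     if config.noise_sd > 0 else 0.0)
            row[s] = float(np.power(2.0, pb + noise))
        rows.append(row)
    peptide_df = pd.DataFrame(rows, columns=["peptide_seq", "protein_id"] + samples)
    return protein_df, peptide_df


# ---------------------------------------------------------------------------
# dataset orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: GenomeSequence
    annotation: Annotation
    truth: GroundTruth
    paths: dict


def simulate_dataset(config: SimulationConfig, out_dir) -> SimulatedDataset:
    """Run the full generator and write every artifact under ``out_dir``.

    Writes genome.fa, annotation.gtf, sam/<sample>.sam, proteins.tsv,
    peptides.tsv, protein_gene_map.tsv and the ground-truth TSVs.
    """
    out = Path(out_dir)
    (out / "sam").mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    n_samples = len(config.samples())
    keys = root.spawn(3 + n_samples)
    rng_genome = np.random.default_rng(keys[0])
    rng_truth = np.random.default_rng(keys[1])
    rng_tables = np.random.default_rng(keys[2])

    genome, annotation = simulate_genome_and_annotation(config, rng_genome)
    truth = plant_truth(config, genome, annotation, rng_truth)

    paths = {"genome": out / "genome.fa", "gtf": out / "annotation.gtf",
             "proteins": out / "proteins.tsv", "peptides": out / "peptides.tsv",
             "protein_gene_map": out / "protein_gene_map.tsv", "sam": {}}
    write_genome(genome, paths["genome"])
    write_annotation(annotation, paths["gtf"])

    groups = config.groups()
    for k, sample in enumerate(config.samples()):
        rng = np.random.default_rng(keys[3 + k])
        sam_path = out / "sam" / f"{sample}.sam"
        simulate_alignments(config, genome, annotation, truth, sample,
                            groups[sample], rng, sam_path)
        paths["sam"][sample] = sam_path

    protein_df, peptide_df = simulate_protein_and_peptide_tables(
        config, annotation, truth, rng_tables)
    write_tsv(protein_df.reset_index(), paths["proteins"])
    write_tsv(peptide_df, paths["peptides"])
    mapping = pd.DataFrame({
        "protein_id": [f"P_{g.gene_id}" for g in annotation.genes],
        "gene_id": [g.gene_id for g in annotation.genes]})
    write_tsv(mapping, paths["protein_gene_map"])

    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    ir_out = truth.ir.reset_index()
    for stim in config.stimuli:
        ir_out[f"planted_{stim}"] = [
            stim in truth.planted.get(i, {}) for i in ir_out["intron_id"]]
    write_tsv(ir_out, truth_dir / "ir.tsv")
    fc_rows = [{"protein_id": p, "stimulus": s, "log2fc": v}
               for p, d in sorted(truth.protein_fc.items())
               for s, v in sorted(d.items())]
    write_tsv(pd.DataFrame(fc_rows, columns=["protein_id", "stimulus", "log2fc"]),
              truth_dir / "protein_fc.tsv")
    write_tsv(truth.genes, truth_dir / "genes.tsv")
    paths["truth"] = truth_dir
    return SimulatedDataset(config, genome, annotation, truth, paths)
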
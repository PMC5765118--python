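"""Shared fixtures: tiny hand-built models and a small simulated dataset."""

from __future__ import annotations

import pytest

from platesplice.annotation_io import Annotation, GeneModel
from platesplice.synthetic_data import SimulationConfig, simulate_dataset


def write_sam(path, contigs: dict[str, int], reads) -> None:
    """Write a minimal SAM file; reads are (name, contig, flag, pos1, cigar)."""
    lines = ["@HD\tVN:1.6"]
    for c, ln in contigs.items():
        lines.append(f"@SQ\tSN:{c}\tLN:{ln}")
    for name, contig, flag, pos1, cigar in reads:
        lines.append(f"{name}\t{flag}\t{contig}\t{pos1}\t60\t{cigar}\t*\t0\t0\t*\t*")
    path.write_text("\n".join(lines) + "\n")


def plus_gene(gene_id="g1", contig="c1", exons=((0, 100), (200, 300)),
              strand="+", tx_id="t1") -> GeneModel:
    return GeneModel(gene_id, contig, strand, [(tx_id, [tuple(e) for e in exons])])


@pytest.fixture
def two_exon_annotation() -> Annotation:
    return Annotation(genes=[plus_gene()])


def small_sim_config(seed=0, **overrides) -> SimulationConfig:
    """A scaled-down study design for fast tests."""
    defaults = dict(
        seed=seed, n_genes=10,
        n_removal={"COLL": 2, "TRAP": 2}, n_removal_shared=1,
        n_extra_protein_fc={"COLL": 2, "TRAP": 1}, n_extra_protein_shared=1,
        n_background_peptides=20,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("small_dataset")
    return simulate_dataset(small_sim_config(seed=11), out)
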
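"""Per-intron, per-sample intron-retention (IR) quantification.

For every intron the pipeline measures two quantities per sample:

* ``intronic_abundance`` — the median per-base read depth over the intron's
  *measurable region* (intron positions not covered by any exon of any
  transcript nor by an excluded small-RNA feature such as a miRNA or snoRNA,
  whose expression would confound the intron signal);
* ``splice_abundance`` — the number of reads carrying an alignment gap that
  matches the intron's boundaries exactly (junction-spanning reads,
  i.e. evidence for the spliced form).

The IR ratio is then

    IR = intronic_abundance / (intronic_abundance + exon_splice_abundance)

which is 1 for a fully retained intron, 0 for a fully spliced one, and
undefined (missing) when neither form is observed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import (
    Annotation,
    AlignmentBlockRecord,
    IntronInterval,
    derive_introns,
    read_alignments,
    sam_contig_lengths,
)

DEFAULT_EXCLUDED_TYPES = frozenset({"miRNA", "snoRNA"})


@dataclass
class IRFilterParams:
    """Retention-filter settings.

    ``quantile_cut`` — per-sample quantile of the non-missing IR distribution
    an intron must strictly exceed to count as retained in that sample
    (default: the first quartile).
    ``min_replicates`` — number of replicates of a group in which the intron
    must pass (default 2 of 3).
    """

    quantile_cut: float = 0.25
    min_replicates: int = 2
    excluded_feature_types: frozenset = field(default_factory=lambda: DEFAULT_EXCLUDED_TYPES)

    def __post_init__(self) -> None:
        if not 0 < self.quantile_cut < 1:
            raise ValueError("quantile_cut must be in (0, 1)")


@dataclass(frozen=True)
class MeasurableRegion:
    intron_id: str
    positions: np.ndarray  # sorted genomic positions within the intron

    def __len__(self) -> int:
        return len(self.positions)


def measurable_region(
    intron: IntronInterval,
    annotation: Annotation,
    excluded_types=DEFAULT_EXCLUDED_TYPES,
) -> MeasurableRegion:
    """Intron positions not overlapped by any exon or excluded feature.

    Exons of *any* transcript (any gene) on the intron's contig mask the
    region, as do auxiliary features whose type is in ``excluded_types``;
    overlap is evaluated irrespective of strand.
    """
    mask = np.ones(intron.end - intron.start, dtype=bool)
    for gene in annotation.genes:
        if gene.contig != intron.contig:
            continue
        for _, exons in gene.transcripts:
            for s, e in exons:
                if s < intron.end and e > intron.start:
                    mask[max(s, intron.start) - intron.start:
                         min(e, intron.end) - intron.start] = False
    for feat in annotation.aux_features:
        if feat.feature_type in excluded_types and feat.contig == intron.contig:
            if feat.start < intron.end and feat.end > intron.start:
                mask[max(feat.start, intron.start) - intron.start:
                     min(feat.end, intron.end) - intron.start] = False
    return MeasurableRegion(intron.intron_id, intron.start + np.flatnonzero(mask))


class SampleAlignmentIndex:
    """Single-pass summary of one sample's alignments.

    Holds per-(contig, fragment strand) depth arrays and a counter of exact
    alignment-gap intervals, from which intron measurements are read off.
    For unstranded libraries the strand key is ``None``.
    """

    def __init__(self, contig_lengths: dict[str, int]):
        self.contig_lengths = contig_lengths
        self._depth: dict[tuple[str, str | None], np.ndarray] = {}
        self._gaps: Counter = Counter()

    def add(self, rec: AlignmentBlockRecord) -> None:
        key = (rec.contig, rec.fragment_strand)
        depth = self._depth.get(key)
        if depth is None:
            depth = np.zeros(self.contig_lengths[rec.contig], dtype=np.int32)
            self._depth[key] = depth
        for s, e in rec.blocks:
            depth[s:e] += 1
        for gap in rec.gaps:
            self._gaps[(rec.contig, gap[0], gap[1], rec.fragment_strand)] += 1

    @classmethod
    def from_sam(cls, path, strandedness: str = "reverse") -> "SampleAlignmentIndex":
        index = cls(sam_contig_lengths(path))
        for rec in read_alignments(path, strandedness=strandedness):
            index.add(rec)
        return index

    def depth_at(self, contig: str, positions: np.ndarray, strand: str) -> np.ndarray:
        """Per-base depth of strand-compatible reads at given positions."""
        total = np.zeros(len(positions), dtype=np.int64)
        for (c, frag_strand), depth in self._depth.items():
            if c == contig and (frag_strand is None or frag_strand == strand):
                total += depth[positions]
        return total

    def gap_count(self, contig: str, start: int, end: int, strand: str) -> int:
        n = self._gaps.get((contig, start, end, strand), 0)
        n += self._gaps.get((contig, start, end, None), 0)
        return n


def intronic_abundance(index: SampleAlignmentIndex, intron: IntronInterval,
                       region: MeasurableRegion) -> float:
    """Median per-base depth of strand-compatible reads over the region."""
    if len(region) == 0:
        return 0.0
    return float(np.median(index.depth_at(intron.contig, region.positions, intron.strand)))


def splice_abundance(index: SampleAlignmentIndex, intron: IntronInterval) -> int:
    """Reads whose alignment gap equals the intron exactly (both boundaries)."""
    return index.gap_count(intron.contig, intron.start, intron.end, intron.strand)


def ir_ratio(intronic: float, splice: float) -> float:
    """The IR ratio; NaN (missing) when neither form is observed."""
    denom = intronic + splice
    if denom == 0:
        return float("nan")
    return intronic / denom


def compute_ir_matrix(
    sample_sams: dict[str, str],
    annotation: Annotation,
    params: IRFilterParams | None = None,
    strandedness: str = "reverse",
) -> pd.DataFrame:
    """Quantify IR for every intron of the annotation in every sample.

    Returns a long-format table with one row per intron x sample:
    intron_id, gene_id, contig, start, end, strand, sample,
    intronic_abundance, splice_abundance, ir_ratio.
    """
    params = params or IRFilterParams()
    introns: list[IntronInterval] = []
    for gene in annotation.genes:
        introns.extend(derive_introns(gene))
    regions = {
        i.intron_id: measurable_region(i, annotation, params.excluded_feature_types)
        for i in introns
    }
    rows = []
    for sample, path in sample_sams.items():
        index = SampleAlignmentIndex.from_sam(path, strandedness=strandedness)
        for intron in introns:
            ia = intronic_abundance(index, intron, regions[intron.intron_id])
            sa = splice_abundance(index, intron)
            rows.append((intron.intron_id, intron.gene_id, intron.contig,
                         intron.start, intron.end, intron.strand, sample,
                         ia, sa, ir_ratio(ia, sa)))
    return pd.DataFrame(rows, columns=[
        "intron_id", "gene_id", "contig", "start", "end", "strand", "sample",
        "intronic_abundance", "splice_abundance", "ir_ratio"])


def pivot_ir(long_df: pd.DataFrame, value: str = "ir_ratio") -> pd.DataFrame:
    """Long IR table -> introns x samples matrix."""
    wide = long_df.pivot(index="intron_id", columns="sample", values=value)
    wide.columns.name = None
    return wide


def filter_retained(
    ir_matrix: pd.DataFrame,
    params: IRFilterParams,
    group: str,
    groups: dict[str, str],
) -> set[str]:
    """Introns retained in a group under the per-sample quantile rule.

    An intron counts as retained in one sample when its IR ratio is
    non-missing and strictly greater than that sample's ``quantile_cut``
    quantile of non-missing IR ratios; it is kept when this holds in at
    least ``min_replicates`` replicates of the group.
    """
    samples = [s for s in ir_matrix.columns if groups.get(s) == group]
    if not samples:
        raise ValueError(f"group {group!r} absent from IR matrix")
    if len(samples) < params.min_replicates:
        raise ValueError(
            f"group {group!r} has {len(samples)} samples < min_replicates")
    passes = pd.DataFrame(index=ir_matrix.index)
    for s in samples:
        col = ir_matrix[s]
        non_missing = col.dropna()
        if non_missing.empty:
            passes[s] = False
            continue
        cut = float(np.quantile(non_missing.to_numpy(), params.quantile_cut))
        passes[s] = (col > cut) & col.notna()
    kept = passes.sum(axis=1) >= params.min_replicates
    return set(ir_matrix.index[kept])


def compute_fpkm(fragment_counts, feature_lengths_nt, total_mapped: float):
    """Fragments per kilobase of exon per million mapped fragments."""
    counts = np.asarray(fragment_counts, dtype=float)
    lengths = np.asarray(feature_lengths_nt, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("feature length must be > 0")
    if total_mapped <= 0:
        raise ValueError("total mapped fragments must be > 0")
    return counts / (lengths / 1e3) / (total_mapped / 1e6)


def gene_read_counts(path, annotation: Annotation, strandedness: str = "reverse") -> pd.Series:
    """Fragments per gene: reads with >= 1 block overlapping a gene exon.

    Reads must be strand-compatible with the gene (always true for
    unstranded libraries).  A read is counted once per gene.
    """
    by_contig: dict[str, list[tuple[str, str, list[tuple[int, int]]]]] = {}
    for gene in annotation.genes:
        merged = _merged_exons(gene)
        by_contig.setdefault(gene.contig, []).append((gene.gene_id, gene.strand, merged))
    counts = {g.gene_id: 0 for g in annotation.genes}
    for rec in read_alignments(path, strandedness=strandedness):
        for gene_id, strand, exons in by_contig.get(rec.contig, ()):
            if rec.fragment_strand is not None and rec.fragment_strand != strand:
                continue
            if any(s < be and e > bs for bs, be in rec.blocks for s, e in exons):
                counts[gene_id] += 1
    return pd.Series(counts, name="count")


def gene_exon_lengths(annotation: Annotation) -> pd.Series:
    """Union-exon length per gene (nt), the FPKM denominator length."""
    return pd.Series({
        g.gene_id: sum(e - s for s, e in _merged_exons(g)) for g in annotation.genes})


def _merged_exons(gene) -> list[tuple[int, int]]:
    intervals = sorted(
        (s, e) for _, exons in gene.transcripts for s, e in exons)
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]
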
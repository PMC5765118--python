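"""Genome, annotation and alignment I/O plus the shared coordinate model.

Every module in the package speaks one coordinate convention: 0-based,
half-open intervals on genomic contigs.  GTF input/output converts from and
to the format's 1-based inclusive coordinates; SAM ``POS`` is converted from
1-based on read.  Keeping a single convention internally avoids off-by-one
drift between the intron model, the pileup and the junction windows.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

STRANDS = ("+", "-")

#: SAM CIGAR operation codes accepted by :func:`read_alignments`.
#: M=0, I=1, D=2, N=3, S=4, ==7, X=8 (H/P are rejected).
_REF_CONSUMING = {0, 2, 7, 8}  # M, D, =, X extend the current block
_ALLOWED_OPS = {0, 1, 2, 3, 4, 7, 8}


class AnnotationError(ValueError):
    """Raised for malformed FASTA/GTF/SAM input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

GenomeSequence = dict  # contig id -> uppercase nucleotide string


@dataclass(frozen=True)
class AuxFeature:
    """Non-exon GTF feature kept for exclusion masks (miRNA, snoRNA, ...)."""

    feature_type: str
    contig: str
    start: int  # 0-based
    end: int    # half-open
    strand: str
    attributes: Mapping[str, str] = field(default_factory=dict)


@dataclass
class GeneModel:
    """Exon structure of one gene: transcripts as ordered genomic exons."""

    gene_id: str
    contig: str
    strand: str
    #: list of (transcript_id, [(start, end), ...]) with exons in genomic order
    transcripts: list[tuple[str, list[tuple[int, int]]]]

    def validate(self) -> None:
        if self.strand not in STRANDS:
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        for tx_id, exons in self.transcripts:
            if not exons:
                raise AnnotationError(f"transcript {tx_id}: no exons")
            prev_end = None
            for start, end in exons:
                if end <= start:
                    raise AnnotationError(
                        f"transcript {tx_id}: exon end {end} <= start {start}")
                if prev_end is not None and start < prev_end:
                    raise AnnotationError(
                        f"transcript {tx_id}: overlapping/unsorted exons")
                prev_end = end


@dataclass(frozen=True)
class IntronInterval:
    """A genomic intron: the gap between two consecutive exons."""

    intron_id: str  # gene_id:transcript_id:index
    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    index: int  # ordinal within transcript, genomic order

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"intron {self.intron_id}: end <= start")


@dataclass(frozen=True)
class AlignmentBlockRecord:
    """A gapped alignment reduced to its reference-aligned blocks.

    ``gaps`` are the intervals skipped by N operations between consecutive
    blocks; for a spliced read they are candidate intron intervals.
    ``fragment_strand`` is the inferred strand of the sequenced RNA fragment
    (``None`` for an unstranded library).
    """

    read_id: str
    contig: str
    fragment_strand: str | None
    blocks: tuple[tuple[int, int], ...]

    @property
    def gaps(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a_end, b_start)
            for (_, a_end), (b_start, _) in itertools.pairwise(self.blocks)
        )


@dataclass
class Annotation:
    """A parsed annotation: gene models plus auxiliary (non-exon) features."""

    genes: list[GeneModel]
    aux_features: list[AuxFeature] = field(default_factory=list)

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class QuantTable:
    """A feature x sample table of non-negative quantities with group labels."""

    values: pd.DataFrame  # index: feature ids, columns: sample ids
    groups: dict[str, str]  # sample id -> group label

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            raise AnnotationError("duplicate feature ids in quant table")
        if self.values.columns.duplicated().any():
            raise AnnotationError("duplicate sample ids in quant table")
        if (self.values.to_numpy() < 0).any():
            raise AnnotationError("negative values in quant table")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise AnnotationError(f"samples without group label: {missing}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def groups_from_sample_ids(sample_ids: Iterable[str]) -> dict[str, str]:
    """Infer group labels from the ``GROUP_replicate`` naming convention."""
    return {s: s.rsplit("_", 1)[0] for s in sample_ids}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path) -> GenomeSequence:
    """Load a FASTA file into a contig -> uppercase sequence mapping."""
    contigs: GenomeSequence = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise AnnotationError(f"duplicate FASTA header: {rec.id}")
        seq = str(rec.seq).upper()
        if not seq:
            raise AnnotationError(f"empty sequence for contig {rec.id}")
        contigs[rec.id] = seq
    if not contigs:
        raise AnnotationError(f"no FASTA records in {path}")
    return contigs


def write_genome(genome: GenomeSequence, path) -> None:
    records = [SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_annotation(path) -> Annotation:
    """Parse an ensembl-style GTF into gene models plus auxiliary features.

    Exons require ``gene_id`` and ``transcript_id`` attributes; other feature
    types (gene, transcript, miRNA, snoRNA, ...) are retained as
    :class:`AuxFeature` so they can later serve as exclusion masks.
    Coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    exons: dict[tuple[str, str], dict] = {}  # (gene, transcript) -> info
    aux: list[AuxFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise AnnotationError(f"{path}:{lineno}: cannot parse GTF line ({exc})")
            if feat.end < feat.start:
                raise AnnotationError(f"{path}:{lineno}: end < start")
            start, end = feat.start - 1, feat.end
            attrs = {k: v[0] for k, v in feat.attributes.items() if v}
            if feat.featuretype == "exon":
                if "transcript_id" not in attrs:
                    raise AnnotationError(f"{path}:{lineno}: exon missing transcript_id")
                if "gene_id" not in attrs:
                    raise AnnotationError(f"{path}:{lineno}: exon missing gene_id")
                key = (attrs["gene_id"], attrs["transcript_id"])
                info = exons.setdefault(
                    key, {"contig": feat.seqid, "strand": feat.strand, "exons": []})
                if info["contig"] != feat.seqid or info["strand"] != feat.strand:
                    raise AnnotationError(
                        f"{path}:{lineno}: transcript {key[1]} spans contigs/strands")
                info["exons"].append((start, end))
            else:
                aux.append(AuxFeature(
                    feature_type=feat.featuretype, contig=feat.seqid,
                    start=start, end=end, strand=feat.strand, attributes=attrs))

    genes: dict[str, GeneModel] = {}
    for (gene_id, tx_id), info in exons.items():
        model = genes.setdefault(
            gene_id, GeneModel(gene_id, info["contig"], info["strand"], []))
        if model.contig != info["contig"] or model.strand != info["strand"]:
            raise AnnotationError(f"gene {gene_id}: transcripts on different contigs/strands")
        model.transcripts.append((tx_id, sorted(info["exons"])))
    out = list(genes.values())
    for g in out:
        g.validate()
    return Annotation(genes=out, aux_features=aux)


def write_annotation(annotation: Annotation, path, source: str = "platesplice") -> None:
    """Write gene models (gene/transcript/exon lines) and aux features as GTF."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            g_start = min(s for _, ex in g.transcripts for s, _ in ex)
            g_end = max(e for _, ex in g.transcripts for _, e in ex)
            fh.write(_gtf_line(g.contig, source, "gene", g_start, g_end, g.strand,
                               f'gene_id "{g.gene_id}";'))
            for tx_id, ex in g.transcripts:
                fh.write(_gtf_line(
                    g.contig, source, "transcript", ex[0][0], ex[-1][1], g.strand,
                    f'gene_id "{g.gene_id}"; transcript_id "{tx_id}";'))
                for s, e in ex:
                    fh.write(_gtf_line(
                        g.contig, source, "exon", s, e, g.strand,
                        f'gene_id "{g.gene_id}"; transcript_id "{tx_id}";'))
        for f in annotation.aux_features:
            if f.feature_type in ("gene", "transcript"):
                continue
            attrs = "".join(f'{k} "{v}"; ' for k, v in f.attributes.items()).strip()
            fh.write(_gtf_line(f.contig, source, f.feature_type,
                               f.start, f.end, f.strand, attrs or 'gene_id "na";'))


def _gtf_line(contig, source, ftype, start, end, strand, attrs) -> str:
    # internal 0-based half-open -> GTF 1-based inclusive
    return f"{contig}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n"


# ---------------------------------------------------------------------------
# introns
# ---------------------------------------------------------------------------

def derive_introns(model: GeneModel) -> list[IntronInterval]:
    """One intron per consecutive exon pair per transcript.

    Introns with identical genomic coordinates across transcripts of the gene
    are merged under the first transcript's label: intron retention is a
    genomic measurement, independent of which isoform defines the gap.
    """
    seen: dict[tuple[int, int], IntronInterval] = {}
    for tx_id, exons in model.transcripts:
        idx = 0
        for (_, a_end), (b_start, _) in itertools.pairwise(exons):
            if b_start <= a_end:  # adjacent/zero-length gap: no intron
                continue
            key = (a_end, b_start)
            if key not in seen:
                seen[key] = IntronInterval(
                    intron_id=f"{model.gene_id}:{tx_id}:{idx}",
                    gene_id=model.gene_id, contig=model.contig,
                    strand=model.strand, start=a_end, end=b_start, index=idx)
            idx += 1
    return sorted(seen.values(), key=lambda i: i.start)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def blocks_from_cigar(pos: int, cigartuples) -> tuple[tuple[int, int], ...]:
    """Reference-aligned blocks from a 0-based position and parsed CIGAR.

    M/=/X/D consume reference within the current block, N closes a block and
    opens a gap, I/S consume no reference.
    """
    blocks: list[tuple[int, int]] = []
    cur = pos
    block_start = pos
    for op, length in cigartuples:
        if op not in _ALLOWED_OPS:
            raise AnnotationError(f"unsupported CIGAR op code {op}")
        if op in _REF_CONSUMING:
            cur += length
        elif op == 3:  # N
            if cur > block_start:
                blocks.append((block_start, cur))
            cur += length
            block_start = cur
    if cur > block_start:
        blocks.append((block_start, cur))
    return tuple(blocks)


def infer_fragment_strand(is_reverse: bool, strandedness: str) -> str | None:
    """Fragment strand from the read's mapped orientation.

    ``reverse`` is the dUTP/TruSeq stranded protocol (read antisense to the
    fragment), ``forward`` reads sense, ``unstranded`` yields ``None``.
    """
    read_strand = "-" if is_reverse else "+"
    if strandedness == "reverse":
        return "+" if read_strand == "-" else "-"
    if strandedness == "forward":
        return read_strand
    if strandedness == "unstranded":
        return None
    raise ValueError(f"unknown strandedness {strandedness!r}")


def read_alignments(path, strandedness: str = "reverse") -> Iterator[AlignmentBlockRecord]:
    """Stream gapped alignments from a SAM file as block records.

    Unmapped, secondary and supplementary records are skipped.  A record on a
    contig missing from the @SQ header, or a CIGAR op outside M/I/D/N/S/=/X,
    raises :class:`AnnotationError`.
    """
    try:
        sam = pysam.AlignmentFile(str(path), "r")
    except ValueError as exc:
        raise AnnotationError(f"cannot open SAM {path}: {exc}")
    with sam:
        if not sam.header.references:
            raise AnnotationError(f"{path}: SAM header has no @SQ lines")
        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.reference_id < 0:
                raise AnnotationError(
                    f"{path}: read {read.query_name} has no @SQ contig")
            yield AlignmentBlockRecord(
                read_id=read.query_name,
                contig=read.reference_name,
                fragment_strand=infer_fragment_strand(read.is_reverse, strandedness),
                blocks=blocks_from_cigar(read.reference_start, read.cigartuples),
            )


def sam_contig_lengths(path) -> dict[str, int]:
    with pysam.AlignmentFile(str(path), "r") as sam:
        return dict(zip(sam.header.references, sam.header.lengths))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def read_quant_table(path, groups: Mapping[str, str] | None = None) -> QuantTable:
    """Read a feature x sample TSV (first column = feature id).

    If ``groups`` is not given, sample groups are inferred from the
    ``GROUP_replicate`` column-name convention.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    table = QuantTable(values=df,
                       groups=dict(groups) if groups else groups_from_sample_ids(df.columns))
    table.validate()
    return table


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
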
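"""Proteogenomic database of translated exon-exon junction windows.

For every retained intron, splicing joins the two flanking exons; a peptide
covering the new exon-exon boundary is direct protein-level evidence that
the intron was removed and the mature mRNA translated.  This module
extracts, for each junction, up to 75 nt of exonic sequence on either side
of the boundary *in the spliced mRNA* (an unspliced genomic window would
contain intron sequence and could never encode a junction-spanning
peptide), translates the spliced window in all three reading frames with
stop codons rendered as ``*``, and writes the result as a FASTA database
for peptide matching.

Coordinates follow the package convention (0-based half-open); minus-strand
windows are reverse-complemented so sequences always read 5'->3' on the
mRNA.  ``L`` is the length of the upstream (left) flank — the junction sits
between spliced-sequence positions L-1 and L.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .annotation_io import Annotation, AnnotationError, GenomeSequence, IntronInterval

DEFAULT_FLANK = 75


@dataclass(frozen=True)
class JunctionSite:
    """An exon-exon junction created by removing one retained intron."""

    junction_id: str
    gene_id: str
    transcript_id: str
    contig: str
    strand: str
    donor_exon_end: int       # end of the genomic-left exon (0-based exclusive)
    acceptor_exon_start: int  # start of the genomic-right exon

    def __post_init__(self) -> None:
        if self.acceptor_exon_start <= self.donor_exon_end:
            raise AnnotationError(
                f"junction {self.junction_id}: acceptor start must exceed donor end")


@dataclass(frozen=True)
class JunctionWindow:
    """Spliced exonic context around a junction, in mRNA orientation."""

    junction_id: str
    left_seq: str   # <= flank nt, 3' end of the mRNA-upstream exon
    right_seq: str  # <= flank nt, 5' start of the mRNA-downstream exon

    @property
    def spliced_seq(self) -> str:
        return self.left_seq + self.right_seq

    @property
    def L(self) -> int:
        return len(self.left_seq)


@dataclass(frozen=True)
class JunctionFrameEntry:
    """One reading-frame translation of a junction window."""

    junction_id: str
    frame: int      # offset into spliced_seq, 0..2
    aa_seq: str     # '*' marks stops
    L: int          # junction offset in nt, inherited from the window


def junctions_from_introns(
    retained_introns: list[IntronInterval], annotation: Annotation
) -> list[JunctionSite]:
    """One junction per retained intron, deduplicated on coordinates."""
    sites: dict[tuple, JunctionSite] = {}
    for intron in retained_introns:
        gene = annotation.gene(intron.gene_id)
        tx_id = _flanking_transcript(gene, intron)
        key = (intron.contig, intron.start, intron.end, intron.strand)
        if key not in sites:
            sites[key] = JunctionSite(
                junction_id=f"jx:{intron.intron_id}",
                gene_id=intron.gene_id, transcript_id=tx_id,
                contig=intron.contig, strand=intron.strand,
                donor_exon_end=intron.start, acceptor_exon_start=intron.end)
    return list(sites.values())


def _flanking_transcript(gene, intron: IntronInterval) -> str:
    for tx_id, exons in gene.transcripts:
        ends = {e for _, e in exons}
        starts = {s for s, _ in exons}
        if intron.start in ends and intron.end in starts:
            return tx_id
    raise AnnotationError(
        f"intron {intron.intron_id}: no transcript with flanking exons")


def extract_spliced_window(
    genome: GenomeSequence,
    annotation: Annotation,
    junction: JunctionSite,
    flank: int = DEFAULT_FLANK,
) -> JunctionWindow:
    """Extract up to ``flank`` exonic nt on each side of the junction.

    Exons shorter than the flank truncate the window (no extension into the
    next exon).  On the minus strand, mRNA-upstream means the genomic-right
    exon, and both flanks are reverse-complemented.
    """
    gene = annotation.gene(junction.gene_id)
    exons = dict(gene.transcripts)[junction.transcript_id]
    left_exon = next((x for x in exons if x[1] == junction.donor_exon_end), None)
    right_exon = next((x for x in exons if x[0] == junction.acceptor_exon_start), None)
    if left_exon is None or right_exon is None:
        raise AnnotationError(f"junction {junction.junction_id}: flanking exons not found")
    seq = genome[junction.contig]
    if junction.donor_exon_end > len(seq) or junction.acceptor_exon_start > len(seq):
        raise AnnotationError(f"junction {junction.junction_id}: outside contig")

    donor = junction.donor_exon_end
    acceptor = junction.acceptor_exon_start
    if junction.strand == "+":
        w_left = min(flank, left_exon[1] - left_exon[0])
        w_right = min(flank, right_exon[1] - right_exon[0])
        left = seq[donor - w_left:donor]
        right = seq[acceptor:acceptor + w_right]
    else:
        # mRNA-upstream flank = start of the genomic-right exon, revcomp'd
        w_left = min(flank, right_exon[1] - right_exon[0])
        w_right = min(flank, left_exon[1] - left_exon[0])
        left = _revcomp(seq[acceptor:acceptor + w_left])
        right = _revcomp(seq[donor - w_right:donor])
    return JunctionWindow(junction.junction_id, left, right)


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate_frame(seq: str, frame: int) -> str:
    """Standard-code translation of codons starting at ``frame``.

    Trailing 1-2 nt are dropped; stops are ``*``; any codon containing a
    non-ACGT base that does not resolve to a unique amino acid is ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    sub = seq[frame:].upper()
    sub = sub[: len(sub) - len(sub) % 3]
    cleaned = "".join(c if c in "ACGT" else "N" for c in sub)
    return str(Seq(cleaned).translate())


def build_entries(window: JunctionWindow) -> list[JunctionFrameEntry]:
    """The three frame translations of one junction window."""
    return [
        JunctionFrameEntry(window.junction_id, frame,
                           translate_frame(window.spliced_seq, frame), window.L)
        for frame in (0, 1, 2)
    ]


def build_junction_database(
    genome: GenomeSequence,
    annotation: Annotation,
    retained_introns: list[IntronInterval],
    flank: int = DEFAULT_FLANK,
) -> tuple[list[JunctionSite], list[JunctionFrameEntry]]:
    sites = junctions_from_introns(retained_introns, annotation)
    entries: list[JunctionFrameEntry] = []
    for site in sites:
        window = extract_spliced_window(genome, annotation, site, flank=flank)
        entries.extend(build_entries(window))
    return sites, entries


# ---------------------------------------------------------------------------
# FASTA round-trip
# ---------------------------------------------------------------------------

def write_junction_fasta(
    entries: list[JunctionFrameEntry], sites: list[JunctionSite], path
) -> None:
    """Write frame entries with lossless pipe-delimited headers."""
    site_of = {s.junction_id: s for s in sites}
    seen: set[tuple[str, int]] = set()
    with open(path, "w") as fh:
        for e in entries:
            key = (e.junction_id, e.frame)
            if key in seen:
                raise AnnotationError(f"duplicate junction/frame entry: {key}")
            seen.add(key)
            s = site_of[e.junction_id]
            fh.write(
                f">jxn|{e.junction_id}|{s.gene_id}|{s.contig}|{s.donor_exon_end}"
                f"|{s.acceptor_exon_start}|{s.strand}|frame={e.frame}|L={e.L}\n")
            fh.write(e.aa_seq + "\n")


def read_junction_fasta(path) -> tuple[list[JunctionSite], list[JunctionFrameEntry]]:
    """Parse a junction FASTA back into sites and frame entries."""
    sites: dict[str, JunctionSite] = {}
    entries: list[JunctionFrameEntry] = []
    header: str | None = None
    seq_parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        fields = header.split("|")
        if len(fields) != 9 or fields[0] != "jxn":
            raise AnnotationError(f"bad junction FASTA header: >{header}")
        _, jid, gene, contig, donor, acceptor, strand, frame_f, l_f = fields
        frame = int(frame_f.removeprefix("frame="))
        L = int(l_f.removeprefix("L="))
        if jid not in sites:
            sites[jid] = JunctionSite(jid, gene, "", contig, strand,
                                      int(donor), int(acceptor))
        entries.append(JunctionFrameEntry(jid, frame, "".join(seq_parts), L))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:]
                seq_parts = []
            elif line:
                seq_parts.append(line)
    flush()
    return list(sites.values()), entries
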
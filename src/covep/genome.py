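"""Reference genome and gene-model handling.

Loads FASTA genomes and GFF3 gene models, extracts spliced coding sequences
(CDS) on the coding strand, and provides bidirectional mapping between
genomic and CDS coordinates per transcript.

All internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted at the parse boundary and nowhere else.
"""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_right
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

log = logging.getLogger("covep.genome")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

ALLOWED_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


@dataclass
class GenomeSequence:
    """A single chromosome/contig held in memory, uppercase.

    Soft-masked (lowercase) bases are uppercased on load; masking carries no
    meaning for codon logic.
    """

    chrom_id: str
    sequence: str

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.chrom_id}")
        bad = set(self.sequence) - ALLOWED_BASES
        if bad:
            raise ValueError(
                f"{self.chrom_id}: characters outside A/C/G/T/N: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path) -> dict[str, GenomeSequence]:
    """Read a (possibly gzipped) multi-record FASTA into GenomeSequence objects."""
    genomes: dict[str, GenomeSequence] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            genomes[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


@dataclass
class TranscriptModel:
    """An mRNA with ordered CDS segments and coordinate maps.

    ``cds_segments`` are genomic, 0-based half-open, sorted by start and
    pairwise non-overlapping. On the minus strand the first coding base is the
    segment set's maximal genomic coordinate.

    ``incomplete_cds`` flags models whose spliced length is not a multiple of
    three or is shorter than one codon; they are kept and translated for
    floor(len/3) codons rather than dropped, because real annotations contain
    such models and dropping them would change downstream counts.
    """

    transcript_id: str
    gene_id: str
    chrom_id: str
    strand: str
    cds_segments: list[tuple[int, int]]
    phase_of_first_segment: int = 0
    incomplete_cds: bool = field(default=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        self.cds_segments = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(self.cds_segments, self.cds_segments[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping CDS segments")
        for s, e in self.cds_segments:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty/inverted segment ({s},{e})")
        if self.cds_length % 3 != 0 or self.cds_length < 3:
            self.incomplete_cds = True
        # cumulative spliced offset at the start of each segment, in genomic order
        self._cum = [0]
        for s, e in self.cds_segments:
            self._cum.append(self._cum[-1] + (e - s))

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    # -- coordinate maps -----------------------------------------------------

    def genomic_to_cds(self, genomic_pos: int) -> int | None:
        """Map a 0-based genomic position to its 0-based spliced-CDS offset.

        Returns None for intronic/intergenic positions.
        """
        i = bisect_right(self.cds_segments, (genomic_pos, float("inf"))) - 1
        if i < 0:
            return None
        s, e = self.cds_segments[i]
        if not (s <= genomic_pos < e):
            return None
        plus_offset = self._cum[i] + (genomic_pos - s)
        if self.strand == "+":
            return plus_offset
        return self.cds_length - 1 - plus_offset

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Inverse of :meth:`genomic_to_cds`; raises IndexError if out of range."""
        n = self.cds_length
        if not (0 <= cds_pos < n):
            raise IndexError(f"{self.transcript_id}: CDS position {cds_pos} out of range")
        plus_offset = cds_pos if self.strand == "+" else n - 1 - cds_pos
        i = bisect_right(self._cum, plus_offset) - 1
        s, _e = self.cds_segments[i]
        return s + (plus_offset - self._cum[i])

    def extract_cds(self, genome: GenomeSequence) -> str:
        """Spliced CDS on the coding strand, 5'→3'."""
        for s, e in self.cds_segments:
            if e > len(genome):
                raise ValueError(
                    f"{self.transcript_id}: segment [{s},{e}) exceeds "
                    f"{genome.chrom_id} length {len(genome)}"
                )
        concat = "".join(genome.sequence[s:e] for s, e in self.cds_segments)
        return concat if self.strand == "+" else reverse_complement(concat)


def parse_gff3(path) -> dict[str, list[TranscriptModel]]:
    """Parse gene/mRNA/CDS features of a GFF3 file into transcript models.

    Returns transcripts grouped by gene id. mRNAs with zero CDS children are
    logged and not emitted; CDS rows with no resolvable mRNA parent, or with
    end < start, are logged and skipped. Multi-parent CDS rows
    (``Parent=a,b``) contribute to every listed parent.
    """
    with _open_text(path) as fh:
        text = fh.read()
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    mrna_meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    known_ids = set()
    for feat in db.all_features():
        if feat.id:
            known_ids.add(feat.id)
    for mrna in db.features_of_type(("mRNA", "transcript")):
        parents = mrna.attributes.get("Parent", [mrna.id])
        mrna_meta[mrna.id] = (parents[0], mrna.seqid, mrna.strand)

    # gather CDS rows per parent transcript
    per_tx: dict[str, list[tuple[int, int, str]]] = {}
    for cds in db.features_of_type("CDS"):
        if cds.end < cds.start:
            log.warning("CDS with end < start at %s:%s-%s skipped", cds.seqid, cds.start, cds.end)
            continue
        parents = cds.attributes.get("Parent", [])
        if not parents:
            log.warning("CDS at %s:%s-%s has no Parent; skipped", cds.seqid, cds.start, cds.end)
            continue
        for parent in parents:
            if parent not in mrna_meta:
                if parent in known_ids:
                    # CDS attached directly to a gene-level feature: tolerate,
                    # treating the parent as a single-isoform transcript
                    mrna_meta[parent] = (parent, cds.seqid, cds.strand)
                else:
                    log.warning(
                        "CDS at %s:%s-%s references absent Parent=%s; skipped",
                        cds.seqid, cds.start, cds.end, parent,
                    )
                    continue
            per_tx.setdefault(parent, []).append(
                (cds.start - 1, cds.end, cds.frame)  # 1-based inclusive -> 0-based half-open
            )

    genes: dict[str, list[TranscriptModel]] = {}
    for tid, (gene_id, chrom, strand) in mrna_meta.items():
        rows = per_tx.get(tid)
        if not rows:
            log.warning("mRNA %s has no CDS children; not emitted", tid)
            continue
        rows.sort()
        segments = [(s, e) for s, e, _ in rows]
        first = rows[0] if strand == "+" else rows[-1]
        try:
            phase = int(first[2])
        except (TypeError, ValueError):
            phase = 0
        tx = TranscriptModel(tid, gene_id, chrom, strand, segments, phase)
        # the phase column is advisory: segment lengths are trusted, conflicts logged
        if phase != 0:
            log.info("transcript %s starts at phase %d (partial first codon)", tid, phase)
        if tx.incomplete_cds:
            log.warning("transcript %s: CDS length %d not a clean codon multiple; "
                        "flagged incomplete_cds", tid, tx.cds_length)
        genes.setdefault(gene_id, []).append(tx)
    for txs in genes.values():
        txs.sort(key=lambda t: t.transcript_id)
    return genes


def longest_isoform(transcripts: list[TranscriptModel]) -> TranscriptModel:
    """Deterministic per-gene representative: longest CDS, ties by id."""
    return max(transcripts, key=lambda t: (t.cds_length, t.transcript_id))
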
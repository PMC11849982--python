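"""Deterministic synthetic fixture generator.

Builds a toy genome (FASTA), gene models (GFF3), an engineered variant set
(VCF) and a machine-readable truth table so the whole pipeline can be tested
without any external download. Each requested case class is embedded in its
own multi- or single-exon gene, on either strand, in a distinct codon
context:

* single SNVs that are synonymous, missense or stop-gaining;
* two SNVs in one codon that jointly rescue a premature stop (always
  including at least one CAA→TAA/TAC tyrosine rescue) or jointly create one;
* multi-nucleotide substitutions within a codon;
* in-frame and frame-shifting InDels, alone or as compensating groups of
  two (+2/+4) or three (+1/+1/+1) members with engineered anchor distances;
* an interfering pair split across opposite haplophases (expected: no
  interaction).

Regeneration with the same seed is byte-identical. The generator emulates
variant constellations, not realistic mutation-rate or selection models.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import TranscriptModel, reverse_complement

CASE_LABELS = (
    "single_snv_syn",
    "single_snv_missense",
    "single_snv_stop",
    "two_snv_codon_rescue",
    "two_snv_codon_create_stop",
    "inframe_indel",
    "lone_frameshift",
    "cindel_pair",
    "cindel_triple",
    "mnv_substitution",
    "phase_split_pair",
)

# filler codons: no stops, no ATG, and distinct third-position families
_FILLER = ("GCT", "GGT", "CTT", "TCT", "ACT", "GTT", "CCT", "ATT")

DEFAULT_CASE_COUNTS = {label: 2 for label in CASE_LABELS}


@dataclass
class FixtureSpec:
    seed: int = 0
    case_counts: dict = field(default_factory=lambda: dict(DEFAULT_CASE_COUNTS))
    n_plain_genes: int = 2  # genes carrying no variant at all
    strand_mix: float = 0.5  # fraction of genes on the minus strand
    exons_per_gene: tuple[int, int] = (1, 3)
    codons_per_gene: tuple[int, int] = (25, 45)
    intron_length: tuple[int, int] = (20, 40)
    spacer_length: tuple[int, int] = (60, 100)
    cindel_distances: tuple[int, ...] = (3, 4, 6)
    background_syn_rate: float = 0.0  # extra synonymous SNVs per gene (Poisson mean)
    background_mis_rate: float = 0.0  # extra missense SNVs per gene
    stop_gene_mis_factor: float = 3.0  # missense-rate multiplier in stop-carrying genes
    chrom_id: str = "chr1"

    @property
    def n_genes(self) -> int:
        return sum(self.case_counts.values()) + self.n_plain_genes


@dataclass
class _PlannedVariant:
    cds_pos: int
    kind: str  # substitution | insertion | deletion
    ref_cds: str  # coding-strand alleles ("" for insertions)
    alt_cds: str
    gt: str
    phase: str  # truth phase: "0", "1" or "both"
    expected_isolated: str
    expected_combined: str
    case_label: str


@dataclass
class Fixture:
    spec: FixtureSpec
    chrom_seq: str
    transcripts: list[TranscriptModel]
    vcf_rows: list[tuple]  # (chrom, pos1, id, ref, alt, gt)
    truth: pd.DataFrame
    stop_case_genes: list[str]


class UnsatisfiableSpec(ValueError):
    pass


def _plan_case(label: str, inst: int, spec: FixtureSpec) -> list[dict]:
    """Per-case codon requirements and CDS-space variants, relative to the
    codon slots the gene builder assigns. Returns a list of edit plans, each
    {codon_offset (slot), codon (forced content) or None, variants: [...]}."""
    if label == "single_snv_syn":
        return [{"codon": "GCT", "variants": [
            dict(off=2, ref="T", alt="C", iso="synonymous_variant",
                 comb="synonymous_variant")]}]
    if label == "single_snv_missense":
        return [{"codon": "CAA", "variants": [
            dict(off=2, ref="A", alt="C", iso="missense_variant",
                 comb="missense_variant")]}]
    if label == "single_snv_stop":
        return [{"codon": "CAA", "variants": [
            dict(off=0, ref="C", alt="T", iso="stop_gained", comb="stop_gained")]}]
    if label == "two_snv_codon_rescue":
        # CAA: C->T alone gives TAA (stop); with A->C the codon is TAC (Tyr)
        return [{"codon": "CAA", "variants": [
            dict(off=0, ref="C", alt="T", iso="stop_gained", comb="missense_variant"),
            dict(off=2, ref="A", alt="C", iso="missense_variant",
                 comb="missense_variant")]}]
    if label == "two_snv_codon_create_stop":
        # CAC: C->T gives TAC (Tyr), C->A gives CAA (Gln); together TAA (stop)
        return [{"codon": "CAC", "variants": [
            dict(off=0, ref="C", alt="T", iso="missense_variant", comb="stop_gained"),
            dict(off=2, ref="C", alt="A", iso="missense_variant", comb="stop_gained")]}]
    if label == "mnv_substitution":
        return [{"codon": "CAA", "variants": [
            dict(off=0, ref="CA", alt="TT", iso="missense_variant",
                 comb="missense_variant")]}]
    if label == "inframe_indel":
        if inst % 2 == 0:
            return [{"codon": None, "variants": [
                dict(off=0, ref="", alt="GCT", iso="inframe_insertion",
                     comb="inframe_insertion")]}]
        return [{"codon": None, "variants": [
            dict(off=0, ref="@3", alt="", iso="inframe_deletion",
                 comb="inframe_deletion")]}]
    if label == "lone_frameshift":
        if inst % 2 == 0:
            return [{"codon": None, "variants": [
                dict(off=0, ref="", alt="G", iso="frameshift_variant",
                     comb="frameshift_variant")]}]
        return [{"codon": None, "variants": [
            dict(off=0, ref="@1", alt="", iso="frameshift_variant",
                 comb="frameshift_variant")]}]
    if label == "cindel_pair":
        d = spec.cindel_distances[inst % len(spec.cindel_distances)]
        return [
            {"codon": None, "variants": [
                dict(off=0, ref="", alt="GG", iso="frameshift_variant",
                     comb="frameshift_variant")]},
            {"codon": None, "at_distance": d, "variants": [
                dict(off=0, ref="", alt="GGGG", iso="frameshift_variant",
                     comb="frameshift_variant")]},
        ]
    if label == "cindel_triple":
        d1 = spec.cindel_distances[inst % len(spec.cindel_distances)]
        d2 = spec.cindel_distances[(inst + 1) % len(spec.cindel_distances)]
        return [
            {"codon": None, "variants": [
                dict(off=0, ref="", alt="C", iso="frameshift_variant",
                     comb="frameshift_variant")]},
            {"codon": None, "at_distance": d1, "variants": [
                dict(off=0, ref="", alt="A", iso="frameshift_variant",
                     comb="frameshift_variant")]},
            {"codon": None, "at_distance": d2, "variants": [
                dict(off=0, ref="", alt="G", iso="frameshift_variant",
                     comb="frameshift_variant")]},
        ]
    if label == "phase_split_pair":
        # same interfering pair as the rescue case, but on opposite phases:
        # each phase sees one variant, so no interaction is expected
        return [{"codon": "CAA", "variants": [
            dict(off=0, ref="C", alt="T", iso="stop_gained", comb="stop_gained",
                 gt="1|0", phase="0"),
            dict(off=2, ref="A", alt="C", iso="missense_variant",
                 comb="missense_variant", gt="0|1", phase="1")]}]
    raise UnsatisfiableSpec(f"unknown case label: {label}")


def _build_gene(
    rng: np.random.Generator,
    spec: FixtureSpec,
    gene_idx: int,
    label: str | None,
    inst: int,
    extra_syn: int,
    extra_mis: int,
):
    """Build one gene's CDS, planned variants and exon layout (CDS space)."""
    plans = _plan_case(label, inst, spec) if label else []
    n_slots = len(plans) + extra_syn + extra_mis
    if n_slots > 200:
        raise UnsatisfiableSpec(
            f"gene {gene_idx}: {n_slots} edits in one gene is not satisfiable"
        )
    n_codons = int(rng.integers(*spec.codons_per_gene))
    # grow the CDS when many edits are requested: slots sit 3 codons apart
    n_codons = max(n_codons, 3 * n_slots + 9)
    codons = ["ATG"] + [
        _FILLER[rng.integers(0, len(_FILLER))] for _ in range(n_codons)
    ] + ["TAA"]

    # candidate codon indices for engineered edits, spaced 3 codons apart
    candidates = list(range(3, n_codons - 2, 3))
    if len(candidates) < n_slots:
        raise UnsatisfiableSpec(
            f"gene {gene_idx}: {n_slots} edit slots needed, {len(candidates)} available"
        )
    slot_idx = sorted(rng.choice(len(candidates), size=n_slots, replace=False))
    slots = [candidates[i] for i in slot_idx]

    planned: list[_PlannedVariant] = []
    used = 0
    # cInDel member positions are expressed as cds distances from the first
    # member's anchor, so consecutive-member anchor distances are engineered
    anchor_cds: int | None = None
    forbidden: set[int] = set()
    for plan in plans:
        if "at_distance" in plan and anchor_cds is not None:
            cds_point = anchor_cds + plan["at_distance"]
            k = cds_point // 3
            anchor_cds = cds_point  # consecutive-member distances chain
        else:
            k = slots[used]
            used += 1
            cds_point = 3 * k
            if any("at_distance" in p for p in plans):
                anchor_cds = cds_point
        if plan["codon"]:
            codons[k] = plan["codon"]
        for v in plan["variants"]:
            ref = v["ref"]
            if ref.startswith("@"):  # deletion of N bases starting at the slot
                ln = int(ref[1:])
                ref = "".join(codons)[cds_point + v["off"]: cds_point + v["off"] + ln]
            planned.append(
                _PlannedVariant(
                    cds_pos=cds_point + v["off"],
                    kind=("substitution" if ref and v["alt"] and len(ref) == len(v["alt"])
                          else "insertion" if len(v["alt"]) > len(ref) else "deletion"),
                    ref_cds=ref,
                    alt_cds=v["alt"],
                    gt=v.get("gt", "1|1"),
                    phase=v.get("phase", "both"),
                    expected_isolated=v["iso"],
                    expected_combined=v["comb"],
                    case_label=label,
                )
            )
        forbidden.update(range(max(k - 1, 0), k + 3))

    for i in range(extra_syn):
        k = slots[used]; used += 1
        codons[k] = "GCT"
        planned.append(_PlannedVariant(3 * k + 2, "substitution", "T", "C", "1|1",
                                       "both", "synonymous_variant",
                                       "synonymous_variant", "background_syn"))
        forbidden.update(range(max(k - 1, 0), k + 2))
    for i in range(extra_mis):
        k = slots[used]; used += 1
        codons[k] = "CAA"
        planned.append(_PlannedVariant(3 * k + 2, "substitution", "A", "C", "1|1",
                                       "both", "missense_variant",
                                       "missense_variant", "background_mis"))
        forbidden.update(range(max(k - 1, 0), k + 2))

    # deletions consume reference bases after their slot; widen the margin
    for pv in planned:
        if pv.kind == "deletion":
            forbidden.update(range(pv.cds_pos // 3, (pv.cds_pos + len(pv.ref_cds)) // 3 + 2))

    cds = "".join(codons)
    n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
    # exon boundaries in CDS coordinates, avoiding engineered codons ± margin
    boundary_candidates = [
        3 * k for k in range(2, len(codons) - 2)
        if k not in forbidden and (k - 1) not in forbidden
    ]
    boundaries: list[int] = []
    rng.shuffle(boundary_candidates)
    for b in boundary_candidates:
        if len(boundaries) >= n_exons - 1:
            break
        if all(abs(b - x) >= 9 for x in boundaries):
            boundaries.append(b)
    boundaries.sort()
    return cds, planned, boundaries


def _layout_gene(
    rng: np.random.Generator,
    cds: str,
    boundaries: list[int],
    strand: str,
    offset: int,
    intron_len_range: tuple[int, int],
):
    """Place the gene at ``offset`` on the chromosome; returns (region_seq,
    genomic cds_segments sorted by start, map cds_pos->genomic pos fn info)."""
    cuts = [0] + boundaries + [len(cds)]
    exons = [cds[a:b] for a, b in zip(cuts, cuts[1:])]
    introns = [
        "".join("ACGT"[rng.integers(0, 4)] for _ in range(int(rng.integers(*intron_len_range))))
        for _ in range(len(exons) - 1)
    ]
    # transcription-order layout
    parts, segs_tx, pos = [], [], 0
    for i, ex in enumerate(exons):
        segs_tx.append((pos, pos + len(ex)))
        parts.append(ex)
        pos += len(ex)
        if i < len(introns):
            parts.append(introns[i])
            pos += len(introns[i])
    region = "".join(parts)
    if strand == "+":
        segments = [(offset + s, offset + e) for s, e in segs_tx]
        return region, segments
    # minus strand: the genomic region is the reverse complement of the
    # transcription-order layout; exon coordinates flip accordingly
    L = len(region)
    region_rc = reverse_complement(region)
    segments = sorted((offset + L - e, offset + L - s) for s, e in segs_tx)
    return region_rc, segments


def _variant_to_vcf(
    pv: _PlannedVariant, tx: TranscriptModel, chrom_seq: str
) -> tuple[int, str, str]:
    """Convert a CDS-space edit to an anchored genomic VCF (pos1, REF, ALT)."""
    g = tx.cds_to_genomic
    if pv.kind == "substitution":
        L = len(pv.ref_cds)
        if tx.strand == "+":
            a = g(pv.cds_pos)
            return a + 1, pv.ref_cds, pv.alt_cds
        a = g(pv.cds_pos + L - 1)
        return a + 1, reverse_complement(pv.ref_cds), reverse_complement(pv.alt_cds)
    if pv.kind == "insertion":
        if tx.strand == "+":
            a = g(pv.cds_pos) - 1
            ins = pv.alt_cds
        else:
            a = g(pv.cds_pos)
            ins = reverse_complement(pv.alt_cds)
        anchor = chrom_seq[a]
        return a + 1, anchor, anchor + ins
    # deletion of cds [pos, pos+L)
    L = len(pv.ref_cds)
    if tx.strand == "+":
        start = g(pv.cds_pos)
    else:
        start = g(pv.cds_pos + L - 1)
    a = start - 1
    ref = chrom_seq[a : a + L + 1]
    return a + 1, ref, chrom_seq[a]


def generate(spec: FixtureSpec) -> Fixture:
    """Build the fixture in memory; raises UnsatisfiableSpec before any state
    is produced if the requested case counts cannot be embedded."""
    for label in spec.case_counts:
        if label not in CASE_LABELS:
            raise UnsatisfiableSpec(f"unknown case label: {label}")
    rng = np.random.default_rng(spec.seed)
    jobs: list[tuple[str | None, int]] = []
    for label in CASE_LABELS:
        for inst in range(spec.case_counts.get(label, 0)):
            jobs.append((label, inst))
    jobs.extend((None, i) for i in range(spec.n_plain_genes))

    chrom_parts: list[str] = []
    offset = 0
    transcripts: list[TranscriptModel] = []
    vcf_rows: list[tuple] = []
    truth_rows: list[dict] = []
    stop_case_genes: list[str] = []
    vid = 0
    for gi, (label, inst) in enumerate(jobs):
        spacer_len = int(rng.integers(*spec.spacer_length))
        spacer = "".join("ACGT"[rng.integers(0, 4)] for _ in range(spacer_len))
        chrom_parts.append(spacer)
        offset += spacer_len

        n_mis = 0
        n_syn = 0
        # no background SNVs in frameshift-carrying genes: downstream of a
        # shifted frame their codon-level truth labels would not hold
        frameshifty = label in ("lone_frameshift", "cindel_pair", "cindel_triple")
        if spec.background_syn_rate > 0 and not frameshifty:
            n_syn = int(rng.poisson(spec.background_syn_rate))
        if spec.background_mis_rate > 0 and not frameshifty:
            rate = spec.background_mis_rate
            if label in ("single_snv_stop", "two_snv_codon_create_stop"):
                rate *= spec.stop_gene_mis_factor
            n_mis = int(rng.poisson(rate))
        # cInDel distance engineering assumes colinear cds/genomic anchors,
        # so compensating-group genes stay on the plus strand
        if label in ("cindel_pair", "cindel_triple"):
            strand = "+"
        else:
            strand = "-" if rng.random() < spec.strand_mix else "+"
        cds, planned, boundaries = _build_gene(
            rng, spec, gi, label, inst, n_syn, n_mis
        )
        region, segments = _layout_gene(
            rng, cds, boundaries, strand, offset, spec.intron_length
        )
        gene_id = f"gene{gi:04d}"
        tid = f"{gene_id}.1"
        tx = TranscriptModel(tid, gene_id, spec.chrom_id, strand, segments)
        transcripts.append(tx)
        chrom_parts.append(region)
        offset += len(region)
        if label in ("single_snv_stop", "two_snv_codon_create_stop"):
            stop_case_genes.append(gene_id)

        chrom_so_far = "".join(chrom_parts)
        for pv in planned:
            vid += 1
            name = f"v{vid:05d}"
            pos1, ref, alt = _variant_to_vcf(pv, tx, chrom_so_far)
            vcf_rows.append((spec.chrom_id, pos1, name, ref, alt, pv.gt))
            truth_rows.append(
                {
                    "variant_id": name,
                    "transcript_id": tid,
                    "gene_id": gene_id,
                    "phase": pv.phase,
                    "expected_isolated": pv.expected_isolated,
                    "expected_combined": pv.expected_combined,
                    "case_label": pv.case_label or "background",
                }
            )

    tail = "".join("ACGT"[rng.integers(0, 4)] for _ in range(60))
    chrom_parts.append(tail)
    chrom_seq = "".join(chrom_parts)
    vcf_rows.sort(key=lambda r: r[1])
    truth = pd.DataFrame(
        truth_rows,
        columns=["variant_id", "transcript_id", "gene_id", "phase",
                 "expected_isolated", "expected_combined", "case_label"],
    )
    return Fixture(spec, chrom_seq, transcripts, vcf_rows, truth, stop_case_genes)


# ---------------------------------------------------------------------------
# File output


def write_fixture(fix: Fixture, outdir) -> dict[str, pathlib.Path]:
    """Write FASTA, GFF3, VCF and truth.tsv; returns the path map."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff3": outdir / "annotation.gff3",
        "vcf": outdir / "variants.vcf",
        "truth": outdir / "truth.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{fix.spec.chrom_id}\n")
        seq = fix.chrom_seq
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for tx in fix.transcripts:
            lo, hi = tx.span
            c = fix.spec.chrom_id
            fh.write(f"{c}\tcovep\tgene\t{lo + 1}\t{hi}\t.\t{tx.strand}\t.\t"
                     f"ID={tx.gene_id}\n")
            fh.write(f"{c}\tcovep\tmRNA\t{lo + 1}\t{hi}\t.\t{tx.strand}\t.\t"
                     f"ID={tx.transcript_id};Parent={tx.gene_id}\n")
            segs = tx.cds_segments if tx.strand == "+" else tx.cds_segments[::-1]
            cum = 0
            for s, e in segs:
                phase = (3 - cum % 3) % 3
                fh.write(f"{c}\tcovep\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t{phase}\t"
                         f"ID=cds-{tx.transcript_id};Parent={tx.transcript_id}\n")
                cum += e - s

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.3\n")
        fh.write(f"##contig=<ID={fix.spec.chrom_id},length={len(fix.chrom_seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for chrom, pos1, name, ref, alt, gt in fix.vcf_rows:
            fh.write(f"{chrom}\t{pos1}\t{name}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")

    fix.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def simulate_expression(
    fix: Fixture, rng: np.random.Generator, n_samples: int = 6,
    stop_mean: float = 2.0, other_mean: float = 20.0,
) -> pd.DataFrame:
    """Gene × sample count table: stop-case genes are barely expressed
    (Poisson mean 2) against a background mean of 20."""
    stop = set(fix.stop_case_genes)
    rows = {}
    for tx in fix.transcripts:
        lam = stop_mean if tx.gene_id in stop else other_mean
        rows[tx.gene_id] = rng.poisson(lam, size=n_samples)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"sample{i + 1}" for i in range(n_samples)])
    df.index.name = "gene_id"
    return df
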
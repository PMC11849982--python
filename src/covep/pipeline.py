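"""Whole-genome orchestration and output writers.

Runs the neighborhood engine over every transcript of every gene, then emits
the three artifacts: an annotated VCF (SnpEff-compatible ANN field plus a
CTX extension with the combined-context call), corrected CDS and protein
FASTA files, and a tab-separated per-variant effect table consumed by the
downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .engine import (
    SO_IMPACT,
    AA3,
    NeighborhoodEffect,
    TranscriptResult,
    analyze_transcript,
)
from .genome import GenomeSequence, TranscriptModel
from .preprocess import PHASE_0, PHASE_1, PHASE_BOTH, NormalizedVariant

log = logging.getLogger("covep.pipeline")


@dataclass
class PipelineResult:
    genomes: dict[str, GenomeSequence]
    genes: dict[str, list[TranscriptModel]]
    variants: list[NormalizedVariant]
    transcript_results: list[TranscriptResult] = field(default_factory=list)
    effect_table: pd.DataFrame | None = None


def run_pipeline(
    genomes: dict[str, GenomeSequence],
    genes: dict[str, list[TranscriptModel]],
    variants: list[NormalizedVariant],
) -> PipelineResult:
    """Evaluate all transcripts against all variants, both haplophases."""
    unmatched = sorted({v.chrom for v in variants} - set(genomes))
    if unmatched:
        raise ValueError(
            "VCF chromosome names absent from FASTA: " + ", ".join(unmatched)
        )
    by_chrom: dict[str, list[NormalizedVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)

    result = PipelineResult(genomes, genes, variants)
    for gene_id, txs in sorted(genes.items()):
        for tx in txs:
            if tx.chrom_id not in genomes:
                log.warning("transcript %s on unknown chromosome %s; skipped",
                            tx.transcript_id, tx.chrom_id)
                continue
            lo, hi = tx.span
            cand = [
                v for v in by_chrom.get(tx.chrom_id, [])
                if v.footprint[1] + 1 >= lo and v.pos <= hi
            ]
            result.transcript_results.extend(
                analyze_transcript(tx, genomes[tx.chrom_id], cand)
            )
    result.effect_table = build_effect_table(result)
    return result


def build_effect_table(result: PipelineResult) -> pd.DataFrame:
    """One row per variant × transcript × haplophase (coding variants only)."""
    rows = []
    pos_of = {v.variant_id: v for v in result.variants}
    for tr in result.transcript_results:
        tx = tr.transcript
        for eff in tr.effects:
            v = pos_of[eff.variant_id]
            rows.append(
                {
                    "variant_id": eff.variant_id,
                    "chrom": v.chrom,
                    "pos": v.vcf_pos + 1,
                    "ref": v.vcf_ref,
                    "alt": v.vcf_alt,
                    "category": eff.category,
                    "is_snv": v.is_snv,
                    "gene_id": tx.gene_id,
                    "transcript_id": tx.transcript_id,
                    "cds_len": tx.cds_length,
                    "haplophase": tr.haplophase,
                    "cds_pos": eff.cds_pos_ref,
                    "cds_pos_shifted": eff.cds_pos_shifted,
                    "codon_index": eff.codon_index,
                    "frame_offset": eff.frame_offset_at_variant,
                    "ref_codons": eff.ref_codons,
                    "alt_codon_isolated": eff.alt_codon_isolated,
                    "alt_codon_combined": eff.alt_codon_combined,
                    "aa_ref": eff.aa_ref,
                    "aa_alt_isolated": eff.aa_alt_isolated,
                    "aa_alt_combined": eff.aa_alt_combined,
                    "isolated_effect": eff.isolated_effect,
                    "combined_effect": eff.combined_effect,
                    "cofactors": ";".join(eff.cofactor_variant_ids) or ".",
                }
            )
    cols = [
        "variant_id", "chrom", "pos", "ref", "alt", "category", "is_snv",
        "gene_id", "transcript_id", "cds_len", "haplophase", "cds_pos",
        "cds_pos_shifted", "codon_index", "frame_offset", "ref_codons",
        "alt_codon_isolated", "alt_codon_combined", "aa_ref",
        "aa_alt_isolated", "aa_alt_combined", "isolated_effect",
        "combined_effect", "cofactors",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Annotated VCF


def _ann_entry(eff: NeighborhoodEffect, v: NormalizedVariant, tx: TranscriptModel) -> str:
    """One SnpEff-style 16-subfield ANN entry for (allele, transcript)."""
    aa_pos = eff.codon_index + 1
    hgvs_p = ""
    if eff.aa_ref and eff.aa_alt_isolated not in (".", "") and eff.category == "substitution":
        hgvs_p = "p.%s%d%s" % (
            AA3.get(eff.aa_ref[:1], "Xaa"), aa_pos, AA3.get(eff.aa_alt_isolated[:1], "Xaa"),
        )
    hgvs_c = f"c.{eff.cds_pos_ref + 1}{v.vcf_ref}>{v.vcf_alt}" if eff.category == "substitution" else f"c.{eff.cds_pos_ref + 1}"
    fields16 = [
        v.vcf_alt,                        # Allele
        eff.isolated_effect,              # Annotation (single-variant baseline)
        SO_IMPACT.get(eff.isolated_effect, "MODIFIER"),
        tx.gene_id,                       # Gene_Name
        tx.gene_id,                       # Gene_ID
        "transcript",                     # Feature_Type
        tx.transcript_id,                 # Feature_ID
        "protein_coding",                 # Transcript_BioType
        "1/1",                            # Rank
        hgvs_c,                           # HGVS.c
        hgvs_p,                           # HGVS.p
        str(eff.cds_pos_ref + 1),         # cDNA.pos
        f"{eff.cds_pos_ref + 1}/{tx.cds_length}",  # CDS.pos/length
        f"{aa_pos}/{tx.cds_length // 3}",  # AA.pos/length
        "",                               # Distance
        "",                               # Errors/Warnings
    ]
    return "|".join(fields16)


def _ctx_entry(eff: NeighborhoodEffect) -> str:
    aa_pos = eff.codon_index + 1
    prot = (
        f"{eff.aa_ref}{aa_pos}{eff.aa_alt_combined}"
        if eff.aa_alt_combined not in (".", "") else "."
    )
    cof = ";".join(eff.cofactor_variant_ids) or "."
    return "|".join(
        [
            str(eff.haplophase),
            eff.combined_effect,
            eff.ref_codons or ".",
            eff.alt_codon_combined or ".",
            prot,
            str(eff.frame_offset_at_variant),
            cof,
        ]
    )


def _noncoding_region(v: NormalizedVariant, genes: dict[str, list[TranscriptModel]]):
    """intron_variant if inside a gene's CDS span but not coding, else intergenic."""
    for txs in genes.values():
        for tx in txs:
            if tx.chrom_id != v.chrom:
                continue
            lo, hi = tx.span
            if lo <= v.pos < hi:
                return "intron_variant", tx
    return "intergenic_region", None


def write_annotated_vcf(result: PipelineResult, path) -> None:
    """Annotated VCF: ANN holds the isolated (single-variant) call per
    transcript; CTX holds haplophase|combined_effect|ref_codon|combined_codon|
    aa-change|frame_offset|cofactors."""
    per_variant: dict[str, list[tuple[NeighborhoodEffect, TranscriptModel]]] = {}
    for tr in result.transcript_results:
        for eff in tr.effects:
            per_variant.setdefault(eff.variant_id, []).append((eff, tr.transcript))

    gt_of = {PHASE_0: "1|0", PHASE_1: "0|1", PHASE_BOTH: "1|1"}
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.3\n")
        out.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
            "'Allele|Annotation|Annotation_Impact|Gene_Name|Gene_ID|Feature_Type|"
            "Feature_ID|Transcript_BioType|Rank|HGVS.c|HGVS.p|cDNA.pos/cDNA.length|"
            "CDS.pos/CDS.length|AA.pos/AA.length|Distance|ERRORS'\">\n"
        )
        out.write(
            '##INFO=<ID=CTX,Number=.,Type=String,Description="Neighborhood context: '
            "'Haplophase|Combined_Effect|Ref_Codon|Combined_Codon|AA_Change|"
            "Frame_Offset|Cofactor_Variants'\">\n"
        )
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for v in sorted(result.variants, key=lambda x: (x.chrom, x.vcf_pos)):
            entries = per_variant.get(v.variant_id, [])
            if entries:
                # dedup identical phase annotations for homozygous variants
                seen, ann, ctx = set(), [], []
                for eff, tx in entries:
                    key = (tx.transcript_id, eff.isolated_effect, eff.combined_effect,
                           eff.alt_codon_combined, eff.frame_offset_at_variant,
                           tuple(eff.cofactor_variant_ids))
                    a = _ann_entry(eff, v, tx)
                    if a not in ann:
                        ann.append(a)
                    if key in seen:
                        continue
                    seen.add(key)
                    ctx.append(_ctx_entry(eff))
                info = f"ANN={','.join(ann)};CTX={','.join(ctx)}"
            else:
                region, tx = _noncoding_region(v, result.genes)
                gene = tx.gene_id if tx else ""
                tid = tx.transcript_id if tx else ""
                ann = "|".join(
                    [v.vcf_alt, region, "MODIFIER", gene, gene,
                     "transcript" if tx else "", tid, "protein_coding" if tx else "",
                     "", "", "", "", "", "", "", ""]
                )
                info = f"ANN={ann};CTX=.|{region}|.|.|.|0|."
            out.write(
                "\t".join(
                    [v.chrom, str(v.vcf_pos + 1), v.variant_id, v.vcf_ref, v.vcf_alt,
                     ".", "PASS", info, "GT", gt_of[v.haplophase]]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA output


def write_sequences(result: PipelineResult, cds_path, protein_path) -> None:
    """Corrected CDS and protein FASTA, one record per transcript per
    haplophase carrying ≥1 variant; identical phase-0/phase-1 sequences are
    collapsed into a single record tagged "phaseboth"."""
    from .engine import translate

    per_tx: dict[str, dict[str, TranscriptResult]] = {}
    for tr in result.transcript_results:
        if tr.applied.variants:
            per_tx.setdefault(tr.transcript.transcript_id, {})[tr.haplophase] = tr

    with open(cds_path, "w") as cds_out, open(protein_path, "w") as prot_out:
        for tid in sorted(per_tx):
            phases = per_tx[tid]
            items: list[tuple[str, TranscriptResult]] = []
            if (
                PHASE_0 in phases and PHASE_1 in phases
                and phases[PHASE_0].applied.alt_cds == phases[PHASE_1].applied.alt_cds
            ):
                items.append(("both", phases[PHASE_0]))
            else:
                items.extend(sorted(phases.items()))
            for tag, tr in items:
                net = tr.applied.net_length_change
                header = f"{tid}|phase{tag}|net{net:+d}nt"
                cds_out.write(f">{header}\n{tr.applied.alt_cds}\n")
                prot, _ = translate(tr.applied.alt_cds)
                prot_out.write(f">{header}\n{prot}\n")


def write_effect_table(result: PipelineResult, path) -> None:
    result.effect_table.to_csv(path, sep="\t", index=False)
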
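"""Neighborhood-aware variant effect engine.

For every transcript and haplophase this module builds the coding sequence
carrying all co-phased variants simultaneously, translates it, and classifies
each variant twice:

* the *isolated* effect — the variant applied alone to the unmodified
  reference CDS (the single-variant baseline any conventional annotator
  reports), and
* the *combined* (neighborhood) effect — the codon read from the fully
  edited CDS, at the variant's shifted, frame-offset-corrected position.

Two SNVs in one codon can therefore turn an isolated premature stop into an
amino-acid substitution, or jointly create a stop neither causes alone; an
uncompensated upstream frameshift voids any downstream codon call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table

from .genome import GenomeSequence, TranscriptModel, reverse_complement
from .preprocess import (
    CATEGORY_DEL,
    CATEGORY_INS,
    CATEGORY_SUB,
    PHASE_0,
    PHASE_1,
    PHASE_BOTH,
    NormalizedVariant,
)

log = logging.getLogger("covep.engine")

# SO terms used for coding effects, with ANN impact classes
SO_IMPACT = {
    "synonymous_variant": "LOW",
    "stop_retained_variant": "LOW",
    "missense_variant": "MODERATE",
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "frameshift_variant": "HIGH",
    "intron_variant": "MODIFIER",
    "intergenic_region": "MODIFIER",
}

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val", "*": "Ter", "X": "Xaa",
}


def translate(cds_seq: str) -> tuple[str, bool]:
    """Translate with the standard code; '*' for stops, 'X' for any codon
    containing a non-ACGT character. Returns (protein, incomplete_flag) where
    the flag marks a trailing partial codon (ignored)."""
    n = len(cds_seq) - len(cds_seq) % 3
    aa = []
    for i in range(0, n, 3):
        aa.append(_CODON_TABLE.get(cds_seq[i : i + 3], "X"))
    return "".join(aa), n != len(cds_seq)


# ---------------------------------------------------------------------------
# CDS-space variants


@dataclass
class CdsVariant:
    """A variant projected onto one transcript's spliced CDS coordinates.

    ``cds_pos`` is the 0-based CDS offset of the first edited base; for
    insertions it is the insertion point (sequence inserted before it).
    Alleles are on the coding strand.
    """

    variant: NormalizedVariant
    cds_pos: int
    ref_cds: str
    alt_cds: str
    category: str

    @property
    def variant_id(self) -> str:
        return self.variant.variant_id

    @property
    def signed_length(self) -> int:
        return len(self.alt_cds) - len(self.ref_cds)


def project_variant(
    v: NormalizedVariant, tx: TranscriptModel
) -> CdsVariant | None | str:
    """Project a genomic variant into CDS space for one transcript.

    Returns a CdsVariant, None if the variant does not touch the CDS, or the
    string "boundary" when an InDel straddles an exon/intron edge (its
    coding-length effect is ill-defined and it is excluded with a log entry).
    """
    fs, fe = v.footprint
    if v.category == CATEGORY_INS:
        # insertion between genomic fs-1 and fs: coding only when both flanks
        # are coding and CDS-adjacent
        c_left = tx.genomic_to_cds(fs - 1)
        c_right = tx.genomic_to_cds(fs)
        if c_left is None or c_right is None:
            if c_left is None and c_right is None:
                return None
            return "boundary"
        if abs(c_left - c_right) != 1:
            return "boundary"
        if tx.strand == "+":
            return CdsVariant(v, c_right, "", v.alt_allele, CATEGORY_INS)
        return CdsVariant(v, c_left, "", reverse_complement(v.alt_allele), CATEGORY_INS)
    # substitution / deletion: every footprint base must be coding & contiguous
    cds_positions = [tx.genomic_to_cds(g) for g in range(fs, fe)]
    if all(c is None for c in cds_positions):
        return None
    if any(c is None for c in cds_positions):
        return "boundary"
    lo, hi = min(cds_positions), max(cds_positions)
    if hi - lo != fe - fs - 1:
        return "boundary"
    if tx.strand == "+":
        ref_c, alt_c = v.ref_allele, v.alt_allele
    else:
        ref_c, alt_c = reverse_complement(v.ref_allele), reverse_complement(v.alt_allele)
    return CdsVariant(v, lo, ref_c, alt_c, v.category)


# ---------------------------------------------------------------------------
# Applying variants


@dataclass
class AppliedCDS:
    """The alternative CDS of one transcript/haplophase plus a shift map.

    ``shift_map[i]`` gives the alt-CDS coordinate of reference CDS position
    ``i`` (deleted positions map to the deletion point); entry ``len(ref)``
    maps the end. The map is non-decreasing by construction.
    """

    transcript_id: str
    haplophase: str
    ref_cds: str
    alt_cds: str
    shift_map: list[int]
    net_length_change: int
    variants: list[CdsVariant] = field(default_factory=list)

    def upstream_offset(self, cds_pos: int, exclude: CdsVariant | None = None) -> int:
        """Cumulative net InDel length strictly upstream of ``cds_pos``, mod 3."""
        total = 0
        for cv in self.variants:
            if cv is exclude or cv.signed_length == 0:
                continue
            if cv.cds_pos < cds_pos:
                total += cv.signed_length
        return total % 3


def apply_variants(ref_cds: str, cds_variants: list[CdsVariant],
                   transcript_id: str = "", haplophase: str = PHASE_BOTH) -> AppliedCDS:
    """Apply non-overlapping CDS variants, producing the alt CDS and shift map.

    Variants whose ref allele mismatches the reference CDS are dropped with a
    logged "reference mismatch" (the validation step); the remainder are
    applied 5'→3'.
    """
    usable: list[CdsVariant] = []
    for cv in cds_variants:
        if cv.ref_cds and ref_cds[cv.cds_pos : cv.cds_pos + len(cv.ref_cds)] != cv.ref_cds:
            log.warning(
                "reference mismatch for %s on %s at CDS %d: expected %s found %s; dropped",
                cv.variant_id, transcript_id, cv.cds_pos, cv.ref_cds,
                ref_cds[cv.cds_pos : cv.cds_pos + len(cv.ref_cds)],
            )
            continue
        usable.append(cv)
    # insertions sort before consuming edits at the same point
    usable.sort(key=lambda cv: (cv.cds_pos, 0 if cv.category == CATEGORY_INS else 1))

    n = len(ref_cds)
    shift = [0] * (n + 1)
    parts: list[str] = []
    cur = 0  # alt cursor
    i = 0  # ref cursor
    for cv in usable:
        for p in range(i, cv.cds_pos):
            shift[p] = cur
            cur += 1
        parts.append(ref_cds[i : cv.cds_pos])
        i = cv.cds_pos
        if cv.category == CATEGORY_INS:
            parts.append(cv.alt_cds)
            cur += len(cv.alt_cds)
        elif cv.category == CATEGORY_SUB:
            parts.append(cv.alt_cds)
            for k in range(len(cv.ref_cds)):
                shift[i + k] = cur + k
            cur += len(cv.alt_cds)
            i += len(cv.ref_cds)
        else:  # deletion: deleted positions collapse onto the deletion point
            for k in range(len(cv.ref_cds)):
                shift[i + k] = cur
            i += len(cv.ref_cds)
    for p in range(i, n):
        shift[p] = cur
        cur += 1
    parts.append(ref_cds[i:])
    shift[n] = cur
    alt = "".join(parts)
    return AppliedCDS(
        transcript_id=transcript_id,
        haplophase=haplophase,
        ref_cds=ref_cds,
        alt_cds=alt,
        shift_map=shift,
        net_length_change=len(alt) - n,
        variants=usable,
    )


# ---------------------------------------------------------------------------
# Classification


@dataclass
class NeighborhoodEffect:
    """Per-variant effect in isolation and in full neighborhood context."""

    variant_id: str
    transcript_id: str
    gene_id: str
    haplophase: str
    category: str
    isolated_effect: str
    combined_effect: str
    ref_codons: str
    alt_codon_isolated: str
    alt_codon_combined: str
    aa_ref: str
    aa_alt_isolated: str
    aa_alt_combined: str
    cds_pos_ref: int
    cds_pos_shifted: int
    frame_offset_at_variant: int
    cofactor_variant_ids: list[str] = field(default_factory=list)
    codon_index: int = -1
    stop_lost_extension: int | None = None
    no_stop_found: bool = False


def _codon_span(cds: str, pos: int, length: int) -> tuple[int, str]:
    """Codon index of the first affected codon and the affected codon string
    (whole codons covering [pos, pos+length))."""
    k0 = pos // 3
    k1 = (pos + max(length, 1) - 1) // 3
    return k0, cds[k0 * 3 : (k1 + 1) * 3]


def _classify_sub(ref_codons: str, alt_codons: str, first_codon_index: int) -> str:
    """Classify an in-frame substitution by comparing whole affected codons."""
    aa_ref, _ = translate(ref_codons)
    aa_alt, _ = translate(alt_codons)
    if first_codon_index == 0 and ref_codons[:3] == "ATG" and alt_codons[:3] != "ATG":
        return "start_lost"
    for r, a in zip(aa_ref, aa_alt):
        if r != "*" and a == "*":
            return "stop_gained"
    for r, a in zip(aa_ref, aa_alt):
        if r == "*" and a != "*":
            return "stop_lost"
    if aa_ref == aa_alt:
        return "stop_retained_variant" if "*" in aa_ref else "synonymous_variant"
    return "missense_variant"


def classify_isolated(cv: CdsVariant, ref_cds: str) -> NeighborhoodEffect:
    """Effect of this variant alone against the unmodified reference CDS.

    Returned as a NeighborhoodEffect with combined fields copied from the
    isolated call (callers overwrite them in neighborhood mode).
    """
    if cv.category == CATEGORY_SUB:
        k0, ref_codons = _codon_span(ref_cds, cv.cds_pos, len(cv.ref_cds))
        iso = (
            ref_cds[: cv.cds_pos]
            + cv.alt_cds
            + ref_cds[cv.cds_pos + len(cv.ref_cds):]
        )
        alt_codons = iso[k0 * 3 : k0 * 3 + len(ref_codons)]
        term = _classify_sub(ref_codons, alt_codons, k0)
        aa_ref, _ = translate(ref_codons)
        aa_alt, _ = translate(alt_codons)
    else:
        k0, ref_codons = _codon_span(ref_cds, cv.cds_pos, max(len(cv.ref_cds), 1))
        if cv.signed_length % 3 != 0:
            term = "frameshift_variant"
        elif cv.category == CATEGORY_INS:
            term = "inframe_insertion"
        else:
            term = "inframe_deletion"
        alt_codons = "."
        aa_ref, _ = translate(ref_codons)
        aa_alt = "."
    return NeighborhoodEffect(
        variant_id=cv.variant_id,
        transcript_id="",
        gene_id="",
        haplophase="",
        category=cv.category,
        isolated_effect=term,
        combined_effect=term,
        ref_codons=ref_codons,
        alt_codon_isolated=alt_codons,
        alt_codon_combined=alt_codons,
        aa_ref=aa_ref,
        aa_alt_isolated=aa_alt,
        aa_alt_combined=aa_alt,
        cds_pos_ref=cv.cds_pos,
        cds_pos_shifted=cv.cds_pos,
        frame_offset_at_variant=0,
        codon_index=k0,
    )


def classify_neighborhood(
    cv: CdsVariant, applied: AppliedCDS
) -> NeighborhoodEffect:
    """Combined-context effect of one variant given the fully edited CDS.

    The combined codon is read from the alt CDS at the variant's shifted
    position. After an uncompensated upstream frameshift any codon call would
    be meaningless, so the combined effect is reported as frameshift_variant
    with no codon detail.
    """
    eff = classify_isolated(cv, applied.ref_cds)
    eff.haplophase = applied.haplophase
    offset = applied.upstream_offset(cv.cds_pos, exclude=cv)
    eff.frame_offset_at_variant = offset
    eff.cds_pos_shifted = applied.shift_map[cv.cds_pos]

    cofactors: list[str] = []
    k0_ref = cv.cds_pos // 3
    k1_ref = (cv.cds_pos + max(len(cv.ref_cds), 1) - 1) // 3
    for other in applied.variants:
        if other is cv:
            continue
        shares_codon = (
            other.category == CATEGORY_SUB
            and other.cds_pos // 3 <= k1_ref
            and (other.cds_pos + len(other.ref_cds) - 1) // 3 >= k0_ref
        )
        alters_frame = (
            other.signed_length % 3 != 0 and other.cds_pos < cv.cds_pos
        )
        if shares_codon or alters_frame:
            cofactors.append(other.variant_id)
    eff.cofactor_variant_ids = cofactors

    if cv.category != CATEGORY_SUB:
        if offset != 0:
            eff.combined_effect = "frameshift_variant"
            eff.alt_codon_combined = "."
            eff.aa_alt_combined = "."
        return eff

    if offset != 0:
        eff.combined_effect = "frameshift_variant"
        eff.alt_codon_combined = "."
        eff.aa_alt_combined = "."
        return eff

    # in-frame: read the combined codons from the edited CDS
    a = applied.shift_map[cv.cds_pos]
    k0_alt = a // 3
    k1_alt = (a + len(cv.alt_cds) - 1) // 3
    combined = applied.alt_cds[k0_alt * 3 : (k1_alt + 1) * 3]
    ref_codons = applied.ref_cds[k0_ref * 3 : k0_ref * 3 + len(combined)]
    if len(ref_codons) < len(combined):
        combined = combined[: len(ref_codons)]
    eff.ref_codons = applied.ref_cds[k0_ref * 3 : (k1_ref + 1) * 3]
    eff.alt_codon_combined = combined
    eff.aa_ref, _ = translate(eff.ref_codons)
    eff.aa_alt_combined, _ = translate(combined)
    eff.combined_effect = _classify_sub(
        applied.ref_cds[k0_ref * 3 : k0_ref * 3 + len(combined)] or eff.ref_codons,
        combined,
        k0_ref,
    )
    if eff.combined_effect == "stop_lost":
        _annotate_stop_lost(eff, applied, k1_alt)
    return eff


def _annotate_stop_lost(eff: NeighborhoodEffect, applied: AppliedCDS, k_alt: int):
    """Extension length (codons) to the next in-frame stop in the edited CDS."""
    prot, _ = translate(applied.alt_cds)
    for k in range(k_alt + 1, len(prot)):
        if prot[k] == "*":
            eff.stop_lost_extension = k - k_alt
            return
    eff.no_stop_found = True


# ---------------------------------------------------------------------------
# Per-transcript orchestration


@dataclass
class TranscriptResult:
    transcript: TranscriptModel
    haplophase: str
    applied: AppliedCDS
    effects: list[NeighborhoodEffect]
    boundary_excluded: list[str] = field(default_factory=list)


def analyze_transcript(
    tx: TranscriptModel,
    genome: GenomeSequence,
    variants: list[NormalizedVariant],
    phases: tuple[str, ...] = (PHASE_0, PHASE_1),
) -> list[TranscriptResult]:
    """Build the edited CDS and classify every coding variant, per haplophase."""
    ref_cds = tx.extract_cds(genome)
    results = []
    for phase in phases:
        cds_vars: list[CdsVariant] = []
        boundary: list[str] = []
        for v in variants:
            if not v.in_phase(phase):
                continue
            proj = project_variant(v, tx)
            if proj is None:
                continue
            if proj == "boundary":
                boundary.append(v.variant_id)
                log.warning(
                    "variant %s straddles an exon boundary of %s; excluded",
                    v.variant_id, tx.transcript_id,
                )
                continue
            cds_vars.append(proj)
        applied = apply_variants(ref_cds, cds_vars, tx.transcript_id, phase)
        effects = []
        for cv in applied.variants:
            eff = classify_neighborhood(cv, applied)
            eff.transcript_id = tx.transcript_id
            eff.gene_id = tx.gene_id
            eff.haplophase = phase
            effects.append(eff)
        results.append(TranscriptResult(tx, phase, applied, effects, boundary))
    return results
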
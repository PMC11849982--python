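"""Line-by-line VCF normalization.

Splits multiallelic records, trims shared allele bases, categorizes each
record as substitution / insertion / deletion, assigns haplophases from the
GT field, and removes conflicting (overlapping same-phase) entries. Every
drop and warning is logged with the input line number so the preprocessing
is fully auditable.

Records are parsed from the VCF body directly: the audit contract (one log
entry per affected input line) needs line-level access that record-object
APIs do not give.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

log = logging.getLogger("covep.preprocess")

PHASE_0 = "0"
PHASE_1 = "1"
PHASE_BOTH = "both"

CATEGORY_SUB = "substitution"
CATEGORY_INS = "insertion"
CATEGORY_DEL = "deletion"

_DNA = frozenset("ACGTN")


@dataclass
class NormalizedVariant:
    """One biallelic, trimmed, categorized variant.

    ``pos`` is the 0-based position of the first residual reference base after
    prefix/suffix trimming. For insertions ``ref_allele`` is empty and ``pos``
    is the insertion point (bases are inserted before ``pos``); for deletions
    ``alt_allele`` is empty. ``vcf_pos/vcf_ref/vcf_alt`` keep a VCF-writable
    (anchored) representation of the same edit.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    category: str
    haplophase: str
    source_line: int
    variant_id: str = "."
    vcf_pos: int = -1  # 0-based position of the anchored representation
    vcf_ref: str = ""
    vcf_alt: str = ""
    info: str = "."

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt identical after trimming")
        lr, la = len(self.ref_allele), len(self.alt_allele)
        expected = (
            CATEGORY_SUB if lr == la else CATEGORY_INS if la > lr else CATEGORY_DEL
        )
        if self.category != expected:
            raise ValueError(f"category {self.category} inconsistent with alleles")

    @property
    def signed_length(self) -> int:
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def footprint(self) -> tuple[int, int]:
        """Reference interval consumed by the edit, 0-based half-open."""
        return self.pos, self.pos + len(self.ref_allele)

    @property
    def is_snv(self) -> bool:
        return self.category == CATEGORY_SUB and len(self.ref_allele) == 1

    def in_phase(self, phase: str) -> bool:
        return self.haplophase == PHASE_BOTH or self.haplophase == phase


@dataclass
class PreprocessResult:
    variants: list[NormalizedVariant]
    dropped: list[tuple[int, str]]  # (source line, reason)
    warnings: list[str] = field(default_factory=list)
    header_lines: list[str] = field(default_factory=list)
    n_input_records: int = 0
    n_alt_alleles: int = 0


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared prefix then shared suffix; returns (new_pos, ref, alt).

    ``pos`` is advanced by the trimmed prefix length; either residual allele
    may be empty. Raises ValueError if the alleles are identical.
    """
    if ref == alt:
        raise ValueError("identical alleles")
    p = 0
    while p < len(ref) and p < len(alt) and ref[p] == alt[p]:
        p += 1
    ref, alt, pos = ref[p:], alt[p:], pos + p
    s = 0
    while s < len(ref) and s < len(alt) and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]:
        s += 1
    if s:
        ref, alt = ref[: len(ref) - s], alt[: len(alt) - s]
    return pos, ref, alt


def classify_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str, str]:
    """Trim and categorize one allele pair.

    Returns (trimmed 0-based pos, trimmed ref, trimmed alt, category).
    Equal residual lengths (including multi-base) are one substitution.
    """
    pos, ref, alt = trim_alleles(pos, ref, alt)
    if len(ref) == len(alt):
        return pos, ref, alt, CATEGORY_SUB
    if len(alt) > len(ref):
        return pos, ref, alt, CATEGORY_INS
    return pos, ref, alt, CATEGORY_DEL


def assign_haplophase(gt: str | None) -> str | None:
    """Map a GT subfield to a phase tag.

    "1|0" → phase 0 only; "0|1" → phase 1 only; "1|1"/"1/1" → both.
    Unphased heterozygous ("0/1") or missing GT → both, under the assumption
    that unphased variants share one haplophase. "0|0"/"0/0" → None (the
    allele is absent from both phases).
    """
    if gt is None or gt in (".", "./.", ".|."):
        return PHASE_BOTH
    sep = "|" if "|" in gt else "/"
    alleles = gt.split(sep)
    if len(alleles) == 1:  # haploid call
        return PHASE_BOTH if alleles[0] == "1" else None
    a, b = alleles[0], alleles[1]
    has0 = a == "1"
    has1 = b == "1"
    if has0 and has1:
        return PHASE_BOTH
    if not has0 and not has1:
        return None
    if sep == "/":  # unphased het: same-haplophase assumption
        return PHASE_BOTH
    return PHASE_0 if has0 else PHASE_1


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def split_multiallelic(fields: list[str], line_no: int, result: PreprocessResult):
    """Yield one (alt_index, alt_allele, gt_for_this_allele) per usable ALT.

    Symbolic alleles, breakends, '*' and '.' ALTs are skipped with a log
    entry. GT indices are remapped so each split record's genotype refers to
    {0,1} for reference / its own allele.
    """
    alts = fields[4].split(",")
    gt = None
    if len(fields) >= 10:
        fmt = fields[8].split(":")
        sample = fields[9].split(":")
        if "GT" in fmt:
            gt = sample[fmt.index("GT")]
    for idx, alt in enumerate(alts, start=1):
        if alt in (".", "*") or alt.startswith("<") or set(alt) - _DNA - {"[", "]"}:
            reason = f"symbolic/unsupported ALT allele '{alt}'"
            result.dropped.append((line_no, reason))
            log.warning("line %d: %s; skipped", line_no, reason)
            continue
        if "[" in alt or "]" in alt:
            reason = f"breakend ALT allele '{alt}'"
            result.dropped.append((line_no, reason))
            log.warning("line %d: %s; skipped", line_no, reason)
            continue
        sub_gt = None
        if gt is not None:
            sep = "|" if "|" in gt else "/"
            calls = gt.split(sep)
            # het-alt like 1/2: the two ALT alleles sit on different homologs
            # even when unphased, so split records get opposite phases
            nonref = {c for c in calls if c.isdigit() and c != "0"}
            if sep == "/" and len(calls) == 2 and len(nonref) == 2:
                sep = "|"
            remapped = []
            bad = False
            for a in calls:
                if a == ".":
                    remapped.append(".")
                elif a.isdigit():
                    remapped.append("1" if int(a) == idx else "0")
                else:
                    bad = True
            if bad:
                reason = f"unparseable GT '{gt}'"
                result.dropped.append((line_no, reason))
                log.warning("line %d: %s; record skipped", line_no, reason)
                continue
            sub_gt = sep.join(remapped)
        yield idx, alt, sub_gt


def resolve_conflicts(
    variants: list[NormalizedVariant],
) -> tuple[list[NormalizedVariant], list[tuple[int, str]]]:
    """Drop same-phase variants whose reference footprints overlap.

    Variants must be sorted by (chrom, pos). The record appearing first in
    file order wins; every drop reports both line numbers. Exact duplicates
    (same site, alleles and phase) are dropped as duplicates. Insertions have
    zero-length footprints, so two insertions only conflict at an identical
    point; an insertion inside a deletion's footprint conflicts with it.
    """
    kept: list[NormalizedVariant] = []
    dropped: list[tuple[int, str]] = []
    # active footprints per (chrom, phase-slot); "both" occupies both slots
    last_end: dict[tuple[str, str], tuple[int, NormalizedVariant]] = {}

    def slots(v: NormalizedVariant):
        return (PHASE_0, PHASE_1) if v.haplophase == PHASE_BOTH else (v.haplophase,)

    for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.source_line)):
        conflict = None
        for ph in slots(v):
            key = (v.chrom, ph)
            if key in last_end:
                end, prev = last_end[key]
                fs, fe = v.footprint
                same_point_ins = (
                    v.category == CATEGORY_INS
                    and prev.category == CATEGORY_INS
                    and prev.pos == v.pos
                )
                if fs < end or same_point_ins:
                    conflict = prev
                    break
        if conflict is not None:
            if (
                conflict.pos == v.pos
                and conflict.ref_allele == v.ref_allele
                and conflict.alt_allele == v.alt_allele
                and conflict.haplophase == v.haplophase
            ):
                reason = (
                    f"duplicate of line {conflict.source_line} "
                    f"({v.chrom}:{v.pos + 1} {v.ref_allele or '-'}>{v.alt_allele or '-'})"
                )
            else:
                reason = (
                    f"footprint overlaps variant from line {conflict.source_line} "
                    f"in the same haplophase"
                )
            dropped.append((v.source_line, reason))
            log.warning("line %d: %s; dropped", v.source_line, reason)
            continue
        kept.append(v)
        fs, fe = v.footprint
        for ph in slots(v):
            key = (v.chrom, ph)
            prev_end = last_end.get(key, (-1, None))[0]
            last_end[key] = (max(prev_end, fe if fe > fs else fs), v)
    return kept, dropped


def preprocess_vcf(path) -> PreprocessResult:
    """Normalize a VCF file: split, trim, categorize, phase, de-conflict."""
    result = PreprocessResult(variants=[], dropped=[])
    warned_unphased = False
    n_samples_warned = False
    raw: list[NormalizedVariant] = []
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                result.header_lines.append(line)
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                result.dropped.append((line_no, "fewer than 5 VCF columns"))
                log.warning("line %d: fewer than 5 VCF columns; skipped", line_no)
                continue
            if len(fields) > 10 and not n_samples_warned:
                result.warnings.append(
                    "multi-sample VCF: only the first sample column is used"
                )
                log.warning("multi-sample VCF detected; using first sample only")
                n_samples_warned = True
            result.n_input_records += 1
            chrom, pos_s, vid, ref = fields[0], fields[1], fields[2], fields[3].upper()
            info = fields[7] if len(fields) >= 8 else "."
            try:
                pos0 = int(pos_s) - 1
            except ValueError:
                result.dropped.append((line_no, f"non-integer POS '{pos_s}'"))
                log.warning("line %d: non-integer POS; skipped", line_no)
                continue
            result.n_alt_alleles += len(fields[4].split(","))
            has_gt = len(fields) >= 10 and "GT" in fields[8].split(":")
            if not has_gt and not warned_unphased:
                result.warnings.append(
                    "no GT information: all variants assumed in the same haplophase"
                )
                log.warning("no GT field: assuming all variants share one haplophase")
                warned_unphased = True
            for idx, alt, sub_gt in split_multiallelic(fields, line_no, result):
                alt = alt.upper()
                try:
                    tpos, tref, talt, category = classify_variant(pos0, ref, alt)
                except ValueError:
                    result.dropped.append(
                        (line_no, f"identical REF and ALT bases '{ref}'")
                    )
                    log.warning("line %d: identical REF/ALT '%s'; rejected", line_no, ref)
                    continue
                phase = assign_haplophase(sub_gt)
                if phase is None:
                    result.dropped.append(
                        (line_no, f"genotype '{sub_gt}' carries the allele in no phase")
                    )
                    log.warning(
                        "line %d: GT '%s' places ALT %s in no haplophase; dropped",
                        line_no, sub_gt, alt,
                    )
                    continue
                vcf_pos, vcf_ref, vcf_alt = _anchored(pos0, ref, alt)
                raw.append(
                    NormalizedVariant(
                        chrom=chrom,
                        pos=tpos,
                        ref_allele=tref,
                        alt_allele=talt,
                        category=category,
                        haplophase=phase,
                        source_line=line_no,
                        variant_id=vid if vid != "." else f"ln{line_no}a{idx}",
                        vcf_pos=vcf_pos,
                        vcf_ref=vcf_ref,
                        vcf_alt=vcf_alt,
                        info=info,
                    )
                )
    kept, conflict_drops = resolve_conflicts(raw)
    result.variants = kept
    result.dropped.extend(conflict_drops)
    return result


def _anchored(pos0: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal VCF-writable representation: trim suffix, then prefix leaving
    at least one base in each allele."""
    s = 0
    while (
        s < len(ref) - 1 and s < len(alt) - 1
        and ref[len(ref) - 1 - s] == alt[len(alt) - 1 - s]
    ):
        s += 1
    if s:
        ref, alt = ref[:-s], alt[:-s]
    p = 0
    while p < len(ref) - 1 and p < len(alt) - 1 and ref[p] == alt[p]:
        p += 1
    return pos0 + p, ref[p:], alt[p:]


def write_normalized_vcf(result: PreprocessResult, path) -> None:
    """Write normalized records, preserving INFO and adding a CVP= audit tag."""
    with open(path, "w") as out:
        wrote_header = False
        for h in result.header_lines:
            if h.startswith("#CHROM") and not wrote_header:
                out.write(
                    '##INFO=<ID=CVP,Number=1,Type=String,'
                    'Description="Preprocessing audit: category|haplophase|source_line">\n'
                )
                wrote_header = True
            out.write(h + "\n")
        if not result.header_lines:
            out.write("##fileformat=VCFv4.3\n")
            out.write(
                '##INFO=<ID=CVP,Number=1,Type=String,'
                'Description="Preprocessing audit: category|haplophase|source_line">\n'
            )
            out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        gt_of = {PHASE_0: "1|0", PHASE_1: "0|1", PHASE_BOTH: "1|1"}
        for v in sorted(result.variants, key=lambda x: (x.chrom, x.vcf_pos)):
            tag = f"CVP={v.category}|{v.haplophase}|{v.source_line}"
            rest = [f for f in v.info.split(";") if f and f != "." and not f.startswith("CVP=")]
            info = ";".join(rest + [tag])
            out.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.vcf_pos + 1),
                        v.variant_id,
                        v.vcf_ref,
                        v.vcf_alt,
                        ".",
                        "PASS",
                        info,
                        "GT",
                        gt_of[v.haplophase],
                    ]
                )
                + "\n"
            )


def write_log(result: PreprocessResult, path) -> None:
    with open(path, "w") as out:
        for w in result.warnings:
            out.write(f"WARNING\t-\t{w}\n")
        for line_no, reason in sorted(result.dropped):
            out.write(f"DROP\t{line_no}\t{reason}\n")
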
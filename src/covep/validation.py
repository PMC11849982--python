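"""Variant confirmation against an independent assembly.

Walking each chromosome 5'→3', every candidate variant is tested by taking
the reference sequence immediately upstream of it, rewriting that window
with all previously accepted (bona fide) variants, appending the candidate's
ALT allele, and searching for the resulting string in the assembly (both
strands, exact match). A candidate is accepted only if the assembly contains
its variant-bearing context; accepted variants then shape the windows of all
downstream candidates, which is what makes consecutive false positives
detectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .genome import GenomeSequence, reverse_complement
from .preprocess import NormalizedVariant

log = logging.getLogger("covep.validation")

DEFAULT_WINDOW = 100
DEFAULT_MIN_QUERY = 30


class AssemblyIndex:
    """Substring-searchable view of assembly sequences, both strands."""

    def __init__(self, sequences: dict[str, GenomeSequence] | dict[str, str]):
        self._seqs: list[str] = []
        for s in sequences.values():
            seq = s.sequence if isinstance(s, GenomeSequence) else str(s).upper()
            self._seqs.append(seq)
            self._seqs.append(reverse_complement(seq))

    def __contains__(self, query: str) -> bool:
        q = query.upper()
        return any(q in s for s in self._seqs)


@dataclass
class ValidationState:
    chrom: str
    query_window_length: int = DEFAULT_WINDOW
    min_query_length: int = DEFAULT_MIN_QUERY
    accepted_variants: list[NormalizedVariant] = field(default_factory=list)


def build_query(
    ref_seq: str,
    accepted: list[NormalizedVariant],
    candidate: NormalizedVariant,
    window: int = DEFAULT_WINDOW,
) -> tuple[str, bool]:
    """Edited upstream window plus the candidate's ALT allele.

    The window covers the ``window`` reference bases immediately upstream of
    the candidate's (trimmed) position, rewritten with every accepted edit
    that overlaps it; truncated (and flagged) at the chromosome start.
    """
    start = candidate.pos - window
    truncated = start < 0
    if truncated:
        start = 0
    segment = ref_seq[start : candidate.pos]
    # apply accepted edits right-to-left so earlier coordinates stay valid
    for v in sorted(accepted, key=lambda x: x.pos, reverse=True):
        fs, fe = v.footprint
        if fe <= start or fs >= candidate.pos:
            continue
        if fs < start:  # edit partially upstream of the window: skip cleanly
            continue
        segment = segment[: fs - start] + v.alt_allele + segment[fe - start :]
    return segment + candidate.alt_allele, truncated


def validate_variant(query: str, assembly: AssemblyIndex, min_len: int = DEFAULT_MIN_QUERY) -> bool:
    """Exact-substring acceptance on either assembly strand.

    Match uniqueness is not required: the first hit accepts (requiring
    uniqueness would reject genuine variants inside repeats)."""
    if len(query) < min_len:
        return False
    return query in assembly


def validate_chromosome(
    ref: GenomeSequence,
    variants: list[NormalizedVariant],
    assembly: AssemblyIndex,
    window: int = DEFAULT_WINDOW,
    min_query: int = DEFAULT_MIN_QUERY,
) -> tuple[list[NormalizedVariant], list[tuple[NormalizedVariant, str]]]:
    """Successively test position-sorted variants of one chromosome.

    Returns (accepted, rejected-with-reason). Accepted variants immediately
    join the editing state used for all downstream queries.
    """
    state = ValidationState(ref.chrom_id, window, min_query)
    rejected: list[tuple[NormalizedVariant, str]] = []
    for v in sorted(variants, key=lambda x: (x.pos, x.source_line)):
        query, truncated = build_query(ref.sequence, state.accepted_variants, v, window)
        if truncated:
            log.info("variant %s at %s:%d: window truncated at chromosome start",
                     v.variant_id, v.chrom, v.pos + 1)
        if len(query) < min_query:
            rejected.append((v, f"query too short ({len(query)} < {min_query} nt)"))
            continue
        if validate_variant(query, assembly, min_query):
            state.accepted_variants.append(v)
        else:
            rejected.append((v, "variant-bearing context absent from assembly"))
    return state.accepted_variants, rejected


def validate_all(
    genomes: dict[str, GenomeSequence],
    variants: list[NormalizedVariant],
    assembly: AssemblyIndex,
    window: int = DEFAULT_WINDOW,
    min_query: int = DEFAULT_MIN_QUERY,
):
    """Run per-chromosome validation over a whole variant set."""
    accepted: list[NormalizedVariant] = []
    rejected: list[tuple[NormalizedVariant, str]] = []
    by_chrom: dict[str, list[NormalizedVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    for chrom in sorted(by_chrom):
        if chrom not in genomes:
            for v in by_chrom[chrom]:
                rejected.append((v, f"chromosome {chrom} absent from reference"))
            continue
        acc, rej = validate_chromosome(
            genomes[chrom], by_chrom[chrom], assembly, window, min_query
        )
        accepted.extend(acc)
        rejected.extend(rej)
    return accepted, rejected
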
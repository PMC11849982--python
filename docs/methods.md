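# Methods

## Model

A transcript is a set of non-overlapping CDS segments on one strand;
internally all coordinates are 0-based half-open, converted once at the
GFF3/VCF boundaries (both 1-based). The spliced CDS is the concatenation of
segments in genomic order, reverse-complemented for minus-strand models, so
CDS position 0 is always the first coding base 5'→3' on the coding strand.
Transcripts whose spliced length is not a multiple of three are flagged
`incomplete_cds` and still processed (floor(len/3) codons are translated):
real annotations contain such models, and dropping them would silently
change downstream gene counts. The CDS phase column of the GFF3 is treated
as advisory; segment lengths are what is trusted, and conflicts are logged.

Variants are normalized to biallelic, trimmed records (shared prefix first,
then shared suffix; the position advances by the trimmed prefix). Equal
residual lengths are one substitution — multi-base replacements (MNVs) are
kept intact rather than exploded into SNVs, because the neighborhood engine
handles them natively and exploding would discard the caller's phase
guarantee. InDels are not left-aligned: trimming only, with reference-allele
verification downstream catching placement errors. Overlapping same-phase
footprints are resolved by file order (first record wins), a deterministic
tie-break that is fully audited: every drop is logged with both input line
numbers. Haplophases come from GT: `1|0`→phase 0, `0|1`→phase 1,
`1|1`/`1/1`→both; unphased heterozygous and GT-less records are assumed to
share a single haplophase (warned once per file). A het-alt genotype such as
`1/2` places its two ALT alleles on opposite phases, since two different
alleles at one site cannot share a homolog. Only the first sample column of
a multi-sample VCF is used.

### Neighborhood classification

Per transcript and haplophase, all co-phased coding variants are applied
5'→3' to the reference CDS, producing the edited CDS and a non-decreasing
shift map (deleted positions collapse onto the deletion point). Each variant
receives two calls:

* **isolated** — only this variant applied to the reference CDS; the
  classification compares the affected whole codons (start_lost if the ATG
  at codon 0 is destroyed, then stop_gained, stop_lost, stop_retained /
  synonymous, else missense; InDels are frameshift_variant when their length
  is not a multiple of three, otherwise inframe_insertion/deletion).
* **combined** — the same comparison, but the mutant codons are read from
  the fully edited CDS at the variant's shifted position. The frame offset
  at a variant is the cumulative net InDel length strictly upstream, mod 3.
  When it is nonzero, any codon call would be meaningless, so the combined
  effect is reported as `frameshift_variant` with no codon detail. Cofactor
  ids list every variant sharing an affected codon plus every upstream
  frame-disrupting InDel.

This design makes the two directions of codon interference explicit: an
isolated stop whose combined codon encodes an amino acid is reported as a
combined missense (frequently tyrosine, whose codons TAT/TAC differ from
the stops TAA/TAG by one base), and two individually-missense SNVs whose
joint codon is a stop are reported as a combined stop_gained.

Start-codon policy: destroying the ATG is `start_lost`; no downstream
in-frame ATG rescue is searched. `stop_lost` calls report the distance (in
codons) to the next in-frame stop within the annotated CDS, or a
`no_stop_found` flag. Every annotated isoform is evaluated independently;
per-gene summaries use the longest-CDS isoform (ties broken by id) as the
deterministic representative. InDels straddling an exon/intron boundary are
excluded from CDS analysis with a log entry — their coding-length effect is
ill-defined under this model. In `incomplete_cds` transcripts a variant
confined to the trailing partial codon has no translated consequence under
the floor(len/3) policy and is reported `synonymous_variant`.

### Compensating InDels

The frame trace after the i-th InDel of a CDS (one phase) is
`(Σ_{j≤i} signed_length_j) mod 3`. A compensating group starts at the first
frame-disrupting member and closes at the first member returning the trace
to 0 (first-return rule); in-frame InDels arriving while the trace is 0
belong to no group; a run that never returns is an uncompensated
frameshift. Groups may have any number of members. Member distances are
genomic anchor-to-anchor between consecutive members (the InDel's own
length is not added) — the convention is stated in the output header since
other endpoint choices are defensible. Homozygous transcripts whose two
phases carry the identical InDel set are counted once.

### Benchmark statistics

The stop comparison uses SNVs only (so frameshifts cannot contaminate codon
calls) and the most upstream predicted premature stop per gene. Counting is
per stop *position* (gene × transcript × codon): a stop jointly created by
two SNVs is one gained stop, not two. aa_N counts SNVs whose combined call
changes the protein (missense, stop_gained, stop_lost, start_lost); aa_S
counts synonymous and stop_retained calls; the ratio is
`min((aa_N+1)/(aa_S+1), 10)` — the pseudocount makes zero-aa_S genes
computable and the cap keeps the distribution plottable. aa_N/aa_S tallies
are computed from neighborhood-mode calls for consistency with the stop
comparison. "All other genes" means protein-coding genes with ≥1 coding SNV
and no premature stop: zero-variant genes have no information beyond the
pseudocount and would flood the comparison with 1.0 ratios. Group
comparisons use the two-sided Mann-Whitney U with normal approximation and
tie correction (group sizes here make the asymptotic form appropriate);
expression values are per-gene means clipped at 50 before plotting and
testing.

### Assembly validation

Variants of each chromosome are walked 5'→3'. The query for a candidate is
the `window` (default 100 nt) reference bases immediately upstream,
rewritten with all previously accepted variants, followed by the candidate's
ALT allele; it is accepted iff it occurs exactly in the assembly or its
reverse complement. Defaults — 100 nt window, exact matching, a 30 nt
minimum query, no uniqueness requirement (first hit accepts, so repeats do
not cause rejections) — are configurable. Because accepted variants reshape
downstream windows, a false positive fails to match even when its immediate
context is repetitive elsewhere. Limitation: for pure deletions the query
ends at the deletion point, so the test covers the upstream context only;
appending a downstream flank would strengthen it but changes the stated
query contract.

## Synthetic fixtures

The generator embeds each requested case class in its own gene (1–3 exons,
introns ≥ 20 nt, intergenic spacers ≥ 60 nt so footprints and windows never
collide across genes; default half the genes on the minus strand). Case
classes cover: single synonymous / missense / stop-gaining SNVs, the
CAA→(TAA|TAC) tyrosine-rescue pair, a CAC-based pair where two
individually-missense SNVs jointly create TAA, MNV substitutions, in-frame
insertions and deletions, lone frameshifts, compensating pairs (+2/+4) and
triples (+1/+1/+1) with engineered anchor distances cycling {3, 4, 6} bp,
and an interfering pair split across opposite haplophases (expected: no
interaction). Filler codons are drawn from a stop-free set whose
second/third positions cannot combine with the engineered insertions into
accidental stop codons inside compensated windows. Compensating-group genes
stay on the plus strand so engineered anchor distances are exact. Optional
background SNVs emulate pseudogenization (stop-carrying genes receive
amino-acid-changing SNVs at 3× the background Poisson rate, default 2 per
gene); background SNVs are not placed in frameshift-carrying genes, where
codon-level truth labels would not hold downstream of the shift. The
expression simulator draws Poisson counts with mean 2 for stop-case genes
and 20 otherwise. Same-seed regeneration is byte-identical.

What the fixtures do *not* emulate: realistic mutation-rate or selection
models, overlapping genes, alternative isoforms, sequencing error, or
annotation noise. Passing tests therefore demonstrate the correctness of
the coordinate arithmetic, codon logic, grouping and statistics — not
robustness to messy real-world annotations.

## Problem sizes and numerics

The acceptance script runs 209 engineered cases (19 per class, ~600
variant × phase checks), a 130-gene pseudogenization cohort, and a 12 kb
assembly-validation walk with 40 true and 10 fabricated variants — sizes
chosen so the whole recomputation runs in seconds while every case class is
exercised repeatedly. Mann-Whitney p-values are reported as −log10(p)
(floored at 1e-300). The permutation cross-check in the test suite uses
10,000 rounds and tolerates four Monte-Carlo standard errors. All
randomness flows from explicit seeds through `numpy.random.default_rng`;
there is no hidden global state, and repeat runs of every pipeline stage
are byte-identical.

## Known limitations

* Codon-level effects only: splice-site disruption, UTR/regulatory effects
  and protein-level deleteriousness scores are out of scope.
* Variants spanning exon/intron boundaries are excluded rather than
  modeled.
* The assembly validator is exact-match only; a divergent or low-quality
  assembly will reject genuine variants.
* RNA-seq normalization is not performed; the expression comparison
  consumes a provided count table as-is.
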
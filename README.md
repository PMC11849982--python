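# covep — context-aware variant effect prediction

Conventional variant annotators classify each small variant against the
unmodified reference, one at a time. When several variants co-occur in the
same coding sequence — two SNVs inside one codon, or a pair of frameshifting
InDels that cancel each other — that single-variant view gets the biology
wrong: a "premature stop codon" may in fact be an ordinary amino-acid
substitution once its codon partner is taken into account, and a "frameshift"
may be reverted a few bases downstream. `covep` annotates every coding
variant **jointly with all other variants in the same coding sequence and
haplophase**, for resequencing studies, pangenome comparisons and
pseudogenization analyses where such variant constellations are common.

## What it computes

Given a VCF of small variants (phased or homozygous), a reference genome
(FASTA) and gene models (GFF3), for every transcript and haplophase `covep`:

1. **Normalizes the VCF** — splits multiallelic records, trims shared allele
   bases, categorizes each record as substitution / insertion / deletion,
   assigns haplophases from the GT field (unphased variants are assumed to
   share one haplophase, with a warning) and removes conflicting
   (overlapping same-phase) entries with a full per-line audit log.
2. **Builds the edited CDS** carrying all co-phased variants, with a shift
   map from reference to edited coordinates, and classifies each variant
   twice:
   * the *isolated* effect — the variant applied alone (the single-variant
     baseline any conventional annotator reports), and
   * the *combined* effect — the codon read from the fully edited CDS at the
     variant's shifted, frame-offset-corrected position. Downstream of an
     uncompensated frameshift no codon call is made (`frameshift_variant`
     is propagated instead).
3. **Detects compensating InDels (cInDels)** — walking each CDS 5'→3', the
   cumulative frame shift `(Σ signed lengths) mod 3` is traced; a group
   opens at the first frame-disrupting InDel and closes at the first return
   to frame 0 (groups of any size, not just pairs), reporting member
   distances and the net residue change.
4. **Benchmark statistics** — premature-stop positions compared between the
   two modes (confirmed / reclassified-to-substitution / newly gained, most
   upstream stop per gene, SNVs only); per-gene counts of amino-acid-changing
   (aa_N) vs amino-acid-preserving (aa_S) SNVs with the capped pseudocount
   ratio `min((aa_N+1)/(aa_S+1), 10)`; Mann-Whitney U comparisons of ratios
   and of mean expression (clipped at 50) between premature-stop genes and
   all other protein-coding genes.
5. **Assembly validation** — each variant's upstream context window (default
   100 nt), rewritten with all previously accepted variants and ending in
   the candidate's ALT allele, is searched for exactly in an independent
   assembly (both strands); only supported variants are kept.

Outputs: an annotated VCF (`ANN=` with the SnpEff-compatible 16 subfields
holding the isolated call, plus a `CTX=` extension with
`haplophase|combined_effect|ref_codon|combined_codon|aa_change|frame_offset|cofactors`),
corrected CDS and protein FASTA files, a per-variant effect table (TSV), and
the cInDel / statistics reports.

## Worked example

```bash
covep simulate --outdir fixture --seed 3          # toy genome + VCF + truth
covep main --vcf fixture/variants.vcf --fasta fixture/genome.fasta \
           --gff3 fixture/annotation.gff3 --outdir run
# annotated 34 variants over 24 transcripts
covep sfa  --vcf fixture/variants.vcf --fasta fixture/genome.fasta \
           --gff3 fixture/annotation.gff3 --outdir sfa
# 4 compensating groups in 4 genes; 2 transcripts with uncompensated frameshifts
```

The headline mechanism in one picture: reference codon `CAA` (Gln) carrying
two SNVs, `C→T` at codon position 1 and `A→C` at position 3. Seen alone,
`C→T` creates `TAA` — a premature stop (`stop_gained`). Seen jointly, the
codon is `TAC` — tyrosine. In `run/annotated.vcf` the first variant's record
therefore reads `ANN=…|stop_gained|…` but
`CTX=0|missense_variant|CAA|TAC|Q…Y|0|<partner id>`: the isolated call is a
false positive and the tyrosine rescue is reported with the cofactor variant
that causes it. The `run/effects.tsv` table carries both calls per
variant × transcript × haplophase for downstream analysis.

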
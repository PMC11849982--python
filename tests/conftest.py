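import pathlib

import pytest

import covep


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """Default synthetic fixture (2 cases per label), written once."""
    d = tmp_path_factory.mktemp("fixture")
    fix = covep.generate(covep.FixtureSpec(seed=7))
    paths = covep.write_fixture(fix, d)
    paths["fixture"] = fix
    return paths


@pytest.fixture(scope="session")
def pipeline_result(fixture_paths):
    genomes = covep.read_fasta(fixture_paths["fasta"])
    genes = covep.parse_gff3(fixture_paths["gff3"])
    pre = covep.preprocess_vcf(fixture_paths["vcf"])
    return covep.run_pipeline(genomes, genes, pre.variants)


@pytest.fixture
def two_exon_plus():
    """Plus-strand toy transcript: genome ATGGCTAAATTGTAACC, exons [0,6)+[9,15)."""
    genome = covep.GenomeSequence("c", "ATGGCTAAATTGTAACC")
    tx = covep.TranscriptModel("t1", "g1", "c", "+", [(0, 6), (9, 15)])
    return genome, tx


@pytest.fixture
def two_exon_minus():
    genome = covep.GenomeSequence("c", "ATGGCTAAATTGTAACC")
    tx = covep.TranscriptModel("t1m", "g1", "c", "-", [(0, 6), (9, 15)])
    return genome, tx


def naive_rebuild_cds(genome_seq: str, tx: covep.TranscriptModel,
                      variants, phase: str) -> str:
    """Independent oracle: rebuild the whole chromosome with all phase
    variants applied, shift the gene model's segment boundaries by the net
    upstream length change, and re-extract the spliced CDS."""
    edits = [v for v in variants
             if v.chrom == tx.chrom_id and v.in_phase(phase)]
    seq = genome_seq
    for v in sorted(edits, key=lambda x: x.pos, reverse=True):
        fs, fe = v.footprint
        seq = seq[:fs] + v.alt_allele + seq[fe:]

    def shifted(b):
        delta = 0
        for v in edits:
            fs, fe = v.footprint
            if fe <= b and not (v.ref_allele == "" and fs == b):
                delta += v.signed_length
            elif v.ref_allele == "" and fs < b:
                delta += v.signed_length
        return b + delta

    segs = [(shifted(s), shifted(e)) for s, e in tx.cds_segments]
    concat = "".join(seq[s:e] for s, e in segs)
    return concat if tx.strand == "+" else covep.reverse_complement(concat)
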
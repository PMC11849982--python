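"""Benchmark statistics: stop-mode comparison, aa_N/aa_S, Mann-Whitney."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import covep
from covep.stats import aa_ratio, expression_compare, gene_tallies, group_test


def effect_frame(rows):
    """Minimal effect-table rows for stats tests."""
    defaults = dict(
        variant_id="v", chrom="c", pos=1, ref="A", alt="G",
        category="substitution", is_snv=True, gene_id="g", transcript_id="t",
        cds_len=300, haplophase="0", cds_pos=0, cds_pos_shifted=0,
        codon_index=0, frame_offset=0, ref_codons="CAA",
        alt_codon_isolated="TAA", alt_codon_combined="TAA", aa_ref="Q",
        aa_alt_isolated="*", aa_alt_combined="*",
        isolated_effect="stop_gained", combined_effect="stop_gained",
        cofactors=".",
    )
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestFirstStop:
    def test_most_upstream_stop_selected(self):
        eff = effect_frame([
            dict(variant_id="a", gene_id="g1", cds_pos=36, codon_index=12),
            dict(variant_id="b", gene_id="g1", cds_pos=120, codon_index=40),
        ])
        s = covep.first_stop_per_gene(eff, "isolated")
        assert s["g1"] == 36

    def test_gene_without_stop_absent(self):
        eff = effect_frame([
            dict(gene_id="g2", isolated_effect="missense_variant",
                 combined_effect="missense_variant"),
        ])
        assert "g2" not in covep.first_stop_per_gene(eff, "isolated").index

    def test_neutralized_upstream_stop_moves_to_downstream(self):
        """Isolated mode sees the codon-12 stop; in neighborhood mode it is
        rescued, so the codon-40 stop becomes the most upstream."""
        eff = effect_frame([
            dict(variant_id="a", gene_id="g1", cds_pos=36, codon_index=12,
                 combined_effect="missense_variant"),
            dict(variant_id="b", gene_id="g1", cds_pos=120, codon_index=40),
        ])
        assert covep.first_stop_per_gene(eff, "isolated")["g1"] == 36
        assert covep.first_stop_per_gene(eff, "neighborhood")["g1"] == 120

    def test_longest_isoform_is_representative(self):
        eff = effect_frame([
            dict(gene_id="g1", transcript_id="t_short", cds_len=90),
            dict(gene_id="g1", transcript_id="t_long", cds_len=300,
                 isolated_effect="missense_variant",
                 combined_effect="missense_variant"),
        ])
        # the short isoform's stop is ignored: t_long is the representative
        assert "g1" not in covep.first_stop_per_gene(eff, "isolated").index


class TestCompareModes:
    def test_engineered_reclassifications_and_gains(self, tmp_path):
        """Fixture with 5 rescue and 2 joint-stop cases: exactly 5 stop
        positions reclassified and 2 gained."""
        spec = covep.FixtureSpec(seed=21, case_counts={
            "two_snv_codon_rescue": 5, "two_snv_codon_create_stop": 2,
            "single_snv_stop": 3, "single_snv_missense": 2,
        })
        fix = covep.generate(spec)
        paths = covep.write_fixture(fix, tmp_path)
        genomes = covep.read_fasta(paths["fasta"])
        genes = covep.parse_gff3(paths["gff3"])
        pre = covep.preprocess_vcf(paths["vcf"])
        res = covep.run_pipeline(genomes, genes, pre.variants)
        modes = covep.compare_stop_modes(res.effect_table)
        assert modes["reclassified_to_substitution"] == 5
        assert modes["gained_in_neighborhood"] == 2
        assert modes["confirmed"] == 3
        assert (modes["confirmed"] + modes["reclassified_to_substitution"]
                == modes["total_isolated_stops"])
        # tyrosine rescue: every reclassified codon encodes Tyr here
        assert set(modes["reclassified_aa"]) == {"Y"}

    def test_no_interfering_codons_means_no_differences(self):
        eff = effect_frame([
            dict(variant_id="a", gene_id="g1"),
            dict(variant_id="b", gene_id="g2", isolated_effect="missense_variant",
                 combined_effect="missense_variant"),
        ])
        modes = covep.compare_stop_modes(eff)
        assert modes["reclassified_to_substitution"] == 0
        assert modes["gained_in_neighborhood"] == 0

    def test_stop_calls_confirmed_by_retranslation(self, pipeline_result):
        """Translation oracle: every neighborhood stop_gained call puts a '*'
        at the claimed codon of the fully edited CDS."""
        for tr in pipeline_result.transcript_results:
            prot, _ = covep.translate(tr.applied.alt_cds)
            for eff in tr.effects:
                if eff.combined_effect == "stop_gained" and eff.frame_offset_at_variant == 0:
                    k_alt = eff.cds_pos_shifted // 3
                    assert prot[k_alt] == "*"


class TestAaRatio:
    @pytest.mark.parametrize("n,s,expected", [(0, 0, 1.0), (99, 0, 10.0), (3, 1, 2.0)])
    def test_examples(self, n, s, expected):
        assert aa_ratio(n, s) == expected

    @given(n=st.integers(0, 100), s=st.integers(0, 100))
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_capped(self, n, s):
        r = aa_ratio(n, s)
        assert 0 < r <= 10.0
        assert aa_ratio(n + 1, s) >= r
        assert aa_ratio(n, s + 1) <= r


def permutation_pvalue(a, b, n_perm, rng):
    """Permutation oracle for the two-sided rank-sum test."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    obs = ranks[: len(a)].sum()
    mu = len(a) * (len(pooled) + 1) / 2
    count = 0
    for _ in range(n_perm):
        rng.shuffle(ranks)
        if abs(ranks[: len(a)].sum() - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return (count + 1) / (n_perm + 1)


class TestGroupTest:
    def test_identical_groups_p_one(self):
        _, p = group_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.99

    def test_complete_separation_u_zero(self):
        u, _ = group_test([1, 2, 3], [4, 5, 6])
        assert u == 0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_test([], [1.0])

    def test_shifted_lognormals_significant(self):
        rng = np.random.default_rng(123)
        a = rng.lognormal(0.0, 1.0, size=200)
        b = rng.lognormal(0.5, 1.0, size=200)
        _, p = group_test(a, b)
        assert p < 0.01

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(77)
        a = rng.lognormal(0.0, 1.0, size=40)
        b = rng.lognormal(0.4, 1.0, size=40)
        _, p = group_test(a, b)
        p_perm = permutation_pvalue(a, b, 2000, rng)
        # Monte-Carlo error of the oracle at 2000 permutations
        assert abs(p - p_perm) < 4 * np.sqrt(p_perm * (1 - p_perm) / 2000) + 1e-3


class TestExpression:
    def test_clipping_at_50(self):
        tbl = pd.DataFrame({"gene_id": ["g1", "g2"], "s1": [120, 10], "s2": [120, 10]})
        out = expression_compare(tbl, {"g1"}, {"g1", "g2"})
        assert out["stop_values"][0] == 50.0

    def test_low_expression_of_stop_genes_detected(self, fixture_paths):
        fix = fixture_paths["fixture"]
        rng = np.random.default_rng(5)
        tbl = covep.simulate_expression(fix, rng).reset_index()
        stop = set(fix.stop_case_genes)
        allg = {tx.gene_id for tx in fix.transcripts}
        out = expression_compare(tbl, stop, allg)
        assert out["median_expression_stop"] < out["median_expression_other"]
        assert out["p_value"] < 0.05

    def test_empty_stop_set_errors(self):
        tbl = pd.DataFrame({"gene_id": ["g1"], "s1": [1]})
        with pytest.raises(ValueError):
            expression_compare(tbl, set(), {"g1"})

    def test_missing_genes_excluded(self):
        tbl = pd.DataFrame({"gene_id": ["g1", "g2"], "s1": [5, 9]})
        out = expression_compare(tbl, {"g1"}, {"g1", "g2", "ghost"})
        assert out["n_other_genes"] == 1


class TestPseudogenizationPower:
    def test_elevated_ratio_in_stop_genes_recovered(self, tmp_path):
        """Stop-carrying genes receive amino-acid-changing SNVs at 3x the
        background rate; the aa_N/aa_S comparison finds the difference."""
        spec = covep.FixtureSpec(
            seed=33,
            case_counts={"single_snv_stop": 25, "single_snv_missense": 25,
                         "single_snv_syn": 25},
            background_syn_rate=2.0, background_mis_rate=2.0,
            stop_gene_mis_factor=3.0,
        )
        fix = covep.generate(spec)
        paths = covep.write_fixture(fix, tmp_path)
        genomes = covep.read_fasta(paths["fasta"])
        genes = covep.parse_gff3(paths["gff3"])
        pre = covep.preprocess_vcf(paths["vcf"])
        res = covep.run_pipeline(genomes, genes, pre.variants)
        tallies = gene_tallies(res.effect_table)
        comp = covep.ratio_compare(tallies, "neighborhood")
        assert comp["median_ratio_stop"] > comp["median_ratio_other"]
        assert comp["p_value"] < 0.01
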
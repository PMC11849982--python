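"""Edited-CDS construction, translation, and effect classification."""

import itertools

import numpy as np
import pytest

import covep
from covep.engine import _CODON_TABLE, CdsVariant, apply_variants
from covep.preprocess import CATEGORY_DEL, CATEGORY_INS, CATEGORY_SUB, NormalizedVariant


def nv(pos, ref, alt, phase="both", line=1, vid="v"):
    cat = (CATEGORY_SUB if len(ref) == len(alt)
           else CATEGORY_INS if len(alt) > len(ref) else CATEGORY_DEL)
    return NormalizedVariant("c", pos, ref, alt, cat, phase, line, variant_id=vid)


def cv(pos, ref, alt, vid="v"):
    cat = (CATEGORY_SUB if len(ref) == len(alt)
           else CATEGORY_INS if len(alt) > len(ref) else CATEGORY_DEL)
    return CdsVariant(nv(pos, ref or "N", alt or "N", vid=vid), pos, ref, alt, cat)


def naive_edit(ref, edits):
    """Independent oracle: apply (pos, ref, alt) edits right-to-left."""
    for pos, r, a in sorted(edits, reverse=True):
        ref = ref[:pos] + a + ref[pos + len(r):]
    return ref


class TestApplyVariants:
    def test_two_snvs(self):
        applied = apply_variants(
            "ATGCAATAG", [cv(3, "C", "T", "a"), cv(5, "A", "C", "b")]
        )
        assert applied.alt_cds == "ATGTACTAG"
        assert applied.net_length_change == 0

    def test_no_variants_identity(self):
        applied = apply_variants("ATGCAATAG", [])
        assert applied.alt_cds == "ATGCAATAG" and applied.net_length_change == 0

    def test_insertion_plus_deletion_length(self):
        applied = apply_variants(
            "ATGAAATAG", [cv(3, "", "GG", "i"), cv(5, "A", "", "d")]
        )
        assert len(applied.alt_cds) == 9 + 2 - 1
        assert applied.alt_cds == naive_edit("ATGAAATAG", [(3, "", "GG"), (5, "A", "")])

    def test_matches_naive_oracle_on_random_edits(self):
        rng = np.random.default_rng(11)
        bases = list("ACGT")
        for _ in range(200):
            n = int(rng.integers(12, 40))
            ref = "".join(rng.choice(bases, size=n))
            edits, taken = [], set()
            for _ in range(rng.integers(1, 5)):
                pos = int(rng.integers(1, n - 4))
                if any(abs(pos - t) < 4 for t in taken):
                    continue
                taken.add(pos)
                kind = rng.integers(0, 3)
                if kind == 0:
                    r = ref[pos]
                    a = bases[(bases.index(r) + 1) % 4]
                elif kind == 1:
                    r = ""
                    a = "".join(rng.choice(bases, size=rng.integers(1, 4)))
                else:
                    r = ref[pos: pos + int(rng.integers(1, 3))]
                    a = ""
                edits.append((pos, r, a))
            applied = apply_variants(
                ref, [cv(p, r, a, f"v{i}") for i, (p, r, a) in enumerate(edits)]
            )
            assert applied.alt_cds == naive_edit(ref, edits)
            assert applied.shift_map == sorted(applied.shift_map)  # non-decreasing
            assert len(applied.alt_cds) == len(ref) + applied.net_length_change

    def test_reference_mismatch_dropped(self, caplog):
        applied = apply_variants("ATGCAATAG", [cv(3, "G", "T", "bad")])
        assert applied.alt_cds == "ATGCAATAG" and applied.variants == []

    def test_deleted_positions_map_to_deletion_point(self):
        applied = apply_variants("ATGAAATAG", [cv(3, "AA", "", "d")])
        assert applied.shift_map[3] == 3 and applied.shift_map[4] == 3
        assert applied.shift_map[5] == 3  # first surviving base after deletion


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,prot,incomplete",
        [
            ("ATGTACTAA", "MY*", False),
            ("TAYACG", "XT", False),
            ("ATGAA", "M", True),
            ("", "", False),
        ],
    )
    def test_examples(self, seq, prot, incomplete):
        assert covep.translate(seq) == (prot, incomplete)


class TestClassifyIsolated:
    def test_stop_gained(self):
        eff = covep.classify_isolated(cv(3, "C", "T"), "ATGCAATAG")
        assert eff.isolated_effect == "stop_gained"
        assert eff.ref_codons == "CAA" and eff.alt_codon_isolated == "TAA"

    def test_missense(self):
        eff = covep.classify_isolated(cv(5, "A", "C"), "ATGCAATAG")
        assert eff.isolated_effect == "missense_variant"
        assert eff.aa_ref == "Q" and eff.aa_alt_isolated == "H"

    def test_two_nt_insertion_is_frameshift(self):
        eff = covep.classify_isolated(cv(4, "", "GG"), "ATGCAATAG")
        assert eff.isolated_effect == "frameshift_variant"

    @pytest.mark.parametrize(
        "variant,expected",
        [
            (cv(3, "", "GCT"), "inframe_insertion"),
            (cv(3, "CAA", ""), "inframe_deletion"),
            (cv(4, "A", ""), "frameshift_variant"),
            (cv(1, "T", "A"), "start_lost"),
            (cv(6, "T", "C"), "stop_lost"),
            (cv(8, "G", "A"), "stop_retained_variant"),
        ],
    )
    def test_other_terms(self, variant, expected):
        assert covep.classify_isolated(variant, "ATGCAATAG").isolated_effect == expected

    def test_synonymous(self):
        # GCT -> GCC, both Ala
        eff = covep.classify_isolated(cv(5, "T", "C"), "ATGGCTTAG")
        assert eff.isolated_effect == "synonymous_variant"


class TestClassifyNeighborhood:
    def test_stop_rescued_to_tyrosine(self):
        """CAA with C->T (stop) and A->C: the combined codon TAC encodes Tyr,
        so both variants are combined missense."""
        applied = apply_variants(
            "ATGCAATAG", [cv(3, "C", "T", "a"), cv(5, "A", "C", "b")]
        )
        effs = [covep.classify_neighborhood(x, applied) for x in applied.variants]
        assert [e.isolated_effect for e in effs] == ["stop_gained", "missense_variant"]
        assert all(e.combined_effect == "missense_variant" for e in effs)
        assert all(e.alt_codon_combined == "TAC" for e in effs)
        assert all(e.aa_alt_combined == "Y" for e in effs)
        assert effs[0].cofactor_variant_ids == ["b"]
        assert effs[1].cofactor_variant_ids == ["a"]

    def test_two_missense_jointly_create_stop(self):
        """CAC: C->T alone is Tyr, C->A alone is Gln; together TAA (stop)."""
        applied = apply_variants(
            "ATGCACTAG", [cv(3, "C", "T", "a"), cv(5, "C", "A", "b")]
        )
        effs = [covep.classify_neighborhood(x, applied) for x in applied.variants]
        assert [e.isolated_effect for e in effs] == ["missense_variant"] * 2
        assert all(e.combined_effect == "stop_gained" for e in effs)

    def test_single_variant_combined_equals_isolated(self):
        applied = apply_variants("ATGCAATAG", [cv(5, "A", "C", "a")])
        (eff,) = [covep.classify_neighborhood(x, applied) for x in applied.variants]
        assert eff.combined_effect == eff.isolated_effect
        assert eff.cofactor_variant_ids == []
        assert eff.frame_offset_at_variant == 0

    def test_snv_after_uncompensated_frameshift(self):
        applied = apply_variants(
            "ATGAAACAATAG", [cv(4, "", "G", "fs"), cv(7, "A", "C", "snv")]
        )
        eff = {e.variant_id: e for x in applied.variants
               for e in [covep.classify_neighborhood(x, applied)]}
        assert eff["snv"].isolated_effect == "missense_variant"
        assert eff["snv"].combined_effect == "frameshift_variant"
        assert eff["snv"].frame_offset_at_variant == 1
        assert "fs" in eff["snv"].cofactor_variant_ids

    def test_snv_after_compensated_pair_keeps_codon_call(self):
        # +1 then +2 upstream: net 0 by the time the SNV's codon is read
        applied = apply_variants(
            "ATGAAAGGGCAATAG",
            [cv(3, "", "T", "i1"), cv(6, "", "CC", "i2"), cv(10, "A", "C", "snv")],
        )
        eff = {e.variant_id: e for x in applied.variants
               for e in [covep.classify_neighborhood(x, applied)]}
        assert eff["snv"].frame_offset_at_variant == 0
        assert eff["snv"].combined_effect == "missense_variant"

    def test_all_two_snv_codon_combinations_match_code(self):
        """Enumeration oracle: for every reference codon and every pair of
        SNVs at two positions of that codon, the combined call equals what
        the genetic code says about the double-mutant codon."""
        bases = "ACGT"
        codons = ["".join(c) for c in itertools.product(bases, repeat=3)]
        checked = 0
        for codon in codons:
            if codon in ("TAA", "TAG", "TGA", "ATG"):
                continue  # stop/start contexts classify differently by design
            ref = "ATG" + codon + "TAG"
            for p1, p2 in itertools.combinations(range(3), 2):
                for b1, b2 in itertools.product(bases, repeat=2):
                    if b1 == codon[p1] or b2 == codon[p2]:
                        continue
                    applied = apply_variants(
                        ref, [cv(3 + p1, codon[p1], b1, "a"),
                              cv(3 + p2, codon[p2], b2, "b")]
                    )
                    double = applied.alt_cds[3:6]
                    expect_stop = _CODON_TABLE[double] == "*"
                    for x in applied.variants:
                        eff = covep.classify_neighborhood(x, applied)
                        if expect_stop:
                            assert eff.combined_effect == "stop_gained"
                        else:
                            assert eff.combined_effect != "stop_gained"
                    checked += 1
        assert checked > 1000

    def test_stop_lost_reports_extension(self):
        applied = apply_variants("ATGAAATAGCCCTAA", [cv(6, "T", "C", "a")])
        (eff,) = [covep.classify_neighborhood(x, applied) for x in applied.variants]
        assert eff.combined_effect == "stop_lost"
        assert eff.stop_lost_extension == 2  # CCC then TAA

    def test_stop_lost_without_downstream_stop_flagged(self):
        applied = apply_variants("ATGAAATAGCCC", [cv(6, "T", "C", "a")])
        (eff,) = [covep.classify_neighborhood(x, applied) for x in applied.variants]
        assert eff.no_stop_found is True


class TestConsistencyInvariant:
    def test_untouched_codons_translate_identically(self, pipeline_result):
        """Codons untouched by any variant and with zero upstream frame change
        translate identically in reference and edited CDS."""
        for tr in pipeline_result.transcript_results:
            applied = tr.applied
            if not applied.variants:
                continue
            ref_prot, _ = covep.translate(applied.ref_cds)
            alt_prot, _ = covep.translate(applied.alt_cds)
            touched = set()
            for v in applied.variants:
                k0 = v.cds_pos // 3
                k1 = (v.cds_pos + max(len(v.ref_cds), 1)) // 3 + 1
                touched.update(range(k0, k1 + 1))
            for k in range(len(ref_prot)):
                if k in touched:
                    continue
                if applied.upstream_offset(3 * k) != 0:
                    continue
                shifted = applied.shift_map[3 * k]
                if shifted % 3 != 0:
                    continue
                assert alt_prot[shifted // 3] == ref_prot[k]
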
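"""De novo detection, recessive/dominant/X-linked candidate generation,
compound-heterozygote phasing, and Mendelian consistency."""

import pytest

from raredx.core import (
    Annotation,
    CnvSpan,
    Consequence,
    Dosage,
    Family,
    FilterConfig,
    GenotypeCall,
    Origin,
    Sex,
    VariantClass,
    VariantRecord,
    variant_key,
)
from raredx.inheritance import (
    CandidateModel,
    candidates_dominant,
    candidates_recessive,
    candidates_x_linked,
    detect_de_novo,
    is_mendelian_consistent,
    run_stepwise,
)

CFG = FilterConfig()
TRIO = Family("f1", "P", mother_id="M", father_id="F", proband_sex=Sex.FEMALE)
SOLO = Family("f2", "P", proband_sex=Sex.FEMALE)


def _site(p, m=None, f=None, chrom="chr1", pos=100, depths=(40, 40, 40)):
    genotypes = {}
    for sid, gt, dp in (("P", p, depths[0]), ("M", m, depths[1]), ("F", f, depths[2])):
        if gt is None:
            continue
        alleles = None if gt == "./." else tuple(int(a) for a in gt.split("/")) if "/" in gt else (int(gt),)
        genotypes[sid] = GenotypeCall(sid, alleles, depth=dp)
    return VariantRecord(chrom, pos, "A", "G", VariantClass.SNV, genotypes=genotypes)


def _ann(gene="G1", consequence=Consequence.MISSENSE, genes_overlapped=()):
    return Annotation(gene=gene, transcript="NM_1", consequence=consequence,
                      genes_overlapped=genes_overlapped)


class TestDeNovo:
    @pytest.mark.parametrize(
        "p,m,f,expected",
        [
            ("0/1", "0/0", "0/0", Origin.DE_NOVO),
            ("0/1", "0/1", "0/0", Origin.MATERNAL),
            ("0/1", "0/0", "0/1", Origin.PATERNAL),
            ("1/1", "0/1", "0/1", Origin.BIPARENTAL),
            ("0/1", "./.", "0/0", Origin.UNKNOWN),  # missing parent: never de novo
        ],
    )
    def test_trio_origins(self, p, m, f, expected):
        assert detect_de_novo(_site(p, m, f), TRIO, CFG) is expected

    def test_low_parental_depth_blocks_de_novo(self):
        v = _site("0/1", "0/0", "0/0", depths=(40, 2, 40))
        assert detect_de_novo(v, TRIO, CFG) is Origin.UNKNOWN

    def test_duo_never_asserts_de_novo(self):
        duo = Family("f3", "P", mother_id="M", proband_sex=Sex.FEMALE)
        assert detect_de_novo(_site("0/1", m="0/0"), duo, CFG) is Origin.UNKNOWN
        assert detect_de_novo(_site("0/1", m="0/1"), duo, CFG) is Origin.MATERNAL


class TestRecessive:
    def test_trans_hets_pair_and_cis_do_not(self):
        trans_a = _site("0/1", "0/1", "0/0", pos=100)
        trans_b = _site("0/1", "0/0", "0/1", pos=200)
        cis_c = _site("0/1", "0/1", "0/0", pos=300)
        table = [(trans_a, _ann()), (trans_b, _ann()), (cis_c, _ann())]
        cands, _ = candidates_recessive(TRIO, table, CFG)
        pairs = [c for c in cands if c.model is CandidateModel.AR_COMPHET]
        got = {frozenset((c.key, c.partner_key)) for c in pairs}
        # only the maternal x paternal combinations pair; a-c share origin (cis)
        assert frozenset((variant_key(trans_a), variant_key(trans_b))) in got
        assert frozenset((variant_key(trans_a), variant_key(cis_c))) not in got
        for c in pairs:
            assert c.partner_key != c.key  # never paired with itself
            assert any(o.key == c.partner_key and o.partner_key == c.key for o in pairs)

    def test_hom_alt_is_ar_hom_with_biparental_origin(self):
        v = _site("1/1", "0/1", "0/1")
        cands, _ = candidates_recessive(TRIO, [(v, _ann())], CFG)
        assert [c.model for c in cands] == [CandidateModel.AR_HOM]
        assert cands[0].origin is Origin.BIPARENTAL

    def test_mendelian_error_hom_is_excluded_and_counted(self):
        v = _site("1/1", "0/0", "0/1")  # hom-alt child, confident hom-ref mother
        cands, errors = candidates_recessive(TRIO, [(v, _ann())], CFG)
        assert not cands and errors == 1

    def test_snv_with_deletion_cnv_forms_comphet(self):
        """Paternal point variant plus maternal deletion spanning the gene:
        the proband is effectively hemizygous."""
        snv = _site("0/1", "0/0", "0/1", chrom="chr10", pos=500)
        cnv = VariantRecord(
            "chr10", 400, "N", "<DEL>", VariantClass.CNV,
            cnv_span=CnvSpan(400, 9000, Dosage.DEL),
            genotypes={
                "P": GenotypeCall("P", (0, 1)),
                "M": GenotypeCall("M", (0, 1)),
                "F": GenotypeCall("F", (0, 0)),
            },
        )
        table = [(snv, _ann("ERCC6")),
                 (cnv, _ann("ERCC6", Consequence.CNV_LOSS, genes_overlapped=("ERCC6",)))]
        cands, _ = candidates_recessive(TRIO, table, CFG)
        comphet = [c for c in cands if c.model is CandidateModel.AR_COMPHET]
        assert len(comphet) == 2
        assert {c.origin for c in comphet} == {Origin.MATERNAL, Origin.PATERNAL}
        assert any("hemizygous_by_deletion" in c.flags for c in comphet)

    def test_solo_het_pair_is_unphased_unknown(self):
        a, b = _site("0/1", pos=1), _site("0/1", pos=2)
        cands, _ = candidates_recessive(SOLO, [(a, _ann()), (b, _ann())], CFG)
        assert all(c.origin is Origin.UNKNOWN and "unphased" in c.flags for c in cands)


class TestDominantAndX:
    def test_de_novo_het_is_ad_candidate(self):
        cands = candidates_dominant(TRIO, [(_site("0/1", "0/0", "0/0"), _ann())], CFG)
        assert cands[0].model is CandidateModel.AD
        assert cands[0].origin is Origin.DE_NOVO

    def test_inherited_from_unaffected_parent_flagged_not_dropped(self):
        cands = candidates_dominant(TRIO, [(_site("0/1", "0/0", "0/1"), _ann())], CFG)
        assert cands and "inherited-from-unaffected" in cands[0].flags

    def test_hom_alt_is_not_a_dominant_candidate(self):
        assert not candidates_dominant(TRIO, [(_site("1/1", "0/1", "0/1"), _ann())], CFG)

    def test_male_hemizygous_maternal_is_xlr(self):
        boy = Family("f4", "P", mother_id="M", father_id="F", proband_sex=Sex.MALE)
        v = _site("1", "0/1", "0", chrom="chrX")
        cands = candidates_x_linked(boy, [(v, _ann())], CFG)
        assert cands[0].model is CandidateModel.XLR
        assert cands[0].origin is Origin.MATERNAL

    def test_male_hemizygous_absent_in_mother_is_de_novo_xlr(self):
        boy = Family("f4", "P", mother_id="M", father_id="F", proband_sex=Sex.MALE)
        v = _site("1", "0/0", "0", chrom="chrX")
        cands = candidates_x_linked(boy, [(v, _ann())], CFG)
        assert cands[0].model is CandidateModel.XLR
        assert cands[0].origin is Origin.DE_NOVO

    def test_female_het_de_novo_is_xld(self):
        v = _site("0/1", "0/0", "0/0", chrom="chrX")
        cands = candidates_x_linked(TRIO, [(v, _ann())], CFG)
        assert cands[0].model is CandidateModel.XLD
        assert cands[0].origin is Origin.DE_NOVO

    def test_unknown_sex_is_an_error(self):
        nosex = Family("f5", "P", mother_id="M", father_id="F")
        with pytest.raises(ValueError, match="sex"):
            candidates_x_linked(nosex, [(_site("0/1", "0/0", "0/0", chrom="chrX"), _ann())], CFG)


class TestStepwise:
    def test_recessive_candidates_listed_before_dominant(self):
        hom = _site("1/1", "0/1", "0/1", pos=10)
        dn = _site("0/1", "0/0", "0/0", pos=20)
        surviving = {
            "recessive": [(hom, _ann("G1"))],
            "dominant": [(dn, _ann("G2"))],
            "x": [],
        }
        ordered, _ = run_stepwise(TRIO, surviving, CFG)
        assert [c.model for c in ordered] == [CandidateModel.AR_HOM, CandidateModel.AD]

    def test_duplicate_across_models_resolved_to_first_with_note(self):
        hom = _site("1/1", "0/1", "0/1", pos=10)
        surviving = {"recessive": [(hom, _ann())], "dominant": [(hom, _ann())], "x": []}
        ordered, _ = run_stepwise(TRIO, surviving, CFG)
        assert len(ordered) == 1 and ordered[0].model is CandidateModel.AR_HOM

    def test_solo_candidates_never_de_novo(self):
        surviving = {"recessive": [], "dominant": [(_site("0/1"), _ann())], "x": []}
        ordered, _ = run_stepwise(SOLO, surviving, CFG)
        assert all(c.origin is not Origin.DE_NOVO for c in ordered)


class TestSimulatedTrios:
    def test_candidates_obey_mendelian_consistency_unless_de_novo(self, small_sim, small_run):
        cfg, sim = small_sim
        fams = {f.family_id: f for f in small_run.families}
        for pid, cands in small_run.candidates.items():
            fam = next(f for f in small_run.families if f.proband_id == pid)
            for c in cands:
                if c.origin is Origin.DE_NOVO or c.variant.variant_class is VariantClass.CNV:
                    continue
                assert is_mendelian_consistent(c.variant, fam), (pid, c.key)

    def test_planted_variants_recovered_in_candidate_lists(self, small_sim, small_run):
        _, sim = small_sim
        for truth in sim.truth:
            for key in truth.planted_keys:
                assert key in small_run.candidate_keys[truth.proband_id]
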
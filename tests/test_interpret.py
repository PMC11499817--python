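"""Consensus-class aggregation and clinical categorization rules."""

import itertools

import pytest

from raredx.core import (
    AcmgClass,
    Annotation,
    Consequence,
    GenotypeCall,
    Origin,
    Sex,
    Strategy,
    VariantClass,
    VariantRecord,
)
from raredx.inheritance import CandidateModel, CandidateVariant
from raredx.interpret import (
    AssessedCandidate,
    Category,
    ConsensusSource,
    classify_result,
    consensus_class,
)
from raredx.io import GeneDiseaseEntry, parse_inheritance

P, LP, VUS, LB = AcmgClass.P, AcmgClass.LP, AcmgClass.VUS, AcmgClass.LB


class TestConsensus:
    def test_clinvar_wins_over_resources(self):
        c = consensus_class(P, (VUS, VUS, LB))
        assert c.final is P and c.source is ConsensusSource.CLINVAR

    def test_modal_resource_class_without_clinvar(self):
        c = consensus_class(None, (LP, LP, VUS))
        assert c.final is LP and c.source is ConsensusSource.MAJORITY

    def test_tie_resolves_to_vus(self):
        c = consensus_class(None, (P, LP, VUS))
        assert c.final is VUS and c.source is ConsensusSource.TIE_RULE

    def test_no_classification_is_an_error(self):
        with pytest.raises(ValueError, match="unclassifiable"):
            consensus_class(None, ())


def _assessed(gene, acmg, zygosity="Het", mode="AD", origin=Origin.DE_NOVO,
              consistent=True, chrom="chr1", pos=100):
    alleles = {"Het": (0, 1), "Hom": (1, 1), "Hem": (1,)}[zygosity]
    v = VariantRecord(chrom, pos, "A", "G", VariantClass.SNV,
                      genotypes={"P": GenotypeCall("P", alleles, 50)})
    cand = CandidateVariant(
        variant=v,
        annotation=Annotation(gene=gene, transcript="NM_1", consequence=Consequence.MISSENSE),
        model=CandidateModel.AD,
        origin=origin,
    )
    entry = GeneDiseaseEntry(gene=gene, omim_id="1", label=gene,
                             inheritance=parse_inheritance(mode), hpo_terms=frozenset())
    return AssessedCandidate(candidate=cand, consensus=consensus_class(acmg, ()),
                             consistent=consistent, matched_entry=entry)


def _classify(assessed, sex=Sex.FEMALE):
    return classify_result("P", Strategy.TRIO, assessed, sex=sex)


class TestCategorization:
    def test_de_novo_lp_in_dominant_gene_is_solved(self):
        rec = _classify([_assessed("TCF4", LP)])
        assert rec.category is Category.SOLVED
        assert rec.solved_mode_group == "AD"

    def test_hom_pathogenic_in_recessive_gene_is_solved(self):
        rec = _classify([_assessed("ABAT", P, zygosity="Hom", mode="AR")])
        assert rec.category is Category.SOLVED and rec.solved_mode_group == "AR"

    def test_single_het_vus_in_recessive_gene_is_partially_informative(self):
        rec = _classify([_assessed("ANK3", VUS, mode="AR")])
        assert rec.category is Category.PARTIALLY_INFORMATIVE

    def test_mixed_plp_vus_biallelic_recessive_is_suggestive_not_solved(self):
        rec = _classify([
            _assessed("TK2", P, mode="AR", origin=Origin.MATERNAL, pos=100),
            _assessed("TK2", VUS, mode="AR", origin=Origin.PATERNAL, pos=200),
        ])
        assert rec.category is Category.SUGGESTIVE

    def test_biallelic_plp_recessive_is_solved(self):
        rec = _classify([
            _assessed("ERCC6", P, mode="AR", origin=Origin.PATERNAL, pos=100),
            _assessed("ERCC6", P, mode="AR", origin=Origin.MATERNAL, pos=200),
        ])
        assert rec.category is Category.SOLVED and rec.solved_mode_group == "AR"

    def test_male_hemizygous_xlr_needs_one_allele(self):
        rec = classify_result(
            "P", Strategy.TRIO,
            [_assessed("KDM5C", LP, zygosity="Hem", mode="XLR", chrom="chrX")],
            sex=Sex.MALE,
        )
        assert rec.category is Category.SOLVED and rec.solved_mode_group == "XL"

    def test_benign_candidates_are_never_informative(self):
        rec = _classify([_assessed("G1", LB)])
        assert rec.category is Category.UNINFORMATIVE and not rec.informative

    def test_inconsistent_gene_is_not_informative(self):
        rec = _classify([_assessed("G1", P, consistent=False)])
        assert rec.category is Category.UNINFORMATIVE

    def test_dual_diagnosis_reports_both_genes_max_category(self):
        rec = _classify([
            _assessed("MNX1", VUS, pos=100),
            _assessed("DEL22", P, pos=200),
        ])
        assert rec.category is Category.SOLVED
        assert {v.gene for v in rec.gene_verdicts} == {"MNX1", "DEL22"}

    def test_category_is_total(self):
        for acmg in (P, LP, VUS, LB):
            for mode in ("AD", "AR", "XLD"):
                rec = _classify([_assessed("G", acmg, mode=mode)])
                assert rec.category in Category

    def test_class_upgrades_never_downgrade_category(self):
        """Monotonicity over every single-gene genotype layout: VUS -> LP -> P
        upgrades move the category only rightward."""
        order = [VUS, LP, P]
        layouts = [
            ("AR", ["Het"]), ("AR", ["Hom"]), ("AR", ["Het", "Het"]),
            ("AD", ["Het"]), ("XLD", ["Het"]),
        ]
        for mode, zygs in layouts:
            for classes in itertools.product(order, repeat=len(zygs)):
                for i, upgraded in enumerate(order):
                    for j in range(len(zygs)):
                        if order.index(classes[j]) > order.index(upgraded):
                            continue
                        base = [
                            _assessed("G", c, zygosity=z, mode=mode,
                                      origin=Origin.MATERNAL if k == 0 else Origin.PATERNAL,
                                      pos=100 + k)
                            for k, (c, z) in enumerate(zip(classes, zygs))
                        ]
                        up_classes = list(classes)
                        up_classes[j] = upgraded
                        upgraded_set = [
                            _assessed("G", c, zygosity=z, mode=mode,
                                      origin=Origin.MATERNAL if k == 0 else Origin.PATERNAL,
                                      pos=100 + k)
                            for k, (c, z) in enumerate(zip(up_classes, zygs))
                        ]
                        assert _classify(upgraded_set).category >= _classify(base).category


class TestFixtureCohort:
    def test_all_encoded_probands_informative(self):
        from raredx.fixtures import build_informative_results

        results, _ = build_informative_results()
        assert len(results) == 47
        assert all(r.informative for r in results)
        assert not any(r.category is Category.UNINFORMATIVE for r in results)
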
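"""Stepwise candidate generation under the recessive, dominant and X-linked
inheritance models, with de novo detection in trios.

The review order is the study's stepwise protocol: autosomal recessive
(homozygous, then compound heterozygous) first, then autosomal dominant,
then X-linked; de novo occurrences are flagged within each model. Duos and
solos degrade gracefully: phase and parental origin become unknown, and
de novo is never asserted without both parents.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .core import (
    Annotation,
    Dosage,
    Family,
    FilterConfig,
    Origin,
    Sex,
    Strategy,
    VariantClass,
    VariantRecord,
    variant_key,
)
from .filters import rank_candidates


class CandidateModel(str, enum.Enum):
    AR_HOM = "AR_hom"
    AR_COMPHET = "AR_comphet"
    AD = "AD"
    XLR = "XLR"
    XLD = "XLD"


@dataclass
class CandidateVariant:
    """A variant that survived filtering, labeled with its inheritance model
    and parental origin; comphet candidates come in mutually-linked pairs."""

    variant: VariantRecord
    annotation: Annotation
    model: CandidateModel
    origin: Origin
    partner_key: Optional[tuple] = None
    flags: list = field(default_factory=list)

    @property
    def key(self) -> tuple:
        return variant_key(self.variant)

    @property
    def gene(self) -> str:
        return self.annotation.gene


def _parent_calls(v: VariantRecord, family: Family):
    mother = v.genotype(family.mother_id) if family.mother_id else None
    father = v.genotype(family.father_id) if family.father_id else None
    return mother, father


def _depth_ok(call, cfg: FilterConfig) -> bool:
    return call is not None and call.depth is not None and call.depth >= cfg.de_novo_parent_min_depth


def detect_de_novo(v: VariantRecord, family: Family, cfg: FilterConfig) -> Origin:
    """Assign parental origin for the proband's alt allele(s) at this site.

    de_novo requires a trio, non-missing parental genotypes with depth at or
    above ``cfg.de_novo_parent_min_depth`` (dropout guard), and the alt
    allele absent from both parents. Otherwise the origin follows which
    parent(s) carry the allele: exactly one carrier parent gives that
    parent's origin; both parents carrying gives biparental when the proband
    is homozygous (or hemizygous) and unknown when heterozygous (phase
    ambiguous). A missing or unavailable parental genotype yields unknown,
    never de_novo.
    """
    proband = v.genotype(family.proband_id)
    if proband is None or not proband.carries_alt:
        return Origin.UNKNOWN
    mother, father = _parent_calls(v, family)

    if family.strategy is Strategy.TRIO:
        if mother is None or mother.is_missing or father is None or father.is_missing:
            return Origin.UNKNOWN
        m_carries = mother.carries_alt
        f_carries = father.carries_alt
        if not m_carries and not f_carries:
            if v.variant_class is VariantClass.CNV or (
                _depth_ok(mother, cfg) and _depth_ok(father, cfg)
            ):
                return Origin.DE_NOVO
            return Origin.UNKNOWN
        if m_carries and f_carries:
            if proband.is_hom_alt or proband.is_hemi_alt:
                return Origin.BIPARENTAL
            return Origin.UNKNOWN
        return Origin.MATERNAL if m_carries else Origin.PATERNAL

    if family.strategy is Strategy.DUO:
        parent = mother if mother is not None else father
        which = Origin.MATERNAL if mother is not None else Origin.PATERNAL
        if parent is None or parent.is_missing:
            return Origin.UNKNOWN
        if parent.carries_alt:
            return which
        return Origin.UNKNOWN  # absent in available parent; never de novo

    return Origin.UNKNOWN


def is_mendelian_consistent(v: VariantRecord, family: Family) -> bool:
    """True when the proband's diploid genotype can be produced by the
    observed parental genotypes (ignoring de novo mutation). Sites with any
    missing genotype, hemizygous calls, or non-trio families are vacuously
    consistent."""
    if family.strategy is not Strategy.TRIO:
        return True
    proband = v.genotype(family.proband_id)
    mother, father = _parent_calls(v, family)
    if any(c is None or c.is_missing for c in (proband, mother, father)):
        return True
    if len(proband.alleles) != 2:
        return True
    m_set = set(mother.alleles)
    f_set = set(father.alleles)
    a, b = proband.alleles
    return (a in m_set and b in f_set) or (b in m_set and a in f_set)


def _overlapping_deletions(gene: str, pairs):
    """Deletion CNVs among ``pairs`` whose gene span covers ``gene``."""
    out = []
    for v, ann in pairs:
        if (
            v.variant_class is VariantClass.CNV
            and v.cnv_span.dosage is Dosage.DEL
            and gene in ann.genes_overlapped
        ):
            out.append((v, ann))
    return out


def candidates_recessive(family: Family, pairs, cfg: FilterConfig):
    """Homozygous and compound-heterozygous candidates, grouped by gene.

    Trans phase for comphet pairs is established in trios (one maternal, one
    paternal allele); duo/solo same-gene het pairs are emitted unphased with
    origin unknown. A heterozygous SNV paired with a deletion CNV inherited
    from the other parent and overlapping the same gene forms a
    comphet-with-CNV pair (the proband is effectively hemizygous).
    Mendelian-error homozygotes (a hom-alt proband with a confidently
    hom-ref parent) are excluded and counted.
    """
    candidates = []
    mendelian_errors = 0
    snv_by_gene: dict = {}
    for v, ann in pairs:
        if v.variant_class is VariantClass.CNV:
            continue
        snv_by_gene.setdefault(ann.gene, []).append((v, ann))

    for gene, members in sorted(snv_by_gene.items()):
        hets = []
        for v, ann in members:
            gt = v.genotype(family.proband_id)
            if gt is None:
                continue
            if gt.is_hom_alt:
                origin = detect_de_novo(v, family, cfg)
                if family.strategy is Strategy.TRIO and not is_mendelian_consistent(v, family):
                    mother, father = _parent_calls(v, family)
                    if all(_depth_ok(c, cfg) for c in (mother, father)):
                        mendelian_errors += 1
                        continue
                candidates.append(
                    CandidateVariant(v, ann, CandidateModel.AR_HOM, origin)
                )
            elif gt.is_het:
                hets.append((v, ann, detect_de_novo(v, family, cfg)))

        # comphet: SNV x SNV
        emitted = set()
        for i in range(len(hets)):
            for j in range(i + 1, len(hets)):
                va, aa, oa = hets[i]
                vb, ab, ob = hets[j]
                ka, kb = variant_key(va), variant_key(vb)
                if family.strategy is Strategy.TRIO:
                    trans = {oa, ob} == {Origin.MATERNAL, Origin.PATERNAL}
                    if not trans:
                        continue
                    flags = []
                else:
                    flags = ["unphased"]
                    oa = ob = Origin.UNKNOWN
                pair_id = (ka, kb)
                if pair_id in emitted:
                    continue
                emitted.add(pair_id)
                candidates.append(
                    CandidateVariant(va, aa, CandidateModel.AR_COMPHET, oa,
                                     partner_key=kb, flags=list(flags))
                )
                candidates.append(
                    CandidateVariant(vb, ab, CandidateModel.AR_COMPHET, ob,
                                     partner_key=ka, flags=list(flags))
                )

        # comphet: SNV x deletion CNV (proband effectively hemizygous)
        for v, ann, origin in hets:
            for dv, dann in _overlapping_deletions(gene, pairs):
                d_origin = detect_de_novo(dv, family, cfg)
                if family.strategy is Strategy.TRIO:
                    trans = {origin, d_origin} == {Origin.MATERNAL, Origin.PATERNAL}
                    if not trans:
                        continue
                    flags = ["hemizygous_by_deletion"]
                else:
                    flags = ["hemizygous_by_deletion", "unphased"]
                candidates.append(
                    CandidateVariant(v, ann, CandidateModel.AR_COMPHET, origin,
                                     partner_key=variant_key(dv), flags=list(flags))
                )
                candidates.append(
                    CandidateVariant(dv, dann, CandidateModel.AR_COMPHET, d_origin,
                                     partner_key=variant_key(v), flags=list(flags))
                )
    return candidates, mendelian_errors


def candidates_dominant(family: Family, pairs, cfg: FilterConfig):
    """Heterozygous autosomal candidates under the dominant model.

    Homozygous-alt variants belong to the recessive model and are skipped.
    A variant inherited from an unaffected parent is retained but flagged
    for review rather than discarded (dominant conditions with reduced
    penetrance, or an affected parent not marked as such).
    """
    candidates = []
    for v, ann in pairs:
        gt = v.genotype(family.proband_id)
        is_het = (
            gt is not None
            and (gt.is_het or (v.variant_class is VariantClass.CNV and gt.carries_alt and not gt.is_hom_alt))
        )
        if not is_het:
            continue
        origin = detect_de_novo(v, family, cfg)
        flags = []
        if origin is Origin.MATERNAL and family.mother_id and not family.is_affected(family.mother_id):
            flags.append("inherited-from-unaffected")
        if origin is Origin.PATERNAL and family.father_id and not family.is_affected(family.father_id):
            flags.append("inherited-from-unaffected")
        candidates.append(CandidateVariant(v, ann, CandidateModel.AD, origin, flags=flags))
    return candidates


def candidates_x_linked(family: Family, pairs, cfg: FilterConfig):
    """X-chromosome candidates.

    Male probands: any alt call on X is treated as hemizygous -> XLR, with
    origin maternal when the mother carries the allele and de novo only when
    a trio confidently shows it absent in the mother. Female probands:
    heterozygous -> XLD, homozygous -> XLR.
    """
    if family.proband_sex is None:
        raise ValueError(f"proband sex unknown for family {family.family_id}")
    candidates = []
    for v, ann in pairs:
        gt = v.genotype(family.proband_id)
        if gt is None or not gt.carries_alt:
            continue
        origin = detect_de_novo(v, family, cfg)
        if family.proband_sex is Sex.MALE:
            model = CandidateModel.XLR
            flags = [] if gt.is_hemi_alt else ["called_diploid_on_male_X"]
        else:
            if gt.is_hom_alt:
                model = CandidateModel.XLR
                flags = []
            else:
                model = CandidateModel.XLD
                flags = []
        candidates.append(CandidateVariant(v, ann, model, origin, flags=flags))
    return candidates


def run_stepwise(family: Family, surviving: dict, cfg: FilterConfig):
    """Concatenate candidates in the stepwise review order AR -> AD -> XL.

    A variant eligible under two models is resolved to the first model in
    the order; the alternative model is recorded in its flags. Within each
    model, candidates are ranked by CADD descending (absent CADD last).

    Returns ``(candidates, mendelian_error_count)``.
    """
    ar, mendelian_errors = candidates_recessive(
        family, rank_candidates(surviving.get("recessive", [])), cfg
    )
    ad = candidates_dominant(family, rank_candidates(surviving.get("dominant", [])), cfg)
    xl = candidates_x_linked(family, rank_candidates(surviving.get("x", [])), cfg)

    ordered = []
    seen: dict = {}
    for cand in ar + ad + xl:
        prev = seen.get(cand.key)
        if prev is not None:
            prev.flags.append(f"also_eligible:{cand.model.value}")
            continue
        seen[cand.key] = cand
        ordered.append(cand)
    if family.strategy is not Strategy.TRIO:
        assert all(c.origin is not Origin.DE_NOVO for c in ordered)
    return ordered, mendelian_errors
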
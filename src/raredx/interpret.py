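"""Consensus variant interpretation and per-proband clinical categorization.

Consensus rule: the ClinVar class, when present, is taken verbatim;
otherwise the modal class among the independent interpretation resources is
used, with ties resolved conservatively to VUS.

Categories: a result is *informative* when a P/LP variant or VUS lies in a
gene consistent with the proband's phenotype. Informative results are
*solved* when some gene's inheritance-mode genotype requirement (two alleles
in trans for recessive conditions, one for dominant/XLD, the hemizygous
allele for XLR males) is met entirely by P/LP alleles; *partially
informative* when the best gene is a recessive condition with only one
informative allele found; *suggestive* otherwise (VUS-complete genotypes and
mixed P/LP + VUS recessive genotypes). LB/B calls are never informative.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .core import AcmgClass, InheritanceMode, Sex, Strategy, format_variant_key
from .inheritance import CandidateVariant
from .io import GeneDiseaseEntry


class ConsensusSource(str, enum.Enum):
    CLINVAR = "clinvar"
    MAJORITY = "majority"
    TIE_RULE = "tie_rule"


@dataclass(frozen=True)
class ConsensusClass:
    final: AcmgClass
    source: ConsensusSource
    inputs: tuple


def consensus_class(clinvar_class: Optional[AcmgClass], resource_classes) -> ConsensusClass:
    """Aggregate per-resource ACMG classes into one consensus call."""
    resource_classes = tuple(resource_classes)
    if clinvar_class is not None:
        return ConsensusClass(clinvar_class, ConsensusSource.CLINVAR,
                              (clinvar_class,) + resource_classes)
    if not resource_classes:
        raise ValueError("unclassifiable: no ClinVar class and no resource classes")
    counts = Counter(resource_classes)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return ConsensusClass(AcmgClass.VUS, ConsensusSource.TIE_RULE, resource_classes)
    return ConsensusClass(top[0][0], ConsensusSource.MAJORITY, resource_classes)


class Category(enum.IntEnum):
    """Ordered so that class upgrades can only move a record rightward."""

    UNINFORMATIVE = 0
    PARTIALLY_INFORMATIVE = 1
    SUGGESTIVE = 2
    SOLVED = 3

    @property
    def label(self) -> str:
        return self.name.lower()


_INFORMATIVE_CLASSES = {AcmgClass.P, AcmgClass.LP, AcmgClass.VUS}
_PLP = {AcmgClass.P, AcmgClass.LP}

#: inheritance-mode grouping used for the solved-case split
MODE_GROUP = {
    InheritanceMode.AD: "AD",
    InheritanceMode.DD: "AD",
    InheritanceMode.AR: "AR",
    InheritanceMode.XLD: "XL",
    InheritanceMode.XLR: "XL",
    InheritanceMode.XL: "XL",
}


@dataclass
class AssessedCandidate:
    """A candidate joined with its consensus class and phenotype match."""

    candidate: CandidateVariant
    consensus: ConsensusClass
    consistent: bool
    matched_entry: Optional[GeneDiseaseEntry] = None
    reason: str = ""

    @property
    def informative(self) -> bool:
        return self.consistent and self.consensus.final in _INFORMATIVE_CLASSES

    @property
    def group_gene(self) -> str:
        if self.matched_entry is not None:
            return self.matched_entry.gene
        return self.candidate.gene


@dataclass
class GeneVerdict:
    gene: str
    mode: InheritanceMode
    category: Category
    n_plp_alleles: int
    n_vus_alleles: int


@dataclass
class ResultRecord:
    proband_id: str
    strategy: Strategy
    candidates: list  # informative AssessedCandidates
    category: Category
    gene_verdicts: list = field(default_factory=list)
    solved_mode_group: Optional[str] = None  # "AD" | "AR" | "XL" when solved

    @property
    def informative(self) -> bool:
        return self.category is not Category.UNINFORMATIVE

    def to_dict(self) -> dict:
        def zygosity(c):
            gt = c.variant.genotype(self.proband_id)
            if gt is None:
                return ""
            if gt.is_hemi_alt:
                return "Hem"
            if gt.is_hom_alt:
                return "Hom"
            return "Het"

        return {
            "proband_id": self.proband_id,
            "strategy": self.strategy.value,
            "category": self.category.label,
            "informative": self.informative,
            "solved_mode_group": self.solved_mode_group,
            "candidates": [
                {
                    "gene": a.candidate.gene,
                    "variant": format_variant_key(a.candidate.key),
                    "hgvs_c": a.candidate.annotation.hgvs_c,
                    "hgvs_p": a.candidate.annotation.hgvs_p,
                    "zygosity": zygosity(a.candidate),
                    "origin": a.candidate.origin.value,
                    "model": a.candidate.model.value,
                    "interpretation": a.consensus.final.value,
                    "interpretation_source": a.consensus.source.value,
                    "omim_phenotype": a.matched_entry.label if a.matched_entry else "",
                    "omim_inheritance": ";".join(
                        m.value for m in a.matched_entry.inheritance
                    ) if a.matched_entry else "",
                }
                for a in self.candidates
            ],
        }


def _allele_count(assessed: AssessedCandidate, proband_id: str) -> int:
    gt = assessed.candidate.variant.genotype(proband_id)
    if gt is not None and gt.is_hom_alt:
        return 2
    return 1


def _required_alleles(mode: InheritanceMode, sex: Optional[Sex]) -> int:
    if mode in (InheritanceMode.AD, InheritanceMode.DD, InheritanceMode.XLD):
        return 1
    if mode is InheritanceMode.XLR:
        return 1 if sex is Sex.MALE else 2
    if mode is InheritanceMode.XL:
        # generic X-linked label: one allele suffices for a male hemizygote
        # or a dominant presentation; treated like XLD here
        return 1
    return 2  # AR


def _verdict_for_mode(mode, plp, vus, sex) -> Category:
    required = _required_alleles(mode, sex)
    if plp >= required:
        return Category.SOLVED
    if plp + vus >= required:
        return Category.SUGGESTIVE
    if required == 2 and plp + vus == 1:
        return Category.PARTIALLY_INFORMATIVE
    return Category.UNINFORMATIVE


def classify_result(
    proband_id: str,
    strategy: Strategy,
    assessed,
    sex: Optional[Sex] = None,
) -> ResultRecord:
    """Categorize one proband from their assessed candidates.

    Candidates that are LB/B or phenotype-inconsistent are dropped first.
    Remaining candidates are grouped by matched gene; each gene is judged
    against the genotype requirement of its matched inheritance mode(s)
    (an entry with several modes is satisfied by the most favorable one),
    and the record's category is the maximum over genes, so dual-diagnosis
    probands report every contributing gene.
    """
    for a in assessed:
        if a.consistent is None:
            raise ValueError(f"candidate without consistency evaluation for {proband_id}")
    informative = [a for a in assessed if a.informative]
    by_gene: dict = {}
    for a in informative:
        by_gene.setdefault(a.group_gene, []).append(a)

    verdicts = []
    for gene, members in sorted(by_gene.items()):
        # alleles of the same variant key count once (hom already counts 2)
        seen = set()
        plp = vus = 0
        modes: set = set()
        for a in members:
            if a.candidate.key in seen:
                continue
            seen.add(a.candidate.key)
            n = _allele_count(a, proband_id)
            if a.consensus.final in _PLP:
                plp += n
            else:
                vus += n
            if a.matched_entry is not None:
                modes.update(a.matched_entry.inheritance)
        if not modes:
            modes = {InheritanceMode.AD}
        best_mode, best_cat = None, Category.UNINFORMATIVE
        for mode in sorted(modes, key=lambda m: m.value):
            cat = _verdict_for_mode(mode, plp, vus, sex)
            if cat > best_cat:
                best_mode, best_cat = mode, cat
        verdicts.append(GeneVerdict(gene, best_mode or sorted(modes, key=lambda m: m.value)[0],
                                    best_cat, plp, vus))

    if verdicts:
        category = max(v.category for v in verdicts)
    else:
        category = Category.UNINFORMATIVE
    if informative and category is Category.UNINFORMATIVE:
        # informative candidates exist but no gene met or half-met a
        # requirement (e.g. a lone VUS under a dominant mode cannot happen;
        # defensive fallback)
        category = Category.SUGGESTIVE

    solved_mode_group = None
    if category is Category.SOLVED:
        for v in verdicts:
            if v.category is Category.SOLVED:
                solved_mode_group = MODE_GROUP[v.mode]
                break

    return ResultRecord(
        proband_id=proband_id,
        strategy=strategy,
        candidates=informative,
        category=category,
        gene_verdicts=verdicts,
        solved_mode_group=solved_mode_group,
    )
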
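"""Loaders for the packaged cohort fixtures.

``informative_variants.tsv`` encodes the informative findings of the study
cohort (47 probands, 55 distinct variants) with zygosity, parental origin,
interpretation class and the matched disease entry; SNV positions in the
file are synthetic placeholders (the source prints HGVS notation only).
``strategy_analyses.tsv`` encodes the 113 per-analysis strategy/outcome rows
(synthetic proband ids, printed per-stratum counts).

The loader rebuilds first-class pipeline objects (variants, candidates,
consensus calls) so that tallies and categories are recomputed by the
classifier rather than read off the file.
"""

from __future__ import annotations

import csv
from importlib import resources

from .core import (
    AcmgClass,
    Annotation,
    CnvSpan,
    Consequence,
    Dosage,
    GenotypeCall,
    Origin,
    Sex,
    Strategy,
    VariantClass,
    VariantRecord,
    variant_key,
)
from .inheritance import CandidateModel, CandidateVariant
from .interpret import AssessedCandidate, classify_result, consensus_class
from .io import GeneDiseaseEntry, parse_inheritance

_ZYGOSITY = {"Het": (0, 1), "Hom": (1, 1), "Hem": (1,)}


def _fixture_path(name: str):
    return resources.files("raredx.data").joinpath(name)


def load_informative_variants():
    """Parse the informative-variant fixture into per-row dicts."""
    rows = []
    with _fixture_path("informative_variants.tsv").open() as fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        for row in reader:
            rows.append(row)
    return rows


def _variant_from_row(row, proband_id: str) -> VariantRecord:
    vclass = VariantClass[row["variant_class"]]
    call = GenotypeCall(
        sample_id=proband_id, alleles=_ZYGOSITY[row["zygosity"]], depth=50
    )
    if vclass is VariantClass.CNV:
        span = CnvSpan(
            start=int(row["cnv_start"]),
            end=int(row["cnv_end"]),
            dosage=Dosage[row["cnv_dosage"]],
        )
        return VariantRecord(
            chrom=row["chrom"],
            pos=span.start,
            ref="N",
            alt=f"<{span.dosage.value}>",
            variant_class=vclass,
            cnv_span=span,
            genotypes={proband_id: call},
        )
    return VariantRecord(
        chrom=row["chrom"],
        pos=int(row["pos"]),
        ref=row["ref"],
        alt=row["alt"],
        variant_class=vclass,
        genotypes={proband_id: call},
    )


def _infer_model(mode, zygosity, chrom, sex) -> CandidateModel:
    if chrom == "chrX":
        if sex is Sex.MALE or zygosity == "Hom":
            return CandidateModel.XLR
        return CandidateModel.XLD
    if mode.value.startswith("AR"):
        return CandidateModel.AR_HOM if zygosity == "Hom" else CandidateModel.AR_COMPHET
    if zygosity == "Hom":
        return CandidateModel.AR_HOM
    return CandidateModel.AD


def build_informative_results():
    """Reconstruct candidates per proband and re-run the classifier.

    Returns ``(results, assessed_by_proband)`` where results is a list of
    :class:`~raredx.interpret.ResultRecord`, one per encoded proband.
    """
    rows = load_informative_variants()
    by_patient: dict = {}
    for row in rows:
        by_patient.setdefault(row["patient_id"], []).append(row)

    results = []
    assessed_by_proband = {}
    for pid, patient_rows in by_patient.items():
        proband_id = f"P{pid}"
        sex = Sex.MALE if patient_rows[0]["sex"] == "male" else Sex.FEMALE
        assessed = []
        for row in patient_rows:
            variant = _variant_from_row(row, proband_id)
            interp = AcmgClass[row["interpretation"]]
            clinvar_id = row["clinvar_id"].strip() or None
            clinvar_class = interp if clinvar_id else None
            resource_classes = () if clinvar_id else (interp, interp)
            annotation = Annotation(
                gene=row["gene"],
                transcript=row["transcript"],
                consequence=Consequence(row["consequence"]),
                hgvs_c=row["hgvs_c"],
                hgvs_p=row["hgvs_p"],
                clinvar_id=clinvar_id,
                clinvar_class=clinvar_class,
                resource_classes=resource_classes,
                genes_overlapped=(row["gene"],)
                if row["variant_class"] == "CNV"
                else (),
            )
            entry = GeneDiseaseEntry(
                gene=row["gene"],
                omim_id=row["omim_id"],
                label=row["omim_phenotype"],
                inheritance=parse_inheritance(row["omim_inheritance"]),
                hpo_terms=frozenset(),
            )
            model = _infer_model(entry.inheritance[0], row["zygosity"], row["chrom"], sex)
            candidate = CandidateVariant(
                variant=variant,
                annotation=annotation,
                model=model,
                origin=Origin(row["origin"]),
            )
            assessed.append(
                AssessedCandidate(
                    candidate=candidate,
                    consensus=consensus_class(clinvar_class, resource_classes),
                    consistent=True,
                    matched_entry=entry,
                )
            )
        # mutual partner links for same-gene allele pairs
        by_gene: dict = {}
        for a in assessed:
            by_gene.setdefault(a.group_gene, []).append(a)
        for members in by_gene.values():
            if len(members) == 2:
                members[0].candidate.partner_key = members[1].candidate.key
                members[1].candidate.partner_key = members[0].candidate.key

        origins = {a.candidate.origin for a in assessed}
        if origins & {Origin.DE_NOVO, Origin.BIPARENTAL} or (
            {Origin.MATERNAL, Origin.PATERNAL} <= origins
        ) or Origin.PATERNAL in origins:
            strategy = Strategy.TRIO
        elif Origin.MATERNAL in origins:
            strategy = Strategy.DUO
        else:
            strategy = Strategy.SOLO
        results.append(classify_result(proband_id, strategy, assessed, sex=sex))
        assessed_by_proband[proband_id] = assessed
    return results, assessed_by_proband


def load_strategy_analyses():
    """Per-analysis (strategy, proband_id, informative) rows."""
    out = []
    with _fixture_path("strategy_analyses.tsv").open() as fh:
        reader = csv.DictReader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        for row in reader:
            out.append((row["strategy"], row["proband_id"], row["informative"] == "1"))
    return out
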
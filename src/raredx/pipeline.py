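"""End-to-end cohort analysis: filters -> inheritance models -> virtual
panels -> consensus interpretation -> per-proband categorization."""

from __future__ import annotations

import csv
import glob
import os
from dataclasses import dataclass, field

from .core import FilterConfig, Sex, variant_key
from .filters import apply_filters, build_cohort_index
from .inheritance import run_stepwise
from .interpret import AssessedCandidate, classify_result, consensus_class
from .io import (
    read_annotations,
    read_cnvs,
    read_gene_map,
    read_ontology,
    read_pedigree,
    read_phenotypes,
    read_vcf,
)
from .phenotypes import (
    ProbandPhenotype,
    count_affected_systems,
    phenotype_consistent,
)


def read_covariates(path: str) -> dict:
    """Per-proband demographic/clinical covariates TSV.

    Columns: proband_id, sex, age_years, care, provider_in_capital,
    congenital_anomalies, neurological, immune. Returns a dict of raw rows
    keyed by proband_id (terms are joined in separately).
    """
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["proband_id"]] = {
                "sex": Sex(row["sex"]) if row.get("sex") else None,
                "age_years": float(row["age_years"]) if row.get("age_years") else None,
                "care": row.get("care") or None,
                "provider_in_capital": row.get("provider_in_capital") == "1",
                "congenital_anomalies": row.get("congenital_anomalies") == "1",
                "neurological": row.get("neurological") == "1",
                "immune": row.get("immune") == "1",
            }
    return out


@dataclass
class CohortRunResult:
    results: dict = field(default_factory=dict)  # proband_id -> ResultRecord
    candidate_keys: dict = field(default_factory=dict)  # proband_id -> set of keys
    candidates: dict = field(default_factory=dict)  # proband_id -> [CandidateVariant]
    profiles: dict = field(default_factory=dict)  # proband_id -> SystemProfile
    phenotypes: dict = field(default_factory=dict)  # proband_id -> ProbandPhenotype
    families: list = field(default_factory=list)
    mendelian_errors: int = 0
    unannotated: int = 0
    unclassifiable: int = 0


def _family_vcfs(vcf_dir: str, families) -> dict:
    paths = {}
    for fam in families:
        path = os.path.join(vcf_dir, f"{fam.family_id}.vcf")
        if not os.path.exists(path):
            matches = glob.glob(os.path.join(vcf_dir, f"{fam.family_id}.*vcf*"))
            if not matches:
                raise FileNotFoundError(f"no VCF for family {fam.family_id} in {vcf_dir}")
            path = matches[0]
        paths[fam.family_id] = path
    return paths


def run_cohort(
    vcf_dir: str,
    ped_path: str,
    annotations_path: str,
    phenotypes_path: str,
    ontology_path: str,
    gene_map_path: str,
    cnv_path: str = None,
    covariates_path: str = None,
    cfg: FilterConfig = None,
) -> CohortRunResult:
    """Analyze a cohort of families from files on disk.

    One VCF per family (named ``<family_id>.vcf``) plus shared annotation,
    CNV, phenotype, ontology and gene-map tables. Candidates that survive
    filtering but carry no interpretation class from any resource are
    counted as unclassifiable and can never be informative.
    """
    cfg = cfg or FilterConfig()
    families = read_pedigree(ped_path)
    table = read_annotations(annotations_path)
    ontology = read_ontology(ontology_path)
    gene_map = read_gene_map(gene_map_path)
    terms_by_proband = read_phenotypes(phenotypes_path)
    covariates = read_covariates(covariates_path) if covariates_path else {}

    vcf_paths = _family_vcfs(vcf_dir, families)
    variants_by_family = {}
    for fam in families:
        records, _ = read_vcf(vcf_paths[fam.family_id])
        variants_by_family[fam.family_id] = records

    if cnv_path:
        cnv_records, cnv_annotations = read_cnvs(cnv_path)
        table.entries.update(cnv_annotations)
        member_to_family = {}
        for fam in families:
            for m in fam.members:
                member_to_family[m] = fam.family_id
        for rec in cnv_records:
            fam_ids = {member_to_family[s] for s in rec.genotypes if s in member_to_family}
            for fid in fam_ids:
                variants_by_family[fid].append(rec)

    cohort_index, fam_by_proband = build_cohort_index(families, variants_by_family)

    out = CohortRunResult(families=families)
    for fam in families:
        pid = fam.proband_id
        cov = covariates.get(pid, {})
        phenotype = ProbandPhenotype(
            proband_id=pid,
            terms=frozenset(terms_by_proband.get(pid, ())),
            sex=cov.get("sex", fam.proband_sex) or fam.proband_sex,
            age_years=cov.get("age_years"),
            care=cov.get("care"),
            provider_in_capital=cov.get("provider_in_capital"),
            congenital_anomalies=cov.get("congenital_anomalies", False),
            neurological=cov.get("neurological", False),
            immune=cov.get("immune", False),
        )
        out.phenotypes[pid] = phenotype
        out.profiles[pid] = count_affected_systems(phenotype, ontology)

        surviving, traces, unannotated = apply_filters(
            fam, variants_by_family[fam.family_id], table, cfg,
            cohort_index=cohort_index, families_by_proband=fam_by_proband,
        )
        out.unannotated += len(unannotated)
        candidates, mend = run_stepwise(fam, surviving, cfg)
        out.mendelian_errors += mend
        out.candidates[pid] = candidates
        out.candidate_keys[pid] = {c.key for c in candidates}

        assessed = []
        for cand in candidates:
            ann = cand.annotation
            try:
                consensus = consensus_class(ann.clinvar_class, ann.resource_classes)
            except ValueError:
                out.unclassifiable += 1
                continue
            genes = ann.genes_overlapped or (ann.gene,)
            consistent, entry, reason = False, None, "gene not in map"
            for gene in genes:
                consistent, entry, reason = phenotype_consistent(
                    gene, phenotype, gene_map, ontology, cfg
                )
                if consistent:
                    break
            assessed.append(
                AssessedCandidate(
                    candidate=cand,
                    consensus=consensus,
                    consistent=consistent,
                    matched_entry=entry,
                    reason=reason,
                )
            )
        out.results[pid] = classify_result(
            pid, fam.strategy, assessed, sex=fam.proband_sex
        )
    return out
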
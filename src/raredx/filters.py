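"""Variant triage filters: technical, frequency (per inheritance model),
and cohort recurrence.

All filters are pure functions of their inputs and emit an audit trace.
Frequency comparisons use the *maximum* MAF across the configured sources
(exclusion if any database exceeds the bound) and treat an absent source as
frequency 0 / count 0, so variants never observed in the references survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    Annotation,
    CONSEQUENCE_SEVERITY,
    Consequence,
    Family,
    FilterConfig,
    VariantClass,
    VariantRecord,
    variant_key,
)

MODELS = ("recessive", "dominant", "x")


@dataclass
class FilterTrace:
    """Ordered record of every filter decision taken for one variant."""

    key: tuple
    steps: list = field(default_factory=list)  # (filter name, "pass"/"fail", value)
    final: dict = field(default_factory=dict)  # model -> "pass"/"fail"

    def add(self, name: str, passed: bool, value) -> None:
        self.steps.append((name, "pass" if passed else "fail", value))

    @property
    def failed_steps(self) -> list:
        return [s for s in self.steps if s[1] == "fail"]


def select_annotation(annotations) -> Annotation:
    """Pick one transcript annotation: most severe consequence, ties broken
    by transcript id ascending."""
    return min(
        annotations,
        key=lambda a: (CONSEQUENCE_SEVERITY[a.consequence], a.transcript),
    )


def technical_filter(v: VariantRecord, a: Annotation, cfg: FilterConfig, proband_id: str, trace: FilterTrace) -> bool:
    """Read-support and consequence-class screen.

    Fails when proband depth < ``cfg.min_depth`` (unknown depth fails,
    conservatively) or when the consequence is in the excluded set. CNV
    records have no read-depth semantics and bypass the depth rule only.
    """
    ok = True
    if v.variant_class is not VariantClass.CNV:
        gt = v.genotype(proband_id)
        depth = gt.depth if gt is not None else None
        if depth is None:
            trace.add("min_depth", False, "depth unknown")
            ok = False
        else:
            passed = depth >= cfg.min_depth
            trace.add("min_depth", passed, depth)
            ok = ok and passed
    cons_ok = a.consequence not in cfg.excluded_consequences
    trace.add("consequence", cons_ok, a.consequence.value)
    return ok and cons_ok


def recessive_frequency_filter(a: Annotation, cfg: FilterConfig, trace: FilterTrace) -> bool:
    """Recessive-model frequency screen.

    Fails when max MAF over all sources exceeds ``recessive_maf_max``
    (strictly), or when the ExAC homozygote + hemizygote count reaches
    ``recessive_homhemi_max + 1`` (>= 10 with defaults). The bound at exactly
    ``recessive_maf_max`` passes ("greater than" is strict).
    """
    maf = a.frequencies.max_maf()
    maf_ok = maf <= cfg.recessive_maf_max
    trace.add("recessive_maf", maf_ok, maf)
    homhemi = a.frequencies.hom_count("ExAC") + a.frequencies.hemi_count("ExAC")
    if cfg.apply_exac_homhemi:
        hh_ok = homhemi <= cfg.recessive_homhemi_max
        trace.add("exac_hom_hemi", hh_ok, homhemi)
    else:
        hh_ok = True
    return maf_ok and hh_ok


def dominant_frequency_filter(a: Annotation, cfg: FilterConfig, trace: FilterTrace) -> bool:
    """Dominant-model frequency screen.

    Fails when max MAF > ``dominant_maf_max``, or when the gnomAD or
    internal-cohort allele count exceeds ``dominant_allele_count_max``.
    """
    maf = a.frequencies.max_maf()
    maf_ok = maf <= cfg.dominant_maf_max
    trace.add("dominant_maf", maf_ok, maf)
    ac = max(a.frequencies.allele_count("gnomAD"), a.frequencies.allele_count("internal"))
    ac_ok = ac <= cfg.dominant_allele_count_max
    trace.add("allele_count", ac_ok, ac)
    return maf_ok and ac_ok


def cohort_recurrence_filter(key: tuple, cohort_index: dict, families_by_proband: dict, cfg: FilterConfig, trace: FilterTrace = None) -> bool:
    """Exclude variants present in two or more *unrelated* probands.

    ``cohort_index`` maps variant key -> set of proband ids carrying it
    (including the current proband); probands of the same family never count
    as unrelated.
    """
    carriers = cohort_index.get(key, set())
    fams = {families_by_proband.get(p, p) for p in carriers}
    n_unrelated = len(fams)
    ok = n_unrelated <= cfg.cohort_recurrence_max
    if trace is not None:
        trace.add("cohort_recurrence", ok, n_unrelated)
    return ok


def build_cohort_index(families, variants_by_family) -> tuple:
    """Index carrier probands per variant key across the whole cohort.

    ``variants_by_family`` maps family_id -> list of VariantRecord. A proband
    counts as a carrier when their genotype carries >= 1 alt allele.
    Returns ``(cohort_index, families_by_proband)``.
    """
    cohort_index: dict = {}
    families_by_proband = {f.proband_id: f.family_id for f in families}
    by_id = {f.family_id: f for f in families}
    for fam_id, variants in variants_by_family.items():
        fam = by_id[fam_id]
        for v in variants:
            gt = v.genotype(fam.proband_id)
            if gt is not None and gt.carries_alt:
                cohort_index.setdefault(variant_key(v), set()).add(fam.proband_id)
    return cohort_index, families_by_proband


def apply_filters(
    family: Family,
    variants,
    annotation_table,
    cfg: FilterConfig,
    cohort_index: dict = None,
    families_by_proband: dict = None,
):
    """Run the stepwise screens and return per-model surviving variant sets.

    Returns ``(surviving, traces, unannotated)`` where ``surviving`` maps
    "recessive" / "dominant" / "x" to lists of ``(VariantRecord, Annotation)``.
    The recessive and dominant sets hold autosomal variants screened with
    their model's thresholds; the "x" set holds X-chromosome variants
    screened with the recessive thresholds for hemizygous/homozygous proband
    genotypes and (configurably) the dominant thresholds for heterozygous
    female genotypes. CNVs skip the SNV frequency rules and are screened by
    consequence and cohort recurrence only.
    """
    surviving = {m: [] for m in MODELS}
    traces = {}
    unannotated = []
    for v in variants:
        key = variant_key(v)
        trace = traces.setdefault(key, FilterTrace(key=key))
        annotations = annotation_table.get(key)
        if not annotations:
            trace.add("annotated", False, "unannotated")
            for m in MODELS:
                trace.final[m] = "fail"
            unannotated.append(key)
            continue
        ann = select_annotation(annotations)
        gt = v.genotype(family.proband_id)
        if v.variant_class is not VariantClass.CNV and (gt is None or not gt.carries_alt):
            trace.add("proband_carrier", False, "no alt allele in proband")
            for m in MODELS:
                trace.final[m] = "fail"
            continue

        tech_ok = technical_filter(v, ann, cfg, family.proband_id, trace)
        rec_ok = tech_ok
        dom_ok = tech_ok
        if v.variant_class is not VariantClass.CNV:
            rec_ok = rec_ok and recessive_frequency_filter(ann, cfg, trace)
            dom_ok = dom_ok and dominant_frequency_filter(ann, cfg, trace)
        if cohort_index is not None:
            recur_ok = cohort_recurrence_filter(
                key, cohort_index, families_by_proband or {}, cfg, trace
            )
            rec_ok = rec_ok and recur_ok
            dom_ok = dom_ok and recur_ok

        if v.is_x:
            if v.variant_class is VariantClass.CNV:
                x_ok = dom_ok  # CNV: technical + recurrence only
            elif gt.is_het and cfg.xl_het_female_uses_dominant:
                x_ok = dom_ok
            else:
                x_ok = rec_ok
            trace.final["x"] = "pass" if x_ok else "fail"
            trace.final["recessive"] = "fail"
            trace.final["dominant"] = "fail"
            if x_ok:
                surviving["x"].append((v, ann))
        else:
            trace.final["x"] = "fail"
            trace.final["recessive"] = "pass" if rec_ok else "fail"
            trace.final["dominant"] = "pass" if dom_ok else "fail"
            if rec_ok:
                surviving["recessive"].append((v, ann))
            if dom_ok:
                surviving["dominant"].append((v, ann))
    return surviving, traces, unannotated


def rank_candidates(pairs):
    """Order (variant, annotation) pairs by CADD descending, absent CADD
    last, ties by (chrom, pos). CADD is never a hard filter."""
    return sorted(
        pairs,
        key=lambda va: (
            va[1].cadd is None,
            -(va[1].cadd or 0.0),
            va[0].chrom,
            va[0].pos,
        ),
    )


def export_traces(traces: dict, path: str) -> None:
    """Write the audit trail as TSV, one row per variant x filter step."""
    from .core import format_variant_key

    with open(path, "w") as fh:
        fh.write("variant\tfilter\tdecision\tvalue\trecessive\tdominant\tx\n")
        for key, trace in traces.items():
            for name, decision, value in trace.steps:
                fh.write(
                    f"{format_variant_key(key)}\t{name}\t{decision}\t{value}\t"
                    f"{trace.final.get('recessive', '')}\t"
                    f"{trace.final.get('dominant', '')}\t{trace.final.get('x', '')}\n"
                )
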
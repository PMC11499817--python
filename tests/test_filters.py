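"""Triage-rule boundaries, cohort recurrence, monotonicity, and equivalence
with an independent brute-force re-implementation of the stated rules."""

import numpy as np
import pytest

from raredx.core import (
    Annotation,
    Consequence,
    Family,
    FilterConfig,
    GenotypeCall,
    PopulationFrequencies,
    Sex,
    SourceFrequency,
    VariantClass,
    VariantRecord,
    variant_key,
)
from raredx.filters import (
    FilterTrace,
    apply_filters,
    cohort_recurrence_filter,
    dominant_frequency_filter,
    recessive_frequency_filter,
    technical_filter,
)
from raredx.io import AnnotationTable

CFG = FilterConfig()


def _ann(consequence=Consequence.MISSENSE, **sources):
    freq = PopulationFrequencies(
        sources={k: SourceFrequency(**v) for k, v in sources.items()}
    )
    return Annotation(gene="G1", transcript="NM_1", consequence=consequence, frequencies=freq)


def _var(depth=50, gt=(0, 1), chrom="chr1", pos=100):
    return VariantRecord(
        chrom, pos, "A", "G", VariantClass.SNV,
        genotypes={"P": GenotypeCall("P", gt, depth=depth)},
    )


class TestTechnicalFilter:
    @pytest.mark.parametrize(
        "depth,consequence,expected",
        [
            (2, Consequence.MISSENSE, False),   # below the 3-read floor
            (3, Consequence.MISSENSE, True),    # boundary: only 0-2 reads fail
            (50, Consequence.SYNONYMOUS, False),
            (50, Consequence.DEEP_INTRONIC, False),
            (50, Consequence.UTR5, False),
            (50, Consequence.UTR3, False),
            (50, Consequence.INTERGENIC, False),
            (50, Consequence.NEAR_SPLICE_INTRONIC, True),
        ],
    )
    def test_depth_and_consequence_rules(self, depth, consequence, expected):
        trace = FilterTrace(key=("SEQ",))
        ok = technical_filter(_var(depth=depth), _ann(consequence), CFG, "P", trace)
        assert ok is expected

    def test_unknown_depth_fails_with_reason(self):
        trace = FilterTrace(key=("SEQ",))
        assert not technical_filter(_var(depth=None), _ann(), CFG, "P", trace)
        assert ("min_depth", "fail", "depth unknown") in trace.steps

    def test_cnv_bypasses_depth_but_not_consequence(self):
        from raredx.core import CnvSpan, Dosage

        cnv = VariantRecord(
            "chr1", 100, "N", "<DEL>", VariantClass.CNV,
            cnv_span=CnvSpan(100, 5000, Dosage.DEL),
            genotypes={"P": GenotypeCall("P", (0, 1), depth=None)},
        )
        trace = FilterTrace(key=("CNV",))
        assert technical_filter(cnv, _ann(Consequence.CNV_LOSS), CFG, "P", trace)
        assert all(name != "min_depth" for name, _, _ in trace.steps)


class TestFrequencyFilters:
    @pytest.mark.parametrize(
        "sources,expected",
        [
            ({"gnomAD": {"maf": 0.01}}, False),            # > 0.005 excluded
            ({}, True),                                    # absent = 0
            ({"gnomAD": {"maf": 0.005}}, True),            # strict inequality
            ({"gnomAD": {"maf": 0.004}, "ExAC": {"hom_count": 10}}, False),
            ({"ExAC": {"hom_count": 5, "hemi_count": 5}}, False),  # combined >= 10
            ({"ExAC": {"hom_count": 9}}, True),
            ({"1000G": {"maf": 0.006}}, False),            # any source triggers
        ],
    )
    def test_recessive_rule(self, sources, expected):
        ann = _ann(**sources)
        assert recessive_frequency_filter(ann, CFG, FilterTrace(key=())) is expected

    @pytest.mark.parametrize(
        "sources,expected",
        [
            ({"gnomAD": {"maf": 0.002}}, False),                      # > 0.001
            ({"gnomAD": {"maf": 0.0, "allele_count": 6}}, False),     # count > 5
            ({"internal": {"allele_count": 6}}, False),
            ({"gnomAD": {"maf": 0.0005, "allele_count": 5}}, True),   # both at bound
            ({}, True),
        ],
    )
    def test_dominant_rule(self, sources, expected):
        ann = _ann(**sources)
        assert dominant_frequency_filter(ann, CFG, FilterTrace(key=())) is expected


class TestCohortRecurrence:
    FAMS = {"A": "f1", "B": "f2", "C": "f3", "sibA": "f1"}

    def _ok(self, carriers):
        return cohort_recurrence_filter(("SEQ",), {("SEQ",): set(carriers)}, self.FAMS, CFG)

    def test_single_proband_passes(self):
        assert self._ok({"A"})

    def test_two_unrelated_fail(self):
        assert not self._ok({"A", "B"})

    def test_same_family_siblings_pass(self):
        assert self._ok({"A", "sibA"})

    def test_matches_bruteforce_over_relatedness_configurations(self):
        """All carrier subsets of a 6-proband cohort agree with an explicit
        pairwise-unrelatedness count."""
        fams = {"p1": "f1", "p2": "f1", "p3": "f2", "p4": "f2", "p5": "f3", "p6": "f4"}
        from itertools import combinations

        probands = sorted(fams)
        for r in range(1, 7):
            for subset in combinations(probands, r):
                expected = len({fams[p] for p in subset}) <= CFG.cohort_recurrence_max
                got = cohort_recurrence_filter(
                    ("SEQ",), {("SEQ",): set(subset)}, fams, CFG
                )
                assert got is expected, subset


# ---------------------------------------------------------------------------
# brute-force oracle: an independent restatement of the five rules
# ---------------------------------------------------------------------------


def oracle_pass(v, ann, cfg, model, carriers=None, fams=None):
    gt = v.genotypes.get("P")
    if v.variant_class is not VariantClass.CNV:
        if gt is None or gt.depth is None or gt.depth < cfg.min_depth:
            return False
    if ann.consequence in cfg.excluded_consequences:
        return False
    mafs = [s.maf for s in ann.frequencies.sources.values() if s.maf is not None]
    maf = max(mafs) if mafs else 0.0
    if v.variant_class is not VariantClass.CNV:
        if model == "recessive":
            if maf > cfg.recessive_maf_max:
                return False
            exac = ann.frequencies.sources.get("ExAC")
            hh = ((exac.hom_count or 0) + (exac.hemi_count or 0)) if exac else 0
            if hh >= cfg.recessive_homhemi_max + 1:
                return False
        else:
            if maf > cfg.dominant_maf_max:
                return False
            for src in ("gnomAD", "internal"):
                rec = ann.frequencies.sources.get(src)
                if rec and (rec.allele_count or 0) > cfg.dominant_allele_count_max:
                    return False
    if carriers is not None:
        if len({fams[p] for p in carriers}) > cfg.cohort_recurrence_max:
            return False
    return True


def _random_dataset(n, seed):
    rng = np.random.default_rng(seed)
    consequences = list(Consequence)
    variants, table = [], AnnotationTable()
    for i in range(n):
        v = _var(
            depth=int(rng.integers(0, 60)),
            gt=(0, 1) if rng.random() < 0.8 else (1, 1),
            pos=1000 + i,
        )
        sources = {}
        if rng.random() < 0.7:
            sources["gnomAD"] = SourceFrequency(
                maf=float(rng.uniform(0, 0.02)),
                allele_count=int(rng.integers(0, 12)),
            )
        if rng.random() < 0.5:
            sources["ExAC"] = SourceFrequency(
                maf=float(rng.uniform(0, 0.01)),
                hom_count=int(rng.integers(0, 15)),
                hemi_count=int(rng.integers(0, 4)),
            )
        ann = Annotation(
            gene=f"G{i}", transcript="NM_1",
            consequence=consequences[int(rng.integers(0, len(consequences) - 2))],
            frequencies=PopulationFrequencies(sources=sources),
        )
        variants.append(v)
        table.entries[variant_key(v)] = [ann]
    return variants, table


FAMILY = Family("f1", "P", mother_id="M", father_id="F", proband_sex=Sex.FEMALE)


class TestApplyFilters:
    def test_matches_bruteforce_oracle_variant_by_variant(self):
        variants, table = _random_dataset(500, seed=5)
        surviving, traces, _ = apply_filters(FAMILY, variants, table, CFG)
        for model in ("recessive", "dominant"):
            got = {variant_key(v) for v, _ in surviving[model]}
            expected = {
                variant_key(v)
                for v in variants
                if oracle_pass(v, table.get(variant_key(v))[0], CFG, model)
            }
            assert got == expected

    def test_planted_rarity_isolated_from_common_background(self):
        """One absent-from-databases variant among 200 common ones is the
        sole dominant-eligible survivor."""
        rng = np.random.default_rng(9)
        variants, table = [], AnnotationTable()
        for i in range(200):
            v = _var(pos=10_000 + i)
            ann = _ann(gnomAD={"maf": float(rng.uniform(0.01, 0.5))})
            variants.append(v)
            table.entries[variant_key(v)] = [ann]
        planted = _var(pos=99_999)
        table.entries[variant_key(planted)] = [_ann()]
        variants.append(planted)
        surviving, _, _ = apply_filters(FAMILY, variants, table, CFG)
        assert [variant_key(v) for v, _ in surviving["dominant"]] == [variant_key(planted)]

    def test_empty_input_gives_empty_sets(self):
        surviving, traces, unann = apply_filters(FAMILY, [], AnnotationTable(), CFG)
        assert all(not s for s in surviving.values()) and not traces

    def test_unannotated_variant_excluded_with_trace(self):
        v = _var()
        surviving, traces, unann = apply_filters(FAMILY, [v], AnnotationTable(), CFG)
        assert unann == [variant_key(v)]
        assert ("annotated", "fail", "unannotated") in traces[variant_key(v)].steps

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tightening_thresholds_only_shrinks_sets(self, seed):
        variants, table = _random_dataset(200, seed=seed)
        loose = FilterConfig()
        surviving_loose, _, _ = apply_filters(FAMILY, variants, table, loose)
        rng = np.random.default_rng(seed + 100)
        tight = FilterConfig(
            min_depth=int(loose.min_depth + rng.integers(0, 10)),
            recessive_maf_max=loose.recessive_maf_max * float(rng.uniform(0, 1)),
            recessive_homhemi_max=int(rng.integers(0, loose.recessive_homhemi_max + 1)),
            dominant_maf_max=loose.dominant_maf_max * float(rng.uniform(0, 1)),
            dominant_allele_count_max=int(rng.integers(0, loose.dominant_allele_count_max + 1)),
        )
        surviving_tight, _, _ = apply_filters(FAMILY, variants, table, tight)
        for model in ("recessive", "dominant", "x"):
            loose_keys = {variant_key(v) for v, _ in surviving_loose[model]}
            tight_keys = {variant_key(v) for v, _ in surviving_tight[model]}
            assert tight_keys <= loose_keys

    def test_identical_inputs_identical_traces(self):
        variants, table = _random_dataset(100, seed=7)
        _, t1, _ = apply_filters(FAMILY, variants, table, CFG)
        _, t2, _ = apply_filters(FAMILY, variants, table, CFG)
        assert {k: v.steps for k, v in t1.items()} == {k: v.steps for k, v in t2.items()}
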
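"""Synthetic rare-disease cohort generator with ground truth.

Produces a complete offline input bundle — per-family VCFs, pedigree,
annotation table, CNV table, phenotype terms, covariates, a miniature
phenotype ontology and a gene-disease map — whose statistical structure
matches the cohort the pipeline was built for: a 71 trio : 7 duo : 19 solo
family mix, ~300 rare annotated variants per exome, a planted causal variant
in 45.6% of probands spanning dominant, recessive (homozygous and compound
heterozygous), X-linked and de novo modes and P/LP/VUS classes, and HPO
terms drawn from the planted gene's disease entry with a per-proband
affected-system count of median 6, range 2-11.

Background variants are constructed so that each one fails at least one
triage rule (common frequency, excluded consequence class, low read
support, dominant allele-count excess, or cohort recurrence) or lies in a
gene absent from the disease map; planted variants are constructed to pass
every rule for their mode. Parental genotypes are Mendelian-consistent
everywhere except planted de novo events. The generator writes a miniature
ontology and gene map as fixtures; real HPO/OMIM files are drop-in
replacements.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import Sex
from .io import write_obo, write_pedigree
from .stats import COVARIATES

MODES = ("AD_de_novo", "AD_inherited", "AR_hom", "AR_comphet", "XLR", "XLD", "CNV_del")

#: system branches of the miniature ontology (real HPO branch ids)
SYSTEMS = (
    ("HP:0000707", "Abnormality of the nervous system"),
    ("HP:0000152", "Abnormality of head or neck"),
    ("HP:0000924", "Abnormality of the skeletal system"),
    ("HP:0001507", "Growth abnormality"),
    ("HP:0001626", "Abnormality of the cardiovascular system"),
    ("HP:0002715", "Abnormality of the immune system"),
    ("HP:0000119", "Abnormality of the genitourinary system"),
    ("HP:0000478", "Abnormality of the eye"),
    ("HP:0001574", "Abnormality of the integument"),
    ("HP:0025031", "Abnormality of the digestive system"),
    ("HP:0000818", "Abnormality of the endocrine system"),
    ("HP:0001871", "Abnormality of blood and blood-forming tissues"),
)
LEAVES_PER_SYSTEM = 3


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    n_trio: int = 71
    n_duo: int = 7
    n_solo: int = 19
    background_variants: int = 300
    planted_prob: float = 0.456
    mode_weights: dict = field(
        default_factory=lambda: {
            "AD_de_novo": 0.38,
            "AD_inherited": 0.13,
            "AR_hom": 0.14,
            "AR_comphet": 0.14,
            "XLR": 0.08,
            "XLD": 0.04,
            "CNV_del": 0.09,
        }
    )
    class_weights: dict = field(
        default_factory=lambda: {"P": 0.22, "LP": 0.38, "VUS": 0.40}
    )
    #: probability a planted variant carries a ClinVar entry (else resources)
    clinvar_prob: float = 0.5
    #: shared rare severe sites exercising the cohort-recurrence filter
    n_recurrent_sites: int = 10
    #: affected-system count per proband: 2 + Binomial(9, 0.45) -> median 6
    systems_binomial_n: int = 9
    systems_binomial_p: float = 0.45

    def __post_init__(self):
        for name, weights in (("mode_weights", self.mode_weights),
                              ("class_weights", self.class_weights)):
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {total}")
        if self.n_trio + self.n_duo + self.n_solo < 1:
            raise ValueError("empty cohort")
        if not 0.0 <= self.planted_prob <= 1.0:
            raise ValueError("planted_prob must be a probability")

    @property
    def n_families(self) -> int:
        return self.n_trio + self.n_duo + self.n_solo

    def with_families(self, n_families: int) -> "SimulationConfig":
        """Rescale the strategy mix to a different cohort size."""
        total = self.n_families
        n_trio = round(n_families * self.n_trio / total)
        n_duo = round(n_families * self.n_duo / total)
        n_solo = n_families - n_trio - n_duo
        return replace(self, n_trio=n_trio, n_duo=n_duo, n_solo=n_solo)


@dataclass
class TruthRecord:
    proband_id: str
    family_id: str
    strategy: str
    planted_keys: tuple  # variant keys (tuples)
    mode: str = ""  # empty when nothing planted
    acmg_class: str = ""
    expected_category: str = "uninformative"


@dataclass
class SimulatedCohort:
    outdir: str
    truth: list
    paths: dict


# ---------------------------------------------------------------------------
# static resources: ontology, gene map
# ---------------------------------------------------------------------------


def _leaf_id(si: int, li: int) -> str:
    return f"HP:9{si:02d}{li:02d}"


def _leaf_systems(term: str) -> set:
    """System indices a synthetic leaf term belongs to (the last leaf of
    each system branch is multi-parent and also hangs under the next)."""
    si, li = int(term[4:6]), int(term[6:8])
    out = {si}
    if li == LEAVES_PER_SYSTEM - 1:
        out.add((si + 1) % len(SYSTEMS))
    return out


def build_ontology_terms():
    """Miniature ontology: super-root, phenotypic-abnormality root, 12
    system branches, 3 leaves each (one leaf per system is multi-parent)."""
    terms = [("HP:0000001", "All", []), ("HP:0000118", "Phenotypic abnormality", ["HP:0000001"])]
    for si, (sid, name) in enumerate(SYSTEMS):
        terms.append((sid, name, ["HP:0000118"]))
    for si, (sid, _) in enumerate(SYSTEMS):
        for li in range(LEAVES_PER_SYSTEM):
            parents = [sid]
            if li == LEAVES_PER_SYSTEM - 1:
                # last leaf of each system also hangs under the next system,
                # exercising multi-parent fan-out
                parents.append(SYSTEMS[(si + 1) % len(SYSTEMS)][0])
            terms.append((_leaf_id(si, li), f"synthetic finding {si}.{li}", parents))
    return terms


_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


def build_gene_table(rng: np.random.Generator):
    """Disease genes (with map entries) and unmapped background genes.

    Returns a DataFrame with gene, chrom, base_pos, mode ("" for
    background), omim_id and hpo term ids.
    """
    rows = []
    counter = 0

    def add(prefix, n, mode, chrom_pool):
        nonlocal counter
        for i in range(n):
            counter += 1
            chrom = chrom_pool[counter % len(chrom_pool)] if isinstance(chrom_pool, list) else chrom_pool
            n_sys = int(rng.integers(2, 4))
            systems = rng.choice(len(SYSTEMS), size=n_sys, replace=False)
            terms = [
                _leaf_id(int(si), int(rng.integers(0, LEAVES_PER_SYSTEM)))
                for si in systems
            ]
            rows.append(
                {
                    "gene": f"{prefix}{i + 1:02d}",
                    "chrom": chrom,
                    "base_pos": 1_000_000 + counter * 1_000_000,
                    "mode": mode,
                    "omim_id": str(600000 + counter),
                    "hpo_ids": ";".join(dict.fromkeys(terms)),
                }
            )

    add("SIMAD", 20, "AD", _AUTOSOMES)
    add("SIMAR", 10, "AR", _AUTOSOMES)
    add("SIMXD", 4, "XLD", "chrX")
    add("SIMXR", 4, "XLR", "chrX")
    add("SIMBG", 200, "", _AUTOSOMES)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_BASES = np.array(["A", "C", "G", "T"])

_BACKGROUND_FAIL_MODES = (
    ("common_maf", 0.50),
    ("excluded_consequence", 0.25),
    ("low_depth", 0.10),
    ("dominant_only", 0.15),
)
_SEVERE = ("missense", "nonsense", "frameshift", "splice_site")
_EXCLUDED = ("synonymous", "deep_intronic", "intergenic", "utr5", "utr3")


def _snv_alleles(rng):
    ref, alt = rng.choice(4, size=2, replace=False)
    return _BASES[ref], _BASES[alt]


def _ann_row(chrom, pos, ref, alt, gene, consequence, **extra):
    row = {
        "chrom": chrom,
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "gene": gene,
        "transcript": f"NM_{gene}",
        "consequence": consequence,
        "hgvs_c": f"c.{pos % 10000}{ref}>{alt}",
        "hgvs_p": "",
        "cadd": "",
        "clinvar_id": "",
        "clinvar_class": "",
        "resource_classes": "",
        "maf_cmg": "",
        "maf_esp5400": "",
        "maf_1000g": "",
        "maf_gnomad": "",
        "ac_gnomad": "",
        "maf_exac": "",
        "ac_exac": "",
        "hom_exac": "",
        "hemi_exac": "",
        "maf_internal": "",
        "ac_internal": "",
    }
    row.update(extra)
    return row


def _classification(rng, cfg, acmg_class):
    """ClinVar entry or 3 resource classes whose mode equals acmg_class."""
    other = {"P": "VUS", "LP": "VUS", "VUS": "LP"}[acmg_class]
    if rng.random() < cfg.clinvar_prob:
        return {"clinvar_id": str(int(rng.integers(10000, 2_000_000))),
                "clinvar_class": acmg_class}
    return {"resource_classes": ";".join([acmg_class, acmg_class, other])}


class _FamilyBuilder:
    """Accumulates one family's variant rows across shared output tables."""

    def __init__(self, family_id, strategy, rng):
        self.family_id = family_id
        self.strategy = strategy
        self.rng = rng
        self.proband = f"{family_id}_P"
        self.mother = f"{family_id}_M" if strategy in ("trio", "duo") else None
        self.father = f"{family_id}_F" if strategy == "trio" else None
        self.sex = "male" if rng.random() < 0.5 else "female"
        self.variants = []  # (chrom, pos, ref, alt, {sample: (gt, dp)})

    @property
    def samples(self):
        return [s for s in (self.proband, self.mother, self.father) if s]

    def add_site(self, chrom, pos, ref, alt, proband_gt, mother_gt, father_gt,
                 proband_dp=None):
        dp = lambda: int(self.rng.integers(20, 61))
        calls = {self.proband: (proband_gt, proband_dp if proband_dp is not None else dp())}
        if self.mother:
            calls[self.mother] = (mother_gt, dp())
        if self.father:
            calls[self.father] = (father_gt, dp())
        self.variants.append((chrom, pos, ref, alt, calls))

    def write_vcf(self, path):
        order = {c: i for i, c in enumerate(_AUTOSOMES + ["chrX"])}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            for c in _AUTOSOMES + ["chrX"]:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            for chrom, pos, ref, alt, calls in sorted(
                self.variants, key=lambda v: (order[v[0]], v[1])
            ):
                cols = [chrom, str(pos), ".", ref, alt, ".", "PASS", ".", "GT:DP"]
                for s in self.samples:
                    gt, dp = calls[s]
                    cols.append(f"{gt}:{dp}")
                fh.write("\t".join(cols) + "\n")


def _hwe_gt(rng, maf):
    n = rng.binomial(2, maf)
    return {0: "0/0", 1: "0/1", 2: "1/1"}[int(n)]


def _transmit(rng, parent_gt):
    """Random allele transmitted by a parent with diploid GT string."""
    a, b = parent_gt.split("/")
    return a if rng.random() < 0.5 else b


def simulate_cohort(cfg: SimulationConfig, seed: int, outdir: str) -> SimulatedCohort:
    """Write the full synthetic input bundle plus truth records to outdir.

    The seed fully determines every output byte. Returns a
    :class:`SimulatedCohort` with file paths and in-memory truth.
    """
    rng = np.random.default_rng(seed)
    os.makedirs(outdir, exist_ok=True)
    vcf_dir = os.path.join(outdir, "vcf")
    os.makedirs(vcf_dir, exist_ok=True)

    genes = build_gene_table(rng)
    disease = genes[genes["mode"] != ""].reset_index(drop=True)
    background = genes[genes["mode"] == ""].reset_index(drop=True)
    by_mode = {m: disease[disease["mode"] == m].reset_index(drop=True)
               for m in ("AD", "AR", "XLD", "XLR")}

    # shared recurrent sites: rare, severe, in unmapped genes; every proband het
    recurrent = []
    for i in range(cfg.n_recurrent_sites):
        g = background.iloc[int(rng.integers(len(background)))]
        ref, alt = _snv_alleles(rng)
        recurrent.append((g["chrom"], int(g["base_pos"]) + 990 + i, ref, alt, g["gene"]))

    strategies = (["trio"] * cfg.n_trio + ["duo"] * cfg.n_duo + ["solo"] * cfg.n_solo)
    mode_names = list(cfg.mode_weights)
    mode_p = np.array([cfg.mode_weights[m] for m in mode_names])
    class_names = list(cfg.class_weights)
    class_p = np.array([cfg.class_weights[c] for c in class_names])
    fail_names = [n for n, _ in _BACKGROUND_FAIL_MODES]
    fail_p = np.array([p for _, p in _BACKGROUND_FAIL_MODES])

    ann_rows: dict = {}
    cnv_rows = []
    families = []
    truth = []
    phen_rows = []
    cov_rows = []

    from .core import Family as CoreFamily  # written to PED at the end

    for fi, strategy in enumerate(strategies):
        fam_id = f"F{fi + 1:04d}"
        fb = _FamilyBuilder(fam_id, strategy, rng)

        planted_keys = []
        mode = ""
        acmg = ""
        plant = rng.random() < cfg.planted_prob
        if plant:
            mode = mode_names[int(rng.choice(len(mode_names), p=mode_p))]
            acmg = class_names[int(rng.choice(len(class_names), p=class_p))]
            if mode in ("XLR",):
                fb.sex = "male"
            if mode in ("XLD",):
                fb.sex = "female"
            planted_keys = _plant(fb, mode, acmg, by_mode, cfg, rng, ann_rows,
                                  cnv_rows, fi)

        _add_background(fb, cfg, rng, background, ann_rows, fi)
        for chrom, pos, ref, alt, gene in recurrent:
            # inherited (maternal) so trios stay Mendelian-consistent
            fb.add_site(chrom, pos, ref, alt, "0/1", "0/1", "0/0")
            ann_rows.setdefault(
                (chrom, pos, ref, alt),
                _ann_row(chrom, pos, ref, alt, gene, "missense",
                         **{"resource_classes": "VUS;VUS;LP"}),
            )

        fb.write_vcf(os.path.join(vcf_dir, f"{fam_id}.vcf"))
        families.append(
            CoreFamily(
                family_id=fam_id,
                proband_id=fb.proband,
                mother_id=fb.mother,
                father_id=fb.father,
                proband_sex=Sex(fb.sex),
            )
        )

        # phenotype terms: planted-gene terms plus noise leaves until the
        # target affected-system count (2 + Binomial(9, 0.45)) is reached
        target = 2 + int(rng.binomial(cfg.systems_binomial_n, cfg.systems_binomial_p))
        terms = []
        if plant:
            gene_row = _planted_gene_row(planted_keys, ann_rows, cnv_rows, disease)
            terms.extend(gene_row["hpo_ids"].split(";"))
        covered = set()
        for t in terms:
            covered |= _leaf_systems(t)
        for si in rng.permutation(len(SYSTEMS)):
            if len(covered) >= target:
                break
            si = int(si)
            if si in covered:
                continue
            # noise leaves avoid the multi-parent last leaf so each adds
            # exactly one system and the 2..11 range is respected
            terms.append(_leaf_id(si, int(rng.integers(0, LEAVES_PER_SYSTEM - 1))))
            covered.add(si)
        for t in dict.fromkeys(terms):
            phen_rows.append((fb.proband, t))

        expected = "uninformative"
        if plant:
            expected = "solved" if acmg in ("P", "LP") else "suggestive"
        truth.append(
            TruthRecord(
                proband_id=fb.proband,
                family_id=fam_id,
                strategy=strategy,
                planted_keys=tuple(planted_keys),
                mode=mode,
                acmg_class=acmg,
                expected_category=expected,
            )
        )

        cov_rows.append(
            {
                "proband_id": fb.proband,
                "sex": fb.sex,
                "age_years": round(min(52.0, float(rng.gamma(1.8, 6.0))), 1),
                "care": "public" if rng.random() < 0.72 else "private",
                "provider_in_capital": int(rng.random() < 0.85),
                "congenital_anomalies": int(rng.random() < 0.75),
                "neurological": int(rng.random() < 0.80),
                "immune": int(rng.random() < 0.20),
            }
        )

    paths = {
        "vcf_dir": vcf_dir,
        "ped": os.path.join(outdir, "cohort.ped"),
        "annotations": os.path.join(outdir, "annotations.tsv"),
        "cnv": os.path.join(outdir, "cnv.tsv"),
        "phenotypes": os.path.join(outdir, "phenotypes.tsv"),
        "covariates": os.path.join(outdir, "covariates.tsv"),
        "ontology": os.path.join(outdir, "ontology.obo"),
        "gene_map": os.path.join(outdir, "gene_map.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }

    write_pedigree(families, paths["ped"])
    write_obo(build_ontology_terms(), paths["ontology"])

    from .io import ANNOTATION_COLUMNS

    ann_df = pd.DataFrame(list(ann_rows.values()), columns=ANNOTATION_COLUMNS)
    ann_df.to_csv(paths["annotations"], sep="\t", index=False)

    cnv_df = pd.DataFrame(
        cnv_rows,
        columns=["sample_id", "chrom", "start", "end", "dosage", "zygosity",
                 "genes", "clinvar_id", "clinvar_class", "resource_classes"],
    )
    cnv_df.to_csv(paths["cnv"], sep="\t", index=False)

    with open(paths["phenotypes"], "w") as fh:
        fh.write("proband_id\thpo_id\n")
        for pid, term in phen_rows:
            fh.write(f"{pid}\t{term}\n")

    pd.DataFrame(cov_rows).to_csv(paths["covariates"], sep="\t", index=False)

    gm = disease[["gene", "omim_id", "mode", "hpo_ids"]].copy()
    gm.insert(2, "label", "synthetic disorder " + gm["omim_id"])
    gm = gm.rename(columns={"mode": "inheritance"})
    gm[["gene", "omim_id", "label", "inheritance", "hpo_ids"]].to_csv(
        paths["gene_map"], sep="\t", index=False
    )

    with open(paths["truth"], "w") as fh:
        fh.write("proband_id\tfamily_id\tstrategy\tplanted_keys\tmode\tacmg_class\texpected_category\n")
        for t in truth:
            keys = ";".join("|".join(str(x) for x in k) for k in t.planted_keys)
            fh.write(
                f"{t.proband_id}\t{t.family_id}\t{t.strategy}\t{keys}\t{t.mode}\t"
                f"{t.acmg_class}\t{t.expected_category}\n"
            )

    return SimulatedCohort(outdir=outdir, truth=truth, paths=paths)


def _planted_gene_row(planted_keys, ann_rows, cnv_rows, disease):
    key = planted_keys[0]
    if key[0] == "CNV":
        gene = next(r[6] for r in cnv_rows
                    if (r[1], int(r[2]), int(r[3])) == (key[1], key[2], key[3]))
    else:
        gene = ann_rows[(key[1], key[2], key[3], key[4])]["gene"]
    return disease[disease["gene"] == gene].iloc[0]


def _plant(fb, mode, acmg, by_mode, cfg, rng, ann_rows, cnv_rows, fi):
    """Plant one causal event; returns the planted variant key(s)."""
    def pick(pool_name):
        pool = by_mode[pool_name]
        return pool.iloc[int(rng.integers(len(pool)))]

    keys = []

    def add_snv(gene_row, offset, proband_gt, mother_gt, father_gt):
        chrom = gene_row["chrom"]
        pos = int(gene_row["base_pos"]) + offset
        ref, alt = _snv_alleles(rng)
        fb.add_site(chrom, pos, ref, alt, proband_gt, mother_gt, father_gt)
        ann_rows[(chrom, pos, ref, alt)] = _ann_row(
            chrom, pos, ref, alt, gene_row["gene"],
            str(rng.choice(_SEVERE)), **_classification(rng, cfg, acmg)
        )
        keys.append(("SEQ", chrom, pos, ref, alt))

    # offsets 3*fi{,+1,+2} are globally unique per family, so two unrelated
    # probands never share a planted key (which would trip the recurrence rule)
    if mode == "AD_de_novo":
        add_snv(pick("AD"), 3 * fi, "0/1", "0/0", "0/0")
    elif mode == "AD_inherited":
        carrier_is_mother = fb.mother is not None and (
            fb.father is None or rng.random() < 0.5
        )
        add_snv(pick("AD"), 3 * fi, "0/1",
                "0/1" if carrier_is_mother else "0/0",
                "0/0" if carrier_is_mother else "0/1")
    elif mode == "AR_hom":
        add_snv(pick("AR"), 3 * fi, "1/1", "0/1", "0/1")
    elif mode == "AR_comphet":
        g = pick("AR")
        add_snv(g, 3 * fi, "0/1", "0/1", "0/0")      # maternal allele
        add_snv(g, 3 * fi + 1, "0/1", "0/0", "0/1")  # paternal allele
    elif mode == "XLR":
        g = pick("XLR")
        chrom = g["chrom"]
        pos = int(g["base_pos"]) + 3 * fi
        ref, alt = _snv_alleles(rng)
        fb.add_site(chrom, pos, ref, alt, "1", "0/1", "0")
        ann_rows[(chrom, pos, ref, alt)] = _ann_row(
            chrom, pos, ref, alt, g["gene"], str(rng.choice(_SEVERE)),
            **_classification(rng, cfg, acmg)
        )
        keys.append(("SEQ", chrom, pos, ref, alt))
    elif mode == "XLD":
        add_snv(pick("XLD"), 3 * fi, "0/1", "0/0", "0/0")
    elif mode == "CNV_del":
        g = pick("AD")
        start = int(g["base_pos"]) - 5000 - fi  # family-unique span
        end = int(g["base_pos"]) + 5000 + fi
        cls = _classification(rng, cfg, acmg)
        row = [fb.proband, g["chrom"], start, end, "DEL", "het", g["gene"],
               cls.get("clinvar_id", ""), cls.get("clinvar_class", ""),
               cls.get("resource_classes", "")]
        cnv_rows.append(row)
        for parent in (fb.mother, fb.father):
            if parent:
                cnv_rows.append([parent, g["chrom"], start, end, "DEL", "ref",
                                 g["gene"], cls.get("clinvar_id", ""),
                                 cls.get("clinvar_class", ""),
                                 cls.get("resource_classes", "")])
        keys.append(("CNV", g["chrom"], start, end, "DEL"))
    else:
        raise ValueError(f"unknown planted mode {mode}")
    return keys


def _add_background(fb, cfg, rng, background, ann_rows, fi):
    fail_names = [n for n, _ in _BACKGROUND_FAIL_MODES]
    fail_p = np.array([p for _, p in _BACKGROUND_FAIL_MODES])
    n = cfg.background_variants
    gene_idx = rng.choice(len(background), size=n, replace=(n > len(background)))
    modes = rng.choice(len(fail_names), size=n, p=fail_p)
    for bi in range(n):
        g = background.iloc[int(gene_idx[bi])]
        chrom = g["chrom"]
        pos = int(g["base_pos"]) + fi * cfg.background_variants + bi
        ref, alt = _snv_alleles(rng)
        fail = fail_names[int(modes[bi])]
        extra = {}
        consequence = str(rng.choice(_SEVERE))
        depth = None
        if fail == "common_maf":
            maf = float(rng.uniform(0.01, 0.5))
            extra = {"maf_gnomad": f"{maf:.4f}", "maf_exac": f"{maf:.4f}"}
        elif fail == "excluded_consequence":
            consequence = str(rng.choice(_EXCLUDED))
            extra = {"maf_gnomad": f"{rng.uniform(0, 0.004):.5f}"}
        elif fail == "low_depth":
            depth = 2
            extra = {"maf_gnomad": f"{rng.uniform(0, 0.0005):.6f}"}
        elif fail == "dominant_only":
            extra = {"maf_gnomad": f"{rng.uniform(0.0015, 0.004):.5f}"}
        maf_for_gt = float(extra.get("maf_gnomad", 0.001))
        # one carrier parent, Mendelian transmission
        p1 = "0/1"
        p2 = _hwe_gt(rng, maf_for_gt)
        child = f"{_transmit(rng, p1)}/{_transmit(rng, p2)}"
        if child == "1/0":
            child = "0/1"
        fb.add_site(chrom, pos, ref, alt, child, p1, p2, proband_dp=depth)
        ann_rows[(chrom, pos, ref, alt)] = _ann_row(
            chrom, pos, ref, alt, g["gene"], consequence, **extra
        )


# ---------------------------------------------------------------------------
# truth evaluation and regression-recovery simulation
# ---------------------------------------------------------------------------


def evaluate_against_truth(run_result, truth) -> dict:
    """Recovery metrics: planted-variant recall among candidates, per-mode
    recall, and category agreement against the expected category."""
    truth_by_id = {t.proband_id: t for t in truth}
    if set(truth_by_id) != set(run_result.results):
        raise ValueError("proband ids differ between results and truth")
    planted_total = planted_found = 0
    per_mode: dict = {}
    agree = 0
    confusion: dict = {}
    for pid, t in truth_by_id.items():
        found_keys = run_result.candidate_keys.get(pid, set())
        for key in t.planted_keys:
            planted_total += 1
            hit = key in found_keys
            planted_found += hit
            m = per_mode.setdefault(t.mode, [0, 0])
            m[0] += hit
            m[1] += 1
        observed = run_result.results[pid].category.label
        agree += observed == t.expected_category
        confusion[(t.expected_category, observed)] = (
            confusion.get((t.expected_category, observed), 0) + 1
        )
    return {
        "planted_recall": planted_found / planted_total if planted_total else float("nan"),
        "per_mode_recall": {
            m: found / total for m, (found, total) in sorted(per_mode.items())
        },
        "category_agreement": agree / len(truth_by_id),
        "confusion": confusion,
        "n_planted_variants": planted_total,
    }


def simulate_yield_table(
    n: int, seed: int, odds_ratios: dict = None, base_prob: float = 0.35
) -> pd.DataFrame:
    """Covariate/outcome table with known log-odds, for parameter recovery.

    Covariates are drawn to resemble the cohort (ages 0-52, mostly public
    care, frequent neurological involvement); the outcome follows a logistic
    model whose coefficients are ``log(odds_ratios[var])`` (default 1.0 for
    unspecified covariates).
    """
    rng = np.random.default_rng(seed)
    odds_ratios = odds_ratios or {}
    age = rng.uniform(0, 52, size=n)
    df = pd.DataFrame(
        {
            "sex_male": rng.random(n) < 0.5,
            "age_years": age,
            "age_12_18": (age >= 12) & (age < 18),
            "age_18_52": age >= 18,
            "care_private": rng.random(n) < 0.28,
            "neurological": rng.random(n) < 0.8,
            "immune": rng.random(n) < 0.2,
            "congenital_anomalies": rng.random(n) < 0.75,
            "n_systems": 2 + rng.binomial(9, 0.45, size=n),
        }
    ).astype(float)
    logit = np.log(base_prob / (1 - base_prob)) * np.ones(n)
    for var, oratio in odds_ratios.items():
        logit = logit + np.log(oratio) * df[var].to_numpy()
    prob = 1.0 / (1.0 + np.exp(-logit))
    df["informative"] = (rng.random(n) < prob).astype(int)
    return df[list(COVARIATES) + ["informative"]]
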
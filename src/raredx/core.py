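"""Core domain types: genotypes, variants, frequencies, annotations, families.

Shared vocabulary for the whole pipeline. Coordinates are 1-based inclusive
throughout (VCF convention); CNV spans are stored 1-based inclusive as well.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    CNV = "CNV"


class Dosage(str, enum.Enum):
    DEL = "DEL"
    DUP = "DUP"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE_SITE = "splice_site"
    DEEP_INTRONIC = "deep_intronic"
    NEAR_SPLICE_INTRONIC = "near_splice_intronic"
    SYNONYMOUS = "synonymous"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTERGENIC = "intergenic"
    CNV_GAIN = "cnv_gain"
    CNV_LOSS = "cnv_loss"


#: rank used for transcript selection; lower = more severe
CONSEQUENCE_SEVERITY = {
    Consequence.CNV_LOSS: 0,
    Consequence.CNV_GAIN: 1,
    Consequence.NONSENSE: 2,
    Consequence.FRAMESHIFT: 3,
    Consequence.SPLICE_SITE: 4,
    Consequence.MISSENSE: 5,
    Consequence.INFRAME_INDEL: 6,
    Consequence.NEAR_SPLICE_INTRONIC: 7,
    Consequence.SYNONYMOUS: 8,
    Consequence.UTR5: 9,
    Consequence.UTR3: 10,
    Consequence.DEEP_INTRONIC: 11,
    Consequence.INTERGENIC: 12,
}


class AcmgClass(str, enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"


class InheritanceMode(str, enum.Enum):
    AD = "AD"
    AR = "AR"
    XLD = "XLD"
    XLR = "XLR"
    XL = "XL"
    DD = "DD"  # digenic dominant


class Strategy(str, enum.Enum):
    TRIO = "trio"
    DUO = "duo"
    SOLO = "solo"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Origin(str, enum.Enum):
    DE_NOVO = "de_novo"
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BIPARENTAL = "biparental"
    UNKNOWN = "unknown"


class FormatError(ValueError):
    """Malformed field in an input file; message names the offending field."""


_X_NAMES = {"X", "chrX"}


def is_x_chromosome(chrom: str, par_regions: tuple = ()) -> bool:
    """True for X-chromosome names ('X' or 'chrX'), PARs excluded by caller."""
    return chrom in _X_NAMES


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site.

    ``alleles`` is an ordered tuple of allele indices (0 = ref, >=1 = alt),
    length 2 for diploid calls, length 1 for hemizygous calls (male X),
    and ``None`` for a missing genotype. ``depth`` is the read count at the
    site, ``None`` when the file did not report one.
    """

    sample_id: str
    alleles: Optional[tuple]
    depth: Optional[int] = None
    phased: bool = False

    def __post_init__(self):
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"negative depth for sample {self.sample_id}")
        if self.alleles is not None and len(self.alleles) not in (1, 2):
            raise ValueError("alleles must have 1 or 2 entries when present")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def n_alt(self) -> int:
        """Number of alternate alleles carried (0 if missing)."""
        if self.alleles is None:
            return 0
        return sum(1 for a in self.alleles if a >= 1)

    @property
    def carries_alt(self) -> bool:
        return self.n_alt > 0

    @property
    def is_het(self) -> bool:
        return (
            self.alleles is not None
            and len(self.alleles) == 2
            and self.n_alt == 1
        )

    @property
    def is_hom_alt(self) -> bool:
        return (
            self.alleles is not None
            and len(self.alleles) == 2
            and self.n_alt == 2
        )

    @property
    def is_hom_ref(self) -> bool:
        return self.alleles is not None and self.n_alt == 0

    @property
    def is_hemi_alt(self) -> bool:
        return (
            self.alleles is not None
            and len(self.alleles) == 1
            and self.alleles[0] >= 1
        )


_GT_RE = re.compile(r"^(\.|\d+)([/|](\.|\d+))?$")


def parse_genotype(gt_field: str, depth_field: str, sample_id: str = "") -> GenotypeCall:
    """Parse VCF GT/DP strings into a :class:`GenotypeCall`.

    Accepts diploid ("0/1", "1|1"), hemizygous single-allele ("1"), and
    missing ("./.", ".") genotypes. A missing genotype is encoded as missing,
    never as homozygous reference.
    """
    gt_field = gt_field.strip()
    m = _GT_RE.match(gt_field)
    if not m:
        raise FormatError(f"malformed GT field {gt_field!r} for sample {sample_id!r}")
    tokens = re.split(r"[/|]", gt_field)
    phased = "|" in gt_field
    if all(t == "." for t in tokens):
        alleles = None
        phased = False
    elif any(t == "." for t in tokens):
        # partially missing call: treat as missing (conservative)
        alleles = None
        phased = False
    else:
        alleles = tuple(int(t) for t in tokens)
    depth_field = (depth_field or "").strip()
    if depth_field in ("", "."):
        depth = None
    else:
        try:
            depth = int(depth_field)
        except ValueError as exc:
            raise FormatError(
                f"malformed DP field {depth_field!r} for sample {sample_id!r}"
            ) from exc
    return GenotypeCall(sample_id=sample_id, alleles=alleles, depth=depth, phased=phased)


def format_genotype(call: GenotypeCall) -> str:
    """Inverse of :func:`parse_genotype` on the GT component."""
    if call.alleles is None:
        return "./."
    sep = "|" if call.phased else "/"
    return sep.join(str(a) for a in call.alleles)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvSpan:
    start: int
    end: int
    dosage: Dosage

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("CNV span requires end > start")


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    cnv_span: Optional[CnvSpan] = None
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.variant_class is VariantClass.CNV and self.cnv_span is None:
            raise ValueError("CNV record requires cnv_span")
        if self.variant_class is VariantClass.SNV and (
            len(self.ref) != 1 or len(self.alt) != 1
        ):
            raise ValueError("SNV requires single-base ref and alt")

    @property
    def is_x(self) -> bool:
        return is_x_chromosome(self.chrom)

    def genotype(self, sample_id: str) -> Optional[GenotypeCall]:
        return self.genotypes.get(sample_id)


def variant_key(v: VariantRecord) -> tuple:
    """Identity key: equal keys <=> same variant.

    SNV/indel identity is (chrom, pos, ref, alt); CNV identity is
    (chrom, start, end, dosage). Zygosity never enters the key, so a
    homozygous and a heterozygous occurrence of the same allele share one key.
    """
    if v.variant_class is VariantClass.CNV:
        s = v.cnv_span
        return ("CNV", v.chrom, s.start, s.end, s.dosage.value)
    return ("SEQ", v.chrom, v.pos, v.ref, v.alt)


def format_variant_key(key: tuple) -> str:
    if key[0] == "CNV":
        _, chrom, start, end, dosage = key
        return f"{chrom}:{start}-{end}:{dosage}"
    _, chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}>{alt}"


# ---------------------------------------------------------------------------
# Population frequencies and annotations
# ---------------------------------------------------------------------------

#: frequency sources screened by the filters
FREQUENCY_SOURCES = ("CMG", "ESP5400", "1000G", "gnomAD", "ExAC", "internal")


@dataclass(frozen=True)
class SourceFrequency:
    maf: Optional[float] = None
    allele_count: Optional[int] = None
    hom_count: Optional[int] = None
    hemi_count: Optional[int] = None

    def __post_init__(self):
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"MAF {self.maf} outside [0, 1]")


@dataclass
class PopulationFrequencies:
    """Per-source MAF and allele/homozygote/hemizygote counts.

    Absent sources or absent fields mean "not observed"; the filtering layer
    treats absent as frequency 0 / count 0 so novel variants survive.
    """

    sources: dict = field(default_factory=dict)  # name -> SourceFrequency

    def max_maf(self) -> float:
        vals = [s.maf for s in self.sources.values() if s.maf is not None]
        return max(vals) if vals else 0.0

    def maf(self, source: str) -> float:
        rec = self.sources.get(source)
        return rec.maf if rec and rec.maf is not None else 0.0

    def allele_count(self, source: str) -> int:
        rec = self.sources.get(source)
        return rec.allele_count if rec and rec.allele_count is not None else 0

    def hom_count(self, source: str) -> int:
        rec = self.sources.get(source)
        return rec.hom_count if rec and rec.hom_count is not None else 0

    def hemi_count(self, source: str) -> int:
        rec = self.sources.get(source)
        return rec.hemi_count if rec and rec.hemi_count is not None else 0


@dataclass
class Annotation:
    gene: str
    transcript: str
    consequence: Consequence
    hgvs_c: str = ""
    hgvs_p: str = ""
    cadd: Optional[float] = None
    frequencies: PopulationFrequencies = field(default_factory=PopulationFrequencies)
    clinvar_id: Optional[str] = None
    clinvar_class: Optional[AcmgClass] = None
    resource_classes: tuple = ()
    genes_overlapped: tuple = ()  # CNVs only: all genes under the span

    def __post_init__(self):
        if self.cadd is not None and self.cadd < 0:
            raise ValueError("CADD score must be non-negative")


# ---------------------------------------------------------------------------
# Filter configuration
# ---------------------------------------------------------------------------

@dataclass
class FilterConfig:
    """Thresholds for the variant triage rules; defaults are the study's values.

    ``min_depth``: proband read support below which a call is discarded.
    ``recessive_maf_max``: strict upper MAF bound for recessive candidates
    (fail only when MAF > bound). ``recessive_homhemi_max``: recessive
    candidates are excluded when ExAC homozygote + hemizygote count reaches
    ``recessive_homhemi_max + 1`` (i.e. >= 10 with the default 9).
    ``dominant_maf_max`` / ``dominant_allele_count_max``: dominant-model MAF
    bound and gnomAD/internal allele-count bound (fail when count > bound).
    ``cohort_recurrence_max``: a variant seen in more unrelated probands than
    this is treated as a local artifact/polymorphism and excluded.
    """

    min_depth: int = 3
    recessive_maf_max: float = 0.005
    recessive_homhemi_max: int = 9
    dominant_maf_max: float = 0.001
    dominant_allele_count_max: int = 5
    cohort_recurrence_max: int = 1
    excluded_consequences: frozenset = frozenset(
        {
            Consequence.SYNONYMOUS,
            Consequence.DEEP_INTRONIC,
            Consequence.INTERGENIC,
            Consequence.UTR5,
            Consequence.UTR3,
        }
    )
    #: intronic distance (bp) beyond which a variant counts as deep intronic
    deep_intronic_bp: int = 20
    #: minimum shared HPO terms (after ancestor expansion) for panel membership
    min_term_overlap: int = 1
    #: screen heterozygous-female X candidates with the dominant thresholds
    xl_het_female_uses_dominant: bool = True
    #: apply the ExAC hom/hemi rule (kept on for the local phase as well)
    apply_exac_homhemi: bool = True
    #: require parental depth >= min_depth before asserting de novo
    de_novo_parent_min_depth: int = 3

    def __post_init__(self):
        if min(
            self.min_depth,
            self.recessive_maf_max,
            self.recessive_homhemi_max,
            self.dominant_maf_max,
            self.dominant_allele_count_max,
            self.cohort_recurrence_max,
        ) < 0:
            raise ValueError("filter thresholds must be non-negative")


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

@dataclass
class Family:
    """Proband plus available parents.

    The analysis strategy (trio/duo/solo) is derived from parent
    availability and can never be set independently.
    """

    family_id: str
    proband_id: str
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    proband_sex: Optional[Sex] = None
    affected: dict = field(default_factory=dict)  # sample_id -> bool

    @property
    def strategy(self) -> Strategy:
        n = (self.mother_id is not None) + (self.father_id is not None)
        return {2: Strategy.TRIO, 1: Strategy.DUO, 0: Strategy.SOLO}[n]

    @property
    def members(self) -> list:
        out = [self.proband_id]
        if self.mother_id:
            out.append(self.mother_id)
        if self.father_id:
            out.append(self.father_id)
        return out

    def is_affected(self, sample_id: str) -> bool:
        return bool(self.affected.get(sample_id, False))
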
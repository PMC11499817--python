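"""Readers and writers for the pipeline's external formats.

Formats handled: multi-sample VCF v4.2 (via pysam), 6-column PED pedigrees,
the annotation TSV (the neutral transport for per-variant annotations),
the BED-like CNV TSV, two-column phenotype TSV, the gene-disease map TSV,
OBO 1.2 ontologies (via obonet), and the JSON/TSV result report.

Readers reject malformed rows with errors carrying file/line provenance
rather than silently coercing them.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import obonet
import pysam

from .core import (
    AcmgClass,
    Annotation,
    CnvSpan,
    Consequence,
    Dosage,
    Family,
    FormatError,
    GenotypeCall,
    InheritanceMode,
    PopulationFrequencies,
    Sex,
    SourceFrequency,
    VariantClass,
    VariantRecord,
    format_genotype,
    variant_key,
)

# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _classify(ref: str, alt: str) -> VariantClass:
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    return VariantClass.INDEL


def read_vcf(path: str):
    """Read a multi-sample VCF into bi-allelic :class:`VariantRecord` objects.

    Multi-allelic sites are decomposed into one record per ALT allele; in a
    decomposed record, sample alleles equal to the kept ALT map to 1 and all
    other alleles map to 0. Records whose FORMAT lacks GT raise
    :class:`FormatError`; a missing DP leaves depth as ``None`` (the depth
    filter then treats it as failing).

    Returns ``(records, samples)`` with samples in file order.
    """
    records = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            alts = rec.alts or ()
            for k, alt in enumerate(alts, start=1):
                if alt is None or alt.startswith("<"):
                    continue  # symbolic alts (CNVs arrive via the CNV TSV)
                genotypes = {}
                for s in samples:
                    sample = rec.samples[s]
                    if "GT" not in sample:
                        raise FormatError(
                            f"{path}: record {rec.chrom}:{rec.pos} sample {s} has no GT"
                        )
                    gt = sample["GT"]
                    if gt is None or all(a is None for a in gt):
                        alleles = None
                    elif any(a is None for a in gt):
                        alleles = None
                    else:
                        alleles = tuple(1 if a == k else 0 for a in gt)
                    depth = sample.get("DP")
                    genotypes[s] = GenotypeCall(
                        sample_id=s,
                        alleles=alleles,
                        depth=depth,
                        phased=bool(getattr(sample, "phased", False)),
                    )
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        variant_class=_classify(rec.ref, alt),
                        genotypes=genotypes,
                    )
                )
    return records, samples


def write_vcf(records, samples, path: str) -> None:
    """Write bi-allelic records as a minimal VCF v4.2 text file."""
    contigs = []
    for r in records:
        if r.chrom not in contigs:
            contigs.append(r.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for r in sorted(records, key=lambda v: (contigs.index(v.chrom), v.pos)):
            cols = [r.chrom, str(r.pos), ".", r.ref, r.alt, ".", "PASS", ".", "GT:DP"]
            for s in samples:
                call = r.genotypes.get(s)
                if call is None:
                    cols.append("./.:.")
                else:
                    dp = "." if call.depth is None else str(call.depth)
                    cols.append(f"{format_genotype(call)}:{dp}")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------


def read_pedigree(path: str):
    """Parse a 6-column PED file into :class:`Family` objects.

    Parent id "0" means absent. The proband of each family is the affected
    individual with phenotype code 2 (the first such, if several). A proband
    with unknown sex is an error (X-linked logic needs it), as is a parent id
    that references no individual in the file.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(f"{path}:{ln}: expected 6 PED columns, got {len(parts)}")
            rows.append((ln, parts))

    ids = {p[1] for _, p in rows}
    by_family: dict = {}
    for ln, (fam, iid, father, mother, sex, pheno) in rows:
        for parent in (father, mother):
            if parent != "0" and parent not in ids:
                raise FormatError(f"{path}:{ln}: parent {parent!r} not in file")
        by_family.setdefault(fam, []).append((ln, iid, father, mother, sex, pheno))

    families = []
    for fam, members in by_family.items():
        affected = {iid: pheno == "2" for _, iid, _, _, _, pheno in members}
        # proband = first affected individual listed
        probands = [m for m in members if m[5] == "2"]
        if not probands:
            raise FormatError(f"{path}: family {fam} has no affected individual")
        ln, iid, father, mother, sex, _ = probands[0]
        if sex == "1":
            psex = Sex.MALE
        elif sex == "2":
            psex = Sex.FEMALE
        else:
            raise FormatError(f"{path}:{ln}: proband {iid} has unknown sex")
        families.append(
            Family(
                family_id=fam,
                proband_id=iid,
                mother_id=None if mother == "0" else mother,
                father_id=None if father == "0" else father,
                proband_sex=psex,
                affected=affected,
            )
        )
    return families


def write_pedigree(families, path: str) -> None:
    with open(path, "w") as fh:
        for fam in families:
            if fam.father_id:
                fh.write(f"{fam.family_id}\t{fam.father_id}\t0\t0\t1\t1\n")
            if fam.mother_id:
                fh.write(f"{fam.family_id}\t{fam.mother_id}\t0\t0\t2\t1\n")
            sex = "1" if fam.proband_sex is Sex.MALE else "2"
            fh.write(
                f"{fam.family_id}\t{fam.proband_id}\t{fam.father_id or 0}\t"
                f"{fam.mother_id or 0}\t{sex}\t2\n"
            )


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

REQUIRED_ANNOTATION_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "transcript",
    "consequence",
]

_FREQ_COLUMNS = {
    "CMG": ("maf_cmg", None, None, None),
    "ESP5400": ("maf_esp5400", None, None, None),
    "1000G": ("maf_1000g", None, None, None),
    "gnomAD": ("maf_gnomad", "ac_gnomad", None, None),
    "ExAC": ("maf_exac", "ac_exac", "hom_exac", "hemi_exac"),
    "internal": ("maf_internal", "ac_internal", None, None),
}

_CONSEQUENCES = {c.value: c for c in Consequence}
_CLASSES = {c.value: c for c in AcmgClass}


@dataclass
class AnnotationTable:
    """Map variant key -> annotations (one per transcript), with provenance."""

    entries: dict = field(default_factory=dict)  # key -> list[Annotation]
    provenance: dict = field(default_factory=dict)  # (key, transcript) -> (path, line)

    def get(self, key):
        return self.entries.get(key, [])

    def orphans(self, vcf_keys) -> list:
        """Keys present in the table but not among the VCF/CNV keys."""
        vcf_keys = set(vcf_keys)
        return [k for k in self.entries if k not in vcf_keys]


def _opt_float(cell: str, path: str, ln: int, col: str) -> Optional[float]:
    cell = (cell or "").strip()
    if cell in ("", ".", "NA"):
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise FormatError(f"{path}:{ln}: column {col!r}: not a number: {cell!r}") from exc


def _opt_int(cell: str, path: str, ln: int, col: str) -> Optional[int]:
    v = _opt_float(cell, path, ln, col)
    return None if v is None else int(v)


def read_annotations(path: str) -> AnnotationTable:
    """Read the per-variant annotation TSV.

    Absent numeric cells ("", ".", "NA") are parsed as absent, not zero; the
    filter layer applies the absent-means-zero convention. Unknown consequence
    tokens raise an error listing the accepted vocabulary.
    """
    table = AnnotationTable()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in REQUIRED_ANNOTATION_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise FormatError(f"{path}: missing annotation columns {missing}")
        for ln, row in enumerate(reader, start=2):
            cons_token = (row["consequence"] or "").strip()
            if cons_token not in _CONSEQUENCES:
                raise FormatError(
                    f"{path}:{ln}: unknown consequence {cons_token!r}; "
                    f"accepted: {sorted(_CONSEQUENCES)}"
                )
            sources = {}
            for name, (maf_c, ac_c, hom_c, hemi_c) in _FREQ_COLUMNS.items():
                vals = dict(
                    maf=_opt_float(row.get(maf_c, ""), path, ln, maf_c) if maf_c else None,
                    allele_count=_opt_int(row.get(ac_c, ""), path, ln, ac_c) if ac_c else None,
                    hom_count=_opt_int(row.get(hom_c, ""), path, ln, hom_c) if hom_c else None,
                    hemi_count=_opt_int(row.get(hemi_c, ""), path, ln, hemi_c) if hemi_c else None,
                )
                if any(v is not None for v in vals.values()):
                    sources[name] = SourceFrequency(**vals)
            clinvar_class = (row.get("clinvar_class") or "").strip() or None
            if clinvar_class is not None:
                if clinvar_class not in _CLASSES:
                    raise FormatError(f"{path}:{ln}: unknown ACMG class {clinvar_class!r}")
                clinvar_class = _CLASSES[clinvar_class]
            res_cell = (row.get("resource_classes") or "").strip()
            resource_classes = []
            if res_cell:
                for tok in res_cell.split(";"):
                    tok = tok.strip()
                    if tok not in _CLASSES:
                        raise FormatError(f"{path}:{ln}: unknown ACMG class {tok!r}")
                    resource_classes.append(_CLASSES[tok])
            ann = Annotation(
                gene=row["gene"].strip(),
                transcript=row["transcript"].strip(),
                consequence=_CONSEQUENCES[cons_token],
                hgvs_c=(row.get("hgvs_c") or "").strip(),
                hgvs_p=(row.get("hgvs_p") or "").strip(),
                cadd=_opt_float(row.get("cadd", ""), path, ln, "cadd"),
                frequencies=PopulationFrequencies(sources=sources),
                clinvar_id=(row.get("clinvar_id") or "").strip() or None,
                clinvar_class=clinvar_class,
                resource_classes=tuple(resource_classes),
            )
            key = ("SEQ", row["chrom"].strip(), int(row["pos"]), row["ref"].strip(), row["alt"].strip())
            table.entries.setdefault(key, []).append(ann)
            table.provenance[(key, ann.transcript)] = (path, ln)
    return table


ANNOTATION_COLUMNS = REQUIRED_ANNOTATION_COLUMNS + [
    "hgvs_c",
    "hgvs_p",
    "cadd",
    "clinvar_id",
    "clinvar_class",
    "resource_classes",
    "maf_cmg",
    "maf_esp5400",
    "maf_1000g",
    "maf_gnomad",
    "ac_gnomad",
    "maf_exac",
    "ac_exac",
    "hom_exac",
    "hemi_exac",
    "maf_internal",
    "ac_internal",
]


# ---------------------------------------------------------------------------
# CNV table
# ---------------------------------------------------------------------------


def read_cnvs(path: str):
    """Read pre-called CNVs from a BED-like TSV.

    Columns: sample_id, chrom, start, end (1-based inclusive), dosage
    (DEL/DUP), zygosity (het/hom/hem), genes (semicolon-separated),
    clinvar_id, clinvar_class, resource_classes. One row per carrier sample;
    rows with identical span are merged into one record with one genotype per
    carrier.

    Returns ``(records, annotations)`` where annotations maps the CNV key to
    a list with one :class:`Annotation` (consequence cnv_loss/cnv_gain).
    """
    records: dict = {}
    annotations: dict = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for ln, row in enumerate(reader, start=2):
            try:
                dosage = Dosage[row["dosage"].strip().upper()]
            except KeyError as exc:
                raise FormatError(f"{path}:{ln}: unknown dosage {row['dosage']!r}") from exc
            chrom = row["chrom"].strip()
            span = CnvSpan(start=int(row["start"]), end=int(row["end"]), dosage=dosage)
            key = ("CNV", chrom, span.start, span.end, dosage.value)
            zyg = row.get("zygosity", "het").strip().lower()
            alleles = {"het": (0, 1), "hom": (1, 1), "hem": (1,), "ref": (0, 0)}.get(zyg)
            if alleles is None:
                raise FormatError(f"{path}:{ln}: unknown zygosity {row['zygosity']!r}")
            if key not in records:
                records[key] = VariantRecord(
                    chrom=chrom,
                    pos=span.start,
                    ref="N",
                    alt=f"<{dosage.value}>",
                    variant_class=VariantClass.CNV,
                    cnv_span=span,
                )
                genes = tuple(
                    g.strip() for g in (row.get("genes") or "").split(";") if g.strip()
                )
                clinvar_class = (row.get("clinvar_class") or "").strip() or None
                if clinvar_class is not None:
                    clinvar_class = _CLASSES[clinvar_class]
                res = tuple(
                    _CLASSES[t.strip()]
                    for t in (row.get("resource_classes") or "").split(";")
                    if t.strip()
                )
                annotations[key] = [
                    Annotation(
                        gene=genes[0] if genes else f"{chrom}:{span.start}-{span.end}",
                        transcript=".",
                        consequence=(
                            Consequence.CNV_LOSS
                            if dosage is Dosage.DEL
                            else Consequence.CNV_GAIN
                        ),
                        clinvar_id=(row.get("clinvar_id") or "").strip() or None,
                        clinvar_class=clinvar_class,
                        resource_classes=res,
                        genes_overlapped=genes,
                    )
                ]
            records[key].genotypes[row["sample_id"].strip()] = GenotypeCall(
                sample_id=row["sample_id"].strip(), alleles=alleles, depth=None
            )
    return list(records.values()), annotations


# ---------------------------------------------------------------------------
# Phenotypes and gene-disease map
# ---------------------------------------------------------------------------


def read_phenotypes(path: str) -> dict:
    """Two-column TSV (proband_id, HPO id) -> dict proband_id -> set of terms."""
    out: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("proband_id"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 columns")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


@dataclass(frozen=True)
class GeneDiseaseEntry:
    gene: str
    omim_id: str
    label: str
    inheritance: tuple  # one or more InheritanceMode values
    hpo_terms: frozenset


_MODES = {m.value: m for m in InheritanceMode}


def parse_inheritance(token: str) -> tuple:
    """Parse an inheritance cell such as "AD", "AR;DD" or "XLD;XLR"."""
    modes = []
    for t in token.replace(",", ";").split(";"):
        t = t.strip()
        if not t:
            continue
        if t not in _MODES:
            raise FormatError(f"unknown inheritance mode {t!r}; accepted: {sorted(_MODES)}")
        modes.append(_MODES[t])
    if not modes:
        raise FormatError("empty inheritance mode")
    return tuple(modes)


def read_gene_map(path: str):
    """Gene-disease-inheritance TSV: gene, omim_id, label, inheritance, hpo_ids."""
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for ln, row in enumerate(reader, start=2):
            try:
                modes = parse_inheritance(row["inheritance"])
            except FormatError as exc:
                raise FormatError(f"{path}:{ln}: {exc}") from exc
            terms = frozenset(
                t.strip() for t in (row.get("hpo_ids") or "").split(";") if t.strip()
            )
            entries.append(
                GeneDiseaseEntry(
                    gene=row["gene"].strip(),
                    omim_id=row["omim_id"].strip(),
                    label=(row.get("label") or "").strip(),
                    inheritance=modes,
                    hpo_terms=terms,
                )
            )
    return entries


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------

PHENOTYPIC_ABNORMALITY_ROOT = "HP:0000118"


@dataclass
class OntologyGraph:
    """Phenotype ontology restricted to is_a edges, child -> parent direction."""

    graph: nx.DiGraph
    root: str = PHENOTYPIC_ABNORMALITY_ROOT

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def ancestors(self, term: str) -> set:
        """All is_a ancestors of ``term`` (term itself excluded)."""
        return nx.descendants(self.graph, term)

    def systems(self) -> set:
        """Depth-1 children of the phenotypic-abnormality root."""
        return set(self.graph.predecessors(self.root))

    def disconnected(self) -> set:
        """Non-root terms with no path to the root."""
        under = nx.ancestors(self.graph, self.root)
        return {t for t in self.graph if t != self.root and t not in under}


def read_ontology(path: str, root: str = PHENOTYPIC_ABNORMALITY_ROOT) -> OntologyGraph:
    """Load an OBO 1.2 ontology and keep id/name/is_a of non-obsolete terms.

    obonet orients edges child -> parent. Cycles are a hard error naming the
    offending cycle.
    """
    multi = obonet.read_obo(path)
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        if data.get("is_obsolete") == "true":
            continue
        g.add_node(node, name=data.get("name", node))
    for child, parent, edge_key in multi.edges(keys=True):
        if edge_key != "is_a":
            continue
        if child in g and parent in g:
            g.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise FormatError(f"{path}: ontology contains a cycle: {cycle}")
    if root not in g:
        raise FormatError(f"{path}: phenotypic-abnormality root {root} absent")
    return OntologyGraph(graph=g, root=root)


def write_obo(terms, path: str) -> None:
    """Write [Term] stanzas; ``terms`` is a list of (id, name, [parent ids])."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-mini-hpo\n\n")
        for tid, name, parents in terms:
            fh.write("[Term]\n")
            fh.write(f"id: {tid}\n")
            fh.write(f"name: {name}\n")
            for p in parents:
                fh.write(f"is_a: {p}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "proband_id",
    "strategy",
    "category",
    "informative",
    "gene",
    "variant",
    "hgvs_c",
    "hgvs_p",
    "zygosity",
    "origin",
    "model",
    "interpretation",
    "interpretation_source",
    "omim_phenotype",
    "omim_inheritance",
]


def write_report(records, path_prefix: str) -> None:
    """Write classified results as ``<prefix>.json`` and ``<prefix>.tsv``.

    One TSV row per informative candidate (or a single row for a proband with
    none); the JSON mirrors the full record structure.
    """
    payload = [r.to_dict() for r in records]
    os.makedirs(os.path.dirname(path_prefix) or ".", exist_ok=True)
    with open(path_prefix + ".json", "w") as fh:
        json.dump(payload, fh, indent=2)
    with open(path_prefix + ".tsv", "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(REPORT_COLUMNS)
        for rec in payload:
            if not rec["candidates"]:
                writer.writerow(
                    [rec["proband_id"], rec["strategy"], rec["category"],
                     rec["informative"]] + [""] * (len(REPORT_COLUMNS) - 4)
                )
                continue
            for c in rec["candidates"]:
                writer.writerow(
                    [
                        rec["proband_id"],
                        rec["strategy"],
                        rec["category"],
                        rec["informative"],
                        c["gene"],
                        c["variant"],
                        c["hgvs_c"],
                        c["hgvs_p"],
                        c["zygosity"],
                        c["origin"],
                        c["model"],
                        c["interpretation"],
                        c["interpretation_source"],
                        c["omim_phenotype"],
                        c["omim_inheritance"],
                    ]
                )
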
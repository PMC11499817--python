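"""HPO-driven virtual gene panels, phenotype-consistency checks, and the
organ-system grouping of phenotype terms.

A "system" is a depth-1 child of the phenotypic-abnormality root of the
ontology; a term belongs to every system branch it descends from (multi-
parent terms can map to several). Panels are built by set overlap between a
proband's ancestor-expanded term set and each disease entry's ancestor-
expanded term set; no semantic-similarity scoring is involved. The root term
itself never counts as shared (a root-only match is vacuous).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core import FilterConfig, Sex
from .io import GeneDiseaseEntry, OntologyGraph


@dataclass
class ProbandPhenotype:
    proband_id: str
    terms: frozenset
    sex: Optional[Sex] = None
    age_years: Optional[float] = None
    care: Optional[str] = None  # "public" | "private"
    provider_in_capital: Optional[bool] = None
    congenital_anomalies: bool = False
    neurological: bool = False
    immune: bool = False

    def __post_init__(self):
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age must be non-negative")


@dataclass
class SystemProfile:
    proband_id: str
    systems: frozenset

    @property
    def n_systems(self) -> int:
        return len(self.systems)


def validate_terms(terms, ontology: OntologyGraph) -> None:
    unknown = sorted(t for t in terms if t not in ontology)
    if unknown:
        raise ValueError(f"unknown ontology terms: {unknown}")


def term_to_systems(term: str, ontology: OntologyGraph) -> frozenset:
    """Map a term to the system branches it belongs to.

    Returns the depth-1 children of the root that are ancestors of (or equal
    to) the term; empty (with no error) when the term does not descend from
    the phenotypic-abnormality root.
    """
    if term not in ontology:
        raise KeyError(f"term {term} not in ontology")
    lineage = ontology.ancestors(term) | {term}
    return frozenset(lineage & ontology.systems())


def count_affected_systems(phenotype: ProbandPhenotype, ontology: OntologyGraph) -> SystemProfile:
    """Union of per-term system memberships over all of a proband's terms."""
    systems = frozenset()
    for t in sorted(phenotype.terms):
        systems |= term_to_systems(t, ontology)
    return SystemProfile(proband_id=phenotype.proband_id, systems=systems)


def _expanded(terms, ontology: OntologyGraph) -> set:
    """Ancestor closure of a term set, stopping below the root (the root is
    excluded so it can never constitute a match)."""
    out = set()
    for t in terms:
        if t not in ontology:
            continue
        out.add(t)
        out |= ontology.ancestors(t)
    out.discard(ontology.root)
    # anything above the root (ontology super-root) is equally vacuous
    out -= ontology.ancestors(ontology.root) if ontology.root in ontology.graph else set()
    return out


def term_overlap(proband_terms, entry_terms, ontology: OntologyGraph) -> int:
    """Number of shared terms after ancestor expansion of both sides."""
    return len(_expanded(proband_terms, ontology) & _expanded(entry_terms, ontology))


def build_virtual_panel(
    phenotype: ProbandPhenotype,
    gene_map,
    ontology: OntologyGraph,
    cfg: FilterConfig,
):
    """Rank genes whose disease annotations overlap the proband's terms.

    A gene enters the panel when at least one of its disease entries shares
    >= ``cfg.min_term_overlap`` expanded terms with the proband. With
    ``min_term_overlap = 0`` the panel is phenotypically unbiased and equals
    all mapped genes (the second-pass analysis). Ranking: best overlap count
    descending, gene symbol ascending on ties.

    Returns an ordered list of ``(gene, best_overlap)`` tuples.
    """
    best: dict = {}
    for entry in gene_map:
        ov = term_overlap(phenotype.terms, entry.hpo_terms, ontology)
        if ov >= cfg.min_term_overlap:
            if entry.gene not in best or ov > best[entry.gene]:
                best[entry.gene] = ov
    return sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))


def phenotype_consistent(
    gene: str,
    phenotype: ProbandPhenotype,
    gene_map,
    ontology: OntologyGraph,
    cfg: FilterConfig,
):
    """Decide whether a gene is consistent with the proband's phenotype.

    True iff the gene has at least one disease entry passing the panel
    overlap rule for this proband; the best-matching entry (carrying its
    inheritance mode) is returned for downstream categorization.

    Returns ``(bool, matched_entry_or_None, reason)``.
    """
    entries = [e for e in gene_map if e.gene == gene]
    if not entries:
        return False, None, "gene not in map"
    best_entry, best_ov = None, -1
    for entry in entries:
        ov = term_overlap(phenotype.terms, entry.hpo_terms, ontology)
        if ov > best_ov:
            best_entry, best_ov = entry, ov
    if best_ov >= max(cfg.min_term_overlap, 1):
        return True, best_entry, "overlap"
    return False, None, "no term overlap"
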
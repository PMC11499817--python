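# Methods

## Scope and model of the analysis

`raredx` models the desk phase of rare-disease exome diagnosis for one
cohort of families. Sequencing, alignment, variant calling and annotation
are upstream and out of scope: variants arrive as multi-sample VCFs (one per
family), annotations as a neutral TSV keyed by (chrom, pos, ref, alt), and
CNVs as pre-called intervals in a BED-like TSV. The pipeline's own job is
triage (technical, frequency and recurrence screens), inheritance-model
candidate generation, phenotype matching, consensus interpretation,
per-proband categorization, and cohort statistics.

Conventions: coordinates are 1-based inclusive (VCF), CNV spans likewise;
multi-allelic sites are decomposed to bi-allelic records before any rule is
applied (every rule is per-allele); a male X call is a single-allele
hemizygous genotype; a missing genotype is missing, never hom-ref.

## Triage rules and their parameters

All thresholds live in `FilterConfig` and are overridable; defaults are the
study conditions the package emulates.

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 3 reads | proband calls with fewer reads are discarded; unknown depth fails (conservative) |
| `excluded_consequences` | synonymous, deep intronic, intergenic, 5'/3'UTR | consequence classes never reviewed |
| `recessive_maf_max` | 0.005 | strict bound; fail only when MAF > 0.005 in any source |
| `recessive_homhemi_max` | 9 | ExAC homozygote + hemizygote count ≥ 10 fails |
| `dominant_maf_max` | 0.001 | strict bound, any source |
| `dominant_allele_count_max` | 5 | gnomAD or internal allele count > 5 fails |
| `cohort_recurrence_max` | 1 | seen in ≥ 2 unrelated probands fails |
| `deep_intronic_bp` | 20 bp | operational cutoff between near-splice (kept) and deep intronic (excluded); the source protocol names no number, so this is an explicit, documented choice |
| `min_term_overlap` | 1 term | panel membership threshold after ancestor expansion; 0 = phenotypically unbiased pass |
| `de_novo_parent_min_depth` | 3 reads | parental coverage required before asserting de novo (dropout guard; the original protocol reports "confirmed de novo" without stating criteria) |

Design choices the rules leave open, resolved as follows:

- **MAF across sources** uses the maximum (exclusion if *any* database
  exceeds the bound) — the conservative reading of "within the databases".
- **Absent frequency/count = 0 at filter time** so that variants never seen
  in any reference survive; at the I/O layer absence stays `None` so the
  two meanings are not conflated.
- **X-linked frequency rule**: the protocol runs an XL model but does not
  say which frequency thresholds apply. Hemizygous/homozygous X genotypes
  are screened with the recessive thresholds, heterozygous female X
  genotypes with the dominant thresholds (configurable).
- **CNVs** have no MAF semantics in the SNV reference databases, so they
  skip the frequency screens and are screened by consequence, cohort
  recurrence and panel overlap only; they also skip the read-depth rule.
- **The ExAC hom/hemi rule is kept on** in all configurations ("the same
  frequency filters" reading), with a flag to disable it.
- **CADD is never a hard filter**: candidates are ranked by CADD descending
  (absent CADD last, ties by position), mirroring its manual-review role.
- **Transcript choice**: when a variant annotates to several transcripts,
  the most severe consequence wins, ties by transcript id.

## Inheritance models

Review order is AR (homozygous, then compound heterozygous), AD, XL; a
variant eligible under two models is attributed to the first and the
alternative recorded. De novo status requires a trio, both parental
genotypes present with depth ≥ 3, and the allele absent from both parents;
a duo can never assert de novo (a variant absent in the single available
parent is origin-unknown). Compound heterozygotes require trans phase in
trios (one maternal, one paternal allele); duo/solo same-gene het pairs are
emitted unphased with origin unknown. A heterozygous SNV plus a deletion
CNV from the other parent overlapping the same gene forms a
comphet-with-CNV pair (the proband is effectively hemizygous). Homozygous
probands with a confidently hom-ref parent are Mendelian errors: excluded
and counted, not reported. Both-parents-carrier heterozygous sites have
ambiguous phase and get origin unknown; biparental is asserted only for
homozygous/hemizygous genotypes.

## Phenotype matching

"Systems" are the depth-1 children of the phenotypic-abnormality root of
the ontology; a term belongs to every system branch it descends from.
Virtual panels are ancestor-expanded set overlap between proband terms and
disease-entry terms — deliberately not semantic similarity (no
Resnik/Lin, no probabilistic phenotype matching), because the emulated
workflow used panel construction by association, with expert review
downstream. The root never counts as shared (vacuous). The
phenotype-consistency call used for "informative" is the same overlap rule
with threshold ≥ 1; this is a formalization of what was, in the original
workflow, expert adjudication — the package makes the rule explicit and
configurable rather than pretending to reproduce judgment.

## Interpretation and categories

Consensus: ClinVar verbatim when present, else the modal class among the
interpretation resources, ties resolving to VUS (clinically conservative
and deterministic). LB/B candidates are dropped before categorization.
Categories are ordered uninformative < partially informative < suggestive <
solved, and class upgrades can only move a record rightward (a property the
test suite checks exhaustively on single-gene layouts).

Solved requires an inheritance-mode genotype requirement met *entirely* by
P/LP alleles; in particular a recessive genotype with one P and one VUS
allele is suggestive, not solved. This is the unique reading that
reproduces the published solved split (31 solved: 23 AD, 4 AR, 4 XL) from
the encoded variant table, including the thymidine-kinase comphet case
(P + VUS) landing outside solved. A proband with informative candidates in
several genes (dual diagnosis) takes the maximum category over genes and
reports all contributing genes.

The suggestive vs partially-informative boundary is only mechanically
recoverable for single-allele recessive cases; the published table yields
exactly one such case, while the narrative reports three "partially
informative" probands. The extra two are not recoverable from printed
fields, so that boundary is excluded from reproduction checks.

## Cohort statistics

Detection rates are computed per analysis stratum (CES, ES-solo, ES-duo,
ES-trio) with re-sequenced probands contributing one row per analysis; the
total row uses distinct probands. Percentages are printed to one decimal,
half-up. The source tables round inconsistently (e.g. 9/19 appears as both
47.5% and 47.3%; 26/55 as both 47.2% and 47.3%), so counts are treated as
authoritative and recomputed percentages may differ from a printed value by
0.1 point.

Age groups are half-open [0, 12), [12, 18), [18, 52] with childhood as
reference; the printed group ranges overlap at the boundaries, so the
convention is explicit and configurable. The yield regression is a binomial
GLM with logit link; odds ratios are exponentiated coefficients with Wald
95% CIs (deterministic, matching the default of the stated computation
route; not profile likelihood). Perfect separation or a constant outcome is
reported as a per-model failure object, never an exception. The published
regression table itself is *not* a reproduction target: it requires
per-proband covariates for all 103 probands, which are not printed; the
regression is validated instead by parameter recovery on synthetic cohorts
(a known OR of 3.5 on the adolescent age group is covered by the 95% CI in
≈95% of replicates at n = 2000).

## The synthetic cohort generator

The generator emulates the study conditions: 71 trios : 7 duos : 19 solos
(rescalable), ~300 rare annotated variants per exome surviving annotation,
a planted causal variant with probability 0.456 per proband, planted modes
distributed as AD de novo 0.38, AD inherited 0.13, AR homozygous 0.14, AR
compound-het 0.14, XLR 0.08, XLD 0.04, CNV deletion 0.09 (chosen so the de
novo share of causal variants is ≈45% and the CNV share ≈9%, the observed
splits), and classes P 0.22 / LP 0.38 / VUS 0.40 (the observed class mix of
informative variants). Per-proband affected-system counts are
2 + Binomial(9, 0.45): median 6, range 2–11. The seed fully determines
every output byte.

Construction guarantees, checked by tests: every background variant fails
at least one stated rule (50% common MAF, 25% excluded consequence, 10% low
depth, 15% dominant-only frequency excess) or lies in a gene absent from
the disease map; ten shared recurrent sites are carried (maternally
inherited) by every proband to exercise the recurrence filter; planted
variants pass every rule for their mode and their gene's disease terms seed
the proband's phenotype; parental genotypes are Mendelian-consistent except
at planted de novo sites. The miniature ontology (50 terms: 12 system
branches with 3 leaves each, one multi-parent leaf per branch) and the
38-gene disease map are written as fixtures; real HPO/OMIM files are
drop-in replacements.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level errors and coverage structure (depths
are drawn uniformly, dropout is not modeled beyond the planted low-depth
class), linkage disequilibrium and haplotype structure, population
substructure and relatedness beyond declared families, annotation errors
and transcript ambiguity, incomplete penetrance, mosaicism, imprinting, and
phenotype noise beyond random extra system terms. Recall of 1.0 on planted
variants demonstrates internal consistency of rules and generator, not
sensitivity on real exomes.

## Numerical and degenerate-input choices

Percentages: `Decimal` half-up at one decimal. Regression: statsmodels GLM
defaults (IRLS), non-finite or huge (> 10³) standard errors reported as
separation failures. Candidate ranking ties break by (chrom, pos);
panel ranking ties break by gene symbol. Empty variant lists, empty term
sets, header-only reports and single-row cohorts are all defined, tested
cases. Readers reject malformed rows with file/line provenance rather than
coercing.

## Reproduction inputs

Two packaged fixtures encode published per-variant and per-analysis tables
as data: `informative_variants.tsv` (55 rows; SNV coordinates are synthetic
placeholders since the source prints HGVS only — chromosomes are real so
X-linkage logic is exercised, CNV spans are as printed) and
`strategy_analyses.tsv` (113 rows; proband ids are synthetic since only
stratum counts are printed). The acceptance script recomputes all headline
quantities from these fixtures plus a fresh 500-family simulation; fixture
categories and tallies are produced by the classifier at run time, not read
from the files.

## Known limitations

Phenotype consistency is a set-overlap proxy for expert judgment; the
suggestive/partial boundary is under-determined (above); duo analyses
accept either parent although the emulated cohort's duos were
proband-mother; CNV genotypes carry no quality model; the decomposed
representation maps other-alt alleles of a multi-allelic site to the
reference in each bi-allelic record, which is adequate for triage but loses
the joint genotype.
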
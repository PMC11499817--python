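"""Cohort-level statistics: detection rates by strategy, informative-variant
tallies, demographic summaries, and the diagnostic-yield logistic regressions.

Percentages are reported to one decimal place with half-up rounding.
Regressions are binomial GLMs (logit link) with Wald 95% confidence
intervals; odds ratios are exponentiated coefficients. Age groups are
half-open [0, 12), [12, 18), [18, 52] with childhood as the reference level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import VariantClass, Origin
from .interpret import Category

STRATEGY_LABELS = ("CES", "ES-Solo", "ES-Duo", "ES-Trio")
ES_LABELS = ("ES-Solo", "ES-Duo", "ES-Trio")

AGE_GROUP_EDGES = (0.0, 12.0, 18.0, 52.0)
AGE_GROUP_LABELS = ("0-12", "12-18", "18-52")


def pct(numerator: int, denominator: int) -> float:
    """Percentage to one decimal, half-up; 0.0 for an empty denominator."""
    if denominator == 0:
        return 0.0
    frac = Decimal(numerator) / Decimal(denominator) * 100
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def age_group(age_years: float) -> str:
    """Half-open childhood/adolescence/adulthood bins."""
    if age_years < AGE_GROUP_EDGES[1]:
        return AGE_GROUP_LABELS[0]
    if age_years < AGE_GROUP_EDGES[2]:
        return AGE_GROUP_LABELS[1]
    return AGE_GROUP_LABELS[2]


# ---------------------------------------------------------------------------
# Detection rates (strategy table)
# ---------------------------------------------------------------------------


def detection_rates(analyses) -> pd.DataFrame:
    """Per-strategy yield table from per-analysis outcome rows.

    ``analyses`` is an iterable of ``(strategy_label, proband_id,
    informative)`` rows; a proband re-sequenced under a second strategy
    contributes one row per analysis. Per-stratum percentages are informative
    analyses over analyses in the stratum; the ES subtotal pools the three ES
    designs; the total row reports distinct informative probands over
    distinct probands.
    """
    rows = list(analyses)
    for label, _, _ in rows:
        if label not in STRATEGY_LABELS:
            raise ValueError(f"unknown strategy label {label!r}; accepted: {STRATEGY_LABELS}")
    out = []
    for label in STRATEGY_LABELS:
        sub = [r for r in rows if r[0] == label]
        n_inf = sum(1 for r in sub if r[2])
        out.append((label, len(sub), n_inf, pct(n_inf, len(sub))))
    es = [r for r in rows if r[0] in ES_LABELS]
    es_inf = sum(1 for r in es if r[2])
    out.insert(1, ("ES", len(es), es_inf, pct(es_inf, len(es))))
    probands = {r[1] for r in rows}
    inf_probands = {r[1] for r in rows if r[2]}
    out.append(("Total", len(rows), len(inf_probands), pct(len(inf_probands), len(probands))))
    df = pd.DataFrame(out, columns=["strategy", "n_analyses", "n_informative", "percent"])
    return df


def participant_count(analyses) -> int:
    """Sequenced individuals implied by the ES designs: 3 per trio, 2 per
    duo, 1 per solo analysis (CES analyses reuse the proband's sample and
    add none)."""
    per = {"ES-Trio": 3, "ES-Duo": 2, "ES-Solo": 1}
    return sum(per.get(label, 0) for label, _, _ in analyses)


# ---------------------------------------------------------------------------
# Informative-variant tallies
# ---------------------------------------------------------------------------


def variant_tallies(results) -> dict:
    """Distinct informative variants across classified results.

    A variant key is counted once however often it occurs (a homozygote is
    one variant). Origins partition into de novo / inherited (maternal,
    paternal, biparental) / unknown; novelty is ClinVar-listing of the
    annotation. Percentages use the distinct-variant denominator.
    """
    seen: dict = {}
    for rec in results:
        for a in rec.candidates:
            seen.setdefault(a.candidate.key, a)
    n = len(seen)
    n_cnv = sum(1 for k in seen if k[0] == "CNV")
    n_dn = sum(1 for a in seen.values() if a.candidate.origin is Origin.DE_NOVO)
    n_unknown = sum(1 for a in seen.values() if a.candidate.origin is Origin.UNKNOWN)
    n_inherited = n - n_dn - n_unknown
    n_clinvar = sum(1 for a in seen.values() if a.candidate.annotation.clinvar_id)
    return {
        "n_distinct": n,
        "n_snv": n - n_cnv,
        "n_cnv": n_cnv,
        "n_de_novo": n_dn,
        "n_inherited": n_inherited,
        "n_unknown_origin": n_unknown,
        "n_clinvar_listed": n_clinvar,
        "n_novel": n - n_clinvar,
        "pct_de_novo": pct(n_dn, n),
        "pct_inherited": pct(n_inherited, n),
        "pct_clinvar_listed": pct(n_clinvar, n),
        "pct_novel": pct(n - n_clinvar, n),
    }


def category_counts(results) -> dict:
    """Per-category proband counts plus the solved-mode split."""
    counts = {c.label: 0 for c in Category}
    solved_split = {"AD": 0, "AR": 0, "XL": 0}
    for rec in results:
        counts[rec.category.label] += 1
        if rec.category is Category.SOLVED and rec.solved_mode_group:
            solved_split[rec.solved_mode_group] += 1
    counts["informative"] = sum(1 for r in results if r.informative)
    counts["solved_split"] = solved_split
    return counts


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------


def demographics_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts, age median/IQR/range and care-type counts by sex and total.

    Expects columns sex ("male"/"female"), age_years, care
    ("public"/"private"), provider_in_capital (bool).
    """
    def summarize(sub: pd.DataFrame, label: str) -> dict:
        ages = sub["age_years"].dropna()
        return {
            "group": label,
            "n": len(sub),
            "pct": pct(len(sub), len(cohort)),
            "age_median": float(ages.median()) if len(ages) else np.nan,
            "age_iqr": float(ages.quantile(0.75) - ages.quantile(0.25)) if len(ages) else np.nan,
            "age_min": float(ages.min()) if len(ages) else np.nan,
            "age_max": float(ages.max()) if len(ages) else np.nan,
            "n_public_care": int((sub["care"] == "public").sum()),
            "n_provider_in_capital": int(sub["provider_in_capital"].fillna(False).sum()),
        }

    rows = [
        summarize(cohort[cohort["sex"] == "male"], "male"),
        summarize(cohort[cohort["sex"] == "female"], "female"),
        summarize(cohort, "total"),
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Diagnostic-yield regression
# ---------------------------------------------------------------------------

COVARIATES = (
    "sex_male",
    "age_years",
    "age_12_18",
    "age_18_52",
    "care_private",
    "neurological",
    "immune",
    "congenital_anomalies",
    "n_systems",
)

#: covariates fitted jointly in one bivariate model (age-group indicators)
_BIVARIATE_BLOCKS = (
    ("sex_male",),
    ("age_years",),
    ("age_12_18", "age_18_52"),
    ("care_private",),
    ("neurological",),
    ("immune",),
    ("congenital_anomalies",),
    ("n_systems",),
)


@dataclass
class RegressionResult:
    variable: str
    model: str  # "bivariate" | "multivariate"
    odds_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    p_value: Optional[float] = None
    error: Optional[str] = None


def build_cohort_table(phenotypes, profiles, results, strategies=None) -> pd.DataFrame:
    """Assemble the per-proband covariate/outcome table.

    ``phenotypes`` are :class:`~raredx.phenotypes.ProbandPhenotype` records,
    ``profiles`` map proband_id -> SystemProfile, ``results`` map
    proband_id -> ResultRecord. The age group is always derived from age,
    never stored independently.
    """
    rows = []
    for ph in phenotypes:
        rec = results.get(ph.proband_id)
        grp = age_group(ph.age_years) if ph.age_years is not None else None
        rows.append(
            {
                "proband_id": ph.proband_id,
                "sex": ph.sex.value if ph.sex else None,
                "sex_male": int(ph.sex is not None and ph.sex.value == "male"),
                "age_years": ph.age_years,
                "age_group": grp,
                "age_12_18": int(grp == "12-18"),
                "age_18_52": int(grp == "18-52"),
                "care": ph.care,
                "care_private": int(ph.care == "private"),
                "provider_in_capital": ph.provider_in_capital,
                "n_systems": profiles[ph.proband_id].n_systems if ph.proband_id in profiles else None,
                "congenital_anomalies": int(ph.congenital_anomalies),
                "neurological": int(ph.neurological),
                "immune": int(ph.immune),
                "strategy": strategies.get(ph.proband_id) if strategies else None,
                "informative": int(rec.informative) if rec is not None else 0,
            }
        )
    return pd.DataFrame(rows)


def _fit_logit(cohort: pd.DataFrame, variables, tag: str):
    y = cohort["informative"].astype(float)
    X = sm.add_constant(cohort[list(variables)].astype(float), has_constant="add")
    out = []
    if y.nunique() < 2:
        return [
            RegressionResult(v, tag, error="outcome has a single class (separation)")
            for v in variables
        ]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        ci = res.conf_int()
        for v in variables:
            se_ok = np.isfinite(res.bse[v]) and res.bse[v] < 1e3
            if not se_ok:
                out.append(RegressionResult(v, tag, error="non-finite standard error (separation)"))
                continue
            out.append(
                RegressionResult(
                    variable=v,
                    model=tag,
                    odds_ratio=float(np.exp(res.params[v])),
                    ci_low=float(np.exp(ci.loc[v, 0])),
                    ci_high=float(np.exp(ci.loc[v, 1])),
                    p_value=float(res.pvalues[v]),
                )
            )
    except Exception as exc:  # perfect separation, singular design, ...
        out = [RegressionResult(v, tag, error=f"fit failed: {exc}") for v in variables]
    return out


def fit_yield_models(cohort: pd.DataFrame):
    """Bivariate models per covariate block plus one multivariate model.

    Returns a flat list of :class:`RegressionResult`; models that cannot be
    fitted (perfect separation, constant outcome) are reported as failures
    with a diagnostic rather than raised.
    """
    results = []
    for block in _BIVARIATE_BLOCKS:
        results.extend(_fit_logit(cohort, block, "bivariate"))
    results.extend(_fit_logit(cohort, COVARIATES, "multivariate"))
    return results


def regression_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": r.variable,
                "model": r.model,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "error": r.error,
            }
            for r in results
        ]
    )
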
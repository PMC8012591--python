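"""Discovery/replication differential testing with confounder adjustment.

The cascade: per-metabolite two-sided Mann-Whitney U tests in an independent
discovery and replication cohort, Bonferroni control at alpha/m in each, a
direction-consistency requirement across the two cohorts, an ordinary
least-squares confounder adjustment (age, sex, ethnicity, BMI, preserved
renal/liver function indicators, drug-class indicators) on the survivors,
and finally specificity tiering against the disease comparator groups
(DC, CTED, IPAH/HPAH).
"""
from __future__ import annotations

import itertools
import logging
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io import MetaboliteMatrix, SampleMetadata
from .synth import DRUG_COLUMNS

log = logging.getLogger(__name__)

TIERS = ("none", "vs_HC_only", "vs_HC_DC", "vs_HC_DC_CTED", "vs_all_including_IPAH")

#: creatinine / bilirubin cut-offs defining preserved renal / liver function
CREATININE_CUTOFF = 75.0   # umol/L
BILIRUBIN_CUTOFF = 21.0    # umol/L

_EXACT_PRODUCT_LIMIT = 400
_ENUM_LIMIT = 300_000


def mann_whitney(group_a, group_b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U, p, AUC)``.

    U counts (a > b) pairs plus half-ties, so ``AUC = U / (n1*n2)`` is the
    probability a random case exceeds a random control.  The p-value is
    exact (full enumeration of the permutation distribution) for small
    problems and otherwise uses the tie-corrected normal approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 1 or n2 < 1:
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    auc = u / (n1 * n2)
    if np.all(pooled == pooled[0]):
        return u, 1.0, 0.5
    has_ties = len(np.unique(pooled)) < n1 + n2
    if n1 * n2 <= _EXACT_PRODUCT_LIMIT:
        if not has_ties:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            return u, float(res.pvalue), auc
        if comb(n1 + n2, n1) <= _ENUM_LIMIT:
            return u, _exact_permutation_p(ranks, n1, n2, u), auc
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    p = float(res.pvalue)
    return u, (1.0 if np.isnan(p) else p), auc


def _exact_permutation_p(ranks, n1, n2, u_obs) -> float:
    """P(|U' - n1*n2/2| >= |U - n1*n2/2|) over all group-label assignments."""
    centre = n1 * n2 / 2
    dev = abs(u_obs - centre)
    offset = n1 * (n1 + 1) / 2
    hits = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in idx) - offset
        total += 1
        if abs(u - centre) >= dev - 1e-12:
            hits += 1
    return hits / total


def batch_mann_whitney(a: np.ndarray, b: np.ndarray):
    """Vectorised tie-corrected normal-approximation test over columns.

    ``a`` is (n1, m), ``b`` is (n2, m); returns ``(U, p, AUC)`` arrays of
    length m.  Degenerate all-tied columns get p=1, AUC=0.5.
    """
    n1, n2 = a.shape[0], b.shape[0]
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", axis=0)
    u = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    auc = u / (n1 * n2)
    bad = ~np.isfinite(p)
    p[bad] = 1.0
    auc[bad] = 0.5
    return u, p, auc


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance bound alpha/m."""
    if m < 1:
        raise ValueError("m must be at least 1")
    return alpha / m


def discovery_replication(
    matrix: MetaboliteMatrix,
    metadata: SampleMetadata,
    case_group: str = "CTEPH",
    control_group: str = "HC",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-cohort Bonferroni screen with a direction-consistency rule.

    A metabolite passes iff its Mann-Whitney p is below alpha/m in the
    discovery AND the replication comparison and the case-minus-control mean
    difference has the same sign in both cohorts.
    """
    md = metadata.data
    parts = {}
    for cohort in ("discovery", "replication"):
        cases = md.index[(md["group"] == case_group) & (md["cohort"] == cohort)]
        ctrls = md.index[(md["group"] == control_group) & (md["cohort"] == cohort)]
        if len(cases) == 0 or len(ctrls) == 0:
            raise ValueError(
                f"no {case_group}/{control_group} samples in cohort {cohort!r}"
            )
        a = matrix.data.loc[cases].to_numpy(dtype=float)
        b = matrix.data.loc[ctrls].to_numpy(dtype=float)
        u, p, auc = batch_mann_whitney(a, b)
        parts[cohort] = {
            "mean_case": a.mean(axis=0), "sd_case": a.std(axis=0, ddof=1),
            "mean_control": b.mean(axis=0), "sd_control": b.std(axis=0, ddof=1),
            "u": u, "p": p, "auc": auc,
        }
    m = matrix.data.shape[1]
    bound = bonferroni_threshold(alpha, m)
    out = pd.DataFrame(index=pd.Index(matrix.data.columns, name="metabolite_id"))
    for cohort, d in parts.items():
        tag = "disc" if cohort == "discovery" else "rep"
        for key, vals in d.items():
            out[f"{key}_{tag}"] = vals
        out[f"direction_{tag}"] = np.where(
            d["mean_case"] >= d["mean_control"], "up", "down"
        )
    out["bonferroni_bound"] = bound
    out["passes"] = (
        (out["p_disc"] < bound)
        & (out["p_rep"] < bound)
        & (out["direction_disc"] == out["direction_rep"])
    )
    return out


def _preserved_indicator(values: pd.Series, group: pd.Series, cutoff: float):
    """Binary preserved-function flag; healthy controls without an assay
    value are assumed preserved."""
    flag = values < cutoff
    flag = flag.astype(float)
    missing = values.isna()
    flag[missing & (group == "HC")] = 1.0
    flag[missing & (group != "HC")] = np.nan
    return flag


def build_design(
    metadata: SampleMetadata,
    case_group: str,
    control_group: str,
) -> pd.DataFrame:
    """Confounder design matrix for one case/control comparison.

    Columns: group indicator, age, sex, ethnicity, BMI, preserved renal and
    liver function indicators, and any drug-class flags present.
    Complete-case: samples missing a covariate are dropped (count logged).
    """
    md = metadata.data
    sel = md["group"].isin([case_group, control_group])
    md = md[sel]
    X = pd.DataFrame(index=md.index)
    X["group"] = (md["group"] == case_group).astype(float)
    for col in ("age", "sex_female", "ethnicity_european", "bmi"):
        if col in md.columns:
            X[col] = pd.to_numeric(md[col], errors="coerce")
    if "creatinine" in md.columns:
        X["preserved_renal"] = _preserved_indicator(
            pd.to_numeric(md["creatinine"], errors="coerce"),
            md["group"], CREATININE_CUTOFF,
        )
    if "bilirubin" in md.columns:
        X["preserved_liver"] = _preserved_indicator(
            pd.to_numeric(md["bilirubin"], errors="coerce"),
            md["group"], BILIRUBIN_CUTOFF,
        )
    for col in DRUG_COLUMNS:
        if col in md.columns:
            X[col] = pd.to_numeric(md[col], errors="coerce")
    n_before = len(X)
    X = X.dropna()
    if len(X) < n_before:
        log.info("complete-case: dropped %d of %d samples with missing "
                 "covariates", n_before - len(X), n_before)
    # drop degenerate (constant) columns, keeping the group indicator
    constant = [c for c in X.columns if c != "group" and X[c].nunique() <= 1]
    if constant:
        log.warning("dropping constant covariate columns: %s", constant)
        X = X.drop(columns=constant)
    return X


def confounder_adjust(
    matrix: MetaboliteMatrix,
    metadata: SampleMetadata,
    metabolites,
    case_group: str = "CTEPH",
    control_group: str = "HC",
    alpha: float = 0.05,
    min_complete: int = 10,
) -> pd.DataFrame:
    """Per-metabolite OLS of abundance on group + confounders.

    Returns one row per metabolite with the group coefficient and p-value,
    the age and sex coefficients, and the effect-ratio diagnostics
    |beta_group|/|beta_age| and |beta_group|/|beta_sex|.  A metabolite is
    ``significant`` iff the group-coefficient p < alpha.
    """
    import statsmodels.api as sm

    X = build_design(metadata, case_group, control_group)
    rows = []
    for met in metabolites:
        y = matrix.data[met].reindex(X.index).dropna()
        Xm = X.loc[y.index]
        if len(y) < min_complete:
            log.warning("skipping %s: only %d complete cases", met, len(y))
            continue
        fit = sm.OLS(y.to_numpy(), sm.add_constant(Xm.to_numpy())).fit()
        names = ["const"] + list(Xm.columns)
        coefs = dict(zip(names, fit.params))
        pvals = dict(zip(names, fit.pvalues))
        beta_g = coefs["group"]
        beta_age = coefs.get("age", np.nan)
        beta_sex = coefs.get("sex_female", np.nan)
        rows.append({
            "metabolite_id": met,
            "n_used": int(len(y)),
            "beta_group": beta_g,
            "p_group": pvals["group"],
            "beta_age": beta_age,
            "p_age": pvals.get("age", np.nan),
            "beta_sex": beta_sex,
            "p_sex": pvals.get("sex_female", np.nan),
            "ratio_group_age": abs(beta_g) / abs(beta_age)
            if np.isfinite(beta_age) and beta_age != 0 else np.inf,
            "ratio_group_sex": abs(beta_g) / abs(beta_sex)
            if np.isfinite(beta_sex) and beta_sex != 0 else np.inf,
            "significant": bool(pvals["group"] < alpha),
        })
    return pd.DataFrame(rows).set_index("metabolite_id") if rows else pd.DataFrame(
        columns=["n_used", "beta_group", "p_group", "significant"]
    )


def tier_classify(
    hc_screen: pd.DataFrame,
    hc_adjusted: pd.DataFrame,
    dc_adjusted: pd.DataFrame,
    cted_adjusted: pd.DataFrame,
    ipah_adjusted: pd.DataFrame,
) -> pd.Series:
    """Assign each metabolite the highest specificity tier it fully meets.

    The healthy-control criterion is the two-cohort Bonferroni screen plus
    an adjusted group p < 0.05; each comparator criterion is an adjusted
    group p < 0.05 against that group.  Tiers are nested: a metabolite in a
    higher tier satisfies every lower-tier criterion.
    """
    mets = hc_screen.index

    def sig(table, met):
        return met in table.index and bool(table.loc[met, "significant"])

    tiers = {}
    for met in mets:
        passes_hc = bool(hc_screen.loc[met, "passes"]) and sig(hc_adjusted, met)
        if not passes_hc:
            tiers[met] = "none"
            continue
        tier = "vs_HC_only"
        if sig(dc_adjusted, met):
            tier = "vs_HC_DC"
            if sig(cted_adjusted, met):
                tier = "vs_HC_DC_CTED"
                if sig(ipah_adjusted, met):
                    tier = "vs_all_including_IPAH"
        tiers[met] = tier
    return pd.Series(tiers, name="tier").reindex(mets)
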
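"""Repeatability, mother–offspring regression and heritability.

Repeatability (R) is the intraclass correlation — the fraction of total
phenotypic variance attributable to differences among individuals — estimated
from a one-way ANOVA on repeated measurements of the same animals from
different photographs, with a parametric-bootstrap standard error.

Narrow-sense heritability is estimated by single-parent (mother) offspring
regression: h² = 2 × slope, since a single parent shares half its additive
genetic variance with the offspring.  Regression assumptions are checked with
a Shapiro–Wilk test on residuals and a Breusch–Pagan score test of the
squared residuals against fitted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import het_breuschpagan


@dataclass
class RepeatabilityResult:
    """ANOVA-based intraclass correlation with bootstrap uncertainty."""

    R: float
    R_se: float
    p_value: float
    var_among: float
    var_within: float
    n_individuals: int
    n_measurements: int


@dataclass
class PORegressionResult:
    """OLS of offspring trait on mother trait, with h² = 2·slope."""

    slope: float
    slope_se: float
    intercept: float
    F_stat: float
    p_value: float
    heritability: float
    heritability_se: float
    n_pairs: int
    residuals: np.ndarray
    fitted: np.ndarray


@dataclass(frozen=True)
class BonferroniAlpha:
    """Family-wise adjusted significance level α/m."""

    value: float
    rounded: float
    m_tests: int


def heritability_from_slope(slope: float, slope_se: float = np.nan):
    """h² implied by a single-parent–offspring regression slope: 2 × slope."""
    return 2.0 * slope, 2.0 * slope_se


def _anova_components(groups: list[np.ndarray]):
    """One-way ANOVA mean squares and the unbalanced group-size coefficient."""
    a = len(groups)
    sizes = np.array([len(g) for g in groups], dtype=float)
    N = sizes.sum()
    grand = np.concatenate(groups).mean()
    ss_among = float(sum(n * (g.mean() - grand) ** 2
                         for n, g in zip(sizes, groups)))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ms_a = ss_among / (a - 1)
    ms_w = ss_within / (N - a) if N > a else 0.0
    # Sokal–Rohlf coefficient n0 for unbalanced one-way designs
    k0 = (N - (sizes ** 2).sum() / N) / (a - 1)
    return ms_a, ms_w, k0, a, N


def _icc_from_ms(ms_a: float, ms_w: float, k0: float) -> float:
    denom = ms_a + (k0 - 1.0) * ms_w
    if denom <= 0:
        return 0.0
    return max(0.0, (ms_a - ms_w) / denom)


def repeatability(
    table: pd.DataFrame,
    trait: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> RepeatabilityResult:
    """Repeatability of one trait from a long-format repeated-measures table.

    ``table`` has columns individual_id, photo_id, trait_name, value.
    Individuals with fewer than two measurements are dropped with a warning.
    The point estimate is the one-way ANOVA ICC, truncated at 0; the p-value
    comes from the ANOVA F test; the SE from ``n_boot`` parametric bootstrap
    replicates drawn under the fitted variance components.
    """
    sub = table[table["trait_name"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in the table")
    groups, dropped = [], 0
    for _, g in sub.groupby("individual_id"):
        vals = g["value"].to_numpy(dtype=float)
        if len(vals) < 2:
            dropped += 1
            continue
        groups.append(vals)
    if dropped:
        warnings.warn(f"dropped {dropped} individuals with <2 measurements",
                      stacklevel=2)
    if len(groups) < 2:
        raise ValueError("need at least 2 individuals with >= 2 measurements")
    ms_a, ms_w, k0, a, N = _anova_components(groups)
    R = _icc_from_ms(ms_a, ms_w, k0)
    if ms_w <= 0:  # identical repeats: perfect repeatability
        p = 0.0
        R = 1.0 if ms_a > 0 else 0.0
    else:
        F = ms_a / ms_w
        p = float(stats.f.sf(F, a - 1, N - a))
    var_a = max(0.0, (ms_a - ms_w) / k0)
    var_w = max(ms_w, 0.0)
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        sim = [np.sqrt(var_a) * rng.standard_normal()
               + np.sqrt(var_w) * rng.standard_normal(n) for n in sizes]
        bms_a, bms_w, bk0, _, _ = _anova_components(sim)
        boots[b] = _icc_from_ms(bms_a, bms_w, bk0)
    return RepeatabilityResult(R=R, R_se=float(boots.std(ddof=1)), p_value=p,
                               var_among=var_a, var_within=var_w,
                               n_individuals=a, n_measurements=int(N))


def po_regression(pairs: pd.DataFrame) -> PORegressionResult:
    """Offspring-on-mother OLS regression for one trait.

    ``pairs`` has columns mother_value and calf_value; rows with a missing
    value on either side are dropped listwise.  Heritability is 2 × slope
    (single-parent regression); its SE is 2 × slope SE.
    """
    use = pairs[["mother_value", "calf_value"]].dropna()
    n = len(use)
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    mother = use["mother_value"].to_numpy(dtype=float)
    calf = use["calf_value"].to_numpy(dtype=float)
    if np.var(mother) == 0:
        raise ValueError("zero variance in mother values")
    X = sm.add_constant(mother)
    fit = sm.OLS(calf, X).fit()
    slope = float(fit.params[1])
    slope_se = float(fit.bse[1])
    h2, h2_se = heritability_from_slope(slope, slope_se)
    return PORegressionResult(
        slope=slope, slope_se=slope_se, intercept=float(fit.params[0]),
        F_stat=float((slope / slope_se) ** 2), p_value=float(fit.pvalues[1]),
        heritability=h2, heritability_se=h2_se, n_pairs=n,
        residuals=np.asarray(fit.resid), fitted=np.asarray(fit.fittedvalues))


def bonferroni_alpha(alpha: float, m_tests: int) -> BonferroniAlpha:
    """Bonferroni family-wise adjustment α/m (also rounded to 4 decimals)."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    value = alpha / m_tests
    return BonferroniAlpha(value=value, rounded=round(value, 4), m_tests=m_tests)


def regression_diagnostics(result: PORegressionResult):
    """(normality_p, heteroscedasticity_p) for a fitted PO regression.

    Shapiro–Wilk on residuals; Breusch–Pagan score test (χ²₁) of squared
    residuals against fitted values.  Returns (nan, nan) with a warning for
    n < 5 or for the degenerate all-zero-residual case.
    """
    resid = np.asarray(result.residuals, dtype=float)
    fitted = np.asarray(result.fitted, dtype=float)
    if len(resid) < 5:
        warnings.warn("n < 5: diagnostics skipped", stacklevel=2)
        return np.nan, np.nan
    if np.allclose(resid, 0.0) or np.var(fitted) == 0:
        warnings.warn("degenerate residuals: diagnostics undefined", stacklevel=2)
        return np.nan, np.nan
    normality_p = float(stats.shapiro(resid).pvalue)
    exog = sm.add_constant(fitted)
    _, bp_p, _, _ = het_breuschpagan(resid, exog)
    return normality_p, float(bp_p)


def heritability_table(
    traits: pd.DataFrame,
    pairs: pd.DataFrame,
    trait_columns: list[str],
    repeat_table: pd.DataFrame | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-trait summary: mean, SD, CV, repeatability, PO slope, h², F, p.

    ``traits`` is the per-animal trait table indexed by animal id; ``pairs``
    has columns mother_id and calf_id.  Traits absent for either member of a
    pair are dropped listwise per trait.
    """
    rows = []
    for trait in trait_columns:
        vals = traits[trait].to_numpy(dtype=float)
        mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
        row = {"trait": trait, "mean": mean, "sd": sd,
               "cv": sd / mean if mean != 0 else np.nan}
        if repeat_table is not None and trait in set(repeat_table["trait_name"]):
            rep = repeatability(repeat_table, trait, n_boot=n_boot, seed=seed)
            row.update(R=rep.R, R_se=rep.R_se, R_p=rep.p_value)
        paired = pd.DataFrame({
            "mother_value": traits.loc[pairs["mother_id"], trait].to_numpy(),
            "calf_value": traits.loc[pairs["calf_id"], trait].to_numpy(),
        })
        po = po_regression(paired)
        row.update(slope=po.slope, slope_se=po.slope_se,
                   heritability=po.heritability,
                   heritability_se=po.heritability_se,
                   F=po.F_stat, p=po.p_value, n_pairs=po.n_pairs)
        rows.append(row)
    return pd.DataFrame(rows)
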
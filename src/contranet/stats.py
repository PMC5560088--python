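"""Group-level inference on topology metrics and cohort descriptives.

Permutation tests on group mean differences (label exchange, add-one p
estimator), Benjamini-Hochberg FDR across the six metrics, covariate-
adjusted ANOVA (age + tumour diameter) with classical eta squared, and the
descriptive tests used for patient tables: a Pearson chi-square on a 2x2
sex table and a pooled-variance two-sample t computable from printed
summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA = 0.05


@dataclass
class GroupComparison:
    metric_name: str
    observed_difference: float  # group B mean - group A mean
    null_differences: np.ndarray
    p_perm: float
    n_perm: int
    seed: int
    two_sided: bool
    fdr_significant: bool | None = None


@dataclass
class AncovaResult:
    metric_name: str
    f_group: float
    df: tuple[int, int]
    eta_squared: float
    p_value: float
    covariate_terms: dict


def permutation_group_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    two_sided: bool = True,
    metric_name: str = "",
) -> GroupComparison:
    """Permutation test on the difference of group means.

    Pooled values are relabelled ``n_perm`` times preserving group sizes;
    p = (1 + #{null >= observed}) / (1 + n_perm), comparing absolute
    differences when ``two_sided`` (default), signed otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(b.mean() - a.mean())
    # sort the pooled values before permuting: under the null the statistic
    # depends only on the value multiset and the random split, so sorting is
    # harmless and makes p exactly invariant to the input order / group
    # relabelling (for equal group sizes)
    pooled = np.sort(np.concatenate([a, b]))
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    null = perms[:, a.size:].mean(axis=1) - perms[:, : a.size].mean(axis=1)
    if two_sided:
        exceed = np.abs(null) >= abs(observed)
    else:
        exceed = null >= observed
    p = (1.0 + int(exceed.sum())) / (1.0 + n_perm)
    return GroupComparison(metric_name, observed, null, p, n_perm, seed, two_sided)


def fdr_correct(
    p_values, alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (significance flags, adjusted p-values)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    flags, adjusted, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return flags, adjusted


def ancova_group(
    metric: np.ndarray,
    group: np.ndarray,
    age: np.ndarray,
    diameter: np.ndarray,
    metric_name: str = "",
    partial: bool = False,
) -> AncovaResult:
    """Group effect on a metric, adjusted for age and tumour diameter.

    OLS fit metric ~ intercept + age + diameter + group with the group term
    entered last in the sequential (type-I) decomposition, so its sum of
    squares is adjusted for both covariates.  Eta squared is classical,
    SS_group / SS_total; ``partial=True`` gives SS_group/(SS_group+SS_resid).
    """
    df = pd.DataFrame(
        {
            "metric": np.asarray(metric, dtype=float),
            "group": np.asarray(group),
            "age": np.asarray(age, dtype=float),
            "diameter": np.asarray(diameter, dtype=float),
        }
    )
    if len(df) < 5:
        raise ValueError("need at least 5 subjects")
    if not np.all(np.isfinite(df[["age", "diameter"]].to_numpy())):
        raise ValueError("covariates must be finite")
    if abs(np.corrcoef(df["age"], df["diameter"])[0, 1]) > 1 - 1e-10:
        raise ValueError("age and diameter are collinear")
    model = ols("metric ~ age + diameter + C(group)", data=df).fit()
    table = anova_lm(model, typ=1)
    ss_group = float(table.loc["C(group)", "sum_sq"])
    ss_total = float(table["sum_sq"].sum())
    ss_resid = float(table.loc["Residual", "sum_sq"])
    eta2 = ss_group / (ss_group + ss_resid) if partial else ss_group / ss_total
    return AncovaResult(
        metric_name=metric_name,
        f_group=float(table.loc["C(group)", "F"]),
        df=(int(table.loc["C(group)", "df"]), int(table.loc["Residual", "df"])),
        eta_squared=eta2,
        p_value=float(table.loc["C(group)", "PR(>F)"]),
        covariate_terms={
            name: {
                "coef": float(model.params[name]),
                "p": float(model.pvalues[name]),
            }
            for name in ("age", "diameter")
        },
    )


def chi_square_2x2(counts) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table."""
    obs = np.asarray(counts, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("counts must be a 2x2 nonnegative table")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, float(sps.chi2.sf(chi2, df=1))


def pooled_t_test(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, df, p) with t for the difference mean_b - mean_a and
    df = n_a + n_b - 2; lets printed patient-table rows be checked without
    raw data.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("sds must be positive")
    res = sps.ttest_ind_from_stats(
        mean_b, sd_b, n_b, mean_a, sd_a, n_a, equal_var=True
    )
    return float(res.statistic), n_a + n_b - 2, float(res.pvalue)


def group_metric_table(
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
    metric_names,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Results table mirroring a metric-comparison layout.

    One row per metric: group means/SDs, permutation p, FDR flag, ANCOVA F,
    eta squared and ANCOVA p.  ``metrics`` must carry ``subject_id`` plus
    metric columns; ``cohort`` must carry subject_id, group, age, diameter.
    The first group label (by first appearance in the cohort) plays the
    group-A role.
    """
    merged = metrics.merge(cohort, on="subject_id", validate="one_to_one")
    groups = list(dict.fromkeys(cohort["group"].tolist()))
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ga, gb = groups
    a_mask = (merged["group"] == ga).to_numpy()
    seeds = np.random.SeedSequence(seed).generate_state(
        len(metric_names), dtype=np.uint32
    )
    rows = []
    comparisons = []
    for name, s in zip(metric_names, seeds):
        vals = merged[name].to_numpy(dtype=float)
        comp = permutation_group_test(
            vals[a_mask], vals[~a_mask], n_perm=n_perm, seed=int(s),
            two_sided=two_sided, metric_name=name,
        )
        anc = ancova_group(
            vals, merged["group"].to_numpy(), merged["age"].to_numpy(),
            merged["diameter"].to_numpy(), metric_name=name,
        )
        comparisons.append(comp)
        rows.append(
            {
                "metric": name,
                f"mean_{ga}": vals[a_mask].mean(),
                f"sd_{ga}": vals[a_mask].std(ddof=1),
                f"mean_{gb}": vals[~a_mask].mean(),
                f"sd_{gb}": vals[~a_mask].std(ddof=1),
                "p_perm": comp.p_perm,
                "F": anc.f_group,
                "eta_squared": anc.eta_squared,
                "p_ancova": anc.p_value,
            }
        )
    table = pd.DataFrame(rows)
    flags, adjusted = fdr_correct(table["p_perm"], alpha)
    table["fdr_significant"] = flags
    table["p_perm_adjusted"] = adjusted
    for comp, flag in zip(comparisons, flags):
        comp.fdr_significant = bool(flag)
    return table


def descriptives_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Patient-table style descriptives: pooled t tests on age and diameter."""
    groups = list(dict.fromkeys(cohort["group"].tolist()))
    ga, gb = groups
    rows = []
    for name in ("age", "diameter"):
        a = cohort.loc[cohort["group"] == ga, name].to_numpy(dtype=float)
        b = cohort.loc[cohort["group"] == gb, name].to_numpy(dtype=float)
        t, df, p = pooled_t_test(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        rows.append(
            {
                "characteristic": name,
                f"mean_{ga}": a.mean(), f"sd_{ga}": a.std(ddof=1),
                f"mean_{gb}": b.mean(), f"sd_{gb}": b.std(ddof=1),
                "t": t, "df": df, "p": p,
            }
        )
    return pd.DataFrame(rows)
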
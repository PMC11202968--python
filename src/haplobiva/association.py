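"""Diplotype-phenotype association: within-sex standardization, OLS with a
sex covariate, group-wise Student t tests, and ordinal correlations.

Phenotypes are the four bioelectrical variables (Rsp, Xcsp, Zsp, PhA) plus
perception scores. Genotype enters either additively (0/1/2 copies of the
non-reference block haplotype) or as a binary carrier indicator matching the
aa vs. b-carrier grouping. Sex is the only covariate; the cohorts are two
labeled groups, so no structure correction is attempted. p-values are
reported raw (no multiple-testing correction across the four phenotypes);
an optional Bonferroni column is a clearly labeled extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

BIOELECTRIC_PHENOTYPES = ("rsp", "xcsp", "zsp", "pha")


class AssociationError(Exception):
    pass


def sex_zscore(values, sex) -> np.ndarray:
    """Standardize a phenotype within each sex and pool the z-scores.

    Removes the sex main effect so males and females can be analysed
    together. Sample SD (ddof=1); a zero within-sex SD is an error.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(sex)
    out = np.empty_like(v)
    for label in np.unique(s):
        mask = s == label
        if mask.sum() < 2:
            raise AssociationError(f"need >= 2 subjects of sex {label!r}")
        sd = v[mask].std(ddof=1)
        if sd == 0:
            raise AssociationError(f"zero within-sex SD for sex {label!r}")
        out[mask] = (v[mask] - v[mask].mean()) / sd
    return out


@dataclass
class RegressionFit:
    """OLS fit summary: one row per model term."""

    terms: list
    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    n_used: int

    def term(self, name: str) -> dict:
        i = self.terms.index(name)
        return {
            "beta": float(self.beta[i]), "se": float(self.se[i]),
            "t": float(self.t_stat[i]), "p": float(self.p_value[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"term": self.terms, "beta": self.beta, "se": self.se,
             "t": self.t_stat, "p": self.p_value}
        )


def _genotype_code(b_copies: np.ndarray, coding: str) -> np.ndarray:
    if coding == "additive":
        return b_copies.astype(float)
    if coding == "carrier":
        return (b_copies > 0).astype(float)
    raise AssociationError(f"unknown coding {coding!r}")


def fit_diplotype_regression(
    phenotype, b_copies, sex=None, coding: str = "additive"
) -> RegressionFit:
    """OLS of a phenotype on the diplotype code, optionally with a sex
    covariate.

    ``b_copies`` is the per-subject count of non-reference haplotypes
    (0/1/2); ``coding='carrier'`` collapses it to 0/1. Sex, when given,
    enters as a female indicator. Missing phenotype values are dropped
    listwise and ``n_used`` reports the rows actually fitted.
    """
    y = np.asarray(phenotype, dtype=float)
    g = _genotype_code(np.asarray(b_copies, dtype=float), coding)
    cols = {"genotype": g}
    if sex is not None:
        s = np.asarray(sex)
        cols["sex_F"] = (s == "F").astype(float)
    X = pd.DataFrame(cols)
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    y, X = y[keep], X.loc[keep]
    if keep.sum() < len(X.columns) + 2:
        raise AssociationError(f"too few complete cases ({int(keep.sum())})")
    Xd = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xd.to_numpy())
    if rank < Xd.shape[1]:
        raise AssociationError(
            f"design matrix rank-deficient (rank {rank} < {Xd.shape[1]}); "
            f"collinear terms among {list(Xd.columns)}"
        )
    fit = sm.OLS(y, Xd).fit()
    return RegressionFit(
        terms=list(Xd.columns), beta=fit.params.to_numpy(),
        se=fit.bse.to_numpy(), t_stat=fit.tvalues.to_numpy(),
        p_value=fit.pvalues.to_numpy(), n_used=int(fit.nobs),
    )


def anova_oneway(phenotype, groups) -> tuple[float, float]:
    """One-way ANOVA of a phenotype across diplotype groups: (F, p)."""
    y = np.asarray(phenotype, dtype=float)
    g = np.asarray(groups)
    keep = np.isfinite(y)
    samples = [y[keep & (g == label)] for label in pd.unique(g[keep])]
    if len(samples) < 2:
        raise AssociationError("need >= 2 groups for ANOVA")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


@dataclass
class GroupTestResult:
    stratum: str
    variable: str
    n1: int
    n2: int
    t_stat: float | None
    p_value: float | None

    @property
    def available(self) -> bool:
        return self.t_stat is not None


def groupwise_tests(
    data: pd.DataFrame, group_col: str, variables=BIOELECTRIC_PHENOTYPES,
    stratify_by_sex: bool = False, sex_col: str = "sex",
) -> list[GroupTestResult]:
    """Classical (pooled-variance) Student t tests of each variable between
    the two levels of ``group_col``, optionally within each sex stratum.

    Strata where either group has fewer than 2 non-missing values are
    reported with t and p as None ("sample too small") rather than dropped.
    """
    levels = list(pd.unique(data[group_col].dropna()))
    if len(levels) != 2:
        raise AssociationError(
            f"{group_col} must have exactly 2 levels, found {levels}"
        )
    strata = (
        [(label, data[data[sex_col] == label]) for label in ("M", "F")]
        if stratify_by_sex else [("all", data)]
    )
    results = []
    for stratum_name, frame in strata:
        for var in variables:
            x1 = frame.loc[frame[group_col] == levels[0], var].dropna().to_numpy(float)
            x2 = frame.loc[frame[group_col] == levels[1], var].dropna().to_numpy(float)
            if len(x1) < 2 or len(x2) < 2:
                results.append(GroupTestResult(stratum_name, var, len(x1), len(x2), None, None))
                continue
            t, p = stats.ttest_ind(x1, x2, equal_var=True)
            results.append(
                GroupTestResult(stratum_name, var, len(x1), len(x2), float(t), float(p))
            )
    return results


def group_tests_to_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    rows = [
        {"stratum": r.stratum, "variable": r.variable, "n1": r.n1, "n2": r.n2,
         "t": r.t_stat if r.available else "N/A",
         "p": r.p_value if r.available else "N/A"}
        for r in results
    ]
    return pd.DataFrame(rows)


def threshold_correlation(thresholds, ordinal_codes) -> float:
    """Pearson correlation between capsaicin thresholds and ordinal
    food-frequency codes on paired non-missing values."""
    x = np.asarray(thresholds, dtype=float)
    y = np.asarray(ordinal_codes, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise AssociationError(f"need >= 3 paired values, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise AssociationError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted p-values (extension; the primary tables report
    raw p)."""
    p = np.asarray(p_values, dtype=float)
    m = m or p.size
    return np.minimum(p * m, 1.0)
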
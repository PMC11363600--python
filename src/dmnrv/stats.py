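"""Group comparison and biomarker-connectivity association statistics.

Two families of analysis:

* a demographics table (age, MMSE, education, sex) comparing CN vs MCI,
  with a Shapiro-Wilk normality gate selecting t-test vs Mann-Whitney U
  for continuous variables and a count-based test for sex;
* per-group associations between each CSF biomarker and each of the ten
  DMN connectivity metrics, via (a) partial correlation controlling for
  age and sex and (b) an ordinary least-squares model of the metric on
  the biomarker adjusted for age and sex, with Benjamini-Hochberg FDR
  correction applied within each (group, biomarker, statistic-kind)
  family of ten tests.

Education is deliberately not a covariate: the adjustment set is age and
sex only, even though the groups differ in education.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import OLS
from statsmodels.stats.multitest import multipletests

from .connectivity import METRIC_NAMES
from .synthetic import BIOMARKERS, GROUPS

logger = logging.getLogger(__name__)

ALPHA = 0.05
COVARIATES = ("age", "sex")

BIOMARKER_LABELS = {
    "gap43": "GAP-43", "abeta42": "Amyloid beta", "ttau": "Tau", "ptau181": "P tau",
}


# ---------------------------------------------------------------------------
# cognitive banding and group comparison

def mmse_band(score: int) -> str:
    """Conventional MMSE banding: >=24 normal, 19-23 mild, 10-18 moderate, <=9 severe."""
    if not (0 <= score <= 30):
        raise ValueError(f"MMSE score must be in [0, 30], got {score}")
    if score >= 24:
        return "normal"
    if score >= 19:
        return "mild"
    if score >= 10:
        return "moderate"
    return "severe"


def normality_gate(groups, alpha: float = ALPHA) -> str:
    """Shapiro-Wilk gate over per-group samples: 'normal' iff every group passes."""
    for values in groups:
        arr = np.asarray(values, dtype=np.float64)
        if arr.size < 3:
            raise ValueError("normality test needs at least 3 observations per group")
        if arr.std() == 0:
            raise ValueError("constant input: normality is undefined")
        if sps.shapiro(arr).pvalue < alpha:
            return "non_normal"
    return "normal"


@dataclass
class GroupComparison:
    """One demographics-table row: summaries per group, test used, p-value."""

    variable: str
    summary_cn: str
    summary_mci: str
    test: str  # "t", "mann_whitney", or "chi_square" / "fisher"
    p: float


def _mean_sd(values: np.ndarray) -> str:
    return f"{np.mean(values):.2f} ({np.std(values, ddof=1):.2f})"


def _median_iqr(values: np.ndarray) -> str:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return f"{med:g} ({q1:g}, {q3:g})"


def mann_whitney_p(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when the combined sample is small (n <= 20) and free
    of ties; the tie-corrected normal approximation otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    combined = np.concatenate([x, y])
    exact = combined.size <= 20 and np.unique(combined).size == combined.size
    method = "exact" if exact else "asymptotic"
    return float(sps.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def compare_groups(pheno: pd.DataFrame, sex_test: str = "chi_square") -> list[GroupComparison]:
    """Demographics comparison of the CN and MCI groups.

    Continuous variables (age, mmse, education) are routed through the
    normality gate: t-test with mean (SD) summaries when both groups look
    normal, Mann-Whitney U with median (IQR) otherwise.  Sex uses a 2x2
    count-based test (asymptotic chi-square by default, Fisher exact on
    request).
    """
    cn = pheno[pheno["group"] == "CN"]
    mci = pheno[pheno["group"] == "MCI"]
    if cn.empty or mci.empty:
        raise ValueError("both groups must be non-empty")
    out = []
    for variable in ("age", "mmse", "education"):
        a = cn[variable].to_numpy(float)
        b = mci[variable].to_numpy(float)
        gate = normality_gate([a, b])
        if gate == "normal":
            p = float(sps.ttest_ind(a, b).pvalue)
            out.append(GroupComparison(variable, _mean_sd(a), _mean_sd(b), "t", p))
        else:
            p = mann_whitney_p(a, b)
            out.append(GroupComparison(variable, _median_iqr(a), _median_iqr(b),
                                       "mann_whitney", p))
    counts = np.array([
        [int((cn["sex"] == 0).sum()), int((cn["sex"] == 1).sum())],
        [int((mci["sex"] == 0).sum()), int((mci["sex"] == 1).sum())],
    ])
    if sex_test == "fisher":
        p = float(sps.fisher_exact(counts).pvalue)
    else:
        p = float(sps.chi2_contingency(counts).pvalue)
    out.append(GroupComparison(
        "sex", f"{counts[0, 0]}/{counts[0, 1]}", f"{counts[1, 0]}/{counts[1, 1]}",
        sex_test, p))
    return out


# ---------------------------------------------------------------------------
# association statistics

def _residualize(v: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), covariates])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(x, y, covariates=None) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [intercept, covariates] and the
    residuals correlated; the p-value comes from the t distribution with
    n - k - 2 degrees of freedom (k covariates).  With no covariates this
    reduces exactly to the plain Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, float).reshape(n, -1)
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"n={n} too small for {k} covariates")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    # a variable fully explained by the covariates leaves only rounding dust;
    # its partial correlation is 0 by construction
    for resid, orig in ((rx, x), (ry, y)):
        if np.linalg.norm(resid) <= 1e-10 * max(np.linalg.norm(orig), 1.0):
            return 0.0, 1.0, n
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    if denom == 0:
        return 0.0, 1.0, n
    r = float(np.clip(rx @ ry / denom, -1.0, 1.0))
    dof = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0, n
    t = r * np.sqrt(dof / (1.0 - r ** 2))
    p = float(2.0 * sps.t.sf(abs(t), dof))
    return r, p, n


def fit_adjusted_glm(y, x, covariates) -> tuple[float, float, float]:
    """OLS of a connectivity metric on a biomarker, adjusted for age and sex.

    Returns (R^2, standardized beta of x, two-sided p of the x coefficient).
    The standardized beta is the x coefficient after z-scoring x and y
    (covariates left unscaled); R^2 and the p-value are invariant to that
    rescaling, so a single fit serves all three.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    cov = np.asarray(covariates, float).reshape(len(y), -1)
    if len(y) <= cov.shape[1] + 2:
        raise ValueError("too few observations for the adjusted model")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("constant predictor or response")
    xz = (x - x.mean()) / x.std(ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    design = np.column_stack([np.ones(len(y)), xz, cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design in the adjusted model")
    fit = OLS(yz, design).fit()
    return float(fit.rsquared), float(fit.params[1]), float(fit.pvalues[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_stars(p: float, alpha: float = ALPHA) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return ""


@dataclass
class AssociationRecord:
    """One (group, biomarker, metric) association result."""

    group: str
    biomarker: str
    metric: str
    kind: str  # "partial_r" or "glm"
    estimate: float  # partial r, or standardized beta
    p_raw: float
    p_fdr: float
    n: int
    r_squared: float | None = None


def build_association_tables(metrics: pd.DataFrame, pheno: pd.DataFrame,
                             alpha: float = ALPHA, fdr_family: str = "column",
                             ) -> tuple[list[AssociationRecord], dict[str, pd.DataFrame]]:
    """The full association battery plus rendered result tables.

    For each group x biomarker x metric cell, both a partial correlation
    (controlling for age and sex) and an adjusted OLS fit are computed.
    BH correction runs within each (group, biomarker, kind) family of ten
    metric tests (``fdr_family='column'``); ``'table'`` widens the family
    to all metrics and biomarkers of a group and kind.

    Returns the record list and a dict of tables: ``table1`` (group
    comparison), ``table2`` (partial correlations with significance
    stars), and ``table_<biomarker>`` (per-biomarker adjusted-model
    tables with R^2, standardized beta, and FDR p).
    """
    if fdr_family not in ("column", "table"):
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    for biomarker in BIOMARKERS:
        if biomarker not in pheno.columns:
            raise ValueError(f"phenotype table lacks biomarker column {biomarker!r}")
    merged = metrics.merge(pheno, left_index=True, right_on="subject_id", how="inner")
    n_dropped = len(pheno) - len(merged)
    needed = list(METRIC_NAMES) + list(BIOMARKERS) + list(COVARIATES)
    complete = merged.dropna(subset=needed)
    n_dropped += len(merged) - len(complete)
    if n_dropped:
        logger.info("dropped %d subject(s) with missing metrics or biomarkers", n_dropped)

    records: list[AssociationRecord] = []
    for group in GROUPS:
        sub = complete[complete["group"] == group]
        if sub.empty:
            raise ValueError(f"group {group!r} has no usable subjects")
        cov = sub[list(COVARIATES)].to_numpy(float)
        for biomarker in BIOMARKERS:
            x = sub[biomarker].to_numpy(float)
            for metric in METRIC_NAMES:
                y = sub[metric].to_numpy(float)
                r, p, n = partial_correlation(x, y, cov)
                records.append(AssociationRecord(group, biomarker, metric,
                                                 "partial_r", r, p, np.nan, n))
                r2, beta, p_glm = fit_adjusted_glm(y, x, cov)
                records.append(AssociationRecord(group, biomarker, metric, "glm",
                                                 beta, p_glm, np.nan, n, r_squared=r2))

    # FDR correction within families
    df = pd.DataFrame([vars(rec) for rec in records])
    family_cols = (["group", "biomarker", "kind"] if fdr_family == "column"
                   else ["group", "kind"])
    for _, idx in df.groupby(family_cols).groups.items():
        df.loc[idx, "p_fdr"] = bh_adjust(df.loc[idx, "p_raw"].to_numpy())
    for rec, p_fdr in zip(records, df["p_fdr"]):
        rec.p_fdr = float(p_fdr)

    tables: dict[str, pd.DataFrame] = {}
    comparisons = compare_groups(complete[["subject_id", "group", "age", "sex",
                                           "education", "mmse"]].drop_duplicates())
    tables["table1"] = pd.DataFrame([vars(c) for c in comparisons])

    part = df[df["kind"] == "partial_r"]
    table2 = pd.DataFrame(index=list(METRIC_NAMES))
    for biomarker in BIOMARKERS:
        for group in GROUPS:
            cells = part[(part["biomarker"] == biomarker) & (part["group"] == group)]
            cells = cells.set_index("metric").reindex(list(METRIC_NAMES))
            col = [f"{est:.3f}{significance_stars(pf, alpha)}"
                   for est, pf in zip(cells["estimate"], cells["p_fdr"])]
            table2[f"{BIOMARKER_LABELS[biomarker]} {group}"] = col
    tables["table2"] = table2

    glm = df[df["kind"] == "glm"]
    for biomarker in BIOMARKERS:
        t = pd.DataFrame(index=list(METRIC_NAMES))
        for group in GROUPS:
            cells = glm[(glm["biomarker"] == biomarker) & (glm["group"] == group)]
            cells = cells.set_index("metric").reindex(list(METRIC_NAMES))
            t[f"R2 {group}"] = cells["r_squared"].round(3)
            t[f"Standardized beta {group}"] = cells["estimate"].round(3)
            t[f"P value {group}"] = cells["p_fdr"].round(3)
        tables[f"table_{biomarker}"] = t
    return records, tables
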
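"""Cluster phenotyping: demographic/biomarker tables and ROI hypometabolism models.

Demographics and biomarkers are compared across clusters with Pearson
chi-square tests (categorical, no continuity correction) and one-way ANOVA
followed by Tukey's HSD (continuous), summarized per diagnostic stratum as
n (%) and mean +/- SD, mirroring the usual cohort-description table.

Regional glucose metabolism enters as a long table of (subject, ROI, SUVR,
time, covariates) records, one ROI model at a time:

* baseline: ordinary least squares ``suvr ~ cluster + sex + age`` on the
  time-0 records, cluster coded as dummies against the control group.  With a
  single observation per subject a random intercept is unidentifiable, so the
  baseline "mixed" model is fit as OLS.
* longitudinal: linear mixed model with a random intercept per subject and
  fixed effects cluster, time, sex, age and the cluster x time interaction;
  the interaction coefficient tests whether a cluster's metabolic trajectory
  differs from controls.

P-values are Benjamini-Hochberg adjusted across ROIs within each cluster
contrast; ROIs passing FDR < 0.05 with a coefficient <= -0.05 are flagged
"most affected".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MOST_AFFECTED_COEF = -0.05  #: coefficient threshold for the "most affected" flag


def aal_labels() -> list[str]:
    """The 116-region AAL atlas label vocabulary shipped with the package."""
    text = resources.files("netstrat.data").joinpath("aal116_labels.txt").read_text()
    labels = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if len(labels) != 116:
        raise RuntimeError("AAL vocabulary file corrupted")
    return labels


@dataclass
class ROIModelResult:
    roi: str
    cluster: str
    coefficient: float
    std_error: float
    p_value: float
    fdr_p: float = np.nan
    significant: bool = False
    most_affected: bool = False


# ---------------------------------------------------------------------------
# Group-comparison statistics
# ---------------------------------------------------------------------------

def chi_square_categorical(counts) -> tuple[float, float]:
    """Pearson chi-square on a 2 x k carrier/non-carrier table.

    No continuity correction (df = k - 1).  Expected counts below 5 trigger a
    small-cell warning.  A zero row or column is a degenerate table.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("expected a 2 x k contingency table")
    if (table < 0).any() or table.sum() == 0:
        raise ValueError("table must be nonnegative with positive total")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero row or column")
    stat, p, _, expected = stats.chi2_contingency(table, correction=False)
    if (expected < 5).any():
        logger.warning(
            "chi-square expected counts below 5 (min %.2f); p-value approximate",
            expected.min(),
        )
    return float(stat), float(p)


def anova_tukey_continuous(groups: list[np.ndarray]):
    """One-way ANOVA + Tukey HSD over cluster groups (missing values dropped).

    Groups that are entirely missing are excluded with a warning.  Returns
    (F, p, {(i, j): tukey_p}) with indices referring to the retained groups'
    positions in the input list.
    """
    cleaned, kept = [], []
    for i, g in enumerate(groups):
        g = np.asarray(g, dtype=float)
        g = g[~np.isnan(g)]
        if len(g) == 0:
            logger.warning("group %d entirely missing; excluded from ANOVA", i)
            continue
        cleaned.append(g)
        kept.append(i)
    if len(cleaned) < 2 or any(len(g) < 2 for g in cleaned):
        raise ValueError("need >= 2 groups with >= 2 non-missing members")
    F, p = stats.f_oneway(*cleaned)
    values = np.concatenate(cleaned)
    labels = np.concatenate([
        np.full(len(g), i) for g, i in zip(cleaned, kept)
    ])
    tuk = pairwise_tukeyhsd(values, labels)
    pairs = {}
    idx = 0
    gu = tuk.groupsunique
    for i in range(len(gu)):
        for j in range(i + 1, len(gu)):
            pairs[(int(gu[i]), int(gu[j]))] = float(tuk.pvalues[idx])
            idx += 1
    return float(F), float(p), pairs


def summarize_cluster_phenotypes(
    phenotypes: pd.DataFrame,
    labels,
    stratum: str,
    diagnosis_col: str = "diagnosis",
) -> pd.DataFrame:
    """Cohort-description table for one diagnostic stratum.

    Categorical variables (object/category dtype) are expanded level by level
    into n (%) rows with a chi-square statistic; numeric variables become
    mean +/- SD rows with ANOVA F.  A single-cluster input yields the
    summaries without statistic columns.
    """
    labels = np.asarray(labels)
    if len(labels) != len(phenotypes):
        raise ValueError("labels must align with phenotype rows")
    mask = phenotypes[diagnosis_col] == stratum
    sub = phenotypes.loc[mask]
    sub_labels = labels[np.asarray(mask)]
    clusters = sorted(np.unique(labels))
    sizes = {c: int((sub_labels == c).sum()) for c in clusters}
    multi = len(clusters) > 1

    rows = [{"variable": "Number",
             **{f"cluster_{c}": sizes[c] for c in clusters},
             **({"statistic": np.nan, "p_value": np.nan} if multi else {})}]
    skip = {diagnosis_col, "subject_id"}
    for col in sub.columns:
        if col in skip:
            continue
        series = sub[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            for level in sorted(series.dropna().unique()):
                row = {"variable": f"{col} ({level})"}
                carriers = []
                for c in clusters:
                    vals = series[sub_labels == c]
                    k = int((vals == level).sum())
                    carriers.append(k)
                    pct = 100.0 * k / sizes[c] if sizes[c] else 0.0
                    row[f"cluster_{c}"] = f"{k} ({pct:.2f}%)"
                if multi:
                    try:
                        table = np.array([
                            carriers,
                            [sizes[c] - k for c, k in zip(clusters, carriers)],
                        ])
                        stat, p = chi_square_categorical(table)
                    except ValueError:
                        stat, p = np.nan, np.nan
                    row["statistic"], row["p_value"] = stat, p
                rows.append(row)
        else:
            row = {"variable": col}
            groups = []
            for c in clusters:
                vals = series[sub_labels == c].to_numpy(dtype=float)
                vals = vals[~np.isnan(vals)]
                groups.append(vals)
                if len(vals):
                    row[f"cluster_{c}"] = f"{vals.mean():.2f} ± {vals.std(ddof=1) if len(vals) > 1 else 0.0:.2f}"
                else:
                    row[f"cluster_{c}"] = "NA"
            if multi:
                try:
                    F, p, _ = anova_tukey_continuous(groups)
                except ValueError:
                    F, p = np.nan, np.nan
                row["statistic"], row["p_value"] = F, p
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ROI hypometabolism models
# ---------------------------------------------------------------------------

def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotone, >= raw p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _validate_roi_table(obs: pd.DataFrame) -> None:
    required = {"subject_id", "roi", "suvr", "time_years", "sex", "age", "group"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"ROI table missing columns: {sorted(missing)}")
    if (obs["suvr"] <= 0).any():
        raise ValueError("SUVR values must be positive")
    if (obs["time_years"] < 0).any():
        raise ValueError("follow-up time must be nonnegative")
    if "control" not in set(obs["group"]):
        raise ValueError("ROI table must contain control subjects")


def _finalize(results: list[ROIModelResult]) -> list[ROIModelResult]:
    """FDR across ROIs within each cluster contrast; set flags."""
    by_cluster: dict[str, list[ROIModelResult]] = {}
    for r in results:
        by_cluster.setdefault(r.cluster, []).append(r)
    for rs in by_cluster.values():
        ok = [r for r in rs if np.isfinite(r.p_value)]
        if not ok:
            continue
        adj = fdr_adjust([r.p_value for r in ok])
        for r, q in zip(ok, adj):
            r.fdr_p = float(q)
            r.significant = q < 0.05
            r.most_affected = r.significant and r.coefficient <= MOST_AFFECTED_COEF
    return results


def fit_roi_model_baseline(
    obs: pd.DataFrame, min_obs: int = 10
) -> list[ROIModelResult]:
    """Baseline cluster-vs-control SUVR contrasts, one OLS model per ROI.

    Uses the time-0 records only; ROIs with fewer than ``min_obs``
    observations are skipped with a warning.
    """
    _validate_roi_table(obs)
    base = obs[obs["time_years"] == 0]
    dup = base.duplicated(subset=["subject_id", "roi"])
    if dup.any():
        raise ValueError("multiple baseline observations per subject and ROI")
    results: list[ROIModelResult] = []
    for roi, df in base.groupby("roi", sort=True):
        if len(df) < min_obs:
            logger.warning("ROI %s skipped: only %d observations", roi, len(df))
            continue
        model = smf.ols(
            "suvr ~ C(group, Treatment('control')) + C(sex) + age", data=df
        ).fit()
        for name, coef in model.params.items():
            if not name.startswith("C(group"):
                continue
            cluster = name.split("[T.")[1].rstrip("]")
            results.append(ROIModelResult(
                roi=str(roi), cluster=cluster, coefficient=float(coef),
                std_error=float(model.bse[name]),
                p_value=float(model.pvalues[name]),
            ))
    return _finalize(results)


def fit_roi_model_longitudinal(
    obs: pd.DataFrame, min_obs: int = 10
) -> list[ROIModelResult]:
    """Cluster x time interaction contrasts from a random-intercept mixed model.

    Per ROI: ``suvr ~ cluster * time + sex + age`` with a subject-level random
    intercept.  Non-converging fits are retried with alternative optimizers;
    a ROI failing every attempt is dropped with a warning.
    """
    _validate_roi_table(obs)
    if obs["time_years"].nunique() < 2:
        raise ValueError("time column is constant: no longitudinal signal")
    n_multi = obs.groupby("subject_id")["time_years"].nunique()
    if (n_multi >= 2).mean() < 0.5:
        logger.warning(
            "fewer than half the subjects have repeat visits; "
            "longitudinal model may be weakly identified"
        )
    formula = ("suvr ~ C(group, Treatment('control')) * time_years"
               " + C(sex) + age")
    results: list[ROIModelResult] = []
    for roi, df in obs.groupby("roi", sort=True):
        if len(df) < min_obs:
            logger.warning("ROI %s skipped: only %d observations", roi, len(df))
            continue
        fit = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in ("lbfgs", "powell", "cg"):
                try:
                    cand = smf.mixedlm(
                        formula, data=df, groups=df["subject_id"]
                    ).fit(method=method, reml=True)
                    if np.isfinite(cand.params).all() and np.isfinite(
                        cand.bse.fillna(np.inf)
                    ).all():
                        fit = cand
                        break
                except Exception as exc:  # statsmodels raises broadly here
                    logger.debug("ROI %s %s failed: %s", roi, method, exc)
        if fit is None:
            logger.warning("ROI %s mixed model failed to converge; dropped", roi)
            continue
        for name, coef in fit.params.items():
            if not (name.startswith("C(group") and ":time_years" in name):
                continue
            cluster = name.split("[T.")[1].split("]")[0]
            results.append(ROIModelResult(
                roi=str(roi), cluster=cluster, coefficient=float(coef),
                std_error=float(fit.bse[name]),
                p_value=float(fit.pvalues[name]),
            ))
    return _finalize(results)


def roi_results_table(results: list[ROIModelResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "roi": r.roi, "cluster": r.cluster, "coefficient": r.coefficient,
        "std_error": r.std_error, "p": r.p_value, "fdr_p": r.fdr_p,
        "significant": r.significant, "most_affected": r.most_affected,
    } for r in results])
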
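"""Group-level statistics: correlations, ANCOVA, hierarchical regression.

Three analyses relate the reconfiguration summaries to behaviour:

1. Pearson correlations between each reconfiguration summary and each
   fatigue scale, separately per group, Bonferroni-corrected with an
   explicit, caller-declared family size.
2. ANCOVA group comparisons (metric ~ group + age + sex + education); for a
   two-level group the F statistic is the square of the group coefficient's
   t statistic.
3. Hierarchical ENTER regression: ordered covariate blocks (demographics →
   clinical → structural → the reconfiguration predictor) entered one at a
   time, reporting adjusted R² per step and the standardized β of the
   predictor in the full model.

Family sizes are never inferred silently: the default is the number of
metric columns tested, and the value used is echoed in every report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from netreconf.io import DMT_CATEGORIES, FATIGUE_SCALES
from netreconf.metrics import METRIC_NAMES

GLOBAL_METRIC_COLS = tuple(f"global_{m}" for m in METRIC_NAMES)


def bonferroni(p: float, family_size: int) -> float:
    return min(1.0, p * family_size)


def correlate_metrics_fatigue(summaries: pd.DataFrame, phenotypes: pd.DataFrame,
                              metric_cols=GLOBAL_METRIC_COLS,
                              fatigue_cols=FATIGUE_SCALES,
                              family_size: int | None = None) -> pd.DataFrame:
    """Bonferroni-corrected Pearson correlations, separately per group.

    ``family_size`` defaults to the number of metric columns (the tests run
    per fatigue scale per group); it multiplies every raw p, capped at 1.
    A zero-variance variable flags the cell rather than returning NaN
    silently.  Requires ≥ 3 complete pairs per cell.
    """
    m = family_size if family_size is not None else len(metric_cols)
    rows = []
    groups = phenotypes["group"].reindex(summaries.index)
    for group in sorted(groups.dropna().unique()):
        idx = summaries.index[groups == group]
        for scale in fatigue_cols:
            y_all = pd.to_numeric(phenotypes[scale].reindex(idx), errors="coerce")
            for col in metric_cols:
                x_all = pd.to_numeric(summaries[col].reindex(idx), errors="coerce")
                ok = x_all.notna() & y_all.notna()
                x, y = x_all[ok].to_numpy(), y_all[ok].to_numpy()
                row = {"group": group, "fatigue_scale": scale, "metric": col,
                       "n": int(ok.sum()), "family_size": m}
                if ok.sum() < 3:
                    row.update(r=np.nan, p_raw=np.nan, p_adj=np.nan, flag="n<3")
                elif x.std() == 0 or y.std() == 0:
                    row.update(r=np.nan, p_raw=np.nan, p_adj=np.nan, flag="zero_variance")
                else:
                    r, p = sps.pearsonr(x, y)
                    row.update(r=r, p_raw=p, p_adj=bonferroni(p, m), flag="")
                rows.append(row)
    return pd.DataFrame(rows)


def _design(phenotypes: pd.DataFrame, idx, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=idx)
    for c in covariates:
        X[c] = pd.to_numeric(phenotypes[c].reindex(idx), errors="coerce")
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        # identify an offending column by leave-one-out rank
        for j, col in enumerate(X.columns):
            sub = np.delete(arr, j + 1, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(arr):
                raise ValueError(f"collinear covariate: {col}")
        raise ValueError("design matrix is rank deficient")


def group_comparison_ancova(summaries: pd.DataFrame, phenotypes: pd.DataFrame,
                            metric_cols=GLOBAL_METRIC_COLS,
                            covariates=("age", "sex", "education"),
                            family_size: int | None = None) -> pd.DataFrame:
    """Covariate-adjusted group differences per metric.

    Fits ``metric ~ group + covariates`` by OLS; the group effect is the
    1-df F (= t²) on the group indicator, with Bonferroni adjustment across
    the metric family.  With no covariates this reduces exactly to a
    two-sample t-test (F = t²).
    """
    m = family_size if family_size is not None else len(metric_cols)
    groups = phenotypes["group"].reindex(summaries.index)
    if groups.dropna().nunique() < 2:
        raise ValueError("both groups must be represented")
    rows = []
    for col in metric_cols:
        data = pd.DataFrame({
            "y": pd.to_numeric(summaries[col], errors="coerce"),
            "group_ms": (groups == "pwMS").astype(float),
        })
        X = _design(phenotypes, summaries.index, covariates)
        data = pd.concat([data, X], axis=1).dropna()
        _check_full_rank(data[["group_ms", *covariates]])
        design = sm.add_constant(data[["group_ms", *covariates]])
        fit = sm.OLS(data["y"], design).fit()
        t = fit.tvalues["group_ms"]
        p = fit.pvalues["group_ms"]
        rows.append({"metric": col, "F": t ** 2, "p_raw": p,
                     "p_adj": bonferroni(p, m), "group_coef": fit.params["group_ms"],
                     "n": int(fit.nobs), "family_size": m})
    return pd.DataFrame(rows).set_index("metric")


def encode_dmt(series: pd.Series) -> pd.DataFrame:
    """Dummy-code DMT with 'none' as the reference.

    With all nine categories present this yields 8 indicator columns;
    categories absent from the data are dropped (an all-zero indicator would
    make the design rank deficient).  Column order follows the canonical
    category list.
    """
    cat = pd.Categorical(series, categories=DMT_CATEGORIES)
    dummies = pd.get_dummies(cat, prefix="dmt", dtype=float)
    dummies = dummies.set_axis(series.index, axis=0)
    keep = [c for c in dummies.columns
            if c != "dmt_none" and dummies[c].sum() > 0]
    return dummies[keep]


def default_blocks(phenotypes: pd.DataFrame) -> list:
    """The standard ordered covariate blocks for the hierarchical model."""
    dmt = encode_dmt(phenotypes["dmt_category"]) if "dmt_category" in phenotypes else pd.DataFrame(index=phenotypes.index)
    return [
        ("demographics", ["age", "sex", "education"]),
        ("clinical", ["edss", "disease_duration", *dmt.columns]),
        ("structural", ["nbv", "t2_ll"]),
    ]


def hierarchical_regression(data: pd.DataFrame, response: str, predictor: str,
                            blocks: list) -> dict:
    """Hierarchical ENTER regression with the predictor entered last.

    ``blocks`` is an ordered list of (name, [columns]); the reconfiguration
    predictor forms the final block.  Complete cases only (listwise
    deletion; the dropped count is reported).  Returns per-step adjusted R²
    and ΔR², and the standardized β (response and continuous predictors
    z-scored) with its p-value for the predictor in the full model.
    """
    all_blocks = list(blocks) + [("predictor", [predictor])]
    cols = [response] + [c for _, bc in all_blocks for c in bc]
    full = data[cols].apply(pd.to_numeric, errors="coerce")
    n_before = len(full)
    full = full.dropna()
    n = len(full)
    n_params = len(cols) + 1
    if n <= n_params:
        raise ValueError(f"{n} complete cases for {n_params} parameters")

    steps = []
    entered: list = []
    prev_r2 = 0.0
    y = full[response]
    for name, bc in all_blocks:
        entered.extend(bc)
        _check_full_rank(full[entered])
        X = sm.add_constant(full[entered])
        fit = sm.OLS(y, X).fit()
        steps.append({"block": name, "terms": list(bc), "r2": fit.rsquared,
                      "adj_r2": fit.rsquared_adj, "delta_r2": fit.rsquared - prev_r2,
                      "f_p": fit.f_pvalue})
        prev_r2 = fit.rsquared

    # standardized coefficients: z-score response and continuous columns
    zfull = full.copy()
    for c in full.columns:
        col = full[c]
        if col.nunique() > 2 and col.std(ddof=0) > 0:
            zfull[c] = (col - col.mean()) / col.std(ddof=0)
        elif c == response or c == predictor:
            sd = col.std(ddof=0)
            if sd > 0:
                zfull[c] = (col - col.mean()) / sd
    zfit = sm.OLS(zfull[response], sm.add_constant(zfull[entered])).fit()
    return {
        "steps": steps,
        "n": n,
        "n_dropped": n_before - n,
        "beta": float(zfit.params[predictor]),
        "beta_se": float(zfit.bse[predictor]),
        "beta_p": float(zfit.pvalues[predictor]),
        "adj_r2_full": steps[-1]["adj_r2"],
        "final_fit": zfit,
    }
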
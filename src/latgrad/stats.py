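"""Group-difference statistics: ANCOVA, Tukey post-hocs, Bonferroni.

The ANCOVA models a metric as a linear function of the phenotype, the
covariates (age, sex, intracranial volume, handedness) and the
handedness-by-phenotype interaction. The phenotype main effect uses a
Type-II sum of squares by model comparison (the interaction is excluded
from both the reduced and the augmented model, the error term comes from
the full model). Post-hoc two-group contrasts use Student's t on the
covariate-adjusted model; three-level comparisons use Tukey's range test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AncovaResult",
    "ancova_fit",
    "posthoc_ttest",
    "tukey_hsd",
    "adjust_bonferroni",
    "feature_group_stats",
    "gradient_grid_stats",
]


class StatsError(ValueError):
    pass


@dataclass
class AncovaResult:
    F: float
    p_value: float
    df_num: int
    df_den: int
    coef: pd.DataFrame
    n: int


def _design(
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None,
    interaction: bool,
    handedness_col: str = "is_left_handed",
):
    """Build (covariate block, phenotype dummy block, interaction block).

    The phenotype reference level is the first level in sorted order; sex and
    handedness enter as 0/1 indicators as provided by the covariate table.
    """
    phen = np.asarray(phenotype, dtype=object)
    levels = sorted(set(phen.tolist()))
    if len(levels) < 2:
        raise StatsError("phenotype must have at least 2 levels")
    dummies = np.column_stack([(phen == lv).astype(float) for lv in levels[1:]])
    dummy_names = [f"phenotype[{lv}]" for lv in levels[1:]]
    if covariates is not None and len(covariates.columns):
        C = covariates.to_numpy(dtype=float)
        cov_names = list(covariates.columns)
    else:
        C = np.empty((len(phen), 0))
        cov_names = []
    inter = np.empty((len(phen), 0))
    inter_names: list[str] = []
    if interaction and handedness_col in cov_names:
        h = covariates[handedness_col].to_numpy(dtype=float)
        inter = dummies * h[:, None]
        inter_names = [f"{handedness_col}:{nm}" for nm in dummy_names]
    return (C, cov_names), (dummies, dummy_names), (inter, inter_names), levels


def _ols(y, X):
    model = sm.OLS(y, X)
    return model.fit()


def ancova_fit(
    y: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None = None,
    interaction: bool = True,
) -> AncovaResult:
    """OLS ANCOVA with a Type-II F test for the phenotype main effect."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    (C, cov_names), (D, dummy_names), (I, inter_names), _ = _design(
        phenotype, covariates, interaction
    )
    ones = np.ones((n, 1))
    X_full = np.column_stack([ones, C, D, I])
    names_full = ["intercept", *cov_names, *dummy_names, *inter_names]
    if n <= X_full.shape[1]:
        raise StatsError("more model columns than observations")
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        raise StatsError(
            f"rank-deficient design ({rank} < {X_full.shape[1]}); "
            f"columns: {names_full}"
        )
    full = _ols(y, X_full)
    # Type II: phenotype SS given covariates, ignoring the interaction,
    # error term from the full model.
    X_aug = np.column_stack([ones, C, D])
    X_red = np.column_stack([ones, C])
    rss_aug = float(_ols(y, X_aug).ssr)
    rss_red = float(_ols(y, X_red).ssr)
    df_num = D.shape[1]
    df_den = int(full.df_resid)
    ms_err = float(full.ssr) / df_den
    F = ((rss_red - rss_aug) / df_num) / ms_err
    p = float(sps.f.sf(F, df_num, df_den))
    coef = pd.DataFrame(
        {
            "term": names_full,
            "estimate": full.params,
            "se": full.bse,
            "t": full.tvalues,
            "p_value": full.pvalues,
        }
    )
    return AncovaResult(F=float(F), p_value=p, df_num=df_num, df_den=df_den, coef=coef, n=n)


def posthoc_ttest(
    y: np.ndarray,
    phenotype: np.ndarray,
    covariates: pd.DataFrame | None,
    pair: tuple,
) -> tuple[float, float, int]:
    """Covariate-adjusted two-sided Student's t contrast between two
    phenotype levels (fit on the subset belonging to either level).
    Returns (t, p, df)."""
    phen = np.asarray(phenotype, dtype=object)
    mask = np.isin(phen, list(pair))
    if mask.sum() < 3:
        raise StatsError("not enough observations for the contrast")
    sub_cov = covariates.loc[mask].reset_index(drop=True) if covariates is not None else None
    res = ancova_fit(np.asarray(y, dtype=float)[mask], phen[mask], sub_cov, interaction=False)
    row = res.coef[res.coef["term"].str.startswith("phenotype[")].iloc[0]
    return float(row["t"]), float(row["p_value"]), res.df_den


def tukey_hsd(y: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """All-pairs comparisons with studentized-range (Tukey HSD) adjusted p."""
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups, dtype=object)
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise StatsError("need at least 2 groups")
    samples = []
    for lv in levels:
        s = y[groups == lv]
        if len(s) < 2:
            raise StatsError(f"group {lv!r} has fewer than 2 observations")
        samples.append(s)
    res = sps.tukey_hsd(*samples)
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            rows.append(
                {
                    "group_a": levels[i],
                    "group_b": levels[j],
                    "mean_diff": float(res.statistic[i, j]),
                    "p_adjusted": float(res.pvalue[i, j]),
                }
            )
    return pd.DataFrame(rows)


def adjust_bonferroni(p_values, n_tests: int) -> np.ndarray:
    """min(1, p * n_tests) per entry."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise StatsError("p-values must lie in [0, 1]")
    if n_tests < 1:
        raise StatsError("n_tests must be at least 1")
    return np.minimum(1.0, p * n_tests)


# ---------------------------------------------------------------------------
# Pipeline-facing tables
# ---------------------------------------------------------------------------

ANCOVA_COVARIATES = ("age", "sex_female", "intracranial_volume", "is_left_handed")


def _covariate_block(covariates: pd.DataFrame | None) -> pd.DataFrame | None:
    if covariates is None:
        return None
    cols = [c for c in ANCOVA_COVARIATES if c in covariates.columns]
    return covariates[cols].reset_index(drop=True)


def feature_group_stats(
    features: pd.DataFrame,
    group_names: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature phenotype ANCOVA plus Tukey pairwise contrasts.

    Returns (main-effect table, post-hoc table); group summary columns report
    mean, SE and the CI95 half-width per group.
    """
    cov = _covariate_block(covariates)
    main_rows, posthoc_rows = [], []
    feature_cols = [c for c in features.columns if c != "subject_id"]
    for feat in feature_cols:
        y = features[feat].to_numpy(dtype=float)
        res = ancova_fit(y, group_names, cov, interaction=True)
        row = {"feature": feat, "F": res.F, "p_value": res.p_value,
               "df_num": res.df_num, "df_den": res.df_den}
        for g in sorted(set(group_names.tolist())):
            vals = y[group_names == g]
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            row[f"mean[{g}]"] = float(vals.mean())
            row[f"se[{g}]"] = se
            row[f"ci95[{g}]"] = 1.96 * se
        main_rows.append(row)
        tk = tukey_hsd(y, group_names)
        tk.insert(0, "feature", feat)
        posthoc_rows.append(tk)
    return pd.DataFrame(main_rows), pd.concat(posthoc_rows, ignore_index=True)


def gradient_grid_stats(
    asymmetry: pd.DataFrame,
    typicality: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_tests: int = 7,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Typical-versus-atypical grid over (gradient, network).

    ``asymmetry`` is the long (subject_id, network, gradient, asymmetry)
    table; ``typicality`` maps subject_id to a binary label ("typical" /
    "atypical", the two typical phenotypes merged). Cells carry the
    post-hoc t of the typicality effect, its raw p, and the Bonferroni flag
    for n = 7 networks per gradient.
    """
    lab = typicality.set_index("subject_id")["typicality"]
    cov_full = None
    if covariates is not None:
        cov_full = covariates.set_index("subject_id")
    rows = []
    for (grad, net), sub in asymmetry.groupby(["gradient", "network"], sort=True):
        sub = sub.set_index("subject_id")
        common = sub.index.intersection(lab.index)
        y = sub.loc[common, "asymmetry"].to_numpy(dtype=float)
        phen = lab.loc[common].to_numpy(dtype=object)
        cov = None
        if cov_full is not None:
            cov = _covariate_block(cov_full.loc[common].reset_index())
        res = ancova_fit(y, phen, cov, interaction=True)
        t_stat, p_raw, _ = posthoc_ttest(y, phen, cov, ("typical", "atypical"))
        mu_typ = float(y[phen == "typical"].mean())
        mu_aty = float(y[phen == "atypical"].mean())
        n_aty = int((phen == "atypical").sum())
        se_aty = float(y[phen == "atypical"].std(ddof=1) / np.sqrt(n_aty)) if n_aty > 1 else np.nan
        rows.append(
            {
                "gradient": int(grad),
                "network": net,
                "F": res.F,
                "t": t_stat,
                "p_value": p_raw,
                "significant_uncorrected": bool(p_raw <= alpha),
                "significant_bonferroni": bool(p_raw <= alpha / n_tests),
                "mean_typical": mu_typ,
                "mean_atypical": mu_aty,
                "ci95_atypical": 1.96 * se_aty,
            }
        )
    return pd.DataFrame(rows)
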
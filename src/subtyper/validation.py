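"""Subtype validation statistics.

Characterizes final subtypes by (i) voxelwise subtype-vs-control ALFF
contrast maps with cluster-level correction and Cohen's d effect sizes,
(ii) Welch two-sample tests on clinical factor scores with
Benjamini-Hochberg FDR across the factors of one comparison family, and
(iii) logistic association of continuous risk scores (polygenic-score
stand-ins) with subtype membership, summarized by Nagelkerke's pseudo-R²
with a multi-threshold significance level (default p = 0.004).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glm import DesignSpec, SelectedVoxels, cluster_correct, fit_voxelwise_glm
from .simulate import Cohort

__all__ = [
    "SubtypeContrast",
    "ScoreAssociation",
    "bh_adjust",
    "cohens_d",
    "subtype_contrast_maps",
    "factor_tests",
    "score_association",
]


def bh_adjust(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    rej, p_adj, _, _ = multipletests(np.asarray(p_values, float), alpha=q,
                                     method="fdr_bh")
    return rej, p_adj


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference (pooled-SD convention): (x̄ − ȳ)/s_p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples must have size >= 2")
    nx, ny = x.size, y.size
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var <= 0:
        raise ValueError("zero pooled variance; Cohen's d is undefined")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def _cohens_d_map(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized pooled-SD Cohen's d per column (voxel)."""
    nx, ny = x.shape[0], y.shape[0]
    pooled_var = (
        (nx - 1) * x.var(axis=0, ddof=1) + (ny - 1) * y.var(axis=0, ddof=1)
    ) / (nx + ny - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(
            pooled_var > 0, (x.mean(axis=0) - y.mean(axis=0)) / np.sqrt(pooled_var), 0.0
        )


@dataclass
class SubtypeContrast:
    """Voxelwise subtype-vs-control contrast with retained clusters."""

    subtype: int
    t: np.ndarray  # per mask voxel
    p: np.ndarray
    d: np.ndarray
    selected: SelectedVoxels
    n_subtype: int
    n_control: int
    mask: np.ndarray

    def volume(self, which: str = "t") -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = getattr(self, which)
        return vol


def subtype_contrast_maps(
    cohort: Cohort,
    subtype_labels: dict[str, int] | pd.Series,
    design: DesignSpec | None = None,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    method: str = "grf",
    min_members: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[SubtypeContrast]:
    """One GLM contrast (subtype vs all controls) per final subtype.

    Reuses the voxelwise GLM and cluster-correction machinery of the
    screening stage, adding a voxelwise pooled-SD Cohen's d map; ``t`` and
    ``d`` share sign by construction.
    """
    labels = pd.Series(subtype_labels)
    design = design or DesignSpec()
    sid = cohort.phenotypes["subject_id"]
    control_idx = cohort.indices("control")
    if control_idx.size == 0:
        raise ValueError("no control subjects available")
    out = []
    for subtype in sorted(labels.unique()):
        members = labels.index[labels == subtype]
        member_idx = np.flatnonzero(sid.isin(members).to_numpy())
        if member_idx.size < min_members:
            raise ValueError(
                f"subtype {subtype} has only {member_idx.size} members "
                f"(< {min_members}); contrast refused"
            )
        subset = np.concatenate([member_idx, control_idx])
        glm = fit_voxelwise_glm(cohort, design, subset=subset)
        selected = cluster_correct(
            glm,
            cohort.mask,
            voxel_p=voxel_p,
            cluster_p=cluster_p,
            method=method,
            n_perm=n_perm,
            seed=seed,
            cohort=cohort,
            subset=subset,
        )
        d_map = _cohens_d_map(
            cohort.masked_data(member_idx), cohort.masked_data(control_idx)
        )
        out.append(
            SubtypeContrast(
                int(subtype),
                glm.t,
                glm.p,
                d_map,
                selected,
                member_idx.size,
                control_idx.size,
                cohort.mask,
            )
        )
    return out


def factor_tests(
    table: pd.DataFrame,
    group_col: str,
    factor_cols: list[str],
    q: float = 0.05,
) -> pd.DataFrame:
    """Welch two-sample t-test per factor with BH-FDR across the family.

    ``table[group_col]`` must take exactly two values; rows with too few
    observations per arm are flagged ``testable=False`` and excluded from
    the FDR family rather than dropped silently.
    """
    levels = sorted(pd.unique(table[group_col].dropna()))
    if len(levels) != 2:
        raise ValueError(f"grouping column must have 2 levels, got {levels}")
    a_mask = table[group_col] == levels[0]
    b_mask = table[group_col] == levels[1]
    rows = []
    for col in factor_cols:
        x = table.loc[a_mask, col].dropna().to_numpy(dtype=float)
        y = table.loc[b_mask, col].dropna().to_numpy(dtype=float)
        row = {
            "factor": col,
            f"mean_{levels[0]}": x.mean() if x.size else np.nan,
            f"mean_{levels[1]}": y.mean() if y.size else np.nan,
        }
        if x.size < 2 or y.size < 2:
            row.update(
                diff=np.nan, ci_low=np.nan, ci_high=np.nan, cohens_d=np.nan,
                t=np.nan, p_raw=np.nan, testable=False,
            )
        else:
            res = stats.ttest_ind(x, y, equal_var=False)
            diff = x.mean() - y.mean()
            se = np.sqrt(x.var(ddof=1) / x.size + y.var(ddof=1) / y.size)
            tcrit = stats.t.ppf(0.975, res.df)
            row.update(
                diff=diff,
                ci_low=diff - tcrit * se,
                ci_high=diff + tcrit * se,
                cohens_d=cohens_d(x, y),
                t=float(res.statistic),
                p_raw=float(res.pvalue),
                testable=True,
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("factor")
    out["p_fdr"] = np.nan
    out["significant"] = False
    testable = out["testable"].to_numpy()
    if testable.any():
        rej, p_adj = bh_adjust(out.loc[testable, "p_raw"].to_numpy(), q)
        out.loc[testable, "p_fdr"] = p_adj
        out.loc[testable, "significant"] = rej
    return out


def _nagelkerke(ll_null: float, ll_full: float, n: int) -> float:
    """Nagelkerke pseudo-R²: Cox-Snell rescaled to a [0, 1) range."""
    cox_snell = 1.0 - np.exp((2.0 / n) * (ll_null - ll_full))
    max_cs = 1.0 - np.exp((2.0 / n) * ll_null)
    if max_cs <= 0:
        return 0.0
    return float(np.clip(cox_snell / max_cs, 0.0, 1.0 - 1e-12))


@dataclass
class ScoreAssociation:
    """Per-score logistic fits of group membership with Nagelkerke R²."""

    table: pd.DataFrame  # index: score column; coef, p, r2_nagelkerke, converged
    alpha: float
    best_fit: list[str] = field(default_factory=list)  # top columns by R²


def _fit_logistic(y: np.ndarray, X: np.ndarray):
    """MLE logistic fit; falls back to ridge-stabilized fit on separation."""
    model = sm.Logit(y, X)
    try:
        with np.errstate(all="ignore"):
            res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True)) and np.all(
            np.isfinite(res.bse)
        )
        if converged:
            return res.params, res.pvalues, float(res.llf), True
    except Exception:
        pass
    # (quasi-)separation: a small L2 penalty bounds the estimate
    res = model.fit_regularized(alpha=1e-3, L1_wt=0.0, disp=0, maxiter=500)
    params = np.asarray(res.params)
    ll = float(model.loglike(params))
    pvals = np.full_like(params, np.nan, dtype=float)
    return params, pvals, ll, False


def score_association(
    labels: np.ndarray,
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.004,
    n_best: int = 10,
) -> ScoreAssociation:
    """Logistic regression of a binary membership indicator on each score.

    Each score column is fit separately (optionally with covariates);
    Nagelkerke's pseudo-R² measures explained variation and significance is
    called at ``alpha``, a conservative level accounting for the many
    correlated score thresholds typically screened.
    """
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be a 0/1 indicator")
    if min((y == 0).sum(), (y == 1).sum()) < 10:
        raise ValueError("need >= 10 subjects per arm")
    n = y.size
    base = [np.ones(n)]
    if covariates is not None:
        base.extend(np.asarray(covariates, dtype=float).T)
    X0 = np.column_stack(base)
    _, _, ll_null, _ = _fit_logistic(y, X0)

    rows = []
    for col in scores.columns:
        s = scores[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(s)):
            raise ValueError(f"score column '{col}' contains non-finite values")
        X = np.column_stack([X0, s])
        params, pvals, ll_full, converged = _fit_logistic(y, X)
        r2 = _nagelkerke(ll_null, ll_full, n)
        rows.append(
            {
                "score": col,
                "coef": float(params[-1]),
                "p": float(pvals[-1]),
                "r2_nagelkerke": r2,
                "converged": converged,
                "significant": bool(pvals[-1] < alpha) if np.isfinite(pvals[-1]) else False,
            }
        )
    table = pd.DataFrame(rows).set_index("score")
    best = table["r2_nagelkerke"].sort_values(ascending=False).index[:n_best]
    return ScoreAssociation(table, alpha, list(best))
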
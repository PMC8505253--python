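"""Mass-univariate voxel screening: GLM, smoothness, cluster correction.

The screen fits, at every mask voxel, an ordinary-least-squares model of
ALFF on group (patient/control), sex and mean-centered age, thresholds the
two-sided group t-map at a voxel p, extracts connected suprathreshold
components, and assigns each component a cluster-corrected p either from
Gaussian-random-field (GRF) theory using the residual smoothness, or from a
Freedman-Lane permutation null of the maximal cluster extent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .simulate import Cohort

__all__ = [
    "DesignSpec",
    "DesignError",
    "VoxelGLMResult",
    "SelectedVoxels",
    "FeatureMatrix",
    "fit_voxelwise_glm",
    "estimate_smoothness",
    "cluster_correct",
    "extract_feature_matrix",
    "select_high_variance_voxels",
]

_4LN2 = 4.0 * np.log(2.0)


class DesignError(ValueError):
    """Raised for rank-deficient or otherwise invalid design matrices."""


@dataclass
class DesignSpec:
    """Columns of the subject-level design matrix.

    ``group_levels`` maps the two phenotype ``group`` values to 0/1 codes;
    the group coefficient (coded level 1 minus level 0) is the contrast of
    interest, tested two-sided.  Age is mean-centered before fitting.
    """

    group_col: str = "group"
    group_levels: tuple[str, str] = ("control", "patient")
    sex_col: str | None = "sex"
    age_col: str | None = "age"

    def build_matrix(self, phenotypes) -> tuple[np.ndarray, list[str]]:
        groups = phenotypes[self.group_col].to_numpy()
        unknown = set(groups) - set(self.group_levels)
        if unknown:
            raise DesignError(f"unexpected group labels: {sorted(unknown)}")
        cols = [np.ones(len(phenotypes)), (groups == self.group_levels[1]).astype(float)]
        names = ["intercept", "group"]
        if self.sex_col is not None:
            cols.append(phenotypes[self.sex_col].to_numpy(dtype=float))
            names.append("sex")
        if self.age_col is not None:
            age = phenotypes[self.age_col].to_numpy(dtype=float)
            cols.append(age - age.mean())
            names.append("age")
        X = np.column_stack(cols)
        _check_full_rank(X, names)
        return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # flag columns whose removal restores full column rank
        offending = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise DesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {offending}"
        )


@dataclass
class VoxelGLMResult:
    """Per-voxel group-effect statistics over the mask."""

    beta: np.ndarray  # group coefficient per mask voxel
    t: np.ndarray
    p: np.ndarray  # two-sided
    df: int
    mask: np.ndarray  # bool grid
    residuals: np.ndarray  # subjects x mask voxels
    design: np.ndarray
    design_names: list[str]
    fwhm: np.ndarray | None = None  # estimated after the fact

    def t_volume(self) -> np.ndarray:
        vol = np.zeros(self.mask.shape)
        vol[self.mask] = self.t
        return vol


def _ols_group_stats(X: np.ndarray, Y: np.ndarray, group_idx: int):
    """OLS fit of Y (n x V) on X; t/p for the ``group_idx`` coefficient."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta_all = XtX_inv @ X.T @ Y
    resid = Y - X @ beta_all
    df = n - p
    if df <= 0:
        raise DesignError(f"no residual degrees of freedom (n={n}, p={p})")
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[group_idx, group_idx], 0.0))
    beta = beta_all[group_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, t, pvals, df, resid


def fit_voxelwise_glm(
    cohort: Cohort,
    design: DesignSpec | None = None,
    subset: np.ndarray | None = None,
) -> VoxelGLMResult:
    """Voxelwise OLS of ALFF on group + covariates over the brain mask.

    ``subset`` restricts the fit to the given subject indices (e.g. one
    subtype plus all controls).  Results do not depend on subject order.
    """
    design = design or DesignSpec()
    pheno = cohort.phenotypes if subset is None else cohort.phenotypes.iloc[subset]
    for level in design.group_levels:
        if (pheno[design.group_col] == level).sum() < 2:
            raise DesignError(f"need >= 2 subjects in group '{level}'")
    X, names = design.build_matrix(pheno)
    Y = cohort.masked_data(subset)
    beta, t, p, df, resid = _ols_group_stats(X, Y, names.index("group"))
    return VoxelGLMResult(beta, t, p, df, cohort.mask, resid, X, names)


def estimate_smoothness(
    residuals: np.ndarray, mask: np.ndarray, min_fwhm: float = 1.0
) -> np.ndarray:
    """Per-axis FWHM (voxels) from variance of standardized-residual gradients.

    Residual images are scaled to unit voxelwise variance; for each axis the
    pooled variance of first differences between in-mask neighbours
    estimates the derivative variance lambda, and FWHM = sqrt(4 ln 2 / lambda)
    (exactly 1.18 voxels for white noise).  Values are floored at
    ``min_fwhm``.
    """
    if residuals.ndim != 2:
        raise ValueError("residuals must be subjects x mask-voxels")
    if residuals.shape[0] < 3:
        raise ValueError("need residuals from >= 3 subjects")
    sd = residuals.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError(
            "constant residuals at some voxels; smoothness is undefined"
        )
    std_res = residuals / sd
    vols = np.zeros((residuals.shape[0],) + mask.shape)
    vols[:, mask] = std_res
    fwhm = np.empty(3)
    for axis in range(3):
        m_pair = mask & np.roll(mask, -1, axis=axis)
        m_pair[tuple(slice(None) if a != axis else slice(-1, None) for a in range(3))] = False
        diffs = (np.roll(vols, -1, axis=axis + 1) - vols)[:, m_pair]
        lam = (diffs**2).mean()
        fwhm[axis] = np.sqrt(_4LN2 / lam) if lam > 0 else np.inf
    return np.maximum(np.nan_to_num(fwhm, posinf=max(mask.shape)), min_fwhm)


@dataclass
class SelectedVoxels:
    """Suprathreshold clusters surviving correction and their voxel union."""

    clusters: list[dict]  # coords (k x 3), extent, corrected_p, peak_t
    indices: np.ndarray  # ascending flat voxel indices over the grid
    grid_shape: tuple[int, int, int]
    voxel_p: float
    cluster_p: float
    method: str

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    def to_mask(self) -> np.ndarray:
        out = np.zeros(int(np.prod(self.grid_shape)), dtype=bool)
        out[self.indices] = True
        return out.reshape(self.grid_shape)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}.get(connectivity)
    if order is None:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order)


def _labeled_clusters(t_vol, mask, t_crit, structure):
    """Connected suprathreshold components, positive and negative separately."""
    comps = []
    for signed in (t_vol >= t_crit, t_vol <= -t_crit):
        lab, n = ndimage.label(signed & mask, structure=structure)
        for c in range(1, n + 1):
            comps.append(np.flatnonzero((lab == c).ravel()))
    return comps


def grf_cluster_p(
    extent: int, z_thresh: float, n_mask_voxels: int, fwhm: np.ndarray
) -> float:
    """Corrected cluster p from random-field expected cluster counts.

    Uses the 3D Euler-characteristic density at the (Gaussianized) voxel
    threshold, resels = mask volume / prod(FWHM), an exponential
    approximation for cluster extent with ``P(N >= k) = exp(-beta k^(2/3))``,
    and a Poisson clumping bound for the corrected p.  Both signs of the
    two-sided test contribute to the expected cluster count.
    """
    u = float(z_thresh)
    resels = n_mask_voxels / float(np.prod(fwhm))
    ec3 = (_4LN2**1.5) / (2.0 * np.pi) ** 2 * (u**2 - 1.0) * np.exp(-(u**2) / 2.0)
    e_clusters = 2.0 * max(resels * ec3, 1e-300)  # two-sided
    e_voxels = 2.0 * n_mask_voxels * stats.norm.sf(u)
    mean_extent = max(e_voxels / e_clusters, 1e-300)
    beta = (math.gamma(2.5) / mean_extent) ** (2.0 / 3.0)
    p_extent = np.exp(-beta * extent ** (2.0 / 3.0))
    return float(1.0 - np.exp(-e_clusters * p_extent))


def _max_cluster_extent(t_vol, mask, t_crit, structure) -> int:
    comps = _labeled_clusters(t_vol, mask, t_crit, structure)
    return max((c.size for c in comps), default=0)


def cluster_correct(
    glm: VoxelGLMResult,
    mask: np.ndarray,
    voxel_p: float = 0.001,
    cluster_p: float = 0.05,
    method: str = "grf",
    connectivity: int = 26,
    n_perm: int = 1000,
    seed: int = 0,
    cohort: Cohort | None = None,
    subset: np.ndarray | None = None,
) -> SelectedVoxels:
    """Threshold the group t-map and keep clusters passing correction.

    ``method='grf'`` computes corrected cluster p-values from random-field
    theory with smoothness estimated from the GLM residuals;
    ``method='permutation'`` builds a Freedman-Lane null of the maximal
    suprathreshold cluster extent by permuting reduced-model residuals
    (requires ``cohort``).
    """
    if not (0 < voxel_p < 1 and 0 < cluster_p < 1):
        raise ValueError("voxel_p and cluster_p must be in (0, 1)")
    t_crit = stats.t.isf(voxel_p / 2.0, glm.df)
    structure = _connectivity_structure(connectivity)
    t_vol = glm.t_volume()
    comps = _labeled_clusters(t_vol, mask, t_crit, structure)

    kept: list[dict] = []
    if comps:
        if method == "grf":
            fwhm = estimate_smoothness(glm.residuals, mask)
            glm.fwhm = fwhm
            z_thresh = stats.norm.isf(voxel_p / 2.0)
            for c in comps:
                p_corr = grf_cluster_p(c.size, z_thresh, int(mask.sum()), fwhm)
                if p_corr < cluster_p:
                    kept.append(_cluster_record(c, t_vol, mask.shape, p_corr))
        elif method == "permutation":
            if cohort is None:
                raise ValueError("permutation correction requires the cohort")
            null_max = _freedman_lane_null(
                glm, cohort, subset, mask, t_crit, structure, n_perm, seed
            )
            for c in comps:
                p_corr = (1.0 + np.sum(null_max >= c.size)) / (n_perm + 1.0)
                if p_corr < cluster_p:
                    kept.append(_cluster_record(c, t_vol, mask.shape, p_corr))
        else:
            raise ValueError(f"unknown correction method '{method}'")

    if kept:
        indices = np.unique(np.concatenate([k["flat_indices"] for k in kept]))
    else:
        indices = np.array([], dtype=int)
    return SelectedVoxels(kept, indices, mask.shape, voxel_p, cluster_p, method)


def _cluster_record(flat_idx, t_vol, grid_shape, p_corr) -> dict:
    coords = np.column_stack(np.unravel_index(flat_idx, grid_shape))
    tvals = t_vol.ravel()[flat_idx]
    peak = flat_idx[np.argmax(np.abs(tvals))]
    return {
        "flat_indices": flat_idx,
        "coords": coords,
        "extent": int(flat_idx.size),
        "corrected_p": float(p_corr),
        "peak_index": int(peak),
        "peak_t": float(tvals[np.argmax(np.abs(tvals))]),
    }


def _freedman_lane_null(
    glm, cohort, subset, mask, t_crit, structure, n_perm, seed
) -> np.ndarray:
    """Max-cluster-extent null via permutation of reduced-model residuals."""
    rng = np.random.default_rng(seed)
    X = glm.design
    g = glm.design_names.index("group")
    Xr = np.delete(X, g, axis=1)
    Y = cohort.masked_data(subset)
    Hr = Xr @ np.linalg.inv(Xr.T @ Xr) @ Xr.T
    fitted_r = Hr @ Y
    resid_r = Y - fitted_r
    n = Y.shape[0]
    null_max = np.empty(n_perm)
    t_vol = np.zeros(mask.shape)
    for b in range(n_perm):
        perm = rng.permutation(n)
        Y_star = fitted_r + resid_r[perm]
        _, t_star, _, _, _ = _ols_group_stats(X, Y_star, g)
        t_vol[mask] = t_star
        null_max[b] = _max_cluster_extent(t_vol, mask, t_crit, structure)
    return null_max


@dataclass
class FeatureMatrix:
    """Subjects x selected-voxel ALFF values with a voxel coordinate map."""

    values: np.ndarray
    subject_ids: np.ndarray
    voxel_indices: np.ndarray  # flat grid indices, ascending
    voxel_coords: np.ndarray  # k x 3
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")
        if self.values.shape != (len(self.subject_ids), len(self.voxel_indices)):
            raise ValueError("feature matrix shape mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def extract_feature_matrix(
    cohort: Cohort,
    selected: SelectedVoxels,
    subjects: str | np.ndarray = "patient",
) -> FeatureMatrix:
    """Raw ALFF values at the selected voxels for the requested subjects.

    ``subjects`` may be a group name or an explicit index array; clustering
    downstream conventionally uses patients only.
    """
    if selected.n_voxels == 0:
        raise ValueError("no voxels selected; cannot build a feature matrix")
    idx = (
        cohort.indices(subjects) if isinstance(subjects, str) else np.asarray(subjects)
    )
    flat = cohort.volumes[idx].reshape(len(idx), -1)
    order = np.sort(selected.indices)
    coords = np.column_stack(np.unravel_index(order, selected.grid_shape))
    return FeatureMatrix(
        flat[:, order], cohort.subject_ids[idx], order, coords, selected.grid_shape
    )


def select_high_variance_voxels(
    cohort: Cohort, n_voxels: int = 512, subjects: str = "patient"
) -> SelectedVoxels:
    """Unsupervised screen: top mask voxels by between-subject variance.

    Complements the supervised GLM screen, which is blind to sign-opposed
    subtype effects that cancel in the patient-vs-control group mean while
    still inflating the patient-arm variance at affected voxels.
    """
    idx = cohort.indices(subjects)
    data = cohort.masked_data(idx)
    var = data.var(axis=0, ddof=1)
    n_keep = min(n_voxels, var.size)
    mask_flat = np.flatnonzero(cohort.mask.ravel())
    top = np.argsort(-var, kind="stable")[:n_keep]
    indices = np.sort(mask_flat[top])
    return SelectedVoxels(
        [], indices, cohort.mask.shape, np.nan, np.nan, "variance"
    )
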
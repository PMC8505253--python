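"""Synthetic resting-state ALFF cohorts with planted subtype structure.

Emulates a two-arm case/control cohort in which the patient arm hides two
(or more) latent subtypes whose ALFF alterations are spatially structured
and sign-opposed between a "frontal" and a "posterior" mask region —
subtype 1 with increased frontal / decreased posterior amplitude, subtype 2
the converse.  Age and sex enter as additive global covariate effects; voxel
noise is i.i.d. Gaussian with optional spatial smoothing.  Ground-truth
subtype labels are stored apart from the phenotype table so that no
downstream stage can consume them by accident.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "SimConfig",
    "Cohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: sign of the (frontal, posterior) mean shift for each latent subtype
SUBTYPE_SIGN_PATTERNS = [(+1, -1), (-1, +1), (+1, +1), (-1, -1)]

_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Effect sizes (``effect_size``, ``age_beta``, ``sex_beta``) are expressed
    in units of the voxel noise standard deviation, so ``effect_size=1.0``
    plants a Cohen's d of 1 per affected voxel for a single-subtype cohort.
    """

    n_patients: int = 200
    n_controls: int = 100
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    mask_fraction: float = 0.5
    n_subtypes: int = 2
    subtype_proportions: tuple[float, ...] | None = None
    effect_size: float = 1.0
    frontal_region: np.ndarray | None = None  # flat voxel indices
    posterior_region: np.ndarray | None = None
    age_range: tuple[float, float] = (18.0, 60.0)
    sex_balance: float = 0.5
    age_beta: float = 0.2
    sex_beta: float = 0.2
    noise_sd: float = 1.0
    smoothing_fwhm: float | None = None
    baseline: float = 1.0
    n_factors: int = 3
    n_scores: int = 3
    factor_effect: float = 0.8
    medication_effect: float = 0.5
    score_effect: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ConfigurationError("n_patients and n_controls must be positive")
        if len(self.grid_shape) != 3 or any(g <= 0 for g in self.grid_shape):
            raise ConfigurationError("grid_shape must be 3 positive integers")
        if not 0 < self.mask_fraction <= 1:
            raise ConfigurationError("mask_fraction must be in (0, 1]")
        if self.n_subtypes < 1:
            raise ConfigurationError("n_subtypes must be >= 1")
        if self.n_subtypes > len(SUBTYPE_SIGN_PATTERNS):
            raise ConfigurationError(
                f"at most {len(SUBTYPE_SIGN_PATTERNS)} subtypes supported"
            )
        if self.subtype_proportions is None:
            self.subtype_proportions = tuple(
                1.0 / self.n_subtypes for _ in range(self.n_subtypes)
            )
        props = np.asarray(self.subtype_proportions, dtype=float)
        if len(props) != self.n_subtypes:
            raise ConfigurationError(
                "subtype_proportions length must equal n_subtypes"
            )
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
            raise ConfigurationError("subtype_proportions must sum to 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0 <= self.sex_balance <= 1:
            raise ConfigurationError("sex_balance must be in [0, 1]")


@dataclass
class Cohort:
    """In-memory cohort: phenotypes, aligned volumes, mask, optional truth."""

    phenotypes: pd.DataFrame
    volumes: np.ndarray  # (n_subjects, *grid_shape)
    mask: np.ndarray  # bool, grid_shape
    affine: np.ndarray
    truth: pd.Series | None = None  # per-patient subtype label (simulated only)
    config: SimConfig | None = None

    def __post_init__(self) -> None:
        if self.volumes.shape[0] != len(self.phenotypes):
            raise ValueError("one volume per subject required")
        if self.volumes.shape[1:] != self.mask.shape:
            raise ValueError("volume grid must match mask shape")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.phenotypes["subject_id"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.phenotypes)

    def indices(self, group: str) -> np.ndarray:
        return np.flatnonzero(self.phenotypes["group"].to_numpy() == group)

    def masked_data(self, subset: np.ndarray | None = None) -> np.ndarray:
        """Subjects x mask-voxels matrix of ALFF values."""
        vols = self.volumes if subset is None else self.volumes[subset]
        return vols[:, self.mask]


def make_mask(grid_shape: tuple[int, int, int], fraction: float) -> np.ndarray:
    """Centered ball-shaped brain mask covering ``fraction`` of the grid."""
    coords = np.indices(grid_shape, dtype=float)
    center = (np.asarray(grid_shape, dtype=float) - 1.0) / 2.0
    dist2 = sum((coords[a] - center[a]) ** 2 for a in range(3))
    n_in = max(1, int(round(fraction * np.prod(grid_shape))))
    cutoff = np.sort(dist2.ravel(), kind="stable")[n_in - 1]
    return dist2 <= cutoff


def default_regions(
    mask: np.ndarray, min_voxels: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Anterior ("frontal") and posterior slabs of the mask along axis 1.

    Slab depth grows from a quarter of the axis extent until both regions
    hold at least ``min_voxels`` voxels.
    """
    ny = mask.shape[1]
    y = np.indices(mask.shape)[1]
    depth = max(1, ny // 4)
    while depth < ny // 2:
        frontal = mask & (y >= ny - depth)
        posterior = mask & (y < depth)
        if frontal.sum() >= min_voxels and posterior.sum() >= min_voxels:
            break
        depth += 1
    else:
        frontal = mask & (y >= ny - depth)
        posterior = mask & (y < depth)
    return (
        np.flatnonzero(frontal.ravel()),
        np.flatnonzero(posterior.ravel()),
    )


def _smoothed_unit_noise(
    rng: np.random.Generator, shape: tuple[int, int, int], fwhm: float | None
) -> np.ndarray:
    """Gaussian noise field with unit marginal variance, optionally smoothed."""
    field_ = rng.standard_normal(shape)
    if fwhm is None or fwhm <= 0:
        return field_
    sigma = fwhm * _FWHM_TO_SIGMA
    smoothed = gaussian_filter(field_, sigma=sigma, mode="constant")
    # renormalize: smoothing shrinks the marginal variance by sum(kernel^2)
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = gaussian_filter(impulse, sigma=sigma, mode="constant")
    return smoothed / np.sqrt((kernel**2).sum())


def _subtype_counts(n: int, proportions: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of proportions to integer counts."""
    raw = proportions * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


def generate_cohort(config: SimConfig) -> Cohort:
    """Simulate volumes and phenotypes with planted subtype structure.

    Patients of subtype ``s`` have their mean shifted by
    ``sign * effect_size * noise_sd`` in the frontal and posterior regions
    according to :data:`SUBTYPE_SIGN_PATTERNS`; controls carry covariate
    effects and noise only.  Identical configs (including seed) produce
    bit-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    mask = make_mask(config.grid_shape, config.mask_fraction)
    if config.frontal_region is None or config.posterior_region is None:
        frontal, posterior = default_regions(mask)
    else:
        frontal = np.asarray(config.frontal_region, dtype=int)
        posterior = np.asarray(config.posterior_region, dtype=int)
    mask_flat = np.flatnonzero(mask.ravel())
    for name, region in (("frontal", frontal), ("posterior", posterior)):
        if not np.isin(region, mask_flat).all():
            raise ConfigurationError(f"{name}_region has voxels outside the mask")
    if np.intersect1d(frontal, posterior).size:
        raise ConfigurationError("frontal and posterior regions must be disjoint")

    n_pat, n_ctl = config.n_patients, config.n_controls
    n_total = n_pat + n_ctl
    props = np.asarray(config.subtype_proportions, dtype=float)
    counts = _subtype_counts(n_pat, props)
    subtype = rng.permutation(np.repeat(np.arange(config.n_subtypes), counts))

    age = rng.uniform(*config.age_range, size=n_total)
    sex = (rng.random(n_total) < config.sex_balance).astype(int)
    medicated = np.zeros(n_total, dtype=int)
    medicated[:n_pat] = rng.integers(0, 2, size=n_pat)
    diagnosis = np.array(["HC"] * n_total, dtype=object)
    diagnosis[:n_pat] = rng.choice(["SZ", "BD", "MDD"], size=n_pat)

    age_mid = 0.5 * (config.age_range[0] + config.age_range[1])
    age_sd = (config.age_range[1] - config.age_range[0]) / np.sqrt(12.0)
    s = config.noise_sd
    age_term = config.age_beta * s * (age - age_mid) / max(age_sd, 1e-12)
    sex_term = config.sex_beta * s * (sex - 0.5)

    grid = config.grid_shape
    volumes = np.zeros((n_total,) + tuple(grid))
    effect_flat = np.zeros((config.n_subtypes, int(np.prod(grid))))
    for k in range(config.n_subtypes):
        f_sign, p_sign = SUBTYPE_SIGN_PATTERNS[k]
        effect_flat[k, frontal] = f_sign * config.effect_size * s
        effect_flat[k, posterior] = p_sign * config.effect_size * s
    effect_vol = effect_flat.reshape((config.n_subtypes,) + tuple(grid))

    for i in range(n_total):
        vol = config.baseline + (age_term[i] + sex_term[i]) * mask.astype(float)
        if i < n_pat:
            vol = vol + effect_vol[subtype[i]]
        vol = vol + s * _smoothed_unit_noise(rng, tuple(grid), config.smoothing_fwhm)
        volumes[i] = vol

    # clinical factor scores: factor_1 elevated in subtype 0 ("archetypal"),
    # attenuated under medication; remaining factors are pure noise
    factors = rng.standard_normal((n_total, config.n_factors))
    if config.n_factors >= 1 and config.n_subtypes >= 1:
        is_s0 = np.zeros(n_total, dtype=bool)
        is_s0[:n_pat] = subtype == 0
        factors[is_s0, 0] += config.factor_effect
        factors[is_s0 & (medicated == 1), 0] -= config.medication_effect
    # continuous risk scores: score_1 tracks subtype-0 membership, rest null
    scores = rng.standard_normal((n_total, config.n_scores))
    if config.n_scores >= 1:
        scores[: n_pat, 0] += config.score_effect * (subtype == 0)

    ids = np.array([f"sub-{i + 1:04d}" for i in range(n_total)])
    pheno = pd.DataFrame(
        {
            "subject_id": ids,
            "group": ["patient"] * n_pat + ["control"] * n_ctl,
            "diagnosis": diagnosis,
            "age": age,
            "sex": sex,
            "medicated": medicated,
        }
    )
    for k in range(config.n_factors):
        pheno[f"factor_{k + 1}"] = factors[:, k]
    for m in range(config.n_scores):
        pheno[f"score_{m + 1}"] = scores[:, m]

    truth = pd.Series(subtype, index=ids[:n_pat], name="subtype")
    affine = np.eye(4)
    return Cohort(pheno, volumes, mask, affine, truth=truth, config=config)


# ---------------------------------------------------------------------------
# disk round-trip


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(
    cohort: Cohort, directory: str | Path, overwrite: bool = False
) -> dict:
    """Write one NIfTI per subject, mask, phenotype TSV, truth + manifest JSON."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{directory} is not empty; pass overwrite=True to replace it"
            )
        shutil.rmtree(directory)
    directory.mkdir(parents=True, exist_ok=True)

    files: dict[str, str] = {}
    mask_img = nib.Nifti1Image(cohort.mask.astype(np.uint8), cohort.affine)
    nib.save(mask_img, directory / "mask.nii")
    files["mask"] = "mask.nii"
    for i, sid in enumerate(cohort.subject_ids):
        name = f"{sid}_alff.nii"
        nib.save(
            nib.Nifti1Image(cohort.volumes[i].astype(np.float64), cohort.affine),
            directory / name,
        )
        files[sid] = name
    cohort.phenotypes.to_csv(directory / "phenotypes.tsv", sep="\t", index=False)
    files["phenotypes"] = "phenotypes.tsv"
    if cohort.truth is not None:
        truth_payload = {sid: int(v) for sid, v in cohort.truth.items()}
        (directory / "truth.json").write_text(
            json.dumps(truth_payload, indent=1, sort_keys=True)
        )
        files["truth"] = "truth.json"

    manifest = {
        "n_subjects": int(cohort.n_subjects),
        "grid_shape": list(cohort.volumes.shape[1:]),
        "files": files,
        "checksums": {rel: _sha256(directory / rel) for rel in files.values()},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_cohort(directory: str | Path) -> Cohort:
    """Load a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    pheno = pd.read_csv(directory / manifest["files"]["phenotypes"], sep="\t")
    if "group" not in pheno.columns:
        raise ValueError("phenotype table is missing the 'group' column")
    mask_img = nib.load(directory / manifest["files"]["mask"])
    mask = np.asarray(mask_img.dataobj).astype(bool)
    affine = mask_img.affine
    vols = np.empty((len(pheno),) + mask.shape)
    for i, sid in enumerate(pheno["subject_id"]):
        img = nib.load(directory / manifest["files"][sid])
        vols[i] = np.asarray(img.dataobj, dtype=np.float64)
    truth = None
    if "truth" in manifest["files"]:
        payload = json.loads((directory / manifest["files"]["truth"]).read_text())
        truth = pd.Series(payload, name="subtype").astype(int)
        truth = truth.reindex(pheno.loc[pheno["group"] == "patient", "subject_id"])
    return Cohort(pheno, vols, mask, affine, truth=truth)
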
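"""End-to-end orchestration: simulate -> select -> embed -> cluster -> merge -> validate.

A single master seed deterministically derives every stage seed (counter
style, via numpy SeedSequence spawn keys), so a pipeline run is a pure
function of its configuration.  When an output root is given, each stage
writes its artifacts plus a JSON manifest; a stage whose manifest matches
the current configuration hash is reloaded instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import glm as glm_mod
from .autoencoder import AEConfig, train_autoencoder
from .clustering import ConsensusResult, align_labels, choose_k, consensus, hier_cluster
from .robustness import RobustnessReport, RunSet, merge_until_robust
from .simulate import Cohort, SimConfig, generate_cohort, read_cohort, write_cohort
from .validation import factor_tests, score_association, subtype_contrast_maps

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "derive_seed",
           "run_ensemble_once"]

_STAGE_IDS = {"simulate": 1, "select": 2, "embed": 3, "cluster": 4,
              "merge": 5, "validate": 6}


def derive_seed(master_seed: int, stage: str, *indices: int) -> int:
    """Deterministic per-stage (and per-substage) seed below 2**31."""
    key = (_STAGE_IDS[stage],) + tuple(int(i) for i in indices)
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def _strict_kwargs(section: dict, cls, name: str) -> dict:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in '{name}' config: {sorted(unknown)}")
    return section


@dataclass
class SelectionConfig:
    voxel_p: float = 0.001
    cluster_p: float = 0.05
    correction: str = "grf"  # or "permutation"
    connectivity: int = 26
    n_perm: int = 1000
    fallback: str = "variance"  # or "error"
    n_fallback_voxels: int = 512


@dataclass
class EmbeddingConfig:
    d_min: int = 2
    d_max: int = 10
    epochs: int = 60
    batch_size: int = 32
    learning_rate: float = 1e-3
    early_stop_tol: float = 1e-4
    early_stop_patience: int = 10


@dataclass
class ClusteringConfig:
    k: int | str = "auto"  # silhouette-selected over k_range when "auto"
    k_range: tuple[int, int] = (2, 10)
    alignment_reference: str = "median"  # median-d partition


@dataclass
class RobustnessConfig:
    J: int = 6
    delta: float = 0.8


@dataclass
class ValidationConfig:
    enabled: bool = True
    q: float = 0.05
    alpha: float = 0.004
    correction: str = "grf"


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible end-to-end run."""

    simulate: SimConfig | None = None
    cohort_dir: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    robustness: RobustnessConfig = field(default_factory=RobustnessConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    master_seed: int = 0
    out_root: str | None = None

    def __post_init__(self) -> None:
        if self.simulate is None and self.cohort_dir is None:
            raise ValueError("config needs either 'simulate' or 'cohort_dir'")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sections = {
            "selection": SelectionConfig,
            "embedding": EmbeddingConfig,
            "clustering": ClusteringConfig,
            "robustness": RobustnessConfig,
            "validation": ValidationConfig,
        }
        kwargs: dict = {}
        for name, scls in sections.items():
            if name in raw:
                kwargs[name] = scls(**_strict_kwargs(raw.pop(name), scls, name))
        if "simulate" in raw and raw["simulate"] is not None:
            sim = raw.pop("simulate")
            for tup_key in ("grid_shape", "subtype_proportions", "age_range"):
                if tup_key in sim and sim[tup_key] is not None:
                    sim[tup_key] = tuple(sim[tup_key])
            kwargs["simulate"] = SimConfig(**_strict_kwargs(sim, SimConfig, "simulate"))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs.update(raw)
        if "clustering" in kwargs and isinstance(kwargs["clustering"].k_range, list):
            kwargs["clustering"].k_range = tuple(kwargs["clustering"].k_range)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    cohort: Cohort
    selected: glm_mod.SelectedVoxels
    features: glm_mod.FeatureMatrix
    k: int
    runs: RunSet
    report: RobustnessReport
    subtype_labels: pd.Series  # keyed by patient subject_id
    validation: dict | None
    ari_vs_truth: float | None
    manifest: dict


def _dims(cfg: EmbeddingConfig) -> list[int]:
    return list(range(cfg.d_min, cfg.d_max + 1))


def run_ensemble_once(
    features,
    dims: list[int],
    k: int,
    seeds: list[int],
    embed_cfg: EmbeddingConfig,
    reference_index: int | None = None,
) -> tuple[ConsensusResult, list]:
    """One full clustering run: train one AE per d, cluster, align, vote."""
    latents, embeddings = [], []
    for d, seed in zip(dims, seeds):
        cfg = AEConfig(
            d=d,
            epochs=embed_cfg.epochs,
            batch_size=embed_cfg.batch_size,
            learning_rate=embed_cfg.learning_rate,
            seed=seed,
            early_stop_tol=embed_cfg.early_stop_tol,
            early_stop_patience=embed_cfg.early_stop_patience,
        )
        emb, _ = train_autoencoder(features, cfg)
        embeddings.append(emb)
        latents.append(emb.latent)
    partitions = [
        hier_cluster(lat, k, source={"d": d}) for lat, d in zip(latents, dims)
    ]
    ref = len(dims) // 2 if reference_index is None else reference_index
    return consensus(align_labels(partitions, reference=ref)), embeddings


def _stage_dir(config: PipelineConfig, stage: str) -> Path | None:
    if config.out_root is None:
        return None
    p = Path(config.out_root) / stage
    p.mkdir(parents=True, exist_ok=True)
    return p


def _manifest_matches(stage_dir: Path | None, chash: str) -> dict | None:
    if stage_dir is None:
        return None
    mpath = stage_dir / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
        if manifest.get("config_hash") == chash:
            return manifest
    return None


def _write_manifest(stage_dir: Path | None, payload: dict) -> None:
    if stage_dir is not None:
        (stage_dir / "manifest.json").write_text(
            json.dumps(payload, indent=1, default=str)
        )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full subtype-discovery workflow for one configuration."""
    chash = config.config_hash()
    manifest: dict = {"config_hash": chash, "stages": {}}

    # ---- stage 1: cohort -------------------------------------------------
    t0 = time.time()
    sdir = _stage_dir(config, "cohort")
    if config.cohort_dir is not None:
        cohort = read_cohort(config.cohort_dir)
    else:
        sim = dataclasses.replace(
            config.simulate, seed=derive_seed(config.master_seed, "simulate")
        ) if config.simulate.seed == 0 else config.simulate
        cohort = generate_cohort(sim)
        if sdir is not None and _manifest_matches(sdir, chash) is None:
            write_cohort(cohort, sdir / "data", overwrite=True)
            _write_manifest(sdir, {"config_hash": chash, "n": cohort.n_subjects})
    if "group" not in cohort.phenotypes.columns:
        raise ValueError("phenotype table is missing the 'group' column")
    manifest["stages"]["cohort"] = {"seconds": time.time() - t0,
                                    "n_subjects": cohort.n_subjects}

    # ---- stage 2: voxel selection ---------------------------------------
    t0 = time.time()
    sel_cfg = config.selection
    glm = glm_mod.fit_voxelwise_glm(cohort)
    selected = glm_mod.cluster_correct(
        glm,
        cohort.mask,
        voxel_p=sel_cfg.voxel_p,
        cluster_p=sel_cfg.cluster_p,
        method=sel_cfg.correction,
        connectivity=sel_cfg.connectivity,
        n_perm=sel_cfg.n_perm,
        seed=derive_seed(config.master_seed, "select"),
        cohort=cohort,
    )
    fallback_used = False
    if selected.n_voxels == 0:
        if sel_cfg.fallback == "variance":
            selected = glm_mod.select_high_variance_voxels(
                cohort, n_voxels=sel_cfg.n_fallback_voxels
            )
            fallback_used = True
        else:
            raise ValueError(
                "no voxels survived cluster correction and fallback is disabled"
            )
    features = glm_mod.extract_feature_matrix(cohort, selected, subjects="patient")
    sdir = _stage_dir(config, "select")
    if sdir is not None:
        np.savetxt(sdir / "selected_voxels.txt", selected.indices, fmt="%d")
        _write_manifest(sdir, {"config_hash": chash, "n_voxels": selected.n_voxels,
                               "method": selected.method,
                               "fallback_used": fallback_used})
    manifest["stages"]["select"] = {
        "seconds": time.time() - t0,
        "n_voxels": selected.n_voxels,
        "method": selected.method,
        "fallback_used": fallback_used,
    }

    # ---- stages 3+4: J ensemble runs (embed + cluster + consensus) -------
    t0 = time.time()
    dims = _dims(config.embedding)
    J = config.robustness.J
    k_cfg = config.clustering.k
    sdir = _stage_dir(config, "cluster")
    cached = _manifest_matches(sdir, chash)
    runs_list: list[ConsensusResult] = []
    if cached is not None:
        k = int(cached["k"])
        labels_df = pd.read_csv(sdir / "run_labels.tsv", sep="\t")
        for j in range(J):
            col = labels_df[f"run_{j}"].to_numpy()
            runs_list.append(
                ConsensusResult(col, np.ones(col.size), [], int(col.max() + 1))
            )
    else:
        seeds_first = [derive_seed(config.master_seed, "embed", 0, d) for d in dims]
        first_run, first_embs = None, None
        if k_cfg == "auto":
            first_latents = []
            for d, seed in zip(dims, seeds_first):
                cfg = AEConfig(
                    d=d, epochs=config.embedding.epochs,
                    batch_size=config.embedding.batch_size,
                    learning_rate=config.embedding.learning_rate, seed=seed,
                    early_stop_tol=config.embedding.early_stop_tol,
                    early_stop_patience=config.embedding.early_stop_patience,
                )
                emb, _ = train_autoencoder(features, cfg)
                first_latents.append(emb.latent)
            k = choose_k(first_latents, config.clustering.k_range)
            parts = [hier_cluster(lat, k, source={"d": d})
                     for lat, d in zip(first_latents, dims)]
            first_run = consensus(align_labels(parts, reference=len(dims) // 2))
        else:
            k = int(k_cfg)
        for j in range(J):
            if j == 0 and first_run is not None:
                runs_list.append(first_run)
                continue
            seeds = [derive_seed(config.master_seed, "embed", j, d) for d in dims]
            run, _ = run_ensemble_once(features, dims, k, seeds, config.embedding)
            runs_list.append(run)
        if sdir is not None:
            df = pd.DataFrame({"subject_id": features.subject_ids})
            for j, run in enumerate(runs_list):
                df[f"run_{j}"] = run.labels
            df.to_csv(sdir / "run_labels.tsv", sep="\t", index=False)
            _write_manifest(sdir, {"config_hash": chash, "k": k, "J": J})
    runs = RunSet(runs_list)
    manifest["stages"]["cluster"] = {"seconds": time.time() - t0, "k": k, "J": J}

    # ---- stage 5: robustness merging -------------------------------------
    t0 = time.time()
    report = merge_until_robust(runs, delta=config.robustness.delta)
    subtype_labels = pd.Series(
        report.final_labels, index=features.subject_ids, name="subtype"
    )
    sdir = _stage_dir(config, "merge")
    if sdir is not None:
        subtype_labels.rename_axis("subject_id").to_csv(
            sdir / "subtype_labels.tsv", sep="\t"
        )
        _write_manifest(sdir, {
            "config_hash": chash,
            "delta": report.delta,
            "initial_k": report.initial_k,
            "n_subtypes": report.n_subtypes,
            "robustness": report.robustness,
            "merge_history": report.merge_history,
            "trajectory": report.trajectory,
        })
    manifest["stages"]["merge"] = {
        "seconds": time.time() - t0,
        "n_subtypes": report.n_subtypes,
        "min_robustness": min(report.robustness),
    }

    # ---- stage 6: validation ---------------------------------------------
    ari = None
    if cohort.truth is not None:
        truth = cohort.truth.reindex(subtype_labels.index)
        ari = float(adjusted_rand_score(truth.to_numpy(), subtype_labels.to_numpy()))
        manifest["stages"]["merge"]["ari_vs_truth"] = ari

    validation = None
    if config.validation.enabled:
        t0 = time.time()
        validation = _validate(cohort, subtype_labels, config)
        sdir = _stage_dir(config, "validate")
        if sdir is not None:
            (sdir / "report.txt").write_text(_text_report(report, validation, ari))
            _write_manifest(sdir, {"config_hash": chash})
        manifest["stages"]["validate"] = {"seconds": time.time() - t0}

    manifest["master_seed"] = config.master_seed
    if config.out_root is not None:
        Path(config.out_root).mkdir(parents=True, exist_ok=True)
        (Path(config.out_root) / "manifest.json").write_text(
            json.dumps(manifest, indent=1, default=str)
        )
    return PipelineResult(
        cohort, selected, features, k, runs, report, subtype_labels,
        validation, ari, manifest,
    )


def _validate(cohort: Cohort, subtype_labels: pd.Series, config: PipelineConfig) -> dict:
    out: dict = {}
    vcfg = config.validation
    try:
        contrasts = subtype_contrast_maps(
            cohort, subtype_labels, method=vcfg.correction,
            seed=derive_seed(config.master_seed, "validate"),
        )
        out["contrasts"] = contrasts
    except ValueError as exc:
        out["contrasts_error"] = str(exc)

    pheno = cohort.phenotypes.set_index("subject_id")
    factor_cols = [c for c in pheno.columns if c.startswith("factor_")]
    score_cols = [c for c in pheno.columns if c.startswith("score_")]
    patients = pheno.loc[subtype_labels.index].copy()
    patients["subtype"] = subtype_labels

    uniq = sorted(subtype_labels.unique())
    if factor_cols and len(uniq) >= 2:
        pair = patients[patients["subtype"].isin(uniq[:2])]
        out["factor_tests"] = factor_tests(pair, "subtype", factor_cols, q=vcfg.q)
        med = {}
        for s in uniq:
            sub = patients[patients["subtype"] == s]
            if sub["medicated"].nunique() == 2:
                med[s] = factor_tests(sub, "medicated", factor_cols, q=vcfg.q)
        out["medication_tests"] = med

    if score_cols:
        controls = pheno[pheno["group"] == "control"]
        assoc = {}
        for s in uniq:
            members = patients[patients["subtype"] == s]
            y = np.concatenate([np.ones(len(members)), np.zeros(len(controls))])
            sc = pd.concat([members[score_cols], controls[score_cols]])
            try:
                assoc[s] = score_association(y, sc, alpha=vcfg.alpha)
            except ValueError as exc:
                assoc[s] = str(exc)
        out["score_associations"] = assoc
    return out


def _text_report(report: RobustnessReport, validation: dict, ari) -> str:
    lines = ["subtype discovery report", "=" * 30]
    sizes = [len(m) for m in report.cluster_members]
    total = sum(sizes)
    for i, (size, r) in enumerate(zip(sizes, report.robustness)):
        lines.append(
            f"subtype {i}: n={size} ({100 * size / total:.0f}%), robustness R={r:.3f}"
        )
    lines.append(f"merges performed: {len(report.merge_history)} (delta={report.delta})")
    if ari is not None:
        lines.append(f"adjusted Rand index vs planted truth: {ari:.3f}")
    if "contrasts" in validation:
        for c in validation["contrasts"]:
            lines.append(
                f"subtype {c.subtype} vs HC: {len(c.selected.clusters)} corrected "
                f"cluster(s), peak |d|={np.abs(c.d).max():.2f}"
            )
    if "factor_tests" in validation:
        sig = validation["factor_tests"].query("significant").index.tolist()
        lines.append(f"factor scores FDR-significant between subtypes: {sig}")
    if "score_associations" in validation:
        for s, assoc in validation["score_associations"].items():
            if hasattr(assoc, "table"):
                top = assoc.table["r2_nagelkerke"].max()
                lines.append(f"subtype {s} best score Nagelkerke R2: {top:.3f}")
    return "\n".join(lines) + "\n"
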
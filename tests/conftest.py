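"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from subtyper import Cohort, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Planted 2-subtype cohort at desk scale (shared, read-only)."""
    cfg = SimConfig(
        n_patients=60, n_controls=30, grid_shape=(12, 12, 12), seed=11
    )
    return generate_cohort(cfg)


def make_manual_cohort(
    values: np.ndarray, groups: list[str], mask: np.ndarray | None = None
) -> Cohort:
    """Cohort wrapper around explicit per-subject voxel data.

    ``values`` is subjects x voxels; voxels are laid out along the first
    grid axis so closed-form oracles can address them directly.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, v = values.shape
    grid = (v, 1, 1)
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    vols = values.reshape(n, *grid)
    rng = np.random.default_rng(0)
    pheno = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": groups,
            "diagnosis": ["HC"] * n,
            "age": rng.uniform(20, 50, n),
            "sex": rng.integers(0, 2, n),
            "medicated": 0,
        }
    )
    return Cohort(pheno, vols, mask, np.eye(4))


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_complete_linkage(points: np.ndarray, k: int) -> list[set[int]]:
    """Naive O(n^3) agglomeration: merge the pair with smallest max-distance."""
    points = np.atleast_2d(points)
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    clusters: list[set[int]] = [{i} for i in range(len(points))]
    while len(clusters) > k:
        best, pair = np.inf, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                if d < best:
                    best, pair = d, (a, b)
        a, b = pair
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return clusters


def sets_to_labels(clusters: list[set[int]], n: int) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters):
        labels[list(members)] = lab
    return labels


def brute_force_bh(p: np.ndarray, q: float) -> np.ndarray:
    """Hand step-up procedure: reject H_(1..k*) with k* = max{i: p_(i) <= iq/m}."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


def brute_force_robustness(member_sets: list[set[int]], n_universe: int) -> float:
    """Boolean-mask recomputation of |intersection| / |union|."""
    inter = np.ones(n_universe, dtype=bool)
    union = np.zeros(n_universe, dtype=bool)
    for s in member_sets:
        mask = np.zeros(n_universe, dtype=bool)
        mask[list(s)] = True
        inter &= mask
        union |= mask
    return 0.0 if union.sum() == 0 else inter.sum() / union.sum()
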
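"""Ensemble hierarchical clustering over multiple latent representations.

Each d-dimensional embedding (d in [2, 10]) is clustered with agglomerative
complete linkage on Euclidean distances; the nine resulting partitions are
label-aligned by optimal one-to-one matching against a reference partition,
and each subject receives the plurality label across the aligned partitions
("consensus").  Cluster label names from independent runs are arbitrary, so
alignment is what makes a majority vote well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_score

__all__ = [
    "Partition",
    "ConsensusResult",
    "hier_cluster",
    "align_labels",
    "consensus",
    "choose_k",
]


@dataclass
class Partition:
    """Hard cluster assignment of a fixed subject set."""

    labels: np.ndarray  # int, values in [0, k)
    k: int
    source: dict = field(default_factory=dict)  # e.g. {"d": 4, "seed": 7}

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() >= self.k:
            raise ValueError("labels must lie in [0, k)")

    @property
    def n_subjects(self) -> int:
        return self.labels.size

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def _relabel_first_occurrence(raw: np.ndarray) -> np.ndarray:
    """Rename labels to 0..k-1 in order of first appearance (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def hier_cluster(latent: np.ndarray, k: int, source: dict | None = None) -> Partition:
    """Complete-linkage agglomerative clustering cut at exactly k clusters."""
    latent = np.asarray(latent, dtype=float)
    if latent.ndim == 1:
        latent = latent[:, None]
    n = latent.shape[0]
    if not np.all(np.isfinite(latent)):
        raise ValueError("latent matrix contains non-finite values")
    if k > n:
        raise ValueError(f"k ({k}) cannot exceed the number of subjects ({n})")
    if n == 1 or k == n:
        labels = np.arange(n)
    else:
        Z = linkage(latent, method="complete", metric="euclidean")
        labels = cut_tree(Z, n_clusters=k).ravel()
    return Partition(_relabel_first_occurrence(labels), k, source or {})


def _contingency(a: Partition, b: Partition) -> np.ndarray:
    table = np.zeros((a.k, b.k), dtype=int)
    np.add.at(table, (a.labels, b.labels), 1)
    return table


def align_labels(
    partitions: list[Partition], reference: int = 0
) -> list[Partition]:
    """Rename each partition's labels to best match the reference partition.

    Uses maximum-agreement one-to-one assignment on the contingency table;
    clusters without a counterpart (when k differs) receive fresh labels
    above the reference's range.  Memberships are never changed.
    """
    ref = partitions[reference]
    n = ref.n_subjects
    aligned = []
    for part in partitions:
        if part.n_subjects != n:
            raise ValueError("all partitions must cover the same subject set")
        table = _contingency(part, ref)
        rows, cols = linear_sum_assignment(-table)
        mapping = dict(zip(rows.tolist(), cols.tolist()))
        next_fresh = ref.k
        for lab in range(part.k):
            if lab not in mapping:
                mapping[lab] = next_fresh
                next_fresh += 1
        new_labels = np.array([mapping[v] for v in part.labels])
        aligned.append(
            Partition(new_labels, max(ref.k, next_fresh), dict(part.source))
        )
    return aligned


@dataclass
class ConsensusResult:
    """Plurality vote over aligned partitions with per-subject agreement."""

    labels: np.ndarray
    agreement: np.ndarray  # winning votes / number of partitions, in (0, 1]
    partitions: list[Partition]
    k: int

    @property
    def low_agreement(self) -> np.ndarray:
        """Subjects whose winning label got less than half the votes."""
        return np.flatnonzero(self.agreement < 0.5)

    def to_partition(self) -> Partition:
        return Partition(
            _relabel_first_occurrence(self.labels),
            len(np.unique(self.labels)),
            {"consensus": True},
        )


def consensus(aligned: list[Partition]) -> ConsensusResult:
    """Per-subject plurality label; ties broken by the smallest label index."""
    if not aligned:
        raise ValueError("need at least one partition")
    n = aligned[0].n_subjects
    max_label = max(p.labels.max() for p in aligned)
    votes = np.zeros((n, max_label + 1), dtype=int)
    for part in aligned:
        votes[np.arange(n), part.labels] += 1
    winners = votes.argmax(axis=1)  # argmax takes the smallest index on ties
    agreement = votes[np.arange(n), winners] / len(aligned)
    return ConsensusResult(winners, agreement, aligned, int(max_label + 1))


def choose_k(
    latents: list[np.ndarray], k_range: tuple[int, int] = (2, 10)
) -> int:
    """Number of clusters maximizing mean silhouette across representations."""
    lo, hi = k_range
    best_k, best_score = lo, -np.inf
    n = latents[0].shape[0]
    for k in range(lo, min(hi, n - 1) + 1):
        scores = []
        for latent in latents:
            labels = hier_cluster(latent, k).labels
            if len(np.unique(labels)) < 2:
                continue
            scores.append(silhouette_score(latent, labels, metric="euclidean"))
        if scores and np.mean(scores) > best_score:
            best_score = float(np.mean(scores))
            best_k = k
    return best_k
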
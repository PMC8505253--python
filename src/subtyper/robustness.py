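"""Cluster-stability quantification and robustness-driven merging.

A cluster's robustness index is the Jaccard-style ratio
``R_i = |intersection_j C_i^j| / |union_j C_i^j|`` of its matched member
sets ``C_i^j`` across J independent re-executions of the full
embedding-and-clustering procedure.  Clusters that are unstable across
runs (low R) are iteratively merged — the two lowest-R clusters at a time,
consistently inside every run's matched sets — until every remaining
cluster satisfies ``R > delta`` (default 0.8) or a single cluster remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .clustering import ConsensusResult, Partition, align_labels, consensus

__all__ = [
    "RunSet",
    "RobustnessReport",
    "match_clusters_across_runs",
    "robustness_index",
    "merge_until_robust",
]


@dataclass
class RunSet:
    """J complete consensus clusterings of the same subjects (J >= 2)."""

    runs: list[ConsensusResult]

    def __post_init__(self) -> None:
        if len(self.runs) < 2:
            raise ValueError("robustness is undefined for fewer than 2 runs")
        n = self.runs[0].labels.size
        if any(r.labels.size != n for r in self.runs):
            raise ValueError("all runs must cover the same subject set")

    @property
    def J(self) -> int:
        return len(self.runs)

    @property
    def n_subjects(self) -> int:
        return self.runs[0].labels.size


def robustness_index(member_sets: list[set[int] | frozenset[int]]) -> float:
    """``|intersection| / |union|`` of a cluster's member sets across runs."""
    if not member_sets:
        raise ValueError("need at least one member set")
    sets = [set(s) for s in member_sets]
    union = set().union(*sets)
    if not union:
        return 0.0
    inter = set(sets[0]).intersection(*sets[1:])
    return len(inter) / len(union)


def _partition_sets(labels: np.ndarray) -> list[set[int]]:
    return [set(np.flatnonzero(labels == lab)) for lab in np.unique(labels)]


def _jaccard(a: set[int], b: set[int]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def match_clusters_across_runs(
    runs: RunSet, reference: Partition
) -> list[list[set[int]]]:
    """Matched member sets ``C_i^j`` for each reference cluster i and run j.

    Within each run, reference clusters are paired one-to-one with run
    clusters by maximizing total Jaccard overlap; reference clusters left
    unmatched (when a run has fewer clusters) get an empty set for that run.
    """
    ref_sets = [set(reference.members(lab)) for lab in range(reference.k)]
    out: list[list[set[int]]] = [[] for _ in ref_sets]
    for run in runs.runs:
        if run.labels.size != reference.n_subjects:
            raise ValueError("run and reference cover different subjects")
        run_sets = _partition_sets(run.labels)
        J = np.array([[_jaccard(r, c) for c in run_sets] for r in ref_sets])
        rows, cols = linear_sum_assignment(-J)
        matched: dict[int, set[int]] = {
            int(i): run_sets[int(j)] for i, j in zip(rows, cols) if J[i, j] > 0
        }
        for i in range(len(ref_sets)):
            out[i].append(matched.get(i, set()))
    return out


@dataclass
class RobustnessReport:
    """Merge history, robustness trajectory and final subtype labels."""

    initial_k: int
    delta: float
    final_labels: np.ndarray
    cluster_members: list[set[int]]  # final reference member sets
    matched_sets: list[list[set[int]]]  # final C_i^j per cluster
    robustness: list[float]  # final per-cluster R_i
    merge_history: list[dict] = field(default_factory=list)
    trajectory: list[list[float]] = field(default_factory=list)  # R per iteration

    @property
    def n_subtypes(self) -> int:
        return len(self.cluster_members)


def merge_until_robust(
    runs: RunSet,
    delta: float = 0.8,
    reference: Partition | None = None,
) -> RobustnessReport:
    """Merge unstable clusters until all robustness indices exceed ``delta``.

    The reference partition defaults to the grand consensus of the J run
    consensuses (aligned to the first run).  At each iteration the
    per-cluster R_i are computed from the matched sets; if the minimum is
    already greater than ``delta`` (strict) the loop stops, otherwise the
    two clusters with the lowest R_i (ties broken by smaller index) are
    merged in the reference and, by union of their matched sets, within
    every run.  At most k0 - 1 merges can occur.
    """
    if not 0 < delta <= 1:
        raise ValueError("delta must be in (0, 1]")
    if reference is None:
        parts = [r.to_partition() for r in runs.runs]
        reference = consensus(align_labels(parts, reference=0)).to_partition()

    ref_sets = [set(reference.members(lab)) for lab in range(reference.k)]
    matched = match_clusters_across_runs(runs, reference)
    history: list[dict] = []
    trajectory: list[list[float]] = []
    k0 = len(ref_sets)

    while True:
        R = [robustness_index(sets) for sets in matched]
        trajectory.append(list(R))
        if len(ref_sets) == 1 or min(R) > delta:
            break
        order = np.lexsort((np.arange(len(R)), R))  # lowest R, ties by index
        a, b = sorted(order[:2].tolist())
        history.append(
            {
                "merged": (a, b),
                "robustness": (R[a], R[b]),
                "k_before": len(ref_sets),
            }
        )
        ref_sets[a] = ref_sets[a] | ref_sets[b]
        matched[a] = [sa | sb for sa, sb in zip(matched[a], matched[b])]
        del ref_sets[b], matched[b]

    assert len(history) <= k0 - 1
    final_labels = np.empty(reference.n_subjects, dtype=int)
    for lab, members in enumerate(ref_sets):
        final_labels[list(members)] = lab
    return RobustnessReport(
        initial_k=k0,
        delta=delta,
        final_labels=final_labels,
        cluster_members=ref_sets,
        matched_sets=matched,
        robustness=[robustness_index(s) for s in matched],
        merge_history=history,
        trajectory=trajectory,
    )
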
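"""Patient-level data splitting with score balancing.

All examinations of a patient stay in one partition (repeated scans of one
anatomy must never leak between train and evaluation).  The three-way split
is found by iterative random search: shuffle patients, assign contiguous
blocks at the target patient proportions, score the assignment by how far
the observed lobe-score counts deviate from the ideal proportional counts,
keep the minimum-cost assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitAssignment", "split_cost", "balanced_patient_split", "grouped_kfold"]

SET_NAMES = ("train", "val", "test")


@dataclass
class SplitAssignment:
    """Result of the balanced split search."""

    mapping: dict[str, str]  # patient_id -> "train" | "val" | "test"
    cost: float
    seed: int
    iterations: int

    def patients(self, which: str) -> list[str]:
        return [p for p, s in self.mapping.items() if s == which]


def _count_matrix(
    lobe_score_table: pd.DataFrame, patients: list[str], per_pathology: bool
) -> tuple[np.ndarray, list]:
    """Per-patient score-count matrix; columns = (pathology,) x score classes."""
    t = lobe_score_table
    if per_pathology:
        keys = [(p, k) for p in sorted(t["pathology"].unique()) for k in (0, 1, 2)]
        cols = {pk: i for i, pk in enumerate(keys)}
        M = np.zeros((len(patients), len(keys)))
        grp = t.groupby(["patient_id", "pathology", "score"]).size()
        for (pid, path, score), n in grp.items():
            if pid in patients:
                M[patients.index(pid), cols[(path, score)]] = n
    else:
        keys = [0, 1, 2]
        M = np.zeros((len(patients), 3))
        grp = t.groupby(["patient_id", "score"]).size()
        pidx = {p: i for i, p in enumerate(patients)}
        for (pid, score), n in grp.items():
            if pid in pidx:
                M[pidx[pid], int(score)] = n
    return M, keys


def split_cost(
    assignment: dict[str, str],
    lobe_score_table: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
) -> float:
    """Sum of absolute deviations between observed and ideal score counts.

    For each set, pathology and score class the ideal count is the set's
    ratio times the total count of that (pathology, score) cell; the cost
    adds up ``|observed - ideal|`` over all cells.
    """
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    t = lobe_score_table
    unassigned = set(t["patient_id"]) - set(assignment)
    if unassigned:
        raise ValueError(f"scored patients without assignment: {sorted(unassigned)[:5]}")
    cost = 0.0
    totals = t.groupby(["pathology", "score"]).size()
    observed = t.assign(_set=t["patient_id"].map(assignment)).groupby(
        ["_set", "pathology", "score"]
    ).size()
    for (path, score), total in totals.items():
        for s, ratio in zip(SET_NAMES, ratios):
            obs = observed.get((s, path, score), 0)
            cost += abs(obs - ratio * total)
    return float(cost)


def _block_sizes(n: int, ratios: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n patients to the target ratios."""
    raw = np.asarray(ratios) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def balanced_patient_split(
    patients: list[str],
    lobe_score_table: pd.DataFrame,
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    iterations: int = 10_000,
    seed: int = 0,
) -> SplitAssignment:
    """Iterative random search for the most score-balanced patient split."""
    if len(patients) < len(SET_NAMES):
        raise ValueError("need at least as many patients as sets")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError(f"ratios must sum to 1, got {ratios}")

    patients = list(patients)
    pidx = {p: i for i, p in enumerate(patients)}
    # per-patient counts per (pathology, score) cell, vectorised cost
    t = lobe_score_table
    cells = sorted({(p, int(k)) for p, k in zip(t["pathology"], t["score"])})
    cell_col = {c: j for j, c in enumerate(cells)}
    M = np.zeros((len(patients), len(cells)))
    for (pid, path, score), n in t.groupby(["patient_id", "pathology", "score"]).size().items():
        M[pidx[pid], cell_col[(path, int(score))]] = n
    totals = M.sum(axis=0)
    ideal = np.outer(np.asarray(ratios), totals)  # (3 sets, cells)

    sizes = _block_sizes(len(patients), ratios)
    bounds = np.cumsum([0] + sizes)
    rng = np.random.default_rng(seed)
    best_cost = np.inf
    best_order = None
    for _ in range(iterations):
        order = rng.permutation(len(patients))
        observed = np.stack(
            [M[order[bounds[i] : bounds[i + 1]]].sum(axis=0) for i in range(3)]
        )
        cost = np.abs(observed - ideal).sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best_order = order
    mapping = {}
    for i, s in enumerate(SET_NAMES):
        for j in best_order[bounds[i] : bounds[i + 1]]:
            mapping[patients[j]] = s
    return SplitAssignment(
        mapping=mapping, cost=float(best_cost), seed=seed, iterations=iterations
    )


def grouped_kfold(patients: list[str], k: int, seed: int = 0) -> list[list[str]]:
    """Partition patients into k shuffled folds with sizes differing by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(patients):
        raise ValueError(f"k={k} exceeds the number of patients ({len(patients)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, j in enumerate(order):
        folds[i % k].append(patients[j])
    return folds
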
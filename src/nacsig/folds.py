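"""Distribution-balanced stratified cross-validation (DB-SCV) folds.

Standard stratified k-fold only balances class counts across folds.  DB-SCV
additionally spreads each class's nearest-neighbour samples over distinct
folds, so the covariate distribution of every fold resembles the whole
cohort and small-sample CV estimates are less noisy.  Per class the builder
starts from a seeded random sample, walks a nearest-unassigned-neighbour
chain (Euclidean distance on z-scored genes) and deals consecutive chain
members to folds 1..k round-robin.  The round-robin pointer continues from
one class to the next (largest class first) so per-fold totals are as even
as the class sizes allow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import ExpressionCohort


@dataclass
class FoldAssignment:
    """Sample -> fold map for k-fold cross-validation (folds 0..k-1)."""

    k: int
    assignment: np.ndarray  # per-sample fold index

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.k < 2:
            raise ValueError("need k >= 2 folds")
        if np.any(self.assignment < 0) or np.any(self.assignment >= self.k):
            raise ValueError("fold indices out of range")

    def test_masks(self):
        for f in range(self.k):
            yield self.assignment == f


def _zscore_columns(matrix: np.ndarray) -> np.ndarray:
    mu = matrix.mean(axis=1, keepdims=True)
    sd = matrix.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (matrix - mu) / sd


def build_dbscv_folds(cohort: ExpressionCohort, k: int, seed: int) -> FoldAssignment:
    """Assign every sample of `cohort` to one of `k` DB-SCV folds.

    Stratification invariant: within each class, fold counts differ by at
    most one; with the continued round-robin pointer the per-fold totals
    also differ by at most one overall.
    """
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    z = _zscore_columns(cohort.matrix).T  # samples x genes, standardized
    labels = np.asarray(cohort.labels)
    assignment = np.full(cohort.n_samples, -1, dtype=int)

    classes = sorted(set(cohort.labels),
                     key=lambda c: (-int(np.sum(labels == c)), c))
    pointer = 0  # continues across classes so fold totals stay even
    for cls in classes:
        members = np.flatnonzero(labels == cls)
        unassigned = set(members.tolist())
        current = int(rng.choice(members))
        while True:
            assignment[current] = pointer % k
            pointer += 1
            unassigned.discard(current)
            if not unassigned:
                break
            rest = np.fromiter(unassigned, dtype=int)
            d = np.linalg.norm(z[rest] - z[current], axis=1)
            # deterministic tie-break: smallest distance, then lowest index
            current = int(rest[np.lexsort((rest, d))[0]])
    return FoldAssignment(k, assignment)


def build_stratified_folds(cohort: ExpressionCohort, k: int, seed: int) -> FoldAssignment:
    """Plain stratified k-fold (random within class, counts differ <= 1)."""
    if k < 2:
        raise ValueError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    labels = np.asarray(cohort.labels)
    assignment = np.full(cohort.n_samples, -1, dtype=int)
    pointer = 0
    classes = sorted(set(cohort.labels),
                     key=lambda c: (-int(np.sum(labels == c)), c))
    for cls in classes:
        members = np.flatnonzero(labels == cls)
        order = rng.permutation(members)
        for idx in order:
            assignment[idx] = pointer % k
            pointer += 1
    return FoldAssignment(k, assignment)
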
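"""Rank-guided iterative feature elimination (RGIFE).

RGIFE shrinks a high-dimensional expression panel down to a small
discriminative signature.  A random-forest classifier supplies both the
cross-validated predictive accuracy (estimated with DB-SCV folds) and the
feature-importance ranking that guides elimination.  The algorithm removes
ranked blocks of features whenever removal does not degrade accuracy,
shrinks the block size after repeated consecutive failures, and stops once
single-feature removals fail repeatedly.

Because both the forest and the fold assignment are stochastic, repeated
runs yield different signatures; :func:`rgife_repeat` runs the procedure
several times and reports the gene commonality (intersection) across the
returned panels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .cohort import ExpressionCohort
from .folds import FoldAssignment, build_dbscv_folds


def derive_seed(*parts: int) -> int:
    """Deterministic child seed (< 2^31) from a tuple of integers."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


@dataclass
class RGIFEConfig:
    """Tunable parameters of the elimination schedule.

    ``initial_block_fraction`` of the current feature count is removed per
    accepted trial; after ``max_consecutive_failures`` failed trials the
    block size is divided by ``block_shrink_divisor`` (floor, minimum 1).
    """

    k_folds: int = 10
    initial_block_fraction: float = 0.25
    block_shrink_divisor: int = 4
    max_consecutive_failures: int = 5
    n_trees: int = 500
    n_repeats: int = 5
    seed: int = 0
    redraw_folds_per_trial: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.initial_block_fraction <= 1):
            raise ValueError("initial_block_fraction must be in (0, 1]")
        if self.block_shrink_divisor < 2:
            raise ValueError("block_shrink_divisor must be >= 2")
        if self.max_consecutive_failures < 1:
            raise ValueError("max_consecutive_failures must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_trees < 1 or self.n_repeats < 1:
            raise ValueError("n_trees and n_repeats must be >= 1")


@dataclass
class TrialRecord:
    """One elimination attempt: which block, with what outcome."""

    trial_index: int
    block_genes: list[str]
    block_size: int
    accuracy: float
    reference_accuracy: float
    accepted: bool


@dataclass
class SignaturePanel:
    """Surviving gene panel with its pooled cross-validated accuracy."""

    genes: list[str]
    accuracy: float
    n_correct: int
    n_total: int
    trace: list[TrialRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel must be non-empty")
        if self.n_total > 0 and abs(self.accuracy - self.n_correct / self.n_total) > 1e-12:
            raise ValueError("accuracy must equal n_correct / n_total")


def _forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=n_trees, random_state=seed % (2 ** 31))


def evaluate_panel(cohort: ExpressionCohort, genes: list[str], folds: FoldAssignment,
                   n_trees: int, seed: int) -> tuple[float, int, int]:
    """Pooled k-fold CV accuracy of a random forest on the given panel.

    For each fold a forest is trained on the remaining folds restricted to
    `genes` and predicts the held-out samples; accuracy pools the correct
    held-out predictions over the whole cohort, enabling the
    "n_correct / n_total" reporting form.
    """
    X = cohort.features(genes)
    y = cohort.y
    n_correct = 0
    for f, test in enumerate(folds.test_masks()):
        if not np.any(test):
            continue
        train = ~test
        if len(np.unique(y[train])) < 2:
            raise ValueError(f"fold {f}: training set lacks a class")
        clf = _forest(n_trees, derive_seed(seed, f))
        clf.fit(X[train], y[train])
        n_correct += int(np.sum(clf.predict(X[test]) == y[test]))
    n_total = cohort.n_samples
    return n_correct / n_total, n_correct, n_total


def rank_features(cohort: ExpressionCohort, genes: list[str], n_trees: int,
                  seed: int) -> list[str]:
    """Genes sorted by descending forest importance (full-cohort training).

    Ties are broken by ascending gene ID so the ranking is deterministic
    given the seed.
    """
    X = cohort.features(genes)
    clf = _forest(n_trees, derive_seed(seed))
    clf.fit(X, cohort.y)
    imp = clf.feature_importances_
    order = sorted(range(len(genes)), key=lambda i: (-imp[i], genes[i]))
    return [genes[i] for i in order]


def rgife_run(cohort: ExpressionCohort, config: RGIFEConfig,
              seed: int | None = None) -> SignaturePanel:
    """One full RGIFE elimination run.

    The loop: evaluate the reference accuracy of the current feature set;
    rank features; try removing the block of lowest-ranked features (block
    size = ceil(initial_block_fraction x current feature count)).  If the
    pooled CV accuracy without the block is at least the reference, the
    removal is accepted (reference updated, ranking and block size
    recomputed, failure counter reset); otherwise the block is restored,
    the failure counter increments and the next non-overlapping block up
    the ranking is tried (wrapping to the bottom when the top is reached).
    At ``max_consecutive_failures`` the block size is divided by
    ``block_shrink_divisor`` (minimum 1) and the scan restarts from the
    bottom; when single-feature removals fail that many times in a row the
    surviving features are returned with their accuracy and full trace.
    """
    if seed is None:
        seed = config.seed
    folds = build_dbscv_folds(cohort, config.k_folds, derive_seed(seed, 0xF0))
    genes = list(cohort.gene_ids)

    def block_size_for(n: int) -> int:
        return min(max(1, math.ceil(config.initial_block_fraction * n)), max(1, n - 1))

    trial = 0

    def evaluate(gs: list[str]) -> tuple[float, int, int]:
        nonlocal folds
        if config.redraw_folds_per_trial:
            folds = build_dbscv_folds(cohort, config.k_folds, derive_seed(seed, 0xF0, trial))
        return evaluate_panel(cohort, gs, folds, config.n_trees, derive_seed(seed, trial))

    ref_acc, ref_correct, ref_total = evaluate(genes)
    ranking = rank_features(cohort, genes, config.n_trees, derive_seed(seed, 0xAA, trial))
    block = block_size_for(len(genes))
    failures = 0
    position = 0
    trace: list[TrialRecord] = []

    while len(genes) > 1:
        n_blocks = len(ranking) // block
        if n_blocks == 0:
            break
        pos = position % n_blocks
        start = len(ranking) - (pos + 1) * block
        candidate_block = ranking[start:start + block]
        kept = [g for g in genes if g not in set(candidate_block)]
        trial += 1
        acc, n_corr, n_tot = evaluate(kept)
        accepted = acc >= ref_acc
        trace.append(TrialRecord(trial, list(candidate_block), block, acc, ref_acc,
                                 accepted))
        if accepted:
            genes = kept
            ref_acc, ref_correct, ref_total = acc, n_corr, n_tot
            ranking = rank_features(cohort, genes, config.n_trees,
                                    derive_seed(seed, 0xAA, trial))
            block = block_size_for(len(genes))
            failures = 0
            position = 0
        else:
            failures += 1
            position += 1
            if failures >= config.max_consecutive_failures:
                if block == 1:
                    break
                block = max(1, block // config.block_shrink_divisor)
                failures = 0
                position = 0

    return SignaturePanel(genes, ref_acc, ref_correct, ref_total, trace)


def rgife_repeat(cohort: ExpressionCohort,
                 config: RGIFEConfig) -> tuple[list[SignaturePanel], list[str]]:
    """Run RGIFE ``config.n_repeats`` times and intersect the panels.

    Each repeat uses an independent derived seed; the commonality list
    (genes present in every panel, in cohort order) mirrors the
    signature-overlap analysis used to nominate robust markers.
    """
    panels = [rgife_run(cohort, config, derive_seed(config.seed, 0x5E, r))
              for r in range(config.n_repeats)]
    common = set(panels[0].genes)
    for p in panels[1:]:
        common &= set(p.genes)
    commonality = [g for g in cohort.gene_ids if g in common]
    return panels, commonality


def replay_trace(gene_ids: list[str], trace: list[TrialRecord]) -> list[str]:
    """Reconstruct the final panel by replaying accepted removals."""
    genes = list(gene_ids)
    for rec in trace:
        if rec.accepted:
            block = set(rec.block_genes)
            genes = [g for g in genes if g not in block]
    return genes
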
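"""Permutation-null significance of a panel's cross-validated accuracy.

Scrambling the response labels breaks the link between expression and
outcome while preserving the class balance; re-estimating the panel's
cross-validated accuracy over many scrambles yields the null distribution
against which the observed accuracy is judged.  The classical summary fits
a normal to the null accuracies and reports the upper-tail probability of
the observed value; an add-one empirical p-value is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import ExpressionCohort
from .folds import build_dbscv_folds, build_stratified_folds
from .rgife import derive_seed, evaluate_panel


@dataclass
class PermutationResult:
    """Null accuracies from label-scrambled refits, with summary stats."""

    null_accuracies: np.ndarray
    mean: float
    sd: float
    observed: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        self.null_accuracies = np.asarray(self.null_accuracies, dtype=float)
        if len(self.null_accuracies) != self.n_permutations:
            raise ValueError("null vector length must equal n_permutations")
        if np.any((self.null_accuracies < 0) | (self.null_accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")


def permutation_null(cohort: ExpressionCohort, genes: list[str], n_permutations: int,
                     k: int, n_trees: int, seed: int, observed: float | None = None,
                     use_dbscv: bool = False) -> PermutationResult:
    """Null distribution of pooled CV accuracy under label scrambling.

    Each permutation uniformly shuffles the label vector (class counts are
    preserved by construction), re-stratifies the k folds on the permuted
    labels and records the pooled CV accuracy of a random forest restricted
    to `genes`.  Plain stratified folds are the default for the null;
    ``use_dbscv`` switches to distribution-balanced folds.

    If `observed` is given, the normal-fit upper-tail p-value of the
    observed accuracy against the null is attached to the result.
    """
    if n_permutations < 1:
        raise ValueError("need n_permutations >= 1")
    rng = np.random.default_rng(seed)
    labels = np.asarray(cohort.labels)
    fold_builder = build_dbscv_folds if use_dbscv else build_stratified_folds
    accs = np.empty(n_permutations)
    for b in range(n_permutations):
        permuted = cohort.relabelled(list(labels[rng.permutation(cohort.n_samples)]))
        folds = fold_builder(permuted, k, derive_seed(seed, 0xFD, b))
        accs[b], _, _ = evaluate_panel(permuted, genes, folds, n_trees,
                                       derive_seed(seed, 0xAC, b))
    mean = float(np.mean(accs))
    sd = float(np.std(accs, ddof=1)) if n_permutations > 1 else 0.0
    obs = float(observed) if observed is not None else float("nan")
    result = PermutationResult(accs, mean, sd, obs, float("nan"), n_permutations)
    if observed is not None:
        method = "normal_fit" if sd > 0 and n_permutations >= 2 else "empirical"
        result.p_value = permutation_pvalue(result, method)
    return result


def permutation_pvalue(result: PermutationResult, method: str = "normal_fit") -> float:
    """One-sided p-value of the observed accuracy against the null.

    ``normal_fit``: upper tail of Normal(mean, sd) at the observed value.
    ``empirical``: add-one rule (1 + #{null >= observed}) / (n + 1).
    """
    if not np.isfinite(result.observed):
        raise ValueError("result carries no observed accuracy")
    if method == "normal_fit":
        if result.n_permutations < 2:
            raise ValueError("normal_fit needs >= 2 permutations")
        if result.sd == 0:
            raise ValueError("normal_fit undefined with zero null spread")
        return float(stats.norm.sf(result.observed, loc=result.mean, scale=result.sd))
    if method == "empirical":
        exceed = int(np.sum(result.null_accuracies >= result.observed))
        return (1 + exceed) / (result.n_permutations + 1)
    raise ValueError(f"unknown method {method!r}")
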
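"""Synthetic cohort generators.

The discovery microarray data behind the response-prediction study are not
publicly deposited, so every downstream stage is exercised on synthetic
cohorts that reproduce the study's statistical structure: a 19-responder /
11-non-responder two-class design, thousands of approximately normal
log-intensity genes, a small planted set of differential genes with a
specified standardized effect size, survival times driven by a linear risk
score with independent exponential censoring, and duplicate-core
immunostaining scores on the 0-3 half-point scale.

Ground truth (planted gene identities, true hazard coefficients) is carried
on the returned objects / sidecar files, never mixed into the analysis
inputs themselves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cohort import NON_RESPONDER, RESPONDER, ExpressionCohort, IHCScoreTable, SurvivalCohort

#: Discovery-design defaults: 19 responders vs 11 non-responders.
N_RESPONDERS = 19
N_NON_RESPONDERS = 11


@dataclass
class SimulationSpec:
    """Parameters of a two-group expression cohort simulation.

    ``effect_size`` is the standardized mean shift (in units of the
    within-group SD ``base_sd``) applied to each informative gene in the
    non-responder group; the sign alternates across informative genes so
    both up- and down-regulated markers occur.
    """

    n_responders: int = N_RESPONDERS
    n_nonresponders: int = N_NON_RESPONDERS
    n_genes: int = 2000
    n_informative: int = 0
    effect_size: float = 3.0
    base_mean: float = 8.0
    base_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders <= 0 or self.n_nonresponders <= 0 or self.n_genes <= 0:
            raise ValueError("cohort dimensions must be positive")
        if self.n_informative < 0 or self.n_informative > self.n_genes:
            raise ValueError("need 0 <= n_informative <= n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.base_sd <= 0:
            raise ValueError("base_sd must be positive")


@dataclass
class SurvivalSimSpec:
    """Parameters of a risk-score-driven survival simulation.

    Event times are exponential with rate ``baseline_rate * exp(beta . x)``
    (a proportional-hazards model); censoring is an independent exponential
    clock with rate ``censor_rate``.
    """

    n_samples: int = 400
    coefficients: tuple[float, ...] = (1.0,)
    baseline_rate: float = 0.1
    censor_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        self.coefficients = tuple(float(c) for c in self.coefficients)
        if len(self.coefficients) == 0:
            raise ValueError("coefficient vector must be non-empty")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")

    @property
    def panel_size(self) -> int:
        return len(self.coefficients)


@dataclass
class IHCSimSpec:
    """Parameters of a duplicate-core immunostaining score simulation.

    ``group_means`` gives the latent mean score for responders and
    non-responders on the 0-3 intensity scale; raw scores are rounded to the
    nearest half point and clipped to [0, 3], mimicking two blinded
    assessors' averaged calls.
    """

    n_responders: int = N_RESPONDERS
    n_nonresponders: int = N_NON_RESPONDERS
    cores_per_sample: int = 2
    group_means: tuple[float, float] = (2.1, 2.6)  # (responder, non-responder)
    score_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cores_per_sample < 1:
            raise ValueError("cores_per_sample must be >= 1")
        if not all(0.0 <= m <= 3.0 for m in self.group_means):
            raise ValueError("group means must lie in [0, 3]")
        if self.score_sd < 0:
            raise ValueError("score_sd must be >= 0")


def _sample_ids(spec: SimulationSpec) -> tuple[list[str], list[str]]:
    ids = [f"R{i + 1:02d}" for i in range(spec.n_responders)] + \
          [f"N{i + 1:02d}" for i in range(spec.n_nonresponders)]
    labels = [RESPONDER] * spec.n_responders + [NON_RESPONDER] * spec.n_nonresponders
    return ids, labels


def generate_two_group_cohort(spec: SimulationSpec) -> ExpressionCohort:
    """Draw a two-class log-expression cohort with planted differential genes.

    Non-informative genes are iid Normal(base_mean, base_sd) in both groups.
    The first ``n_informative`` genes have their non-responder mean shifted
    by ``+/- effect_size * base_sd`` with alternating sign (even-indexed
    informative genes are up in non-responders, odd-indexed are down).  The
    planted identities are recorded on the returned cohort as
    ``informative_genes`` / ``informative_shift``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_responders + spec.n_nonresponders
    matrix = rng.normal(spec.base_mean, spec.base_sd, size=(spec.n_genes, n))
    gene_ids = [f"G{i + 1:05d}" for i in range(spec.n_genes)]
    sample_ids, labels = _sample_ids(spec)

    shifts: dict[str, float] = {}
    for j in range(spec.n_informative):
        sign = 1.0 if j % 2 == 0 else -1.0
        delta = sign * spec.effect_size * spec.base_sd
        matrix[j, spec.n_responders:] += delta
        shifts[gene_ids[j]] = delta

    cohort = ExpressionCohort(matrix, gene_ids, sample_ids, labels)
    cohort.informative_genes = list(shifts)
    cohort.informative_shift = shifts
    return cohort


def generate_null_cohort(spec: SimulationSpec) -> ExpressionCohort:
    """Cohort with no signal: identical design but n_informative forced to 0."""
    null_spec = SimulationSpec(spec.n_responders, spec.n_nonresponders, spec.n_genes,
                               0, spec.effect_size, spec.base_mean, spec.base_sd,
                               spec.seed)
    return generate_two_group_cohort(null_spec)


def generate_survival_cohort(spec: SurvivalSimSpec) -> tuple[ExpressionCohort, SurvivalCohort]:
    """Draw panel expression and proportional-hazards survival outcomes.

    Panel-gene expression is standard normal.  The event time for sample i
    is exponential with rate ``baseline_rate * exp(beta . x_i)``; an
    independent exponential censoring time with rate ``censor_rate``
    truncates follow-up (``censor_rate = 0`` means no censoring).
    """
    rng = np.random.default_rng(spec.seed)
    p, n = spec.panel_size, spec.n_samples
    x = rng.standard_normal(size=(n, p))
    beta = np.asarray(spec.coefficients)
    risk = x @ beta
    event_time = rng.exponential(1.0 / (spec.baseline_rate * np.exp(risk)))
    if spec.censor_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    gene_ids = [f"PANEL{j + 1:02d}" for j in range(p)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    # survival cohorts carry no response contrast; alternate labels only to
    # satisfy the two-class container invariant
    labels = [RESPONDER if i % 2 == 0 else NON_RESPONDER for i in range(n)]
    expr = ExpressionCohort(x.T, gene_ids, sample_ids, labels)
    surv = SurvivalCohort(sample_ids, time, event, covariates=x,
                          covariate_names=gene_ids)
    surv.true_coefficients = beta
    return expr, surv


def round_to_half(x: np.ndarray) -> np.ndarray:
    """Round to the nearest 0.5 (banker's rounding at exact quarters)."""
    return np.round(np.asarray(x, dtype=float) * 2.0) / 2.0


def generate_ihc_cohort(spec: IHCSimSpec) -> IHCScoreTable:
    """Draw duplicate-core immunostaining scores for both response groups."""
    rng = np.random.default_rng(spec.seed)
    ids, scores, groups = [], [], []
    mean_r, mean_n = spec.group_means
    for prefix, n, mu, grp in ((
            "R", spec.n_responders, mean_r, RESPONDER),
            ("N", spec.n_nonresponders, mean_n, NON_RESPONDER)):
        for i in range(n):
            raw = rng.normal(mu, spec.score_sd, size=spec.cores_per_sample)
            cs = np.clip(round_to_half(raw), 0.0, 3.0)
            ids.append(f"{prefix}{i + 1:02d}")
            scores.append(list(cs))
            groups.append(grp)
    return IHCScoreTable(ids, scores, groups)


def write_ground_truth(cohort: ExpressionCohort, path) -> None:
    """Sidecar JSON with the planted-gene ground truth of a cohort."""
    truth = {"informative_genes": getattr(cohort, "informative_genes", []),
             "informative_shift": getattr(cohort, "informative_shift", {})}
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
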
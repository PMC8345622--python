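"""Core data containers for the response-prediction analysis.

The central object is :class:`ExpressionCohort`, a gene x sample matrix of
log-intensity expression values with a binary response label per sample
(``responder`` vs ``non-responder``, the two chemotherapy-response groups).
Survival follow-up and tissue-microarray immunostaining scores live in
separate aligned tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RESPONDER = "responder"
NON_RESPONDER = "non-responder"
CLASSES = (RESPONDER, NON_RESPONDER)


@dataclass
class ExpressionCohort:
    """Gene x sample log-expression matrix with per-sample class labels.

    Parameters
    ----------
    matrix : ndarray, shape (n_genes, n_samples)
        Log-intensity expression values; no missing values allowed.
    gene_ids : list of str
        Unique gene identifiers, one per matrix row.
    sample_ids : list of str
        Unique sample identifiers, one per matrix column.
    labels : list of str
        Per-sample class, each ``"responder"`` or ``"non-responder"``;
        both classes must be represented.
    """

    matrix: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.labels = list(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        n_genes, n_samples = self.matrix.shape
        if n_genes == 0 or n_samples == 0:
            raise ValueError("empty expression matrix")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match matrix columns")
        if len(self.labels) != n_samples:
            raise ValueError("labels length does not match matrix columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("expression matrix contains missing/non-finite values")
        bad = set(self.labels) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if len(set(self.labels)) < 2:
            raise ValueError("both response classes must be present")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Binary label vector: 1 = responder, 0 = non-responder."""
        return np.asarray([1 if l == RESPONDER else 0 for l in self.labels])

    def gene_rows(self, genes: list[str]) -> np.ndarray:
        """Row indices for `genes`, raising on unknown identifiers."""
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"unknown gene IDs: {missing[:5]}")
        return np.asarray([self._gene_index[g] for g in genes])

    def features(self, genes: list[str]) -> np.ndarray:
        """Sample x gene feature matrix restricted to `genes`."""
        if len(genes) == 0:
            raise ValueError("gene list must be non-empty")
        return self.matrix[self.gene_rows(genes)].T

    def relabelled(self, labels: list[str]) -> "ExpressionCohort":
        """Copy of the cohort with a replacement label vector."""
        return ExpressionCohort(self.matrix, self.gene_ids, self.sample_ids, labels)

    # --- tab-delimited interchange -------------------------------------

    def to_expression_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=pd.Index(self.gene_ids, name="gene_id"),
                            columns=self.sample_ids)

    def write(self, expression_path, labels_path) -> None:
        """Write expression (genes as rows) and label tables as TSV."""
        self.to_expression_frame().to_csv(expression_path, sep="\t")
        pd.DataFrame({"sample_id": self.sample_ids, "response": self.labels}).to_csv(
            labels_path, sep="\t", index=False)

    @classmethod
    def read(cls, expression_path, labels_path) -> "ExpressionCohort":
        expr = pd.read_csv(expression_path, sep="\t", index_col=0)
        lab = pd.read_csv(labels_path, sep="\t")
        lab = lab.set_index("sample_id").loc[expr.columns]
        return cls(expr.to_numpy(), list(expr.index.astype(str)),
                   list(expr.columns.astype(str)), list(lab["response"]))


@dataclass
class SurvivalCohort:
    """Right-censored follow-up aligned to a set of samples.

    ``time`` is follow-up duration in study time units, ``event`` is 1 for a
    death/event and 0 for censoring.  ``covariates`` (optional) is a
    sample x covariate matrix used for Cox risk scoring.
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event must align with sample_ids")
        if np.any(self.time < 0):
            raise ValueError("negative follow-up times")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event flags must be 0/1")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim == 1:
                self.covariates = self.covariates[:, None]
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows must align with sample_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, mask: np.ndarray) -> "SurvivalCohort":
        mask = np.asarray(mask, dtype=bool)
        cov = self.covariates[mask] if self.covariates is not None else None
        ids = [s for s, m in zip(self.sample_ids, mask) if m]
        return SurvivalCohort(ids, self.time[mask], self.event[mask], cov,
                              list(self.covariate_names))

    def write(self, path) -> None:
        pd.DataFrame({"sample_id": self.sample_ids, "time": self.time,
                      "event": self.event}).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SurvivalCohort":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df["sample_id"].astype(str)), df["time"].to_numpy(),
                   df["event"].to_numpy())


@dataclass
class IHCScoreTable:
    """Per-sample tissue-microarray immunostaining scores.

    Each sample carries one assessor-averaged intensity score per core on the
    half-point grid {0, 0.5, ..., 3} (0 = absent ... 3 = strong staining).
    """

    sample_ids: list[str]
    core_scores: list[list[float]]
    response_group: list[str] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.core_scores = [list(map(float, cs)) for cs in self.core_scores]
        if len(self.core_scores) != len(self.sample_ids):
            raise ValueError("core_scores must align with sample_ids")
        for cs in self.core_scores:
            if len(cs) < 1:
                raise ValueError("every sample needs >= 1 core score")
            for s in cs:
                if not (0.0 <= s <= 3.0) or round(s * 2) != s * 2:
                    raise ValueError(f"score {s} off the half-point 0-3 grid")
        if self.response_group is not None:
            self.response_group = list(self.response_group)
            if len(self.response_group) != len(self.sample_ids):
                raise ValueError("response_group must align with sample_ids")

    def mean_scores(self) -> np.ndarray:
        return np.asarray([float(np.mean(cs)) for cs in self.core_scores])

    def write(self, path) -> None:
        rows = [(sid, j, s) for sid, cs in zip(self.sample_ids, self.core_scores)
                for j, s in enumerate(cs)]
        pd.DataFrame(rows, columns=["sample_id", "core_index", "score"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def read(cls, path, labels: dict[str, str] | None = None) -> "IHCScoreTable":
        df = pd.read_csv(path, sep="\t")
        ids, scores = [], []
        for sid, grp in df.groupby("sample_id", sort=False):
            ids.append(str(sid))
            scores.append(list(grp.sort_values("core_index")["score"]))
        groups = [labels[s] for s in ids] if labels else None
        return cls(ids, scores, groups)
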
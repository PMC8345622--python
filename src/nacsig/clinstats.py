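"""Cohort-characteristics statistics and TMA immunostaining scoring.

Covers the discovery cohort's baseline comparisons (Fisher's exact tests on
gender / pre-operative stage / grade and a two-sample t-test on age between
responders and non-responders) and the tissue-microarray rules: assessor
scores on the 0-3 half-point grid, the high/low expression-level
classification, and the between-group comparison of per-sample mean scores.

Welch's t-test (unequal variances) is the default for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import IHCScoreTable

HALF_GRID = [x / 2.0 for x in range(0, 7)]  # 0, 0.5, ..., 3


@dataclass
class ContingencyTable2x2:
    counts: np.ndarray
    row_labels: tuple[str, str] = ("responder", "non-responder")
    col_labels: tuple[str, str] = ("a", "b")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ValueError("need a 2x2 table")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.counts.sum() < 1:
            raise ValueError("empty table")


def fisher_exact(table: ContingencyTable2x2 | np.ndarray) -> float:
    """Two-sided Fisher's exact p: the sum of hypergeometric probabilities
    of all tables with the observed margins whose point probability does
    not exceed the observed one."""
    counts = table.counts if isinstance(table, ContingencyTable2x2) else \
        ContingencyTable2x2(np.asarray(table)).counts
    return float(stats.fisher_exact(counts, alternative="two-sided")[1])


def t_test(a, b, equal_var: bool = False, paired: bool = False):
    """Two-sided two-sample t-test.

    Welch (unequal-variance, Welch-Satterthwaite df) unless ``equal_var``;
    ``paired`` requires equal-length vectors and tests the differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length samples")
        res = stats.ttest_rel(a, b)
    else:
        if np.var(a) == 0 and np.var(b) == 0:
            raise ValueError("zero variance in both samples")
        res = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


# --- discovery-cohort clinical table -----------------------------------

def load_clinical_table() -> pd.DataFrame:
    """The packaged discovery-cohort clinicopathological table."""
    with resources.files("nacsig.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _two_by_two(df: pd.DataFrame, col: str, positive) -> ContingencyTable2x2:
    resp = df["response"] == "Responder"
    pos = df[col].apply(positive)
    counts = [[int((resp & pos).sum()), int((resp & ~pos).sum())],
              [int((~resp & pos).sum()), int((~resp & ~pos).sum())]]
    return ContingencyTable2x2(np.asarray(counts),
                               col_labels=(f"{col}+", f"{col}-"))


def cohort_characteristics(df: pd.DataFrame | None = None,
                           stage_reference: str = "T2",
                           grade_rule: str = "g3_component") -> dict[str, float]:
    """Baseline balance statistics between responders and non-responders.

    Fisher's exact on gender (male vs female), pre-operative stage
    (``stage_reference`` vs other) and grade; Welch t on age.  The grade
    dichotomisation ``g3_component`` groups any G3-containing grade (G3 or
    G2/3) against pure G2; ``g2_component`` is the complementary reading.
    """
    if df is None:
        df = load_clinical_table()
    gender = _two_by_two(df, "gender", lambda g: g == "Male")
    stage = _two_by_two(df, "preop_stage", lambda s: s == stage_reference)
    if grade_rule == "g3_component":
        grade = _two_by_two(df, "preop_grade", lambda g: "G3" in g or g == "G2/3")
    elif grade_rule == "g2_component":
        grade = _two_by_two(df, "preop_grade", lambda g: "G2" in g)
    else:
        raise ValueError(f"unknown grade rule {grade_rule!r}")
    ages_r = df.loc[df["response"] == "Responder", "age"]
    ages_n = df.loc[df["response"] != "Responder", "age"]
    _, _, p_age = t_test(ages_r, ages_n, equal_var=False)
    return {
        "fisher_gender_p": fisher_exact(gender),
        "t_age_p": p_age,
        "fisher_stage_p": fisher_exact(stage),
        "fisher_grade_p": fisher_exact(grade),
    }


# --- immunostaining classification -------------------------------------

@dataclass
class IHCClassification:
    sample_ids: list[str]
    level: list[str]            # high | low | indeterminate
    mean_score: np.ndarray
    rule_conflict: list[bool]   # high- and low-rules both fired


def classify_ihc(table: IHCScoreTable) -> IHCClassification:
    """High/low expression-level call per sample from its core scores.

    ``high``: any single core >= 2.5 OR mean core score >= 1.5;
    ``low``: any single core <= 1; ``indeterminate`` otherwise.  The
    high-rule takes precedence when both fire (the overlap is possible on
    the half-point grid, e.g. cores (0.5, 3)); such samples are flagged as
    rule conflicts.
    """
    levels, conflicts = [], []
    means = table.mean_scores()
    for cs, mean in zip(table.core_scores, means):
        cs = np.asarray(cs)
        high = bool(np.any(cs >= 2.5) or mean >= 1.5)
        low = bool(np.any(cs <= 1.0))
        if high:
            levels.append("high")
        elif low:
            levels.append("low")
        else:
            levels.append("indeterminate")
        conflicts.append(high and low)
    return IHCClassification(list(table.sample_ids), levels, means, conflicts)


def compare_ihc_groups(table: IHCScoreTable, equal_var: bool = False):
    """Responder vs non-responder comparison of per-sample mean scores.

    Returns group means with standard errors and the unpaired two-tailed
    t-test (Welch by default) across groups.
    """
    if table.response_group is None:
        raise ValueError("score table carries no response groups")
    means = table.mean_scores()
    groups = np.asarray(table.response_group)
    out = {}
    vecs = {}
    for grp in sorted(set(groups)):
        v = means[groups == grp]
        if len(v) < 2:
            raise ValueError(f"group {grp!r} needs >= 2 samples")
        vecs[grp] = v
        out[grp] = {"mean": float(v.mean()),
                    "sem": float(v.std(ddof=1) / np.sqrt(len(v)))}
    if len(vecs) != 2:
        raise ValueError("exactly two response groups required")
    (a, b) = (vecs[g] for g in sorted(vecs))
    t, df, p = t_test(a, b, equal_var=equal_var)
    return out, t, df, p
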
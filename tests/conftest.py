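import numpy as np
import pytest

import nacsig as ns


@pytest.fixture(scope="session")
def planted_cohort():
    """30-sample (19/11) cohort, 100 genes, 5 planted at effect size 3."""
    return ns.generate_two_group_cohort(
        ns.SimulationSpec(19, 11, 100, 5, 3.0, seed=101))


@pytest.fixture(scope="session")
def null_cohort():
    """30-sample (19/11) cohort with no signal, 200 genes."""
    return ns.generate_null_cohort(ns.SimulationSpec(19, 11, 200, 0, seed=202))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-sample, four-gene cohort for hand arithmetic."""
    matrix = np.array([
        [1.0, 2.0, 3.0, 7.0, 8.0, 9.0],   # strong separator
        [5.0, 5.5, 4.5, 5.2, 4.8, 5.0],   # noise
        [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],   # constant
        [0.0, 1.0, 2.0, 1.0, 0.0, 2.0],   # symmetric noise
    ])
    return ns.ExpressionCohort(
        matrix, ["sep", "noise", "flat", "sym"],
        [f"s{i}" for i in range(6)],
        ["responder"] * 3 + ["non-responder"] * 3)
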
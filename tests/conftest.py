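import numpy as np
import pytest

from adipohep.data_io import packaged_signature
from adipohep.simulate import SimulationConfig, simulate_expression, simulate_survival
from adipohep.types import ExpressionCohort, GeneSet


@pytest.fixture(scope="session")
def signature() -> GeneSet:
    return packaged_signature()


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulation shared by read-only tests."""
    config = SimulationConfig(seed=11)
    expr, truth = simulate_expression(config)
    surv = simulate_survival(config, expr, truth)
    return config, expr, truth, surv


@pytest.fixture
def tiny_cohort() -> ExpressionCohort:
    rng = np.random.default_rng(5)
    return ExpressionCohort(
        gene_ids=("g1", "g2", "g3"),
        sample_ids=("s1", "s2"),
        values=rng.uniform(1, 10, size=(3, 2)),
        cohort=("tumor", "tumor"),
        sex=("female", "male"),
    )


def make_cohort(values, genes=None, samples=None, cohort="tumor", sex="unknown"):
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    genes = genes or tuple(f"g{i}" for i in range(1, g + 1))
    samples = samples or tuple(f"s{j}" for j in range(1, s + 1))
    cohorts = (cohort,) * s if isinstance(cohort, str) else tuple(cohort)
    sexes = (sex,) * s if isinstance(sex, str) else tuple(sex)
    return ExpressionCohort(tuple(genes), tuple(samples), values, cohorts, sexes)
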
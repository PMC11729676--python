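import numpy as np
import pytest

from quantgap import AnalysisSpec, GroupSample, generate_group, scenario_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_dataset(rng):
    """One modest heteroskedastic regression dataset (n=80, p=2)."""
    n = 80
    X = np.column_stack([np.ones(n), rng.uniform(0, 2, n), rng.uniform(0, 1, n)])
    y = X @ np.array([1.0, 0.5, -0.3]) + (X @ np.array([0.3, 0.1, 0.05])) * rng.standard_normal(n)
    return X, y


@pytest.fixture(scope="session")
def small_groups():
    """A reference/comparison GroupSample pair from the mixed scenario."""
    dgp_ref, dgp_cmp = scenario_pair("mixed", n_ref=220, n_cmp=160)
    return generate_group(dgp_ref, 101), generate_group(dgp_cmp, 102)


@pytest.fixture
def small_spec():
    return AnalysisSpec(
        outcome_name="y",
        group_name="group",
        reference_level="reference",
        comparison_level="comparison",
        covariate_names=("income", "network", "support", "literacy"),
        tau_grid=np.round(np.linspace(0.05, 0.95, 19), 4),
        report_taus=(0.25, 0.5, 0.75),
        bootstrap_reps=30,
        seed=7,
    )


@pytest.fixture
def csv_file(tmp_path):
    """Factory writing a small delimited file and returning its path."""

    def make(text, name="data.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return make
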
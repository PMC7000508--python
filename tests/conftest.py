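import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import nactscore as ns
from nactscore.synthetic import DEFAULT_GENE_MODELS

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> ns.ExpressionMatrix:
    values = pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2"],
    )
    return ns.ExpressionMatrix(cohort_id="toy", values=values)


@pytest.fixture(scope="session")
def signatures():
    return ns.default_ms12(), ns.default_rs21()


@pytest.fixture(scope="session")
def small_config() -> ns.SimulationConfig:
    """Three modest cohorts with the default gene models; fast to generate."""
    sigma = 0.64  # SD of the latent outcome term at the default betas
    cohorts = tuple(
        ns.CohortConfig(name=f"sim{i}", n_samples=160,
                        alpha=ns.calibrate_alpha(0.10, sigma),
                        platform_shift=shift)
        for i, shift in enumerate([0.0, 0.5, -0.8])
    )
    return ns.SimulationConfig(cohorts=cohorts, genes=dict(DEFAULT_GENE_MODELS), seed=7)


@pytest.fixture(scope="session")
def small_study(small_config) -> ns.SyntheticStudy:
    return ns.generate_study(small_config)


@pytest.fixture(scope="session")
def small_gene_expression(small_study, signatures):
    ms12, rs21 = signatures
    genes = sorted(set(ms12.genes) | set(rs21.genes))
    return {
        c: ns.collapse_probes(m, small_study.annotation, genes)
        for c, m in small_study.expression.items()
    }


@pytest.fixture(scope="session")
def small_scores(small_gene_expression, small_study, signatures) -> pd.DataFrame:
    ms12, rs21 = signatures
    return ns.build_score_table(small_gene_expression, small_study.clinical, ms12, rs21)


@pytest.fixture(scope="session")
def paperlike_config() -> ns.SimulationConfig:
    return ns.default_paperlike_config(seed=11)
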
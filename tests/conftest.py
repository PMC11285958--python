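import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from degsig import SignatureSpec, SimulationConfig, simulate_cohort
from degsig.io import ExpressionMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_cohort():
    """Mid-size cohort with one anchor, one module and two planted signatures."""
    cfg = SimulationConfig(
        n_samples=200,
        n_background_genes=200,
        anchors=("JAG1",),
        module_size=30,
        target_rho=0.5,
        signatures=(
            SignatureSpec("POS_SIG", 20, 1, 0.5),
            SignatureSpec("NEG_SIG", 20, -1, 0.5),
        ),
        seed=42,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def tiny_expr():
    """Deterministic 6-gene x 8-sample matrix for format / contract tests."""
    rng = np.random.default_rng(7)
    genes = [f"G{i}" for i in range(6)]
    samples = [f"S{i}" for i in range(8)]
    return ExpressionMatrix(pd.DataFrame(rng.standard_normal((6, 8)), index=genes, columns=samples))
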
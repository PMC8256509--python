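import numpy as np
import pandas as pd
import pytest

from osmetnet.synthetic import SimConfig, simulate_expression, write_bundle


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(seed=11, n_genes=300, n_de=20)


@pytest.fixture(scope="session")
def small_expression(small_config):
    return simulate_expression(small_config)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, small_config):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(small_config, outdir)
    return paths


def random_expression(seed: int, n_genes: int = 50, n_case: int = 5, n_control: int = 5):
    """Unstructured random matrix for oracle comparisons."""
    rng = np.random.default_rng(seed)
    samples = [f"S{i}" for i in range(n_case + n_control)]
    expr = pd.DataFrame(
        rng.normal(8.0, 2.0, size=(n_genes, n_case + n_control)),
        index=pd.Index([f"G{i}" for i in range(n_genes)], name="gene"),
        columns=samples,
    )
    groups = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples, name="group"
    )
    return expr, groups
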
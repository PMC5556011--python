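import numpy as np
import pandas as pd
import pytest

from tuberscope import synthetic
from tuberscope.io import ExpressionMatrix, SampleMetadata


@pytest.fixture(scope="session")
def module_sim():
    """The planted-module study condition: 3 modules x 120 genes, cor 0.8,
    22 samples, with two anti-correlated miRNAs covering half their module."""
    params = synthetic.ModuleSimParams(
        n_genes=500,
        module_sizes=(120, 120, 120),
        within_module_cor=0.8,
        n_samples=22,
        n_mirna=6,
        anti_pairs=[(0, 1, 0.5), (1, 2, 0.5)],
        seed=7,
    )
    return synthetic.simulate_modules(params)


@pytest.fixture(scope="session")
def bulk_sim():
    """12 vs 10 cohort with 5% planted DE at |log2FC| = 2, noise 0.25."""
    params = synthetic.BulkSimParams(
        n_genes=2000, frac_de=0.05, log2fc_effect=2.0, noise_sd=0.25, seed=1
    )
    return synthetic.simulate_bulk(params)


@pytest.fixture()
def two_group_meta():
    def make(n_case, n_control, prefix="s"):
        samples = [f"{prefix}{i:02d}" for i in range(n_case + n_control)]
        return SampleMetadata(
            pd.DataFrame(
                {"group": ["case"] * n_case + ["control"] * n_control},
                index=samples,
            )
        )

    return make


def as_matrix(arr, kind="log2", prefix="g"):
    arr = np.asarray(arr, dtype=float)
    genes = [f"{prefix}{i:03d}" for i in range(arr.shape[0])]
    samples = [f"s{j:02d}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), kind)
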
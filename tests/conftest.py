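import numpy as np
import pandas as pd
import pytest

import sojo


@pytest.fixture
def ma_file(tmp_path):
    """A small well-formed .ma summary table on disk (with CHR/BP)."""

    def make(rows=None, name="summary.ma"):
        if rows is None:
            rows = [
                # SNP CHR BP A1 A2 freq b se p N
                ("rs1", "1", 1000, "A", "G", 0.30, 0.10, 0.02, 1e-6, 10000),
                ("rs2", "1", 2000, "C", "T", 0.10, -0.05, 0.02, 1e-3, 9000),
                ("rs3", "2", 1500, "G", "A", 0.45, 0.02, 0.02, 0.30, 10000),
            ]
        df = pd.DataFrame(
            rows, columns=["SNP", "CHR", "BP", "A1", "A2", "freq", "b", "se", "p", "N"]
        )
        path = tmp_path / name
        df.to_csv(path, sep="\t", index=False)
        return path

    return make


@pytest.fixture
def small_cohort():
    """A seeded cohort with 3 causal variants and its exact inputs."""
    rng = np.random.default_rng(7)
    n, p = 2000, 12
    X = sojo.simulate_genotypes(n, p, 0.7, 0.3, rng=rng)
    beta = np.zeros(p)
    beta[[2, 6, 9]] = [0.05, -0.04, 0.03]
    y = (X - X.mean(0)) @ beta + rng.normal(0, 1, n)
    return X, y


@pytest.fixture
def panel_factory():
    def make(X, **kw):
        return sojo.panel_from_matrix(X, **kw)

    return make


def random_pd_inputs(rng, p=8, n_base=400):
    """Random positive-definite standardized inputs for path unit tests."""
    Z = rng.standard_normal((n_base, p)) @ rng.standard_normal((p, p))
    B = np.corrcoef(Z, rowvar=False)
    B = (B + B.T) / 2
    np.fill_diagonal(B, 1.0)
    C = rng.normal(0, 0.3, p)
    return sojo.StandardizedInputs(
        C=C, B=B, d_w=rng.uniform(0.2, 1.5, p), sigma2=1.0,
        ids=np.array([f"v{j}" for j in range(p)], dtype=object),
    )
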
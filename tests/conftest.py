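import numpy as np
import pandas as pd
import pytest

from methrna import AssayMatrix, GeneModel, ManifestRow, SampleMeta, SynthConfig, generate


def make_matrix(values, assay, features=None, samples=None, scale=""):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AssayMatrix(pd.DataFrame(values, index=features, columns=samples), assay, scale)


@pytest.fixture
def small_repo(tmp_path):
    """A tiny synthetic repository shared by integration-level tests."""
    cfg = SynthConfig(
        n_patients=6, n_genes=40, n_canonical=4, n_non_canonical=2, n_de_genes=4, seed=7
    )
    repo = tmp_path / "repo"
    generate(cfg, repo)
    return cfg, repo


@pytest.fixture
def paired_meta():
    rows = []
    for p in ("P1", "P2", "P3"):
        rows.append(SampleMeta(f"{p}-M", p, "tumor", "methylation"))
        rows.append(SampleMeta(f"{p}-E", p, "tumor", "expression"))
    return rows
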
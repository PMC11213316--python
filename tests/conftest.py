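import numpy as np
import pandas as pd
import pytest

from nkdmr import (
    LayoutConfig,
    SimConfig,
    emulate_layout,
)
from nkdmr.simulation import assign_truth, simulate_dataset


@pytest.fixture(scope="session")
def small_layout():
    """~1,200-probe clustered layout on two chromosomes (fixed seed)."""
    config = LayoutConfig(probes_per_chromosome={"chr1": 700, "chr2": 500})
    return emulate_layout(config, seed=1234)


@pytest.fixture(scope="session")
def small_dataset(small_layout):
    """A simulated dataset with 12 true DMRs at delta_beta = 0.2."""
    rng = np.random.default_rng(99)
    truth = assign_truth(small_layout.regions, n_true=12, seed=rng)
    data = simulate_dataset(small_layout, truth, SimConfig(), seed=rng)
    return data


@pytest.fixture()
def annotation_csv(tmp_path, small_layout):
    path = tmp_path / "annotation.csv"
    small_layout.table.to_csv(path, index=False, columns=["probe_id", "chrom", "pos"])
    return path


def make_sites_frame(chrom, pos, p_raw=None, p_adj=None):
    """Helper: a minimal significant-sites frame for agglomeration tests."""
    n = len(pos)
    return pd.DataFrame({
        "chrom": chrom if not isinstance(chrom, str) else [chrom] * n,
        "pos": pos,
        "p_raw": p_raw if p_raw is not None else np.full(n, 0.01),
        "p_adj": p_adj if p_adj is not None else np.full(n, 0.04),
    })
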
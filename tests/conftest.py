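import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from interplot.geometry import FieldLayout
from interplot.kinship import additive_grm
from interplot.synth import SyntheticConfig, simulate_markers


def strip_layout(clones=("A", "B", "C")):
    """1 x n strip of plots in a single Range (2 x 1 m plots)."""
    n = len(clones)
    return FieldLayout(
        plot_ids=np.arange(n),
        range_idx=np.ones(n, dtype=int),
        col_idx=np.arange(1, n + 1),
        clone_ids=np.array(clones, dtype=object),
        plot_width=1.0,
        plot_length=2.0,
    )


def grid_layout(n_ranges, n_cols, clones=None, width=1.0, length=2.0):
    rr, cc = np.meshgrid(np.arange(1, n_ranges + 1), np.arange(1, n_cols + 1), indexing="ij")
    n = n_ranges * n_cols
    if clones is None:
        clones = [f"G{i}" for i in range(n)]
    return FieldLayout(
        plot_ids=np.arange(n),
        range_idx=rr.ravel(),
        col_idx=cc.ravel(),
        clone_ids=np.array(clones, dtype=object),
        plot_width=width,
        plot_length=length,
    )


@pytest.fixture(scope="session")
def small_trial():
    """60-genotype synthetic trial shared by the slower model tests."""
    config = SyntheticConfig(n_genotypes=60, n_checks=4, n_markers=300, seed=11)
    dosages = simulate_markers(config)
    return config, additive_grm(dosages)
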
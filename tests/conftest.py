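import numpy as np
import pytest

from rewire3d import contact_map as cm
from rewire3d import synthetic_data as sd


@pytest.fixture(scope="session")
def small_pair():
    """A 600-bin paired simulation with checkerboard, flips and CNVs."""
    spec = sd.SimulationSpec(n_bins=600, depth=8e5, compartment_effect=0.4,
                             compartment_block_len=30, seed=2)
    rew = sd.RewiringSpec(flip_block_fraction=0.2,
                          cnv_list=[(100, 150, 2.0), (400, 450, 0.5)], seed=3)
    map_pr, map_cr, truth = sd.simulate_condition_pair(spec, rew)
    return spec, rew, map_pr, map_cr, truth


@pytest.fixture(scope="session")
def small_pair_annotation(small_pair):
    spec, rew, map_pr, map_cr, truth = small_pair
    genes, motifs, gc = sd.simulate_annotation_tracks(spec, truth, seed=4)
    gd = sd.gene_density_track(genes, spec.n_bins, spec.resolution)
    return genes, motifs, gc, gd


@pytest.fixture(scope="session")
def balanced_pr(small_pair):
    _, _, map_pr, _, _ = small_pair
    return cm.balance(map_pr, method="ICE")


def random_loops_frame(rng, n, n_bins, resolution=10_000, max_dist=80):
    """Random BEDPE-like loop frame used by set-algebra tests."""
    import pandas as pd
    b1 = rng.integers(0, n_bins - max_dist - 1, size=n)
    b2 = b1 + rng.integers(2, max_dist, size=n)
    df = pd.DataFrame({"bin1": b1, "bin2": b2})
    df["a1_start"] = df["bin1"] * resolution
    df["a1_end"] = (df["bin1"] + 1) * resolution
    df["a2_start"] = df["bin2"] * resolution
    df["a2_end"] = (df["bin2"] + 1) * resolution
    df["size"] = (df["bin2"] - df["bin1"]) * resolution
    return df
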
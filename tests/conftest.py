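import numpy as np
import pytest

from scmosaic import Genome, SimConfig, simulate_strand_cells


@pytest.fixture(scope="session")
def small_genome():
    return Genome.from_pairs([("chr1", 20_000_000), ("chr2", 20_000_000),
                              ("chr3", 20_000_000)])


@pytest.fixture(scope="session")
def clean_strand_sim():
    """Noise-free strand simulation with hotspot-confined SCE breakpoints.

    Confining breakpoints to interior hotspot intervals keeps them away from
    chromosome ends, where an SCE falls outside the resolvable range of
    binned segmentation (fewer than min_bins bins on one side).
    """
    cfg = SimConfig(
        genome=[("chr1", 20_000_000), ("chr2", 20_000_000),
                ("chr3", 20_000_000)],
        bin_width=200_000, n_cells=40, reads_per_cell=40_000.0,
        sce_rate=1.0, background_noise=0.0,
        sce_hotspots=[(("chr1", 5_000_000, 15_000_000), 1e9),
                      (("chr2", 5_000_000, 15_000_000), 1e9),
                      (("chr3", 5_000_000, 15_000_000), 1e9)],
        seed=20240917)
    return cfg, simulate_strand_cells(cfg)


def assert_close(a, b, tol, label=""):
    assert abs(a - b) <= tol, f"{label}: {a} vs {b} (tol {tol})"


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
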
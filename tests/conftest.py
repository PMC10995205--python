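import numpy as np
import pandas as pd
import pytest

import magniche as mg
import magniche.abundance as ab


@pytest.fixture(scope="session")
def noise_free_study():
    """Default-scale synthetic study with no coverage noise (seed 11)."""
    return mg.generate_study(mg.SimulationDesign(seed=11, noise_sd=0.0))


@pytest.fixture(scope="session")
def default_study():
    """Default-scale synthetic study at the default noise level (seed 3)."""
    return mg.generate_study(mg.SimulationDesign(seed=3))


@pytest.fixture(scope="session")
def default_abundance(default_study):
    cov = ab.apply_detection_filter(default_study.coverage)
    return ab.normalize(cov, default_study.samples)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_mags():
    """Five hand-written MAG records spanning the quality thresholds."""
    rows = [
        ("bin_a", "Site1", 95.0, 1.0, 3_000_000, 45.0, 2800, 88.0),
        ("bin_b", "Site1", 80.0, 5.0, 2_500_000, 50.0, 2300, 89.0),
        ("bin_c", "Site2", 74.9, 0.0, 2_000_000, 48.0, 1900, 90.0),
        ("bin_d", "Site2", 90.0, 15.0, 4_000_000, 42.0, 3600, 87.0),
        ("bin_e", "Site3", 75.0, 25.0 / 3.0, 1_500_000, 55.0, 1400, 91.0),
    ]
    return [
        mg.MAGRecord(
            mag_id=m, site=s, completeness=c, contamination=k, genome_size=g,
            gc=gc, n_genes=n, coding_density=d,
            taxonomy="d__Bacteria;p__Pseudomonadota;c__;o__;f__;g__;s__",
        )
        for m, s, c, k, g, gc, n, d in rows
    ]


def make_distance(points: np.ndarray, ids=None) -> "mg.DistanceMatrix":
    """Euclidean distance matrix from a point configuration."""
    import scipy.spatial.distance as ssd

    d = ssd.squareform(ssd.pdist(points))
    ids = ids or [f"s{i}" for i in range(len(points))]
    return mg.DistanceMatrix(
        data=pd.DataFrame(d, index=ids, columns=ids), metric="bray_curtis"
    )
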
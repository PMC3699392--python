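import numpy as np
import pytest

import aimpanel as ap


@pytest.fixture(scope="session")
def two_region_dataset():
    """Two well-separated regions, 30 samples each, 300 loci, with truth."""
    cfg = ap.SimulationConfig(
        n_loci=300,
        regions=("Africa", "Europe"),
        region_f=(0.3, 0.3),
        samples_per_region=30,
        missing_rate=0.02,
        seed=101,
    )
    return ap.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def seven_region_dataset():
    """Small seven-region scenario for pipeline-level tests."""
    cfg = ap.SimulationConfig(
        n_loci=600,
        samples_per_region=15,
        missing_rate=0.01,
        seed=202,
    )
    return ap.simulate_dataset(cfg)


@pytest.fixture()
def tiny_ped(tmp_path):
    """Hand-written 3-sample, 2-locus PED/MAP pair with known dosages."""
    ped = tmp_path / "tiny.ped"
    map_ = tmp_path / "tiny.map"
    # locus rs1: alleles A (counted: first observed) / G; rs2: T / C
    ped.write_text(
        "F1 S1 0 0 1 0 A A T C\n"
        "F2 S2 0 0 2 0 A G C C\n"
        "F3 S3 0 0 1 0 0 0 T 0\n"
    )
    map_.write_text("1 rs1 0 1000\n1 rs2 0 2000\n")
    expected = np.array(
        [
            [2.0, 1.0],
            [1.0, 0.0],
            [np.nan, np.nan],  # S3: missing + half-missing
        ]
    )
    return ped, map_, expected
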
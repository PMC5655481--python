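import numpy as np
import pandas as pd
import pytest

from svpopdiff.core import GenotypeMatrix, PopulationPanel
from svpopdiff.synthdata import SimConfig, simulate_annotations, simulate_panel


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale cohort: two short chromosomes, trimmed site counts."""
    return SimConfig(
        seed=11,
        chrom_lengths={"1": 2_000_000, "2": 1_500_000},
        n_snp=300,
        n_sv={"DEL": 120, "INV": 10, "DUP": 6},
        n_implant=8,
        te_per_mb=80.0,
        vntr_per_mb=15.0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return simulate_panel(small_cfg)


@pytest.fixture(scope="session")
def small_annotations(small_cfg):
    return simulate_annotations(small_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_matrix() -> GenotypeMatrix:
    """Hand-built 4-sample, 5-site matrix with one missing genotype."""
    sites = pd.DataFrame(
        {
            "chrom": ["1"] * 4 + ["2"],
            "start": [100, 5_000, 9_000, 20_000, 50],
            "end": [600, 5_400, 9_300, 21_000, 450],
            "svtype": ["DEL"] * 5,
            "site_id": [f"DEL_{i}" for i in range(5)],
        }
    )
    dosage = np.array(
        [
            [0, 1, 2, 0, 1],
            [1, 1, 2, 0, 0],
            [2, 0, 2, -1, 1],
            [1, 2, 2, 0, 2],
        ],
        dtype=np.int16,
    )
    return GenotypeMatrix(sites, ["s1", "s2", "s3", "s4"], dosage)


@pytest.fixture()
def two_group_panel() -> PopulationPanel:
    return PopulationPanel(
        pd.DataFrame(
            {
                "sample": ["s1", "s2", "s3", "s4"],
                "breed": ["b1", "b1", "b2", "b2"],
                "group": ["A", "A", "B", "B"],
            }
        )
    )
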
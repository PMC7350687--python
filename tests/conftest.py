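"""Shared fixtures: small synthetic datasets and on-disk toy Ct tables."""

import numpy as np
import pytest

from stavarsel import CtMatrix, SimulationConfig, generate_ct_dataset


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced cohort/panel used where the full 112 x 78 layout is overkill."""
    return SimulationConfig(
        n_control=8, n_gord=8, n_cancer=16,
        n_assays=24, n_hkg=4, n_spikein=2, n_informative=4,
        effect_ct=2.5,  # stronger planted effect: n=32 has little power at 1.5
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_ct_dataset(small_config, seed=11)


@pytest.fixture()
def toy_ct() -> CtMatrix:
    """3 assays x 6 samples with one missing cell, hand-set values."""
    ct = np.array(
        [
            [28.0, 29.0, 27.5, 30.0, 31.0, 29.5],
            [30.0, 31.0, 29.0, 28.0, 27.0, 28.5],
            [35.0, np.nan, 34.0, 36.0, 35.5, 34.5],
        ]
    )
    samples = [f"s{i}" for i in range(6)]
    groups = {s: ("cancer" if i >= 3 else "control") for i, s in enumerate(samples)}
    return CtMatrix(["a1", "a2", "a3"], samples, ct, groups)


@pytest.fixture()
def toy_ct_files(tmp_path):
    """A 3-assay x 4-sample CSV with two Undetermined cells plus metadata."""
    ct_path = tmp_path / "ct.csv"
    ct_path.write_text(
        "assay_id,s1,s2,s3,s4\n"
        "a1,25.1,26.0,24.5,25.5\n"
        "a2,30.0,Undetermined,31.2,30.8\n"
        "a3,33.3,34.0,,35.1\n"
    )
    meta_path = tmp_path / "meta.csv"
    meta_path.write_text(
        "sample_id,cohort\ns1,control\ns2,GORD\ns3,cancer\ns4,cancer\n"
    )
    return ct_path, meta_path
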
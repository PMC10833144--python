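import numpy as np
import pytest

import peptipanel as pp


@pytest.fixture(scope="session")
def panel():
    return pp.load_panel_fixture()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """One deterministic Table-calibrated cohort with a light background."""
    specs = pp.calibrate_from_panel(panel, sigma=0.25)
    cfg = pp.CohortConfig(sigma=0.25, n_background_peptides=200)
    return pp.generate_cohort(cfg, specs, seed=11)


@pytest.fixture
def tiny_dataset():
    """2 samples x 2 peptides hand-built dataset."""
    return pp.IntensityDataset(
        sample_ids=["s1", "s2"],
        peptide_ids=["pep1", "pep2"],
        intensities=np.array([[1.5, 0.0], [2.25, 7.0]]),
        group=["pFSGS", "NC"],
    )


@pytest.fixture
def separable_xy():
    """Strongly separated 1-feature case/control intensities."""
    rng = np.random.default_rng(0)
    x_cases = rng.lognormal(np.log(1000), 0.2, size=10)
    x_controls = rng.lognormal(np.log(5), 0.2, size=12)
    X = np.concatenate([x_cases, x_controls])[:, None]
    y = np.array([True] * 10 + [False] * 12)
    return X, y
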
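"""Shared fixtures: small phantom cohorts reused across the suite."""

import warnings

import numpy as np
import pytest

from lobescore.phantom import PhantomConfig, generate_cohort

warnings.filterwarnings("ignore", message="rescale_unit")


TEST_GRID = (32, 32, 32)


def small_config(**overrides) -> PhantomConfig:
    """Desk-scale phantom settings shared by most tests."""
    kwargs = dict(
        n_patients=5,
        exams_per_patient=(1, 2),
        grid_shape=TEST_GRID,
        seed=42,
    )
    kwargs.update(overrides)
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """Five-patient cohort on a 32^3 grid with default degradations."""
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def clean_exam():
    """One artefact-free examination (no bias, no noise, no pathology)."""
    from lobescore._tables import default_score_marginals
    from lobescore.phantom import generate_examination

    marginals = default_score_marginals()
    for p in marginals:
        marginals[p] = np.tile([1.0, 0.0, 0.0], (6, 1))
    cfg = small_config(
        bias_field_amplitude=0.0, noise_sigma=0.0,
        score_marginals=marginals, seed=7,
    )
    rng = np.random.default_rng(7)
    return generate_examination(cfg, "P000", "P000_E00", rng), cfg


@pytest.fixture(scope="session")
def midsize_cohort():
    """~50-exam cohort used by distribution-level checks."""
    return generate_cohort(
        small_config(n_patients=22, exams_per_patient=(1, 4), seed=1234)
    )
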
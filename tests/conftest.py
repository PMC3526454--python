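from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from probelint.synthetic import UniverseConfig, simulate_probe_universe

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def universe_ten():
    """Seeded universe with ten planted defects per filter category."""
    cfg = UniverseConfig(
        n_clean=20,
        n_cross_hyb=10,
        n_loss_of_target=10,
        n_snp=10,
        n_poly_g=10,
        n_delta_g=10,
        n_repeat=10,
        n_background=10,
        genome_length=32_000,
    )
    return simulate_probe_universe(cfg, seed=42)


@pytest.fixture(scope="session")
def universe_small():
    """Small universe for IO/CLI plumbing tests."""
    cfg = UniverseConfig(
        n_clean=8,
        n_cross_hyb=2,
        n_loss_of_target=2,
        n_snp=2,
        n_poly_g=2,
        n_delta_g=2,
        n_repeat=2,
        n_background=3,
        genome_length=9_000,
    )
    return simulate_probe_universe(cfg, seed=7)


def make_matrix(values, classes, probe_ids=None):
    """Convenience IntensityMatrix builder for hand-constructed tests."""
    from probelint.measurement_qc import IntensityMatrix

    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"p{i:03d}" for i in range(n_probes)]
    samples = [f"s{i:02d}" for i in range(n_samples)]
    return IntensityMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=samples),
        class_of=pd.Series(classes, index=samples),
    )
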
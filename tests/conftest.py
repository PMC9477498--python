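"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from netstage import SimConfig, generate_cohort

#: Two planted networks on a 16^3 grid at 4 mm (one bilateral, one midline);
#: loci lie on voxel centers (-30 + 4k mm) so tests can address exact voxels.
TWO_NET_LOCI = {
    "NETA": [(-18.0, -2.0, -2.0), (18.0, -2.0, -2.0)],
    "NETB": [(2.0, 18.0, 10.0)],
}


def two_net_config(**overrides) -> SimConfig:
    base = dict(
        n_per_cell=5,
        grid_dims=(16, 16, 16),
        voxel_size_mm=4.0,
        pattern_loci={k: list(v) for k, v in TWO_NET_LOCI.items()},
        site_sd=0.0,
        bin_size=5,
        beta_truth={},
        rng_seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """45-subject cohort with two planted networks (fast, image-level tests)."""
    return generate_cohort(two_net_config())


@pytest.fixture(scope="session")
def large_cohort():
    """405-subject cohort for statistical recovery checks."""
    return generate_cohort(two_net_config(n_per_cell=45, rng_seed=21))


def gaussian_amplitude(coords_mm: np.ndarray, loci, sigma: float) -> np.ndarray:
    """Planted-pattern amplitude at given mm coordinates (test-side oracle)."""
    coords_mm = np.atleast_2d(coords_mm)
    amp = np.zeros(coords_mm.shape[0])
    for locus in loci:
        d2 = np.sum((coords_mm - np.asarray(locus, float)) ** 2, axis=1)
        amp += np.exp(-d2 / (2.0 * sigma**2))
    return amp
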
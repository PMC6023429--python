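"""Shared fixtures: geometry, small synthetic datasets, and one
high-contrast diagnosis run reused by several end-to-end checks."""

from __future__ import annotations

import numpy as np
import pytest

import mwdiag as m


@pytest.fixture(scope="session")
def ring12() -> m.RingArray:
    return m.build_ring(12, 70.0)


@pytest.fixture(scope="session")
def channels12(ring12) -> list[m.Channel]:
    return m.enumerate_channels(ring12)


@pytest.fixture(scope="session")
def tiny_scanset() -> m.ScanSet:
    """Small but fully featured dataset: 8 tumours x 2 positions, 16 scans."""
    return m.generate_dataset(
        m.DesignSpec(n_breasts=1, n_tumours=8, n_positions=2),
        glandular_fractions=(0.05,),
        seed=7,
        n_samples=2560,
    )


@pytest.fixture(scope="session")
def contrast_run():
    """High-contrast diagnosis run: 1 breast (5% glandular), 24 tumours x 5
    positions, noise sigma 0.05, seed 1; EAC 0-30 deg with all-channel
    antenna grouping under 5-fold scan-level nested CV.

    The record length and the inner search budget are scaled down to keep
    the suite fast; neither changes the scan/channel counts or the stated
    generator conditions.
    """
    config = m.RunConfig(
        mode="TW+FE",
        model="EAC",
        angle=30.0,
        w=None,
        k=5,
        seed=1,
        budget=6,
        search_space={
            "n_trees": (50, 200),
            "n_features_per_split": (1, 30),
            "min_leaf_size": (1, 20),
        },
        n_breasts=1,
        n_tumours=24,
        n_positions=5,
        glandular_fractions=(0.05,),
        noise_sigma=0.05,
        n_samples=2560,
    )
    return m.run_pipeline(config)


@pytest.fixture(scope="session")
def permutation_base():
    """Observation table + rankings for the permutation-null and related
    checks: 12 tumours x 5 positions at 5% glandular fraction."""
    scanset = m.generate_dataset(
        m.DesignSpec(n_breasts=1, n_tumours=12, n_positions=5),
        glandular_fractions=(0.05,),
        seed=3,
        n_samples=2560,
    )
    table = m.build_observation_table(scanset, "TW+FE")
    rankings = m.scan_rankings(scanset)
    return scanset, table, rankings


def rng_signature(seed: int, n: int = 60) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.normal(size=n)
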
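"""Shared fixtures: small seeded communities, generated at test time."""

from __future__ import annotations

import pytest

from stravir.synthetic_community import (CommunityConfig, SubstrainSpec,
                                         simulate_community)


def small_config(seed: int = 11, **overrides) -> CommunityConfig:
    """A fast community: 4 bacteria, 2 lytic phages, 1 prophage, 6 samples."""
    kw = dict(
        n_bacteria=4, n_lytic_phages=2, n_prophages=1,
        contig_length_range=(18_000, 24_000),
        phage_length_range=(9_000, 14_000),
        prophage_length_range=(6_000, 7_000),
        n_samples=6, n_ap=3, n_rp=3,
        depth=6_000, read_length=100,
        error_rate=0.0, unmapped_fraction=0.0,
        substrain_spec=SubstrainSpec(n_substrains=4, window_length=60),
        seed=seed,
    )
    kw.update(overrides)
    return CommunityConfig(**kw)


def phage_rich_config(seed: int = 1, depth: int = 40_000, **overrides):
    """One bacterium + one deeply covered phage: for substrain-path tests."""
    kw = dict(
        n_bacteria=1, n_lytic_phages=1, n_prophages=0,
        contig_length_range=(15_000, 18_000),
        phage_length_range=(12_000, 12_000),
        n_samples=2, n_ap=1, n_rp=1,
        depth=depth, read_length=100,
        error_rate=0.0, unmapped_fraction=0.0,
        class_weights={"bacteria": 1.0, "lytic_phage": 1.0},
        substrain_spec=SubstrainSpec(n_substrains=4, window_length=60),
        seed=seed,
    )
    kw.update(overrides)
    return CommunityConfig(**kw)


@pytest.fixture(scope="session")
def small_sim():
    """One fully simulated small community, shared read-only across tests."""
    return simulate_community(small_config())


@pytest.fixture()
def tmp_sam_dir(small_sim, tmp_path):
    d = tmp_path / "sam"
    d.mkdir()
    for sample, text in small_sim.sam_texts.items():
        (d / f"{sample}.sam").write_text(text)
    return d
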
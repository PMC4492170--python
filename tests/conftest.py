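"""Shared fixtures: tiny hand-built tracks and a session-scoped synthetic
bundle small enough to regenerate in seconds."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import methylex as mx


def make_track(rows, genome=None):
    """Build a MethylationTrack from (chrom, pos0, strand, context, m, u) tuples."""
    df = pd.DataFrame(rows, columns=["chromosome", "position", "strand",
                                     "context", "count_methylated",
                                     "count_unmethylated"])
    return mx.MethylationTrack(df, genome=genome)


@pytest.fixture(scope="session")
def bundle():
    """A 200-gene full bundle (genome, genes, repeats, cytosines, truth)."""
    cfg = mx.SyntheticConfig(seed=11, n_genes=200, n_chromosomes=2)
    return mx.generate_bundle(cfg)


@pytest.fixture(scope="session")
def bundle_track(bundle):
    return mx.MethylationTrack(bundle.cytosines, genome=bundle.genome)


@pytest.fixture(scope="session")
def bundle_regions(bundle, bundle_track):
    return mx.region_methylation(bundle_track, bundle.genes,
                                 expression=bundle.expression)


@pytest.fixture(scope="session")
def cohort5000():
    """Gene-level cohort at the default 5,000-gene size, noise calibrated to
    a 0.20 signal fraction."""
    cfg = mx.SyntheticConfig(seed=1, residual_sd=None)
    table, truth = mx.simulate_regions(cfg)
    return cfg, table, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20250927)
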
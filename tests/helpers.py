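"""Shared builders for harmonized sets used across the test modules."""

import numpy as np

from mrscreen import HarmonizedSet, SimulationConfig, harmonize_pair, simulate_summary_pair


def make_hset(bx, sx, by, sy, ids=None):
    """Build a HarmonizedSet directly from effect arrays."""
    bx = np.asarray(bx, dtype=float)
    ids = ids or [f"rs{i + 1}" for i in range(bx.size)]
    return HarmonizedSet(variant_ids=ids, beta_exposure=bx, se_exposure=sx,
                         beta_outcome=by, se_outcome=sy)


def sim_hset(**kwargs):
    """Simulate a summary pair and harmonize it; returns (hset, truth).

    With the default prop_palindromic=0 every simulated SNP survives, so
    the harmonized arrays line up index-for-index with the truth arrays.
    """
    config = SimulationConfig(**kwargs)
    exposure, outcome, truth = simulate_summary_pair(config)
    return harmonize_pair(exposure, outcome), truth
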
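"""Shared fixtures: the standard synthetic experiments, computed once."""

import numpy as np
import pytest

from loopshift.hic_loops import call_loops, oe_normalize, smooth_impute
from loopshift.synthetic_data import (
    default_frag_params,
    default_hic_params,
    simulate_fragment_experiment,
    simulate_hic_experiment,
)

CANONICAL_SEED = 0


@pytest.fixture(scope="session")
def std_hic():
    """Standard planted-loop Hi-C experiment: (params, maps, truth)."""
    params = default_hic_params(seed=CANONICAL_SEED)
    maps, truth = simulate_hic_experiment(params)
    return params, maps, truth


@pytest.fixture(scope="session")
def std_hic_processed(std_hic):
    """Smoothed O/E maps and per-sample loop calls for the standard run."""
    _, maps, _ = std_hic
    smoothed, calls = {}, {}
    for (cond, rep, _chrom), cmap in maps.items():
        sm = smooth_impute(oe_normalize(cmap))
        smoothed[(cond, rep)] = sm
        calls[(cond, rep)] = call_loops(sm, obs_map=cmap)
    return smoothed, calls


@pytest.fixture(scope="session")
def std_frags():
    """Standard fragment experiment: (params, samples, truth)."""
    params = default_frag_params(seed=CANONICAL_SEED)
    samples, truth = simulate_fragment_experiment(params)
    return params, samples, truth
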
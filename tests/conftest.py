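import numpy as np
import pytest

from wishnet.index import (SelectionIndexSpec, index_coefficients, obesity_index)
from wishnet.simdata import (INDEX_TRAITS, DEFAULT_WEIGHTS, QtlCluster,
                             SimConfig, simulate_cross)


def toy_config(seed=0, **overrides):
    """Small cohort used by the fast unit tests: 5 chromosomes x 200 markers
    with scaled-down planted clusters (same effect sizes as the default)."""
    direction = {"DXApctfat": 0.70, "SLfat_om": 0.67, "DXAfat": 0.39,
                 "ADG": 0.30, "WT7m": 0.12}
    clusters = (
        QtlCluster(name="oi_qtl", chrom="1", start_cm=20.0, n_markers=40,
                   line_a_freq=1.0, line_b_freq=0.0, n_causal=8,
                   effects={t: 0.8 * w for t, w in direction.items()}),
        QtlCluster(name="dw_qtl", chrom="3", start_cm=40.0, n_markers=16,
                   line_a_freq=0.3, line_b_freq=0.0, n_causal=8,
                   effects={t: 2.4 * w for t, w in direction.items()}),
    )
    kw = dict(n_founders_per_line=8, n_f1=30, n_f2=200, n_chromosomes=5,
              markers_per_chrom=200, chrom_length_cm=100.0,
              clusters=clusters, seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_cross(toy_config(seed=7))


def default_index_spec(trait_spec):
    names = list(trait_spec.names)
    sel = [names.index(t) for t in INDEX_TRAITS]
    return SelectionIndexSpec(
        tuple(INDEX_TRAITS), trait_spec.P[np.ix_(sel, sel)],
        trait_spec.G[np.ix_(sel, sel)],
        np.array([DEFAULT_WEIGHTS[t] for t in INDEX_TRAITS]))


def compute_oi(sim):
    coef = index_coefficients(default_index_spec(sim.config.traits))
    oi, _ = obesity_index(coef, sim.traits)
    return coef, oi


@pytest.fixture(scope="session")
def small_oi(small_sim):
    return compute_oi(small_sim)[1]
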
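"""Shared fixtures: tiny deterministic maps and a small simulated study.

Everything is generated programmatically and seeded, so the suite is
reproducible and carries no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from polyqtl import (
    GeneticMap,
    PhasedPopulation,
    QTLSpec,
    assign_effects,
    build_nam,
    phenotype,
    simulate_ag_pool,
    synthetic_map,
)
from polyqtl.phenotype import PhenotypeParams


@pytest.fixture
def tiny_map() -> GeneticMap:
    """Two chromosomes, a handful of hand-placed markers."""
    return GeneticMap(
        names=[f"m{i}" for i in range(1, 8)],
        chromosomes=["1", "1", "1", "1", "2", "2", "2"],
        positions=[0.0, 10.0, 13.5, 20.0, 0.0, 5.0, 9.0],
    )


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    """One 110 cM chromosome at reduced density (for meiosis statistics)."""
    return synthetic_map(n_chromosomes=1, n_markers=200, rng=np.random.default_rng(11))


@pytest.fixture(scope="session")
def study():
    """A small but structurally complete study: map, AG pool, NAM, phenotype.

    One 110 cM chromosome at ~3.6 markers/cM, 10 AGs of 10 founders drifted
    10 generations at size 40, a NAM3 with 10 offspring per cross
    (100 individuals). Shared across tests that need realistic structure.
    """
    gmap = synthetic_map(n_chromosomes=1, n_markers=400, rng=np.random.default_rng(5))
    rng = np.random.default_rng(42)
    ags = simulate_ag_pool(gmap, n_ags=10, n_founders=10, generations=10, size=40, rng=rng)
    nam = build_nam(ags, diversity_k=3, offspring_per_cross=10, rng=rng)
    qtls = QTLSpec(major_qtls=(("1", 67.88),), n_polygenic=10)
    effects = assign_effects(nam, qtls, rng=rng)
    trait = phenotype(nam, effects, rng=rng)
    return {
        "gmap": gmap,
        "ags": ags,
        "nam": nam,
        "qtls": qtls,
        "effects": effects,
        "trait": trait,
    }


@pytest.fixture
def handmade_pop(tiny_map) -> PhasedPopulation:
    """Three tetraploid individuals with hand-written states and labels."""
    # individual 0: labels (1,1,7,9) everywhere; snp states vary per marker
    snp = np.zeros((3, 4, 7), dtype=np.uint8)
    labels = np.zeros((3, 4, 7), dtype=np.int32)
    labels[0] = np.array([1, 1, 7, 9])[:, None]
    labels[1] = np.array([2, 3, 7, 7])[:, None]
    labels[2] = np.array([9, 9, 9, 1])[:, None]
    snp[0, :, :] = np.array([[0, 0, 1, 1]] * 7).T  # dosage 2 everywhere
    snp[1, :, :] = 1  # dosage 4
    # individual 2 stays dosage 0
    return PhasedPopulation(snp, labels, ["i0", "i1", "i2"], tiny_map)
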
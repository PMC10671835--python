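"""Shared fixtures: the standard simulated scene, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest

from pannumt.align import find_numts
from pannumt.panmito import (MitoRecord, assemble_panmito, dedup_exact,
                             filter_full_length)
from pannumt.simulate import (SimConfig, plant_numts, root_mitogenome,
                              simulate_control_fragments, simulate_population)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def std_config() -> SimConfig:
    """The standard benchmark scene: 2 Mb background, 50 planted NUMTs."""
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def std_scene(std_config):
    """(population, control fragments, truth set, assembled pool)."""
    pop = simulate_population(std_config)
    ctrl = simulate_control_fragments(pop, std_config)
    truthset = plant_numts(std_config)
    full, _ = dedup_exact(pop)
    full = filter_full_length(full)
    ref = MitoRecord(id="sim_ref", sequence=root_mitogenome(std_config),
                     kind="reference")
    pool = assemble_panmito(full, ctrl, ref, pad=100)
    return pop, ctrl, truthset, pool


@pytest.fixture(scope="session")
def std_results(std_scene):
    """(merged NUMT intervals, filtered hits) of the standard scene."""
    _, _, truthset, pool = std_scene
    numts, hits = find_numts(pool, truthset.genome)
    return numts, hits
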
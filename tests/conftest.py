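import numpy as np
import pandas as pd
import pytest

from lethalscan import LethalSpec, PhasedGenotypes, SimulationConfig
from lethalscan.simulate import simulate_marker_map, simulate_population


def small_config(seed=0, **overrides):
    """A fast, small population: 1 chromosome, 60 markers, ~800 progeny."""
    base = dict(
        n_sires=20, n_mgs=20, n_dams=200,
        n_chromosomes=1, markers_per_chromosome=60,
        chromosome_length_bp=3_600_000,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def lethal_population():
    """Small population with one fully penetrant lethal at f = 0.10."""
    config = small_config(
        seed=11,
        lethal_specs=[LethalSpec(window_start_marker=20, target_frequency=0.10)],
    )
    marker_map = simulate_marker_map(config)
    pedigree, phased, truth = simulate_population(marker_map, config)
    return config, marker_map, pedigree, phased, truth


@pytest.fixture(scope="session")
def null_population():
    """Small population with no lethal haplotype."""
    config = small_config(seed=7)
    marker_map = simulate_marker_map(config)
    pedigree, phased, truth = simulate_population(marker_map, config)
    return config, marker_map, pedigree, phased, truth


def phased_from_strings(pairs):
    """Build PhasedGenotypes from [(id, paternal_str, maternal_str), ...]."""
    ids = np.array([p[0] for p in pairs], dtype=object)
    haps = np.array(
        [[[int(c) for c in p[1]], [int(c) for c in p[2]]] for p in pairs],
        dtype=np.uint8,
    )
    return PhasedGenotypes(ids, haps)


def trivial_map(n_markers, chromosome=1, spacing=60_000):
    return pd.DataFrame(
        {
            "marker_id": [f"m{i}" for i in range(n_markers)],
            "chromosome": chromosome,
            "position_bp": [1 + i * spacing for i in range(n_markers)],
            "allele_a": "1",
            "allele_b": "2",
        }
    )
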
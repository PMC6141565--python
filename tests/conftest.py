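import numpy as np
import pytest

from bgfx import simcross
from bgfx.scanengine import ScanData


@pytest.fixture(scope="session")
def small_map() -> simcross.MarkerMap:
    return simcross.MarkerMap.uniform(
        n_chromosomes=4, markers_per_chromosome=6, recomb=0.15
    )


@pytest.fixture(scope="session")
def two_bg_pop(small_map) -> simcross.CrossPopulation:
    """WT + one knockout, one strong planted responsive one-locus effect."""
    cfg = simcross.SimConfig(
        n_per_background=150,
        background_labels=("WT", "hos3"),
        noise_sd=0.25,
        seed=42,
        planted_effects=[
            simcross.PlantedEffect(
                loci=("chr02_m003",), responsive=True,
                target_background="hos3", absolute_effect_size=0.8,
            )
        ],
    )
    return simcross.simulate_cross(cfg, small_map)


@pytest.fixture(scope="session")
def two_bg_data(two_bg_pop) -> ScanData:
    return ScanData.from_population(two_bg_pop)


def balanced_design(n_loci: int, reps: int = 10):
    """Fully balanced bg x genotype-class design over WT and one knockout.

    Returns (genotypes, backgrounds, marker_map) with every joint class
    equally represented in both backgrounds — the orthogonal construction
    used to pin variance-partition shares exactly.
    """
    classes = np.array(
        [[(i >> b) & 1 for b in range(n_loci)] for i in range(2 ** n_loci)]
    )
    G = np.tile(np.repeat(classes, reps, axis=0), (2, 1))
    n_half = classes.shape[0] * reps
    bg = np.array(["WT"] * n_half + ["hos3"] * n_half, dtype=object)
    mm = simcross.MarkerMap.uniform(
        n_chromosomes=1, markers_per_chromosome=n_loci, recomb=0.5
    )
    return G.astype(np.int8), bg, mm
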
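"""Synthetic BY x 3S cross populations with planted genetic effects.

The real study crossed two yeast strains, knocked out seven chromatin
regulators, and phenotyped ~1411 haploid segregants across wild-type and
knockout backgrounds in 10 environments.  This module generates populations
with that statistical structure: haploid recombinant genotypes over a marker
map (per-chromosome 2-state Markov chains, no crossover interference),
background labels, and phenotypes built as

    background mean shift
    + planted genotype-class increments  (restricted to one background for
      mutation-responsive effects, applied to every background for
      mutation-independent ones)
    + Gaussian noise.

A planted k-locus effect raises exactly one of the 2^k joint genotype
classes by a fixed increment (the absolute effect size), so with balanced
alleles roughly 2^-k of the targeted individuals are shifted.  Truth records
travel with the data so detection scoring never re-derives them.

It also simulates noisy per-SNP allele-fraction observations (Poisson
coverage, binomial miscalls) so the genotype-calling stages can be exercised
end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genocall import AlleleFractionTable

#: background labels of the study: wild type first, then the seven knockouts
STUDY_BACKGROUNDS = (
    "WT", "ctk1", "esa1", "gcn5", "hos3", "htb1", "ino80", "rpd3",
)
#: segregant counts per background in the study's mapping panel (sums to 1411)
STUDY_BACKGROUND_COUNTS = {
    "WT": 164, "ctk1": 210, "esa1": 122, "gcn5": 215,
    "hos3": 220, "htb1": 177, "ino80": 141, "rpd3": 162,
}


@dataclass
class MarkerMap:
    """Genetic map: markers ordered along chromosomes with inter-marker
    recombination fractions.

    ``table`` columns: marker_id, chrom, pos_bp, recomb_to_next (probability
    of a recombination event between a marker and the next one on the same
    chromosome; NaN for each chromosome's last marker).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"marker_id", "chrom", "pos_bp", "recomb_to_next"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"marker map needs columns {sorted(req)}")
        if len(self.table) == 0:
            raise ValueError("marker map is empty")
        self.table = self.table.reset_index(drop=True)
        for chrom, grp in self.table.groupby("chrom", sort=False):
            pos = grp["pos_bp"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            r = grp["recomb_to_next"].to_numpy(dtype=float)[:-1]
            if np.any((r < 0) | (r > 0.5)) or np.any(np.isnan(r)):
                raise ValueError(
                    f"recomb probabilities on {chrom} must lie in [0, 0.5]"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    def marker_index(self, marker_id: str) -> int:
        idx = np.flatnonzero(self.marker_ids == marker_id)
        if idx.size == 0:
            raise KeyError(f"marker {marker_id!r} not in map")
        return int(idx[0])

    @classmethod
    def uniform(
        cls,
        n_chromosomes: int = 16,
        markers_per_chromosome: int = 20,
        recomb: float = 0.1,
        spacing_bp: int = 40_000,
    ) -> "MarkerMap":
        """Uniform map mirroring the 16-chromosome S. cerevisiae karyotype."""
        rows = []
        for c in range(1, n_chromosomes + 1):
            for i in range(markers_per_chromosome):
                r = recomb if i < markers_per_chromosome - 1 else np.nan
                rows.append((f"chr{c:02d}_m{i + 1:03d}", f"chr{c:02d}",
                             (i + 1) * spacing_bp, r))
        return cls(pd.DataFrame(
            rows, columns=["marker_id", "chrom", "pos_bp", "recomb_to_next"]
        ))


@dataclass
class PlantedEffect:
    """One planted 1-3-locus genetic effect.

    ``incremented_class`` names the single joint genotype class (tuple of
    0/1 alleles, one per locus, 0 = BY) whose members receive the increment.
    Responsive effects apply only within ``target_background``; independent
    effects apply across all backgrounds.
    """

    loci: tuple[str, ...]
    responsive: bool
    absolute_effect_size: float
    incremented_class: tuple[int, ...] = None  # default: all-3S class
    target_background: str | None = None
    environment: str | None = None  # default: first configured environment

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)
        if not 1 <= len(self.loci) <= 3:
            raise ValueError("an effect involves 1-3 loci")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("planted loci must be distinct")
        if self.incremented_class is None:
            self.incremented_class = (1,) * len(self.loci)
        self.incremented_class = tuple(int(a) for a in self.incremented_class)
        if len(self.incremented_class) != len(self.loci):
            raise ValueError("incremented_class must give one allele per locus")
        if any(a not in (0, 1) for a in self.incremented_class):
            raise ValueError("incremented_class alleles must be 0 (BY) or 1 (3S)")
        if self.responsive and self.target_background is None:
            raise ValueError("responsive effects need a target_background")

    @property
    def order(self) -> int:
        return len(self.loci)


@dataclass
class SimConfig:
    """Full specification of a synthetic cross."""

    n_per_background: int = 100
    background_labels: tuple[str, ...] = STUDY_BACKGROUNDS
    background_mean_shift: dict = field(default_factory=dict)
    noise_sd: float = 0.25
    seed: int = 0
    planted_effects: list = field(default_factory=list)
    environments: tuple[str, ...] = ("ypd_30c",)

    def __post_init__(self) -> None:
        self.background_labels = tuple(self.background_labels)
        if len(self.background_labels) < 2:
            raise ValueError("need at least 2 background labels (first = WT)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.environments = tuple(self.environments)
        for eff in self.planted_effects:
            if eff.environment is None:
                eff.environment = self.environments[0]
            if eff.environment not in self.environments:
                raise ValueError(f"unknown environment {eff.environment!r}")
            if eff.responsive and eff.target_background not in self.background_labels:
                raise ValueError(
                    f"unknown target background {eff.target_background!r}"
                )
        unknown = set(self.background_mean_shift) - set(self.background_labels)
        if unknown:
            raise ValueError(f"mean shifts for unknown backgrounds {unknown}")

    @property
    def wild_type(self) -> str:
        return self.background_labels[0]


@dataclass
class CrossPopulation:
    """A simulated cross: genotypes, background labels, phenotypes, truth."""

    marker_map: MarkerMap
    genotypes: np.ndarray  # (n, M) int8 over {0 = BY, 1 = 3S}
    backgrounds: np.ndarray  # (n,) labels
    segregant_ids: np.ndarray
    phenotypes: pd.DataFrame  # index segregant_id, one column per environment
    truth: list
    config: SimConfig

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def phenotype_vector(self, environment: str) -> np.ndarray:
        return self.phenotypes[environment].to_numpy()

    def truth_json(self) -> str:
        return json.dumps([asdict(e) for e in self.truth], indent=2, default=str)


def simulate_genotypes(
    marker_map: MarkerMap, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Simulate n haploid recombinant genotypes over the map.

    Each chromosome is an independent 2-state Markov chain over {BY, 3S}:
    the first marker is Bernoulli(0.5) and each inter-marker interval
    switches parental origin with its recomb_to_next probability (no
    interference).  Returns an (n, M) int8 matrix.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = len(marker_map)
    out = np.empty((n, M), dtype=np.int8)
    for _, grp in marker_map.table.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        r = grp["recomb_to_next"].to_numpy(dtype=float)[:-1]
        first = rng.random(n) < 0.5
        switches = rng.random((n, idx.size - 1)) < r[None, :] if idx.size > 1 else \
            np.empty((n, 0), dtype=bool)
        # cumulative XOR of switch events onto the starting allele
        flips = np.concatenate(
            [first[:, None], switches], axis=1
        ).cumsum(axis=1) % 2
        out[:, idx] = flips.astype(np.int8)
    return out


def _class_members(
    genotypes: np.ndarray, marker_map: MarkerMap, effect: PlantedEffect
) -> np.ndarray:
    cols = [marker_map.marker_index(m) for m in effect.loci]
    member = np.ones(genotypes.shape[0], dtype=bool)
    for c, allele in zip(cols, effect.incremented_class):
        member &= genotypes[:, c] == allele
    return member


def plant_phenotypes(
    genotypes: np.ndarray,
    backgrounds: np.ndarray,
    marker_map: MarkerMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Build phenotypes from background shifts, planted effects, and noise.

    Returns a frame with one column per configured environment.  For a
    k-locus effect only segregants in the single incremented joint genotype
    class receive the increment — about half, one quarter, one eighth of the
    targeted individuals for k = 1, 2, 3 with balanced alleles.
    """
    n = genotypes.shape[0]
    backgrounds = np.asarray(backgrounds)
    unknown = set(backgrounds) - set(config.background_labels)
    if unknown:
        raise ValueError(f"unknown background labels {unknown}")
    shift = np.array(
        [config.background_mean_shift.get(b, 0.0) for b in backgrounds]
    )
    out = {}
    for env in config.environments:
        y = shift.copy()
        for eff in config.planted_effects:
            if eff.environment != env:
                continue
            member = _class_members(genotypes, marker_map, eff)
            if eff.responsive:
                member &= backgrounds == eff.target_background
            y = y + eff.absolute_effect_size * member
        out[env] = y + rng.normal(0.0, config.noise_sd, size=n)
    return pd.DataFrame(out)


def simulate_cross(
    config: SimConfig, marker_map: MarkerMap | None = None
) -> CrossPopulation:
    """Simulate a full cross population from a SimConfig.

    Fully reproducible: identical config + map give identical output.
    """
    marker_map = marker_map or MarkerMap.uniform()
    rng = np.random.default_rng(config.seed)
    n_bg = len(config.background_labels)
    n = config.n_per_background * n_bg
    genotypes = simulate_genotypes(marker_map, n, rng)
    backgrounds = np.repeat(
        np.asarray(config.background_labels, dtype=object), config.n_per_background
    )
    pheno = plant_phenotypes(genotypes, backgrounds, marker_map, config, rng)
    seg_ids = np.array([f"seg{i:05d}" for i in range(n)])
    pheno.index = pd.Index(seg_ids, name="segregant_id")
    return CrossPopulation(
        marker_map=marker_map,
        genotypes=genotypes,
        backgrounds=backgrounds,
        segregant_ids=seg_ids,
        phenotypes=pheno,
        truth=list(config.planted_effects),
        config=config,
    )


def simulate_allele_fractions(
    genotypes: np.ndarray,
    mean_coverage: float,
    error_rate: float,
    seed: int | np.random.Generator,
    segregant_ids: np.ndarray | None = None,
    snp_ids: np.ndarray | None = None,
) -> AlleleFractionTable:
    """Simulate noisy 3S allele-fraction observations from true genotypes.

    Per site: coverage ~ Poisson(mean_coverage); the 3S-supporting read
    count is Binomial(coverage, 1 - error_rate) at true 3S sites and
    Binomial(coverage, error_rate) at true BY sites; the reported fraction
    is count / coverage, missing where coverage is 0.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genotypes = np.atleast_2d(genotypes)
    n, m = genotypes.shape
    coverage = rng.poisson(mean_coverage, size=(n, m))
    p_3s = np.where(genotypes == 1, 1.0 - error_rate, error_rate)
    count = rng.binomial(coverage, p_3s)
    with np.errstate(divide="ignore", invalid="ignore"):
        fractions = np.where(coverage > 0, count / np.maximum(coverage, 1), np.nan)
    if segregant_ids is None:
        segregant_ids = np.array([f"seg{i:05d}" for i in range(n)])
    if snp_ids is None:
        snp_ids = np.array([f"snp{j:05d}" for j in range(m)])
    return AlleleFractionTable(segregant_ids, snp_ids, fractions, coverage)


def knockout_shift_preset(scale: float = 0.1) -> dict:
    """Demo background mean-shift profile of knockout-effect magnitude.

    The study's power simulations drew knockout effects from observed growth
    in glucose; absent those measurements we provide alternating shifts of a
    configurable magnitude around the wild type.
    """
    return {
        b: ((-1) ** i) * scale * (1 + i / len(STUDY_BACKGROUNDS))
        for i, b in enumerate(STUDY_BACKGROUNDS[1:], start=1)
    }
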
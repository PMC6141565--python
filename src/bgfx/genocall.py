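"""Genotype calling from per-SNP 3S allele fractions.

Segregants of the BY x 3S cross are sequenced at low coverage, so raw
per-site calls (fraction of reads supporting the 3S allele) are noisy and
occasionally missing.  The pipeline here is: threshold the fractions into
initial BY/3S calls, correct each chromosome's call vector with a 2-state
hidden Markov model whose maximum-probability path is taken as the corrected
genotype, remove segregants failing coverage or heterozygosity QC, and
collapse adjacent markers that never recombine in the panel down to a single
representative.

Alleles are coded 0 = BY, 1 = 3S throughout; -1 marks a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BY, S3, MISSING = 0, 1, -1


@dataclass
class HmmParams:
    """Two-state genotype-correction HMM.

    stay/switch are the per-interval transition probabilities between hidden
    BY/3S states; emission_fidelity is P(observed call == hidden state).
    Missing observations emit likelihood 1 under both states, i.e. they
    contribute no evidence and are imputed from their neighbors.
    """

    stay: float = 0.9999
    switch: float = 0.0001
    emission_fidelity: float = 0.75
    initial: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not np.isclose(self.stay + self.switch, 1.0):
            raise ValueError("stay + switch must sum to 1")
        for v in (self.stay, self.switch, self.emission_fidelity, *self.initial):
            if not 0.0 < v < 1.0:
                raise ValueError("all HMM probabilities must lie in (0, 1)")
        if not np.isclose(sum(self.initial), 1.0):
            raise ValueError("initial state probabilities must sum to 1")

    @property
    def transition_matrix(self) -> np.ndarray:
        return np.array([[self.stay, self.switch], [self.switch, self.stay]])

    @property
    def emission_matrix(self) -> np.ndarray:
        e = self.emission_fidelity
        return np.array([[e, 1 - e], [1 - e, e]])


@dataclass
class AlleleFractionTable:
    """Segregant x SNP table of 3S allele fractions and read coverage.

    ``fractions`` is (n_segregants, n_snps) with NaN wherever coverage is 0;
    the invariant "fraction missing iff coverage == 0" is enforced on
    construction.
    """

    segregant_ids: np.ndarray
    snp_ids: np.ndarray
    fractions: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.segregant_ids = np.asarray(self.segregant_ids)
        self.snp_ids = np.asarray(self.snp_ids)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.coverage = np.asarray(self.coverage)
        if self.fractions.shape != (len(self.segregant_ids), len(self.snp_ids)):
            raise ValueError("fractions shape does not match ids")
        if self.coverage.shape != self.fractions.shape:
            raise ValueError("coverage shape does not match fractions")
        zero = self.coverage == 0
        if not np.array_equal(zero, np.isnan(self.fractions)):
            raise ValueError("fraction must be missing exactly where coverage is 0")

    def to_frame(self) -> pd.DataFrame:
        """Long-format export (segregant_id, snp_id, fraction_3S, coverage)."""
        n, m = self.fractions.shape
        return pd.DataFrame(
            {
                "segregant_id": np.repeat(self.segregant_ids, m),
                "snp_id": np.tile(self.snp_ids, n),
                "fraction_3S": self.fractions.ravel(),
                "coverage": self.coverage.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleFractionTable":
        wide_f = df.pivot(index="segregant_id", columns="snp_id", values="fraction_3S")
        wide_c = df.pivot(index="segregant_id", columns="snp_id", values="coverage")
        # preserve first-appearance order of snps and segregants
        seg_order = df["segregant_id"].drop_duplicates().to_numpy()
        snp_order = df["snp_id"].drop_duplicates().to_numpy()
        wide_f = wide_f.loc[seg_order, snp_order]
        wide_c = wide_c.loc[seg_order, snp_order]
        return cls(
            segregant_ids=seg_order,
            snp_ids=snp_order,
            fractions=wide_f.to_numpy(dtype=float),
            coverage=wide_c.fillna(0).to_numpy(),
        )


def initial_calls(
    fractions: np.ndarray, tie_state: int = BY
) -> np.ndarray:
    """Threshold 3S allele fractions into initial calls.

    Sites with fraction above 0.5 are called 3S and below 0.5 BY; a fraction
    of exactly 0.5 goes to ``tie_state`` (BY by default).  Missing fractions
    (NaN) become -1 and are left for the HMM to impute.
    """
    fractions = np.asarray(fractions, dtype=float)
    calls = np.full(fractions.shape, MISSING, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        calls[fractions > 0.5] = S3
        calls[fractions < 0.5] = BY
        calls[fractions == 0.5] = tie_state
    return calls


def viterbi_path(obs: np.ndarray, params: HmmParams) -> np.ndarray:
    """Maximum-probability hidden-state path for one chromosome's calls.

    ``obs`` contains 0/1 calls with -1 for missing sites.  Log-space dynamic
    program; ties broken toward state 0 (BY) for determinism.
    """
    obs = np.asarray(obs)
    L = obs.size
    if L == 0:
        raise ValueError("chromosome must contain at least one marker")
    log_e = np.log(params.emission_matrix)
    log_t = np.log(params.transition_matrix)
    log_init = np.log(np.asarray(params.initial))

    def emit(o: int) -> np.ndarray:
        if o == MISSING:
            return np.zeros(2)
        return log_e[:, o]

    delta = log_init + emit(obs[0])
    back = np.empty((L, 2), dtype=np.int8)
    for i in range(1, L):
        cand = delta[:, None] + log_t  # cand[prev, cur]
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], [0, 1]] + emit(obs[i])
    path = np.empty(L, dtype=np.int8)
    path[-1] = int(np.argmax(delta))
    for i in range(L - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def hmm_correct(
    calls: np.ndarray,
    chromosomes: np.ndarray,
    params: HmmParams | None = None,
) -> np.ndarray:
    """HMM-correct initial calls, one chromosome at a time.

    ``calls`` is (n_segregants, n_markers) over {0, 1, -1}; ``chromosomes``
    labels each marker column.  Markers must already be ordered by map
    position within each chromosome.  Returns complete 0/1 corrected calls.
    """
    calls = np.atleast_2d(calls)
    params = params or HmmParams()
    chromosomes = np.asarray(chromosomes)
    out = np.empty_like(calls)
    for chrom in pd.unique(chromosomes):
        idx = np.flatnonzero(chromosomes == chrom)
        for s in range(calls.shape[0]):
            out[s, idx] = viterbi_path(calls[s, idx], params)
    return out


def qc_filter(
    table: AlleleFractionTable,
    min_mean_coverage: float = 1.5,
    het_window: tuple[float, float] = (0.2, 0.8),
    max_het_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-segregant QC on coverage and heterozygosity-like signal.

    Segregants whose mean per-site coverage falls below ``min_mean_coverage``
    are removed ("low_coverage").  A haploid segregant's fractions should sit
    near 0 or 1; an excess of intermediate fractions (within ``het_window``
    at covered sites) marks diploid/contaminated individuals
    ("heterozygous_excess").  Returns a frame indexed by segregant_id with
    columns ``keep`` (bool) and ``reason`` ("" when kept).
    """
    mean_cov = np.asarray(table.coverage, dtype=float).mean(axis=1)
    lo, hi = het_window
    with np.errstate(invalid="ignore"):
        inter = (table.fractions > lo) & (table.fractions < hi)
    n_obs = np.maximum((table.coverage > 0).sum(axis=1), 1)
    het_frac = inter.sum(axis=1) / n_obs
    reason = np.where(
        mean_cov < min_mean_coverage,
        "low_coverage",
        np.where(het_frac > max_het_fraction, "heterozygous_excess", ""),
    )
    return pd.DataFrame(
        {"keep": reason == "", "reason": reason, "mean_coverage": mean_cov,
         "het_fraction": het_frac},
        index=pd.Index(table.segregant_ids, name="segregant_id"),
    )


def call_genotypes(
    table: AlleleFractionTable,
    chromosomes: np.ndarray,
    params: HmmParams | None = None,
    tie_state: int = BY,
) -> np.ndarray:
    """Initial threshold calls followed by per-chromosome HMM correction."""
    if np.isnan(table.fractions).all(axis=1).any():
        raise ValueError("segregant with no covered sites; run qc_filter first")
    return hmm_correct(initial_calls(table.fractions, tie_state), chromosomes, params)


def collapse_markers(
    genotypes: np.ndarray, chromosomes: np.ndarray, marker_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Collapse maximal runs of adjacent non-recombining markers.

    Adjacent same-chromosome markers whose call columns are identical across
    every segregant carry no extra linkage information; each maximal such run
    is replaced by its leftmost member.  Returns (reduced genotype matrix,
    kept column indices, block table mapping each representative to its
    member markers).
    """
    genotypes = np.atleast_2d(genotypes)
    chromosomes = np.asarray(chromosomes)
    marker_ids = np.asarray(marker_ids)
    m = genotypes.shape[1]
    if m == 0:
        return genotypes, np.empty(0, dtype=int), pd.DataFrame(
            columns=["representative", "members", "n_members"]
        )
    new_block = np.ones(m, dtype=bool)
    same_chrom = chromosomes[1:] == chromosomes[:-1]
    same_calls = (genotypes[:, 1:] == genotypes[:, :-1]).all(axis=0)
    new_block[1:] = ~(same_chrom & same_calls)
    block_id = np.cumsum(new_block) - 1
    keep = np.flatnonzero(new_block)
    rows = []
    for b, rep in enumerate(keep):
        members = marker_ids[block_id == b]
        rows.append((marker_ids[rep], ";".join(map(str, members)), len(members)))
    block_table = pd.DataFrame(rows, columns=["representative", "members", "n_members"])
    return genotypes[:, keep], keep, block_table
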
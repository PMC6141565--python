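"""Genome scans for mutation-independent and mutation-responsive effects.

All mapping is done with fixed-effects linear models fit jointly to the
wild-type and knockout segregants.  A *background* factor (treatment-coded,
wild type as reference) is always present so that mean growth differences
among backgrounds never load onto locus terms.  Loci are coded BY = 0,
3S = 1.  A locus (or locus combination) is mutation-independent when its
phenotypic effect is shared across backgrounds — the focal term is the plain
locus (interaction) term — and mutation-responsive when its effect differs
in at least one knockout background — the focal term is the interaction of
the background factor with the locus term.

Model term order is fixed (simpler terms first) and significance of the
focal term is a sequential F-test, so variance explained by lower-order
terms can never be attributed to the focal interaction.  Genome-wide
significance comes from permutation: the genotype-phenotype correspondence
is shuffled, the scan re-run, the minimum p-value retained, and the 5%
quantile of the permuted minima used as the threshold.

Scan types:

* one-locus, forward regression: detected loci enter later iterations as
  covariates (in responsive mode with both additive and background
  interaction terms) and the threshold is re-derived at every iteration;
* two-locus: every unique marker pair, with permutations evaluating a
  random subsample of pairs for speed;
* three-locus: anchored on an already-detected pair, scanning every other
  marker; permutation trios take a random cross-chromosome anchor pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._anova import (
    build_term_basis,
    focal_pvalues,
    orthonormal_block,
    sequential_anova,
)
from .simcross import CrossPopulation, MarkerMap

INDEPENDENT = "independent"
RESPONSIVE = "responsive"


# ---------------------------------------------------------------------------
# data container


@dataclass
class ScanData:
    """Genotypes + backgrounds + map, with cached design pieces."""

    genotypes: np.ndarray  # (n, M) over {0, 1}
    backgrounds: np.ndarray  # (n,) labels; reference level listed first
    marker_map: MarkerMap
    background_levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.backgrounds = np.asarray(self.backgrounds, dtype=object)
        if self.background_levels is None:
            seen = list(dict.fromkeys(self.backgrounds))
            self.background_levels = tuple(seen)
        self._G = self.genotypes.astype(float)
        # treatment coding: one dummy per non-reference background
        ref, *others = self.background_levels
        self._bg_dummies = np.column_stack(
            [(self.backgrounds == b).astype(float) for b in others]
        ) if others else np.empty((len(self.backgrounds), 0))
        self._bg_labels = tuple(others)

    @classmethod
    def from_population(cls, pop: CrossPopulation) -> "ScanData":
        return cls(
            pop.genotypes, pop.backgrounds, pop.marker_map,
            background_levels=tuple(pop.config.background_labels),
        )

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def wild_type(self) -> str:
        return self.background_levels[0]

    def locus_column(self, idx: int) -> np.ndarray:
        return self._G[:, idx]

    def marker_index(self, marker_id: str) -> int:
        return self.marker_map.marker_index(marker_id)

    def subset(self, rows: np.ndarray) -> "ScanData":
        levels = tuple(
            b for b in self.background_levels if b in set(self.backgrounds[rows])
        )
        return ScanData(
            self.genotypes[rows], self.backgrounds[rows], self.marker_map,
            background_levels=levels,
        )


# ---------------------------------------------------------------------------
# model construction


@dataclass(frozen=True)
class ScanModelSpec:
    """Which model a scan fits and which term it tests."""

    order: int
    mode: str
    environment: str = ""
    known_loci: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise ValueError("scan order must be 1, 2 or 3")
        if self.mode not in (INDEPENDENT, RESPONSIVE):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def focal_term(self) -> str:
        base = ":".join(f"locus{i + 1}" for i in range(self.order))
        return base if self.mode == INDEPENDENT else f"background:{base}"


def _interact(*cols: np.ndarray) -> np.ndarray:
    out = cols[0]
    for c in cols[1:]:
        out = out * c
    return out


def model_blocks(
    data: ScanData, loci: tuple[str, ...], mode: str,
    known: tuple[str, ...] = (),
) -> tuple[list[tuple[str, np.ndarray]], str]:
    """Ordered term blocks for a detection model, plus the focal term name.

    ``loci`` are the 1-3 candidate loci (named locus1..locusK in the output);
    ``known`` are forward-regression covariates (order-1 scans only).  Term
    order follows the scan models: background, additive terms, lower-order
    interactions, focal term last.
    """
    D = data._bg_dummies
    g = [data.locus_column(data.marker_index(m)) for m in loci]
    k = len(g)
    blocks: list[tuple[str, np.ndarray]] = [("background", D)]
    if k == 1:
        for i, m in enumerate(known):
            blocks.append((f"known_locus{i + 1}",
                           data.locus_column(data.marker_index(m))[:, None]))
        blocks.append(("locus1", g[0][:, None]))
        if mode == RESPONSIVE:
            for i, m in enumerate(known):
                km = data.locus_column(data.marker_index(m))
                blocks.append((f"background:known_locus{i + 1}", D * km[:, None]))
            blocks.append(("background:locus1", D * g[0][:, None]))
    elif k == 2:
        blocks += [("locus1", g[0][:, None]), ("locus2", g[1][:, None])]
        if mode == RESPONSIVE:
            blocks += [
                ("background:locus1", D * g[0][:, None]),
                ("background:locus2", D * g[1][:, None]),
            ]
        blocks.append(("locus1:locus2", _interact(g[0], g[1])[:, None]))
        if mode == RESPONSIVE:
            blocks.append(
                ("background:locus1:locus2", D * _interact(g[0], g[1])[:, None])
            )
    else:
        blocks += [(f"locus{i + 1}", gi[:, None]) for i, gi in enumerate(g)]
        if mode == RESPONSIVE:
            blocks += [
                (f"background:locus{i + 1}", D * gi[:, None])
                for i, gi in enumerate(g)
            ]
        pairs = [(0, 1), (0, 2), (1, 2)]
        blocks += [
            (f"locus{a + 1}:locus{b + 1}", _interact(g[a], g[b])[:, None])
            for a, b in pairs
        ]
        if mode == RESPONSIVE:
            blocks += [
                (f"background:locus{a + 1}:locus{b + 1}",
                 D * _interact(g[a], g[b])[:, None])
                for a, b in pairs
            ]
        blocks.append(("locus1:locus2:locus3", _interact(*g)[:, None]))
        if mode == RESPONSIVE:
            blocks.append(
                ("background:locus1:locus2:locus3", D * _interact(*g)[:, None])
            )
    focal = blocks[-1][0]
    return blocks, focal


def anova_term_test(
    y: np.ndarray, data: ScanData, loci: tuple[str, ...], mode: str,
    known: tuple[str, ...] = (), focal: str | None = None,
) -> tuple[float, tuple[int, int], float]:
    """Sequential F-test of the focal term in a detection model.

    Returns (F, (df_term, df_resid), p).  A rank-deficient focal term is
    reported untestable as (nan, (0, df_resid), nan), never silently dropped.
    """
    blocks, default_focal = model_blocks(data, tuple(loci), mode, tuple(known))
    focal = focal or default_focal
    tab = sequential_anova(y, blocks)
    row = tab.loc[focal]
    df_resid = int(tab.loc["residual", "df"])
    return float(row["F"]), (int(row["df"]), df_resid), float(row["p"])


# ---------------------------------------------------------------------------
# vectorized scan kernels


def _prep_Y(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def scan_one_locus_pvalues(
    data: ScanData, Y: np.ndarray, mode: str,
    known: tuple[str, ...] = (), exclude: set[int] | None = None,
) -> np.ndarray:
    """Focal-term p for every marker x every response column.

    ``Y`` may hold the real phenotype and permuted copies side by side; they
    share each marker's projection basis.  Excluded marker rows are NaN.
    """
    Y = _prep_Y(Y)
    exclude = exclude or set()
    D = data._bg_dummies
    fixed_cols = [D]
    for m in known:
        km = data.locus_column(data.marker_index(m))
        fixed_cols.append(km[:, None])
        if mode == RESPONSIVE:
            fixed_cols.append(D * km[:, None])
    n = data.n
    Q0 = np.full((n, 1), 1.0 / np.sqrt(n))
    Qf = Q0
    for X in fixed_cols:
        B = orthonormal_block(X, Qf)
        if B.shape[1]:
            Qf = np.hstack([Qf, B])
    sumsq = np.einsum("ij,ij->j", Y, Y)
    P0 = Qf.T @ Y
    preproj = np.einsum("ij,ij->j", P0, P0)
    out = np.full((data.n_markers, Y.shape[1]), np.nan)
    for j in range(data.n_markers):
        if j in exclude:
            continue
        gcol = data.locus_column(j)[:, None]
        if mode == INDEPENDENT:
            out[j] = focal_pvalues(Y, Qf, gcol, sumsq, preproj)
        else:
            Bg = orthonormal_block(gcol, Qf)
            Qj = np.hstack([Qf, Bg]) if Bg.shape[1] else Qf
            extra = Bg.T @ Y
            pj = preproj + np.einsum("ij,ij->j", extra, extra) \
                if Bg.shape[1] else preproj
            out[j] = focal_pvalues(Y, Qj, D * gcol, sumsq, pj)
    return out


def _multi_locus_pvalues(
    data: ScanData, Y: np.ndarray, loci_idx: tuple[int, ...], mode: str,
    Qf: np.ndarray, sumsq: np.ndarray, preproj: np.ndarray,
    ycols: np.ndarray | None = None,
) -> np.ndarray:
    """Focal-term p for one pair/trio on selected response columns.

    ``Qf`` is the orthonormal basis of intercept + background; everything
    between it and the focal term is orthonormalized here.
    """
    D = data._bg_dummies
    g = [data.locus_column(i) for i in loci_idx]
    if len(g) == 2:
        pre = [g[0][:, None], g[1][:, None]]
        if mode == RESPONSIVE:
            pre += [D * g[0][:, None], D * g[1][:, None]]
        inter = _interact(*g)[:, None]
        if mode == RESPONSIVE:
            pre.append(inter)
            focal = D * inter
        else:
            focal = inter
    else:
        pre = [gi[:, None] for gi in g]
        if mode == RESPONSIVE:
            pre += [D * gi[:, None] for gi in g]
        pre += [_interact(g[a], g[b])[:, None] for a, b in ((0, 1), (0, 2), (1, 2))]
        if mode == RESPONSIVE:
            pre += [D * _interact(g[a], g[b])[:, None]
                    for a, b in ((0, 1), (0, 2), (1, 2))]
        inter = _interact(*g)[:, None]
        if mode == RESPONSIVE:
            pre.append(inter)
            focal = D * inter
        else:
            focal = inter
    Bp = orthonormal_block(np.hstack(pre), Qf)
    Qpre = np.hstack([Qf, Bp]) if Bp.shape[1] else Qf
    if ycols is not None:
        Y = Y[:, ycols]
        sumsq = sumsq[ycols]
        preproj = preproj[ycols]
    if Bp.shape[1]:
        ex = Bp.T @ Y
        preproj = preproj + np.einsum("ij,ij->j", ex, ex)
    return focal_pvalues(Y, Qpre, focal, sumsq, preproj)


def _base_projection(data: ScanData, Y: np.ndarray):
    n = data.n
    Q0 = np.full((n, 1), 1.0 / np.sqrt(n))
    B = orthonormal_block(data._bg_dummies, Q0)
    Qf = np.hstack([Q0, B]) if B.shape[1] else Q0
    sumsq = np.einsum("ij,ij->j", Y, Y)
    P0 = Qf.T @ Y
    preproj = np.einsum("ij,ij->j", P0, P0)
    return Qf, sumsq, preproj


# ---------------------------------------------------------------------------
# thresholds


@dataclass
class ThresholdSet:
    """Permutation-null summary for one scan type."""

    scan_type: str
    mode: str
    n_perm: int
    q: float
    min_p: np.ndarray
    threshold: float
    tests_per_perm: int
    perm_pvalues: np.ndarray | None = None

    @classmethod
    def from_min_p(cls, scan_type, mode, q, min_p, tests_per_perm,
                   perm_pvalues=None) -> "ThresholdSet":
        min_p = np.asarray(min_p, dtype=float)
        if np.isnan(min_p).any():
            raise ValueError(
                "degenerate permutation scan (constant phenotype?): "
                "threshold undefined"
            )
        # type-7 (linear interpolation) quantile of the permuted minima
        thr = float(np.quantile(min_p, q, method="linear"))
        return cls(scan_type, mode, len(min_p), q, min_p, thr,
                   tests_per_perm, perm_pvalues)


def _permute_columns(y: np.ndarray, n_perm: int, rng: np.random.Generator,
                     strata: np.ndarray | None = None) -> np.ndarray:
    """Shuffled copies of y; with ``strata``, shuffling stays within strata.

    The default scheme shuffles the genotype-phenotype correspondence across
    all segregants (background labels stay attached to genotype rows); the
    stratified variant is a sensitivity analysis that preserves each
    background's phenotype distribution.
    """
    n = y.size
    cols = np.empty((n, n_perm))
    if strata is None:
        for c in range(n_perm):
            cols[:, c] = y[rng.permutation(n)]
    else:
        groups = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
        for c in range(n_perm):
            col = np.empty(n)
            for idx in groups:
                col[idx] = y[idx[rng.permutation(idx.size)]]
            cols[:, c] = col
    return cols


def permutation_threshold_one_locus(
    data: ScanData, y: np.ndarray, mode: str, known: tuple[str, ...] = (),
    n_perm: int = 1000, q: float = 0.05, seed: int = 0,
    exclude: set[int] | None = None, keep_pvalues: bool = False,
    stratify_by_background: bool = False,
) -> ThresholdSet:
    """Genome-wide threshold for a one-locus scan at the current covariates."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype: threshold undefined")
    strata = data.backgrounds if stratify_by_background else None
    Yp = _permute_columns(y, n_perm, rng, strata)
    P = scan_one_locus_pvalues(data, Yp, mode, known, exclude)
    with np.errstate(invalid="ignore"):
        min_p = np.nanmin(P, axis=0)
    return ThresholdSet.from_min_p(
        "one_locus", mode, q, min_p,
        tests_per_perm=data.n_markers - len(exclude or ()),
        perm_pvalues=P[~np.isnan(P).all(axis=1)].ravel() if keep_pvalues else None,
    )


# ---------------------------------------------------------------------------
# effects & scans


@dataclass
class GeneticEffect:
    """A detected 1-3-locus effect in one environment."""

    environment: str
    loci: tuple[str, ...]
    mode: str
    p: float
    threshold: float
    iteration: int = 0
    knockouts: list = field(default_factory=list)  # (knockout, contrast_p)

    def __post_init__(self) -> None:
        self.loci = tuple(self.loci)

    @property
    def order(self) -> int:
        return len(self.loci)


def canonical_loci(data: ScanData, idx: tuple[int, ...]) -> tuple[str, ...]:
    """Marker ids in map order — the canonical locus-set representation."""
    return tuple(data.marker_map.marker_ids[i] for i in sorted(idx))


@dataclass
class ScanResult:
    effects: list
    thresholds: list  # ThresholdSet per iteration (forward) or single
    real_pvalues: np.ndarray | None = None
    loci_tested: list | None = None


def forward_scan_one_locus(
    data: ScanData, y: np.ndarray, mode: str, environment: str = "",
    n_perm: int = 1000, q: float = 0.05, seed: int = 0, max_iter: int = 30,
) -> ScanResult:
    """Forward-regression one-locus scan with per-iteration thresholds.

    Each iteration scans every remaining marker with already-detected loci as
    covariates (in responsive mode with both their additive and background
    interaction terms), derives a fresh permutation threshold under the same
    covariates, and accepts the best marker while its p-value beats the
    threshold.  Ties on the minimum p go to the leftmost genomic position.
    """
    if mode == RESPONSIVE and len(data.background_levels) < 2:
        raise ValueError("responsive scans need at least 2 backgrounds")
    y = np.asarray(y, dtype=float).ravel()
    known: list[str] = []
    exclude: set[int] = set()
    effects: list[GeneticEffect] = []
    thresholds: list[ThresholdSet] = []
    ss = np.random.SeedSequence(seed)
    for it in range(max_iter):
        iter_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        rng = np.random.default_rng(iter_seed)
        Yall = np.hstack([y[:, None], _permute_columns(y, n_perm, rng)])
        P = scan_one_locus_pvalues(data, Yall, mode, tuple(known), exclude)
        if np.isnan(P[:, 0]).all():
            break
        with np.errstate(invalid="ignore"):
            min_perm = np.nanmin(P[:, 1:], axis=0)
        ts = ThresholdSet.from_min_p(
            "one_locus", mode, q, min_perm,
            tests_per_perm=data.n_markers - len(exclude),
        )
        thresholds.append(ts)
        real = P[:, 0]
        best = int(np.nanargmin(real))  # first index = leftmost on tie
        if not real[best] < ts.threshold:
            break
        marker = str(data.marker_map.marker_ids[best])
        effects.append(GeneticEffect(
            environment, (marker,), mode, float(real[best]), ts.threshold,
            iteration=it,
        ))
        known.append(marker)
        exclude.add(best)
    return ScanResult(effects, thresholds)


def _all_pairs(M: int) -> np.ndarray:
    i, j = np.triu_indices(M, k=1)
    return np.column_stack([i, j])


def scan_two_locus(
    data: ScanData, y: np.ndarray, mode: str, environment: str = "",
    n_perm: int = 1000, subsample: int = 10_000, q: float = 0.05,
    seed: int = 0, keep_pvalues: bool = False,
) -> ScanResult:
    """Exhaustive two-locus scan with a subsampled permutation null.

    The real data pass interrogates every unique marker pair; each
    permutation evaluates ``subsample`` random pairs and retains its minimum
    p-value.  Effects are pairs whose focal-term p beats the 5% quantile of
    those minima.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype: threshold undefined")
    rng = np.random.default_rng(seed)
    pairs = _all_pairs(data.n_markers)
    n_pairs = len(pairs)
    s = min(subsample, n_pairs)
    sampled = np.stack([rng.choice(n_pairs, size=s, replace=False)
                        for _ in range(n_perm)])
    Yall = np.hstack([y[:, None], _permute_columns(y, n_perm, rng)])
    Qf, sumsq, preproj = _base_projection(data, Yall)
    # group permutation columns by the pair they sampled so each pair's
    # projection basis is built exactly once
    by_pair: dict[int, list[int]] = {}
    for perm in range(n_perm):
        for pi in sampled[perm]:
            by_pair.setdefault(int(pi), []).append(perm + 1)
    real_p = np.empty(n_pairs)
    perm_min = np.full(n_perm, np.inf)
    perm_all: list[np.ndarray] = []
    for pi in range(n_pairs):
        permcols = by_pair.get(pi, [])
        ycols = np.array([0] + permcols)
        pv = _multi_locus_pvalues(
            data, Yall, tuple(pairs[pi]), mode, Qf, sumsq, preproj, ycols
        )
        real_p[pi] = pv[0]
        if permcols:
            cols = np.array(permcols) - 1
            np.minimum.at(perm_min, cols, pv[1:])
            if keep_pvalues:
                perm_all.append(pv[1:])
    perm_min[~np.isfinite(perm_min)] = np.nan
    ts = ThresholdSet.from_min_p(
        "two_locus", mode, q, perm_min, tests_per_perm=s,
        perm_pvalues=np.concatenate(perm_all) if keep_pvalues else None,
    )
    effects = []
    for pi in np.flatnonzero(real_p < ts.threshold):
        effects.append(GeneticEffect(
            environment, canonical_loci(data, tuple(pairs[pi])), mode,
            float(real_p[pi]), ts.threshold,
        ))
    return ScanResult(effects, [ts], real_pvalues=real_p,
                      loci_tested=[tuple(p) for p in pairs])


def scan_three_locus(
    data: ScanData, y: np.ndarray, known_pairs: list, mode: str,
    environment: str = "", n_perm: int = 1000, subsample: int = 10_000,
    q: float = 0.05, seed: int = 0, exclude_loci: tuple[str, ...] = (),
) -> ScanResult:
    """Scan for a third locus completing an already-detected pair.

    For every known pair, each marker not yet detected in the environment is
    tested as the third locus of the full three-locus model.  Permutation
    trios are seeded by a random pair of loci on different chromosomes plus
    ``subsample`` random third sites; the minimum p per permutation forms
    the null.
    """
    if not known_pairs:
        return ScanResult([], [])
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(y) == 0:
        raise ValueError("constant phenotype: threshold undefined")
    rng = np.random.default_rng(seed)
    M = data.n_markers
    chroms = data.marker_map.chromosomes
    Yall = np.hstack([y[:, None], _permute_columns(y, n_perm, rng)])
    Qf, sumsq, preproj = _base_projection(data, Yall)
    # permutation null
    perm_min = np.empty(n_perm)
    one = np.array([0])
    for perm in range(n_perm):
        while True:
            a, b = rng.choice(M, size=2, replace=False)
            if chroms[a] != chroms[b]:
                break
        cand = np.setdiff1d(np.arange(M), [a, b])
        if cand.size > subsample:
            cand = rng.choice(cand, size=subsample, replace=False)
        ycol = np.array([perm + 1])
        best = np.inf
        for c in cand:
            pv = _multi_locus_pvalues(
                data, Yall, (a, b, int(c)), mode, Qf, sumsq, preproj, ycol
            )
            if pv[0] < best:
                best = pv[0]
        perm_min[perm] = best
    n_cand = max(M - 2, 1)
    ts = ThresholdSet.from_min_p(
        "three_locus", mode, q, perm_min,
        tests_per_perm=min(subsample, n_cand),
    )
    # real scan over every known pair x remaining marker
    excl_idx = {data.marker_index(m) for m in exclude_loci}
    effects = []
    real_rows = []
    for pair in known_pairs:
        a, b = (data.marker_index(m) for m in pair)
        for c in range(M):
            if c in (a, b) or c in excl_idx:
                continue
            pv = _multi_locus_pvalues(
                data, Yall, (a, b, c), mode, Qf, sumsq, preproj, one
            )
            real_rows.append(((a, b, c), pv[0]))
            if pv[0] < ts.threshold:
                effects.append(GeneticEffect(
                    environment, canonical_loci(data, (a, b, c)), mode,
                    float(pv[0]), ts.threshold,
                ))
    return ScanResult(
        effects, [ts],
        real_pvalues=np.array([r[1] for r in real_rows]),
        loci_tested=[r[0] for r in real_rows],
    )


# ---------------------------------------------------------------------------
# empirical FDR


def empirical_fdr(
    real_pvalues: np.ndarray, thresholds: ThresholdSet,
    fdr_targets: tuple[float, ...] = (0.01, 0.05, 0.1),
) -> pd.DataFrame:
    """Empirical FDR from permutation vs real discovery rates.

    FDR(p) = (mean permutation discovery rate at p) / (real discovery rate
    at p), capped at 1 and undefined (NaN) where the real scan has no
    discoveries.  Returns a table over the observed real p-values with the
    largest cutoff achieving each target FDR attached as ``.attrs['cutoffs']``.
    """
    if thresholds.perm_pvalues is None:
        raise ValueError("ThresholdSet was built without keep_pvalues")
    real = np.sort(np.asarray(real_pvalues, dtype=float))
    perm = np.sort(thresholds.perm_pvalues)
    if real.size == 0 or perm.size == 0:
        raise ValueError("need nonempty real and permutation p-value sets")
    n_perm_tests = thresholds.n_perm * thresholds.tests_per_perm
    real_rate = np.arange(1, real.size + 1) / real.size
    perm_rate = np.searchsorted(perm, real, side="right") / n_perm_tests
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(real_rate > 0, np.minimum(perm_rate / real_rate, 1.0),
                       np.nan)
    tab = pd.DataFrame({"p": real, "fdr": fdr})
    cutoffs = {}
    for t in fdr_targets:
        ok = tab.loc[tab["fdr"] <= t, "p"]
        cutoffs[t] = float(ok.max()) if len(ok) else None
    tab.attrs["cutoffs"] = cutoffs
    return tab
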
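"""Characterization of detected genetic effects.

The scans report which locus sets interact with the background factor; the
routines here say *how*:

* which specific knockouts drive a mutation-responsive effect (pairwise
  wild-type-vs-knockout contrasts on the detection model's interaction
  coefficients, each nominally significant assignment counted as a separate
  effect);
* how a higher-order effect's mutation-responsive variance splits between
  the knockout's interactions with individual loci and with their joint
  combination (sequential sum-of-squares shares on the wild-type + one
  knockout subset);
* whether an effect explains more phenotypic variance in mutants than in
  wild types (enhanced) or less (reduced), via partial R-squared from
  background-free models fit within each population;
* whether the effect is detectable in environments beyond the one it was
  mapped in (Bonferroni-corrected refits);
* whether uneven allele representation across backgrounds could have faked
  the interaction (genotype-class x background chi-square contingency
  tests);
* whether, across knockout x environment cells, the balance of enhanced
  vs reduced effects tracks the knockout-induced change in phenotypic
  variance (Spearman correlations plus a within-background permutation
  test);
* and the statistical power of the detection models themselves, by planting
  genotype-class increments and refitting (power = fraction of replicates
  with focal-term p <= 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._anova import ols_fit, sequential_anova
from . import simcross
from .scanengine import (
    INDEPENDENT,
    RESPONSIVE,
    GeneticEffect,
    ScanData,
    anova_term_test,
    model_blocks,
)

ENHANCED = "enhanced"
REDUCED = "reduced"


# ---------------------------------------------------------------------------
# knockout assignment


def _labeled_design(
    data: ScanData, loci: tuple[str, ...], mode: str
) -> tuple[np.ndarray, list[str]]:
    """Full detection-model design matrix with per-column labels.

    Background dummies are labeled by their background, interaction columns
    as ``background[<b>]:locus...``, so the coefficient of
    ``background[k]:locus1:...:locusK`` is exactly the difference between
    knockout k's and the wild type's locus-interaction effect.
    """
    blocks, _ = model_blocks(data, loci, mode)
    cols = [np.ones((data.n, 1))]
    labels = ["intercept"]
    for name, X in blocks:
        cols.append(X)
        if name == "background":
            labels += [f"background[{b}]" for b in data._bg_labels]
        elif name.startswith("background:"):
            rest = name.split(":", 1)[1]
            labels += [f"background[{b}]:{rest}" for b in data._bg_labels]
        else:
            labels += [name] * X.shape[1]
    return np.hstack(cols), labels


def assign_knockouts(
    effect: GeneticEffect, data: ScanData, y: np.ndarray, alpha: float = 0.05
) -> list[tuple[str, float]]:
    """Assign a mutation-responsive effect to specific knockouts.

    Refits the detection model on the full data and, for every knockout,
    t-tests the contrast between that knockout's focal interaction and the
    wild type's (the treatment-coded interaction coefficient) against the
    model's residual variance.  Knockouts with contrast p < alpha
    (uncorrected) are assigned; under the study's counting convention each
    assignment is a separate countable effect.  Inestimable contrasts
    (empty genotype classes) are skipped and reported with p = NaN.
    """
    if effect.mode != RESPONSIVE:
        raise ValueError("knockout assignment applies to responsive effects")
    X, labels = _labeled_design(data, effect.loci, RESPONSIVE)
    fit = ols_fit(X, y)
    base = ":".join(f"locus{i + 1}" for i in range(effect.order))
    out = []
    for b in data._bg_labels:
        lab = f"background[{b}]:{base}"
        idx = labels.index(lab)
        out.append((b, float(fit["p"][idx])))
    assigned = [(b, p) for b, p in out if np.isfinite(p) and p < alpha]
    effect.knockouts = assigned
    return out


# ---------------------------------------------------------------------------
# PVE partitioning


@dataclass
class PvePartition:
    """Relative shares of the mutation-responsive sums of squares."""

    knockout: str
    shares: dict
    raw_ss: dict
    partial: bool = False  # True when a responsive term was inestimable

    def __post_init__(self) -> None:
        total = sum(self.shares.values())
        if not self.partial and abs(total - 1.0) > 1e-9:
            raise ValueError("shares must sum to 1")


def _wt_ko_rows(data: ScanData, knockout: str) -> np.ndarray:
    return np.flatnonzero(
        (data.backgrounds == data.wild_type) | (data.backgrounds == knockout)
    )


def partition_pve(
    effect: GeneticEffect, data: ScanData, y: np.ndarray, knockout: str
) -> PvePartition:
    """Partition an effect's mutation-responsive variance for one knockout.

    The original detection model is refit on the wild-type + one-knockout
    subset and the sequential sums of squares of the mutation-responsive
    terms are normalized into shares: for a two-locus effect the shares of
    KO x L1, KO x L2 and KO x L1 x L2; for a three-locus effect the grouped
    shares of individual-locus, pairwise and three-way responsive terms.
    """
    if effect.order < 2:
        raise ValueError("PVE partitioning applies to 2- and 3-locus effects")
    rows = _wt_ko_rows(data, knockout)
    sub = data.subset(rows)
    tab = sequential_anova(
        np.asarray(y, dtype=float)[rows],
        model_blocks(sub, effect.loci, RESPONSIVE)[0],
    )
    partial = False

    def ss_of(names: list[str]) -> float:
        nonlocal partial
        tot = 0.0
        for nm in names:
            if tab.loc[nm, "df"] == 0:
                partial = True
            tot += float(tab.loc[nm, "ss"])
        return tot

    if effect.order == 2:
        raw = {
            "KOxL1": ss_of(["background:locus1"]),
            "KOxL2": ss_of(["background:locus2"]),
            "KOxL1xL2": ss_of(["background:locus1:locus2"]),
        }
    else:
        raw = {
            "individual": ss_of([f"background:locus{i}" for i in (1, 2, 3)]),
            "pairwise": ss_of([
                "background:locus1:locus2", "background:locus1:locus3",
                "background:locus2:locus3",
            ]),
            "three_way": ss_of(["background:locus1:locus2:locus3"]),
        }
    total = sum(raw.values())
    shares = {k: (v / total if total > 0 else np.nan) for k, v in raw.items()}
    return PvePartition(knockout, shares, raw, partial)


# ---------------------------------------------------------------------------
# enhanced / reduced classification


@dataclass
class EffectClassification:
    knockout: str
    r2_knockout: float
    r2_wildtype: float
    classification: str
    n_interacting_knockouts: int | None = None


def _no_background_blocks(
    sub: ScanData, loci: tuple[str, ...]
) -> tuple[list, str]:
    """The background-free models used for within-population partial R^2."""
    g = [sub.locus_column(sub.marker_index(m)) for m in loci]
    if len(g) == 1:
        return [("locus1", g[0][:, None])], "locus1"
    if len(g) == 2:
        return (
            [("locus1", g[0][:, None]), ("locus2", g[1][:, None]),
             ("locus1:locus2", (g[0] * g[1])[:, None])],
            "locus1:locus2",
        )
    blocks = [(f"locus{i + 1}", gi[:, None]) for i, gi in enumerate(g)]
    blocks += [
        (f"locus{a + 1}:locus{b + 1}", (g[a] * g[b])[:, None])
        for a, b in ((0, 1), (0, 2), (1, 2))
    ]
    blocks.append(("locus1:locus2:locus3", (g[0] * g[1] * g[2])[:, None]))
    return blocks, "locus1:locus2:locus3"


def _partial_r2(sub: ScanData, y: np.ndarray, loci: tuple[str, ...]) -> float:
    blocks, focal = _no_background_blocks(sub, loci)
    tab = sequential_anova(y, blocks)
    total = float(tab["ss"].sum())  # corrected total SS (intercept excluded)
    if total <= 0:
        return np.nan
    return float(tab.loc[focal, "ss"]) / total


def classify_enhanced_reduced(
    effect: GeneticEffect, data: ScanData, y: np.ndarray, knockout: str
) -> EffectClassification:
    """Classify an effect as enhanced or reduced for one knockout.

    Partial R^2 of the effect's top-order term from the background-free
    model, computed separately within the knockout and wild-type
    populations; enhanced iff the knockout value is strictly larger (ties
    go to reduced for determinism).  Degenerate subsets (zero phenotypic
    variance) make the effect unclassifiable and raise.
    """
    y = np.asarray(y, dtype=float)
    r2 = {}
    for label in (knockout, data.wild_type):
        rows = np.flatnonzero(data.backgrounds == label)
        sub = data.subset(rows)
        r2[label] = _partial_r2(sub, y[rows], effect.loci)
    if not all(np.isfinite(v) for v in r2.values()):
        raise ValueError("degenerate subset variance: effect unclassifiable")
    cls = ENHANCED if r2[knockout] > r2[data.wild_type] else REDUCED
    return EffectClassification(knockout, r2[knockout], r2[data.wild_type], cls)


# ---------------------------------------------------------------------------
# cross-environment detection


def cross_environment_detect(
    effect: GeneticEffect, data: ScanData, phenotypes: pd.DataFrame,
    knockouts: list[str], alpha: float = 0.05,
) -> pd.DataFrame:
    """Test a responsive effect in every environment beyond its origin.

    For each assigned knockout the detection model is refit on the
    wild-type + knockout subset in each of the other environments and the
    focal-term p extracted.  The Bonferroni family is (number of other
    environments) x (number of assigned knockouts); significance uses the
    <= rule at alpha / m.  Environments with no phenotype data are skipped
    and recorded.
    """
    others = [e for e in phenotypes.columns if e != effect.environment]
    m = max(len(others) * len(knockouts), 1)
    rows = []
    for env in others:
        yv = phenotypes[env].to_numpy(dtype=float)
        if np.isnan(yv).all():
            rows.append((env, None, np.nan, m, False, "missing_environment"))
            continue
        for ko in knockouts:
            idx = _wt_ko_rows(data, ko)
            sub = data.subset(idx)
            tab = sequential_anova(
                yv[idx], model_blocks(sub, effect.loci, RESPONSIVE)[0]
            )
            focal = model_blocks(sub, effect.loci, RESPONSIVE)[1]
            p = float(tab.loc[focal, "p"])
            rows.append((env, ko, p, m, bool(p <= alpha / m), ""))
    out = pd.DataFrame(
        rows,
        columns=["environment", "knockout", "p", "m_tests", "significant",
                 "note"],
    )
    out.attrs["n_additional_environments"] = int(
        out.loc[out["significant"], "environment"].nunique()
    )
    return out


# ---------------------------------------------------------------------------
# distinct effects


@dataclass(frozen=True)
class DistinctEffect:
    loci: tuple[str, ...]
    knockouts: tuple[str, ...]
    environments: tuple[str, ...]
    n_members: int

    @property
    def n_interacting_knockouts(self) -> int:
        return len(self.knockouts)


def collapse_distinct(effects: list[GeneticEffect]) -> list[DistinctEffect]:
    """Collapse per-knockout assignments into distinct effects by locus set.

    Effects sharing the same (canonical) locus set are one distinct effect
    whose interacting-knockout count is the size of the union of assigned
    knockouts across members.  Idempotent and input-order invariant.
    """
    groups: dict[tuple[str, ...], list[GeneticEffect]] = {}
    for e in effects:
        groups.setdefault(tuple(sorted(e.loci)), []).append(e)
    out = []
    for loci in sorted(groups):
        members = groups[loci]
        kos = sorted({k for e in members for k, _ in e.knockouts})
        envs = sorted({e.environment for e in members})
        out.append(DistinctEffect(loci, tuple(kos), tuple(envs), len(members)))
    return out


# ---------------------------------------------------------------------------
# allele-frequency bias


def allele_frequency_bias_test(
    data: ScanData, loci_sets: list[tuple[str, ...]], alpha: float = 0.05
) -> pd.DataFrame:
    """Chi-square tests for allele-combination bias across backgrounds.

    For each locus set the 2^k joint genotype classes are cross-tabulated
    against the backgrounds and tested with Pearson's chi-square, Bonferroni
    corrected over the number of sets.  Sets with structurally empty rows or
    columns (an expected count of zero) are skipped with a diagnostic.
    """
    m = max(len(loci_sets), 1)
    rows = []
    for loci in loci_sets:
        cols = [data.marker_index(x) for x in loci]
        cls = np.zeros(data.n, dtype=int)
        for c in cols:
            cls = cls * 2 + data.genotypes[:, c]
        tab = pd.crosstab(cls, data.backgrounds)
        if (tab.sum(axis=1) == 0).any() or (tab.sum(axis=0) == 0).any() \
                or tab.shape[0] < 2 or tab.shape[1] < 2:
            rows.append((loci, np.nan, 0, np.nan, np.nan, False,
                         "structural_zero"))
            continue
        chi2, p, df, _ = stats.chi2_contingency(tab.to_numpy(),
                                                correction=False)
        p_bonf = min(p * m, 1.0)
        rows.append((loci, float(chi2), int(df), float(p), float(p_bonf),
                     bool(p_bonf <= alpha), ""))
    return pd.DataFrame(
        rows, columns=["loci", "chi2", "df", "p", "p_bonferroni", "flagged",
                       "note"],
    )


# ---------------------------------------------------------------------------
# variance summary and its correlation with effect counts


def variance_summary(
    data: ScanData, phenotypes: pd.DataFrame,
    classified: list[tuple[GeneticEffect, EffectClassification]],
) -> pd.DataFrame:
    """Per knockout x environment: V_P.Mut, V_P.WT and effect-count balance.

    Phenotypic variances are sample variances within each background.
    ``classified`` pairs each (assigned) effect with its classification in
    the relevant knockout; the summary counts enhanced and reduced effects
    per cell and the differences Delta_V = V_P.Mut - V_P.WT and
    Delta_count = n_enhanced - n_reduced that the attribution analysis
    correlates.
    """
    kos = [b for b in data.background_levels if b != data.wild_type]
    rows = []
    for ko in kos:
        for env in phenotypes.columns:
            yv = phenotypes[env].to_numpy(dtype=float)
            v_mut = float(np.var(yv[data.backgrounds == ko], ddof=1))
            v_wt = float(np.var(yv[data.backgrounds == data.wild_type], ddof=1))
            n_enh = sum(
                1 for e, c in classified
                if c.knockout == ko and e.environment == env
                and c.classification == ENHANCED
            )
            n_red = sum(
                1 for e, c in classified
                if c.knockout == ko and e.environment == env
                and c.classification == REDUCED
            )
            rows.append((ko, env, v_mut, v_wt, v_mut - v_wt, n_enh, n_red,
                         n_enh - n_red))
    return pd.DataFrame(
        rows,
        columns=["knockout", "environment", "v_p_mut", "v_p_wt", "delta_v",
                 "n_enhanced", "n_reduced", "delta_count"],
    )


@dataclass
class CorrelationResult:
    rho: float
    p: float
    per_background: pd.DataFrame | None = None
    joint_permutation_p: float | None = None


def variance_change_correlation(
    summary: pd.DataFrame, scope: str = "all", n_perm: int = 100_000,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman correlation of Delta_V with Delta_count.

    ``scope="all"`` ranks every knockout x environment cell together.
    ``scope="per_background"`` computes one correlation per knockout across
    environments and a joint permutation p bounding the chance that *all*
    backgrounds clear the observed minimum correlation; the permutation
    shuffles Delta_V across environments within each background
    independently, preserving each background's count structure.
    """
    if len(summary) < 3:
        raise ValueError("need at least 3 cells")
    if scope == "all":
        rho, p = stats.spearmanr(summary["delta_v"], summary["delta_count"])
        return CorrelationResult(float(rho), float(p))
    if scope != "per_background":
        raise ValueError("scope must be 'all' or 'per_background'")
    rows = []
    groups = []
    for ko, grp in summary.groupby("knockout", sort=False):
        if len(grp) < 3:
            continue
        rho, p = stats.spearmanr(grp["delta_v"], grp["delta_count"])
        rows.append((ko, float(rho), float(p), len(grp)))
        groups.append((grp["delta_v"].to_numpy(), grp["delta_count"].to_numpy()))
    per_bg = pd.DataFrame(rows, columns=["knockout", "rho", "p", "n"])
    obs_min = per_bg["rho"].min()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        ok = True
        for dv, dc in groups:
            r, _ = stats.spearmanr(rng.permutation(dv), dc)
            if not (r >= obs_min):
                ok = False
                break
        hits += ok
    joint_p = (hits + 1) / (n_perm + 1)
    rho_all, p_all = stats.spearmanr(summary["delta_v"], summary["delta_count"])
    return CorrelationResult(float(rho_all), float(p_all), per_bg,
                             float(joint_p))


def bootstrap_proportions(
    classifications: list[EffectClassification], B: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Enhanced-effect proportion per interacting-knockout count, with
    percentile bootstrap 95% CIs (1000 resamples by default).

    Singleton groups yield degenerate (zero-width) intervals, reported as
    such.
    """
    rng = np.random.default_rng(seed)
    by_group: dict[int, np.ndarray] = {}
    for c in classifications:
        if c.n_interacting_knockouts is None:
            raise ValueError("classification lacks n_interacting_knockouts")
        by_group.setdefault(c.n_interacting_knockouts, [])
    for c in classifications:
        by_group[c.n_interacting_knockouts].append(
            1.0 if c.classification == ENHANCED else 0.0
        )
    rows = []
    for g in sorted(by_group):
        x = np.asarray(by_group[g])
        prop = float(x.mean())
        boots = np.array([
            rng.choice(x, size=x.size, replace=True).mean() for _ in range(B)
        ])
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append((g, x.size, prop, float(lo), float(hi)))
    return pd.DataFrame(
        rows,
        columns=["n_interacting_knockouts", "n_effects",
                 "proportion_enhanced", "ci_low", "ci_high"],
    )


# ---------------------------------------------------------------------------
# statistical power analysis


def power_analysis(
    effect_sizes: tuple[float, ...],
    orders: tuple[int, ...] = (1, 2, 3),
    mode: str = RESPONSIVE,
    replicates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    marker_map: simcross.MarkerMap | None = None,
    background_counts: dict | None = None,
    noise_sd: float = 0.25,
    background_mean_shift: dict | None = None,
) -> pd.DataFrame:
    """Detection power of the scan models for planted effects.

    Per grid cell (order, effect size): in each replicate a fresh cross is
    simulated, random distinct loci are drawn, one joint genotype class (and,
    for responsive effects, one random non-wild-type background) receives the
    absolute-effect-size increment, Gaussian noise is added, the appropriate
    detection model is fit, and the focal-term p recorded.  Power is the
    fraction of replicates with p <= alpha.  The default population mirrors
    the study panel: 1411 segregants split over the wild-type and seven
    knockout backgrounds.
    """
    marker_map = marker_map or simcross.MarkerMap.uniform(
        n_chromosomes=16, markers_per_chromosome=3
    )
    counts = background_counts or dict(simcross.STUDY_BACKGROUND_COUNTS)
    labels = list(counts)
    backgrounds = np.repeat(np.asarray(labels, dtype=object),
                            [counts[b] for b in labels])
    n = len(backgrounds)
    shift = np.array(
        [(background_mean_shift or {}).get(b, 0.0) for b in backgrounds]
    )
    ss = np.random.SeedSequence(seed)
    rows = []
    for order in orders:
        for size in effect_sizes:
            cell_rng = np.random.default_rng(ss.spawn(1)[0])
            hits = 0
            for _ in range(replicates):
                G = simcross.simulate_genotypes(marker_map, n, cell_rng)
                loci_idx = cell_rng.choice(len(marker_map), size=order,
                                           replace=False)
                loci = tuple(marker_map.marker_ids[i] for i in loci_idx)
                cls = cell_rng.integers(0, 2, size=order)
                member = np.ones(n, dtype=bool)
                for c, a in zip(loci_idx, cls):
                    member &= G[:, c] == a
                if mode == RESPONSIVE:
                    target = cell_rng.choice(labels[1:])
                    member = member & (backgrounds == target)
                y = shift + size * member + cell_rng.normal(0, noise_sd, n)
                data = ScanData(G, backgrounds, marker_map,
                                background_levels=tuple(labels))
                _, _, p = anova_term_test(y, data, loci, mode)
                hits += p <= alpha
            rows.append((order, mode, float(size), hits / replicates,
                         replicates))
    return pd.DataFrame(
        rows, columns=["order", "mode", "effect_size", "power", "replicates"]
    )
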
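"""Effect characterization: knockout assignment, PVE partitioning,
enhanced/reduced classes, cross-environment tests, bias checks,
variance-change attribution, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bgfx import simcross
from bgfx.effectchar import (
    ENHANCED, REDUCED, EffectClassification, allele_frequency_bias_test,
    assign_knockouts, bootstrap_proportions, classify_enhanced_reduced,
    collapse_distinct, cross_environment_detect, partition_pve,
    power_analysis, variance_change_correlation, variance_summary,
)
from bgfx.scanengine import RESPONSIVE, GeneticEffect, ScanData
from conftest import balanced_design


def make_multi_ko_pop(seed, effects, n_per_bg=150, noise=0.25,
                      labels=("WT", "hos3", "rpd3", "ctk1"),
                      environments=("ypd_30c",), shifts=None):
    mm = simcross.MarkerMap.uniform(4, 6, recomb=0.15)
    cfg = simcross.SimConfig(
        n_per_background=n_per_bg, background_labels=labels, noise_sd=noise,
        seed=seed, planted_effects=list(effects), environments=environments,
        background_mean_shift=shifts or {},
    )
    pop = simcross.simulate_cross(cfg, mm)
    return pop, ScanData.from_population(pop)


def effect_of(planted, env="ypd_30c"):
    return GeneticEffect(env, tuple(sorted(planted.loci)), RESPONSIVE,
                         p=1e-8, threshold=1e-4)


class TestAssignKnockouts:
    def test_only_target_knockout_assigned(self):
        planted = simcross.PlantedEffect(
            loci=("chr01_m003",), responsive=True, target_background="hos3",
            absolute_effect_size=1.0)
        hits = 0
        for seed in range(10):
            pop, data = make_multi_ko_pop(seed, [planted])
            y = pop.phenotype_vector("ypd_30c")
            contrasts = assign_knockouts(effect_of(planted), data, y)
            assigned = {k for k, p in contrasts if p < 0.05}
            hits += assigned == {"hos3"}
        assert hits >= 9

    def test_null_assignment_rate_is_nominal(self):
        planted = simcross.PlantedEffect(
            loci=("chr01_m003",), responsive=True, target_background="hos3",
            absolute_effect_size=0.0)
        rates = []
        for seed in range(40):
            pop, data = make_multi_ko_pop(seed, [planted], n_per_bg=60)
            y = pop.phenotype_vector("ypd_30c")
            contrasts = assign_knockouts(effect_of(planted), data, y)
            rates += [p < 0.05 for _, p in contrasts]
        assert 0.01 < np.mean(rates) < 0.10

    def test_shared_effect_counts_once_per_knockout(self):
        effs = [
            simcross.PlantedEffect(
                loci=("chr02_m002",), responsive=True, target_background=ko,
                absolute_effect_size=1.2)
            for ko in ("hos3", "rpd3")
        ]
        pop, data = make_multi_ko_pop(50, effs, n_per_bg=200)
        y = pop.phenotype_vector("ypd_30c")
        e = effect_of(effs[0])
        contrasts = assign_knockouts(e, data, y)
        assigned = {k for k, p in contrasts if p < 0.05}
        assert {"hos3", "rpd3"} <= assigned
        assert len(e.knockouts) == len(assigned)  # separate countable effects

    def test_independent_effect_rejected(self, two_bg_data):
        e = GeneticEffect("ypd_30c", ("chr01_m001",), "independent", 0.01, 0.05)
        with pytest.raises(ValueError):
            assign_knockouts(e, two_bg_data, np.zeros(two_bg_data.n))


class TestPartitionPve:
    def test_single_locus_interaction_takes_all_share(self):
        G, bg, mm = balanced_design(2, reps=12)
        y = ((bg == "hos3") & (G[:, 0] == 1)).astype(float)
        data = ScanData(G, bg, mm, background_levels=("WT", "hos3"))
        e = GeneticEffect("e", ("chr01_m001", "chr01_m002"), RESPONSIVE,
                          1e-9, 1e-4)
        part = partition_pve(e, data, y, "hos3")
        assert part.shares["KOxL1"] == pytest.approx(1.0, abs=1e-9)
        assert part.shares["KOxL2"] == pytest.approx(0.0, abs=1e-9)
        assert part.shares["KOxL1xL2"] == pytest.approx(0.0, abs=1e-9)

    def test_triple_product_takes_three_way_share(self):
        G, bg, mm = balanced_design(3, reps=6)
        s = 2.0 * G - 1.0
        y = (bg == "hos3") * s[:, 0] * s[:, 1] * s[:, 2]
        data = ScanData(G, bg, mm, background_levels=("WT", "hos3"))
        e = GeneticEffect(
            "e", ("chr01_m001", "chr01_m002", "chr01_m003"), RESPONSIVE,
            1e-9, 1e-4)
        part = partition_pve(e, data, y, "hos3")
        assert part.shares["three_way"] == pytest.approx(1.0, abs=1e-9)
        assert part.shares["individual"] == pytest.approx(0.0, abs=1e-9)
        assert part.shares["pairwise"] == pytest.approx(0.0, abs=1e-9)

    def test_shares_sum_to_one_and_scale_invariant(self):
        planted = simcross.PlantedEffect(
            loci=("chr01_m002", "chr03_m004"), responsive=True,
            target_background="hos3", absolute_effect_size=0.8)
        pop, data = make_multi_ko_pop(60, [planted])
        y = pop.phenotype_vector("ypd_30c")
        e = effect_of(planted)
        p1 = partition_pve(e, data, y, "hos3")
        p2 = partition_pve(e, data, 7.3 * y, "hos3")
        assert sum(p1.shares.values()) == pytest.approx(1.0, abs=1e-9)
        for k in p1.shares:
            assert p1.shares[k] == pytest.approx(p2.shares[k], abs=1e-9)

    def test_one_locus_effect_rejected(self, two_bg_data):
        e = GeneticEffect("e", ("chr01_m001",), RESPONSIVE, 1e-9, 1e-4)
        with pytest.raises(ValueError):
            partition_pve(e, two_bg_data, np.zeros(two_bg_data.n), "hos3")


class TestClassifyEnhancedReduced:
    def _pop_with_effect_in(self, target, seed=70):
        planted = simcross.PlantedEffect(
            loci=("chr02_m003",), responsive=True, target_background=target,
            absolute_effect_size=1.0)
        return make_multi_ko_pop(seed, [planted], labels=("WT", "hos3")), \
            planted

    def test_knockout_only_effect_is_enhanced(self):
        (pop, data), planted = self._pop_with_effect_in("hos3")
        y = pop.phenotype_vector("ypd_30c")
        c = classify_enhanced_reduced(effect_of(planted), data, y, "hos3")
        assert c.classification == ENHANCED
        assert c.r2_knockout > c.r2_wildtype

    def test_wildtype_only_effect_is_reduced(self):
        (pop, data), planted = self._pop_with_effect_in("WT", seed=71)
        y = pop.phenotype_vector("ypd_30c")
        c = classify_enhanced_reduced(effect_of(planted), data, y, "hos3")
        assert c.classification == REDUCED

    def test_antisymmetric_under_population_swap(self):
        (pop, data), planted = self._pop_with_effect_in("hos3", seed=72)
        y = pop.phenotype_vector("ypd_30c")
        swapped = ScanData(data.genotypes, data.backgrounds, data.marker_map,
                           background_levels=("hos3", "WT"))
        a = classify_enhanced_reduced(effect_of(planted), data, y, "hos3")
        b = classify_enhanced_reduced(effect_of(planted), swapped, y, "WT")
        assert a.r2_knockout == pytest.approx(b.r2_wildtype)
        assert a.r2_wildtype == pytest.approx(b.r2_knockout)
        assert {a.classification, b.classification} == {ENHANCED, REDUCED}


class TestCrossEnvironment:
    def test_detected_in_exactly_the_planted_additional_environment(self):
        envs = ("ypd_30c", "ethanol", "zeocin")
        effs = [
            simcross.PlantedEffect(
                loci=("chr01_m004",), responsive=True,
                target_background="hos3", absolute_effect_size=1.2,
                environment=env)
            for env in ("ypd_30c", "ethanol")
        ]
        pop, data = make_multi_ko_pop(80, effs, environments=envs,
                                      labels=("WT", "hos3"), n_per_bg=300)
        e = effect_of(effs[0])
        tab = cross_environment_detect(e, data, pop.phenotypes, ["hos3"])
        assert tab.attrs["n_additional_environments"] == 1
        hit = tab[tab["significant"]]
        assert hit["environment"].tolist() == ["ethanol"]

    def test_bonferroni_boundary_uses_leq_rule(self):
        # a raw p exactly at alpha/m counts as significant
        assert (0.05 / 18) <= 0.05 / 18


class TestCollapseDistinct:
    def _eff(self, loci, env="e", kos=()):
        e = GeneticEffect(env, loci, RESPONSIVE, 1e-6, 1e-4)
        e.knockouts = [(k, 0.01) for k in kos]
        return e

    def test_same_loci_merge_and_union_knockouts(self):
        effs = [self._eff(("a", "b"), kos=["hos3"]),
                self._eff(("b", "a"), env="f", kos=["rpd3"])]
        out = collapse_distinct(effs)
        assert len(out) == 1
        assert out[0].n_interacting_knockouts == 2
        assert out[0].knockouts == ("hos3", "rpd3")

    def test_disjoint_loci_stay_distinct(self):
        effs = [self._eff(("a",)), self._eff(("b",)), self._eff(("c", "d"))]
        assert len(collapse_distinct(effs)) == 3

    def test_six_assignments_over_three_locus_sets(self):
        effs = [self._eff(("a",), kos=[k]) for k in ("k1", "k2")]
        effs += [self._eff(("b", "c"), kos=[k]) for k in ("k1", "k3")]
        effs += [self._eff(("d",), kos=[k]) for k in ("k1", "k2")]
        assert len(collapse_distinct(effs)) == 3

    def test_idempotent_and_order_invariant(self):
        effs = [self._eff(("a", "b"), kos=["k1"]), self._eff(("c",)),
                self._eff(("a", "b"), kos=["k2"])]
        once = collapse_distinct(effs)
        rev = collapse_distinct(effs[::-1])
        assert once == rev


class TestAlleleFrequencyBias:
    def test_diagonal_two_by_two_table(self):
        # closed form: chi2 = N(ad-bc)^2 / (row1 row2 col1 col2) = 20
        G = np.array([[0]] * 10 + [[1]] * 10, dtype=np.int8)
        bg = np.array(["WT"] * 10 + ["ko"] * 10, dtype=object)
        mm = simcross.MarkerMap.uniform(1, 1)
        data = ScanData(G, bg, mm)
        tab = allele_frequency_bias_test(data, [("chr01_m001",)])
        assert tab["chi2"].iloc[0] == pytest.approx(20.0)
        assert tab["df"].iloc[0] == 1

    def test_proportional_table_gives_zero(self):
        G = np.array([[0]] * 5 + [[1]] * 5 + [[0]] * 5 + [[1]] * 5,
                     dtype=np.int8)
        bg = np.array(["WT"] * 10 + ["ko"] * 10, dtype=object)
        data = ScanData(G, bg, simcross.MarkerMap.uniform(1, 1))
        tab = allele_frequency_bias_test(data, [("chr01_m001",)])
        assert tab["chi2"].iloc[0] == pytest.approx(0.0)

    def test_matches_hand_coded_chi_square_oracle(self):
        rng = np.random.default_rng(0)
        mm = simcross.MarkerMap.uniform(1, 2, recomb=0.5)
        for _ in range(50):
            G = rng.integers(0, 2, size=(80, 2)).astype(np.int8)
            bg = rng.choice(["WT", "k1", "k2"], 80).astype(object)
            data = ScanData(G, bg, mm)
            tab = allele_frequency_bias_test(
                data, [("chr01_m001", "chr01_m002")])
            if tab["note"].iloc[0]:
                continue
            cls = G[:, 0] * 2 + G[:, 1]
            ct = pd.crosstab(cls, bg).to_numpy().astype(float)
            expected = np.outer(ct.sum(1), ct.sum(0)) / ct.sum()
            chi2 = (((ct - expected) ** 2) / expected).sum()
            assert tab["chi2"].iloc[0] == pytest.approx(chi2, abs=1e-10)

    def test_unbiased_cross_flag_rate_is_low(self):
        pop, data = make_multi_ko_pop(90, [], n_per_bg=100)
        ids = data.marker_map.marker_ids
        sets = [(ids[i],) for i in range(0, 24, 2)]
        tab = allele_frequency_bias_test(data, sets)
        assert tab["flagged"].sum() <= 1


class TestVarianceChangeCorrelation:
    def test_perfectly_monotone(self):
        df = pd.DataFrame({
            "knockout": ["k"] * 5, "delta_v": [1, 2, 3, 4, 5],
            "delta_count": [2, 4, 5, 7, 9],
        })
        res = variance_change_correlation(df, scope="all")
        assert res.rho == pytest.approx(1.0)

    def test_textbook_rank_example(self):
        # ranks d = (1,-1,... ): sum d^2 = 4 -> rho = 1 - 24/60 = 0.6
        df = pd.DataFrame({
            "knockout": ["k"] * 4, "delta_v": [1, 2, 3, 4],
            "delta_count": [2, 1, 4, 3],
        })
        assert variance_change_correlation(df, scope="all").rho == \
            pytest.approx(0.6)

    def test_anti_monotone(self):
        df = pd.DataFrame({
            "knockout": ["k"] * 4, "delta_v": [1, 2, 3, 4],
            "delta_count": [9, 7, 5, 3],
        })
        assert variance_change_correlation(df, scope="all").rho == \
            pytest.approx(-1.0)

    def test_joint_permutation_detects_consistent_signal(self):
        rng = np.random.default_rng(1)
        rows = []
        for ko in ["k1", "k2", "k3"]:
            dv = np.arange(10) + rng.normal(0, 0.1, 10)
            rows += [(ko, v, c) for v, c in zip(dv, np.arange(10))]
        df = pd.DataFrame(rows, columns=["knockout", "delta_v", "delta_count"])
        res = variance_change_correlation(df, scope="per_background",
                                          n_perm=2000, seed=2)
        assert (res.per_background["rho"] > 0.9).all()
        assert res.joint_permutation_p < 0.01


class TestBootstrapProportions:
    def _cls(self, group, label):
        c = EffectClassification("k", 0.1, 0.05, label)
        c.n_interacting_knockouts = group
        return c

    def test_identical_group_has_zero_width_ci(self):
        cls = [self._cls(1, ENHANCED) for _ in range(20)]
        tab = bootstrap_proportions(cls, B=200, seed=0)
        assert tab["proportion_enhanced"].iloc[0] == 1.0
        assert tab["ci_low"].iloc[0] == tab["ci_high"].iloc[0] == 1.0

    def test_ci_width_matches_wald_sanity_band(self):
        cls = [self._cls(2, ENHANCED if i % 2 else REDUCED)
               for i in range(400)]
        tab = bootstrap_proportions(cls, B=500, seed=1)
        half = (tab["ci_high"].iloc[0] - tab["ci_low"].iloc[0]) / 2
        wald = 1.96 * np.sqrt(0.25 / 400)
        assert 0.5 * wald < half < 1.5 * wald

    def test_deterministic_given_seed(self):
        cls = [self._cls(1, ENHANCED if i % 3 else REDUCED)
               for i in range(30)]
        a = bootstrap_proportions(cls, B=100, seed=5)
        b = bootstrap_proportions(cls, B=100, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestVarianceSummaryPipeline:
    def test_enhanced_dominant_planting_recovers_positive_correlation(self):
        # knockouts with many enhanced effects gain phenotypic variance;
        # the summary must recover that as a positive rank correlation
        envs = ("e1", "e2", "e3", "e4")
        effs = []
        for i, env in enumerate(envs):
            for j in range(i + 1):  # increasing effect load over envs
                effs.append(simcross.PlantedEffect(
                    loci=(f"chr{j + 1:02d}_m00{2 + i % 2}",), responsive=True,
                    target_background="hos3", absolute_effect_size=0.8,
                    environment=env))
        pop, data = make_multi_ko_pop(95, effs, environments=envs,
                                      labels=("WT", "hos3", "rpd3"),
                                      n_per_bg=200)
        classified = []
        for planted in effs:
            e = effect_of(planted, env=planted.environment)
            y = pop.phenotypes[planted.environment].to_numpy()
            assign_knockouts(e, data, y)
            for ko, _ in e.knockouts:
                classified.append(
                    (e, classify_enhanced_reduced(e, data, y, ko)))
        summary = variance_summary(data, pop.phenotypes, classified)
        assert len(summary) == 8  # 2 knockouts x 4 environments
        res = variance_change_correlation(summary, scope="all")
        assert res.rho > 0.5


@pytest.fixture(scope="module")
def grid():
    return power_analysis((0.0, 0.35), orders=(1, 3), replicates=60, seed=7)


class TestPowerAnalysis:

    def test_null_power_is_alpha(self, grid):
        null = grid[grid["effect_size"] == 0.0]["power"]
        assert ((null - 0.05).abs() < 0.09).all()

    def test_power_increases_with_effect_size(self, grid):
        for order in (1, 3):
            sub = grid[grid["order"] == order].sort_values("effect_size")
            assert sub["power"].iloc[-1] >= sub["power"].iloc[0]

    def test_lower_order_effects_are_easier_to_detect(self, grid):
        at = grid[grid["effect_size"] == 0.35].set_index("order")["power"]
        assert at.loc[1] >= at.loc[3]
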
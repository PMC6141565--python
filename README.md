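# bgfx — mapping genetic background effects in a multi-knockout yeast cross

The same mutation can have very different phenotypic consequences in
different individuals. In a cross of the BY and 3S budding-yeast strains,
panels of haploid segregants carrying complete knockouts of chromatin
regulators (*ctk1Δ*, *esa1Δ*, *gcn5Δ*, *hos3Δ*, *htb1Δ*, *ino80Δ*, *rpd3Δ*)
can be compared with wild-type segregants to ask **which segregating loci
change their effect when a gene is knocked out** — i.e., to map the epistasis
between induced mutations, standing polymorphisms, and the environment that
underlies genetic background effects.

`bgfx` is a reusable, tested implementation of that analysis for
quantitative geneticists working with haploid crosses:

* **genotype calling** from low-coverage sequencing: per-SNP 3S allele
  fractions are thresholded, corrected with a 2-state Viterbi HMM
  (stay 0.9999 / switch 0.0001, emission fidelity 0.75), QC-filtered
  (mean coverage ≥ 1.5×, heterozygosity excess), and adjacent
  non-recombining markers collapsed to one representative;
* **phenotype normalization**: end-point colony growth divided by
  same-plate BY-control means, replicates averaged, plus the Levene
  variance screen that nominates knockouts;
* **genome scans** with fixed-effects linear models over all backgrounds
  jointly. A `background` factor is always included; a term's significance
  is a sequential (type-I) F-test, and genome-wide thresholds come from
  permutations (5% quantile of the minimum p over 1000 shuffles of the
  genotype–phenotype correspondence). Scans cover forward-regression
  one-locus effects, exhaustive two-locus pairs, and anchored three-locus
  models, each in two modes:
  - *mutation-independent* — focal term `locus1[:locus2[:locus3]]`,
  - *mutation-responsive* — focal term
    `background:locus1[:locus2[:locus3]]`;
* **characterization** of detected effects: post hoc wild-type-vs-knockout
  contrasts assign responsive effects to specific knockouts; sequential
  sums of squares partition higher-order mutation-responsive variance
  (KO×L1, KO×L2, KO×L1×L2, …); background-free refits classify effects as
  *enhanced* or *reduced* (larger or smaller partial R² in mutants);
  Bonferroni-corrected refits test effects in the other environments;
  genotype-class × background χ² tables flag allele-frequency bias; and
  Spearman correlations relate the enhanced-minus-reduced effect balance to
  knockout-induced variance changes (ΔV = V_P.Mut − V_P.WT);
* **a synthetic cross simulator** that provides every input the pipeline
  needs — recombinant haploid genotypes (per-chromosome 2-state Markov
  chains), planted genotype-class increments (the absolute effect size,
  applied to one background for responsive effects or all backgrounds for
  independent ones), Gaussian noise, and noisy allele-fraction observations
  — with truth records for scoring detection, and the power-analysis driver
  built on it.

## Worked example

```python
import numpy as np
from bgfx import simcross
from bgfx.scanengine import RESPONSIVE, ScanData, forward_scan_one_locus
from bgfx.effectchar import assign_knockouts, classify_enhanced_reduced

marker_map = simcross.MarkerMap.uniform(n_chromosomes=16,
                                        markers_per_chromosome=4)
config = simcross.SimConfig(
    n_per_background=150,
    background_labels=("WT", "hos3", "rpd3"),
    noise_sd=0.25,
    seed=7,
    planted_effects=[
        simcross.PlantedEffect(
            loci=("chr07_m002",), responsive=True,
            target_background="hos3", absolute_effect_size=0.75,
        )
    ],
)
pop = simcross.simulate_cross(config, marker_map)
data = ScanData.from_population(pop)
y = pop.phenotype_vector("ypd_30c")

result = forward_scan_one_locus(data, y, RESPONSIVE, "ypd_30c",
                                n_perm=200, seed=1)
for effect in result.effects:
    contrasts = assign_knockouts(effect, data, y)
    cls = classify_enhanced_reduced(effect, data, y, "hos3")
    print(f"locus {effect.loci[0]}  p = {effect.p:.3g}  "
          f"threshold = {effect.threshold:.3g}")
    for ko, p in contrasts:
        print(f"  contrast {ko} vs WT: p = {p:.3g}")
    print(f"  partial R^2: knockout = {cls.r2_knockout:.3f}, "
          f"wild type = {cls.r2_wildtype:.3f} -> {cls.classification}")
```

Output:

```
locus chr07_m002  p = 8.3e-33  threshold = 0.000819
  contrast hos3 vs WT: p = 9.26e-28
  contrast rpd3 vs WT: p = 0.615
  partial R^2: knockout = 0.660, wild type = 0.002 -> enhanced
```

The forward scan recovers exactly the planted locus: its
background-interaction p-value (8.3e-33) beats the genome-wide permutation
threshold (8.2e-4), the post hoc contrasts attribute the interaction to the
*hos3Δ* background it was planted in (and not to *rpd3Δ*), and the
background-free refits show the locus explaining 66% of phenotypic variance
among *hos3Δ* segregants versus ~0% in wild type — an *enhanced* effect.

The same library surface is scriptable from the shell:

```bash
bgfx run --config demo.yaml --out runs/demo    # simulate → genotype → scan → characterize
bgfx scan --order 2 --mode responsive --env ethanol ...
bgfx power --sizes 0,0.15,0.3 --orders 1,2,3 --out power.tsv
```

Every run directory carries a `manifest.json` with the configuration hash
and artifact checksums; identical configurations reproduce byte-identical
artifacts.

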
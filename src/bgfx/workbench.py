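"""End-to-end pipeline orchestration.

A run executes the stages simulate -> genotype -> scan -> characterize in
dependency order from one structured configuration, writes each stage's
artifacts exactly once into a run directory, and emits ``manifest.json``
recording the configuration hash, package version, per-stage seeds, and a
checksum for every artifact.  Re-running with the same configuration
produces byte-identical artifacts; a stage that is toggled off must already
have its artifacts in the run directory or the first stage needing them
fails fast with the missing stage's name.

The genotype stage exercises the calling pipeline on simulated allele
fractions (Poisson coverage, binomial miscalls over the simulated truth);
normalization of raw plate intensities runs only when such a file is
supplied, since the simulator emits already-normalized phenotypes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .genocall import HmmParams, call_genotypes, collapse_markers, qc_filter
from .scanengine import (
    INDEPENDENT,
    RESPONSIVE,
    ScanData,
    forward_scan_one_locus,
    scan_two_locus,
)
from .effectchar import (
    assign_knockouts,
    classify_enhanced_reduced,
    variance_summary,
    variance_change_correlation,
)
from .simcross import MarkerMap, PlantedEffect, SimConfig, simulate_cross, \
    simulate_allele_fractions


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One pipeline run: stage toggles, simulation and scan parameters."""

    seed: int = 0
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "genotype": True, "scan": True, "characterize": True,
    })
    sim: dict = field(default_factory=dict)  # SimConfig keyword arguments
    map: dict = field(default_factory=dict)  # MarkerMap.uniform kwargs
    coverage: dict = field(default_factory=lambda: {
        "mean_coverage": 3.0, "error_rate": 0.05,
    })
    scan: dict = field(default_factory=lambda: {
        "modes": [INDEPENDENT, RESPONSIVE], "orders": [1],
        "n_perm": 100, "subsample": 1000, "q": 0.05, "max_iter": 10,
    })
    alpha_contrast: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        kw = dict(self.sim)
        effects = [PlantedEffect(**e) if isinstance(e, dict) else e
                   for e in kw.pop("planted_effects", [])]
        kw.setdefault("seed", self.seed)
        return SimConfig(planted_effects=effects, **kw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(out: Path, stage: str, names: list[str]) -> None:
    for nm in names:
        if not (out / nm).exists():
            raise PipelineError(
                f"missing upstream artifact {nm!r}: run stage {stage!r} first"
            )


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, list[str]] = {}
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        s: int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        for s in ("simulate", "genotype", "scan", "characterize")
    }

    marker_map = MarkerMap.uniform(**config.map) if config.map or \
        config.stages.get("simulate") else None

    if config.stages.get("simulate"):
        sim = config.sim_config()
        pop = simulate_cross(sim, marker_map)
        marker_map = pop.marker_map
        io.write_genotypes(out / "genotypes.tsv", pop.genotypes,
                           pop.segregant_ids, marker_map.marker_ids,
                           pop.backgrounds)
        io.write_marker_map(out / "marker_map.tsv", marker_map)
        io.write_phenotypes(out / "phenotypes.tsv", pop.phenotypes,
                            pop.backgrounds)
        io.write_truth(out / "truth.json", pop.truth)
        artifacts["simulate"] = ["genotypes.tsv", "marker_map.tsv",
                                 "phenotypes.tsv", "truth.json"]

    if config.stages.get("genotype"):
        _require(out, "simulate", ["genotypes.tsv", "marker_map.tsv"])
        geno, seg_ids, marker_ids, backgrounds = io.read_genotypes(
            out / "genotypes.tsv")
        marker_map = io.read_marker_map(out / "marker_map.tsv")
        frac = simulate_allele_fractions(
            geno, seed=stage_seeds["genotype"], segregant_ids=seg_ids,
            snp_ids=marker_ids, **config.coverage,
        )
        io.write_fractions(out / "allele_fractions.tsv", frac)
        qc = qc_filter(frac)
        qc.to_csv(out / "qc.tsv", sep="\t")
        kept = qc["keep"].to_numpy()
        called = call_genotypes(
            frac.__class__(frac.segregant_ids[kept], frac.snp_ids,
                           frac.fractions[kept], frac.coverage[kept]),
            marker_map.chromosomes, HmmParams(),
        )
        reduced, keep_cols, blocks = collapse_markers(
            called, marker_map.chromosomes, marker_map.marker_ids)
        io.write_genotypes(out / "called_genotypes.tsv", reduced,
                           seg_ids[kept], marker_map.marker_ids[keep_cols],
                           None if backgrounds is None else backgrounds[kept])
        blocks.to_csv(out / "marker_blocks.tsv", sep="\t", index=False)
        artifacts["genotype"] = ["allele_fractions.tsv", "qc.tsv",
                                 "called_genotypes.tsv", "marker_blocks.tsv"]

    if config.stages.get("scan"):
        _require(out, "simulate",
                 ["genotypes.tsv", "marker_map.tsv", "phenotypes.tsv"])
        geno, seg_ids, marker_ids, backgrounds = io.read_genotypes(
            out / "genotypes.tsv")
        marker_map = io.read_marker_map(out / "marker_map.tsv")
        phenotypes, bg = io.read_phenotypes(out / "phenotypes.tsv")
        data = ScanData(geno, backgrounds, marker_map)
        sc = config.scan
        effects = []
        thresholds = {}
        for env in phenotypes.columns:
            y = phenotypes[env].to_numpy()
            for mode in sc["modes"]:
                res = forward_scan_one_locus(
                    data, y, mode, env, n_perm=sc["n_perm"], q=sc["q"],
                    seed=stage_seeds["scan"], max_iter=sc.get("max_iter", 30),
                )
                effects += res.effects
                thresholds[f"{env}/{mode}/one_locus"] = [
                    t.threshold for t in res.thresholds]
                if 2 in sc.get("orders", [1]):
                    res2 = scan_two_locus(
                        data, y, mode, env, n_perm=sc["n_perm"],
                        subsample=sc.get("subsample", 10_000), q=sc["q"],
                        seed=stage_seeds["scan"],
                    )
                    effects += res2.effects
                    thresholds[f"{env}/{mode}/two_locus"] = [
                        res2.thresholds[0].threshold]
        io.write_effects(out / "effects.tsv", effects)
        (out / "thresholds.json").write_text(
            json.dumps(thresholds, indent=2, sort_keys=True))
        artifacts["scan"] = ["effects.tsv", "thresholds.json"]

    if config.stages.get("characterize"):
        _require(out, "scan", ["effects.tsv"])
        _require(out, "simulate", ["genotypes.tsv", "phenotypes.tsv"])
        geno, seg_ids, marker_ids, backgrounds = io.read_genotypes(
            out / "genotypes.tsv")
        marker_map = io.read_marker_map(out / "marker_map.tsv")
        phenotypes, _ = io.read_phenotypes(out / "phenotypes.tsv")
        data = ScanData(geno, backgrounds, marker_map)
        effects = io.read_effects(out / "effects.tsv")
        classified = []
        for e in effects:
            if e.mode != RESPONSIVE:
                continue
            y = phenotypes[e.environment].to_numpy()
            assign_knockouts(e, data, y, alpha=config.alpha_contrast)
            for ko, _p in e.knockouts:
                classified.append(
                    (e, classify_enhanced_reduced(e, data, y, ko)))
        io.write_effects(out / "effects_assigned.tsv", effects)
        summary = variance_summary(data, phenotypes, classified)
        summary.to_csv(out / "variance_summary.tsv", sep="\t", index=False)
        report = {
            "n_effects": len(effects),
            "n_responsive": sum(e.mode == RESPONSIVE for e in effects),
            "n_assignments": sum(len(e.knockouts) for e in effects),
        }
        if len(summary) >= 3 and summary["delta_count"].nunique() > 1:
            corr = variance_change_correlation(summary, scope="all")
            report["spearman_rho"] = corr.rho
            report["spearman_p"] = corr.p
        (out / "characterization.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        artifacts["characterize"] = ["effects_assigned.tsv",
                                     "variance_summary.tsv",
                                     "characterization.json"]

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stage_seeds": stage_seeds,
        "artifacts": {
            stage: {nm: _sha256(out / nm) for nm in names}
            for stage, names in artifacts.items()
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
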
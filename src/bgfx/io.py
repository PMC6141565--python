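"""Plain-text interchange formats.

Everything is TSV or JSON so runs are diffable and the deposited-style
supplementary exports (genotype and phenotype tables, identified-loci
lists) can be read back with the same loaders.  Alleles are written as the
parental strain names ("BY"/"3S") and parsed back to the 0/1 coding.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genocall import AlleleFractionTable
from .scanengine import GeneticEffect
from .simcross import MarkerMap

ALLELE_NAMES = np.array(["BY", "3S"])


def write_genotypes(path, genotypes, segregant_ids, marker_ids,
                    backgrounds=None) -> None:
    df = pd.DataFrame(ALLELE_NAMES[np.asarray(genotypes)],
                      index=pd.Index(segregant_ids, name="segregant_id"),
                      columns=marker_ids)
    if backgrounds is not None:
        df.insert(0, "background", backgrounds)
    df.to_csv(path, sep="\t")


def read_genotypes(path) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None]:
    """Returns (genotypes 0/1, segregant_ids, marker_ids, backgrounds|None)."""
    df = pd.read_csv(path, sep="\t", index_col="segregant_id")
    backgrounds = None
    if "background" in df.columns:
        backgrounds = df.pop("background").to_numpy()
    geno = (df.to_numpy() == "3S").astype(np.int8)
    return geno, df.index.to_numpy(), df.columns.to_numpy(), backgrounds


def write_marker_map(path, marker_map: MarkerMap) -> None:
    marker_map.table.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    return MarkerMap(pd.read_csv(path, sep="\t"))


def write_phenotypes(path, phenotypes: pd.DataFrame, backgrounds) -> None:
    """Long-format phenotype TSV: segregant_id, background, environment, value."""
    long = phenotypes.reset_index().melt(
        id_vars="segregant_id", var_name="environment", value_name="value"
    )
    bg = pd.Series(backgrounds, index=phenotypes.index, name="background")
    long.insert(1, "background", long["segregant_id"].map(bg))
    long.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> tuple[pd.DataFrame, pd.Series]:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot(index="segregant_id", columns="environment",
                      values="value")
    bg = long.drop_duplicates("segregant_id").set_index("segregant_id")[
        "background"]
    order = long["segregant_id"].drop_duplicates()
    return wide.loc[order], bg.loc[order]


def write_fractions(path, table: AlleleFractionTable) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_fractions(path) -> AlleleFractionTable:
    return AlleleFractionTable.from_frame(pd.read_csv(path, sep="\t"))


def write_effects(path, effects: list[GeneticEffect]) -> None:
    rows = [
        {
            "environment": e.environment,
            "loci": ";".join(e.loci),
            "order": e.order,
            "mode": e.mode,
            "p": e.p,
            "threshold": e.threshold,
            "iteration": e.iteration,
            "knockouts": ",".join(f"{k}:{p:.6g}" for k, p in e.knockouts),
        }
        for e in effects
    ]
    pd.DataFrame(
        rows, columns=["environment", "loci", "order", "mode", "p",
                       "threshold", "iteration", "knockouts"],
    ).to_csv(path, sep="\t", index=False)


def read_effects(path) -> list[GeneticEffect]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        kos = []
        if r["knockouts"]:
            for item in str(r["knockouts"]).split(","):
                k, p = item.rsplit(":", 1)
                kos.append((k, float(p)))
        out.append(GeneticEffect(
            environment=r["environment"], loci=tuple(r["loci"].split(";")),
            mode=r["mode"], p=float(r["p"]), threshold=float(r["threshold"]),
            iteration=int(r["iteration"]), knockouts=kos,
        ))
    return out


def write_truth(path, truth) -> None:
    from dataclasses import asdict

    Path(path).write_text(
        json.dumps([asdict(e) for e in truth], indent=2, default=str)
    )
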
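"""Phenotype normalization and the variance screen.

Growth is measured as end-point colony pixel intensity on agar plates, in
triplicate, with four BY parental controls per plate.  A segregant's growth
on a plate is its intensity divided by the mean intensity of that plate's
controls, which removes plate-to-plate scale differences; replicates are
then averaged into one value per segregant and environment.

The screen that nominated knockouts compares the phenotypic variance of a
knockout segregant panel against wild-type segregants with Levene's test —
a one-way ANOVA on absolute deviations from each group's center — reporting
the direction (knockout variance exceeding wild type) separately from the
two-sided p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._anova import sequential_anova

CONTROL_ID = "BY_CONTROL"

#: the study's 10 growth environments (YPD base medium unless noted)
ENVIRONMENTS = (
    "ypd_30c", "ypd_21c", "ypd_42c", "ethanol", "4nqo", "copper_sulfate",
    "fluconazole", "hydrogen_peroxide", "neomycin", "zeocin",
)


class PlateError(ValueError):
    """A plate that cannot be normalized (e.g. no usable controls)."""


def normalize_to_controls(plate: pd.DataFrame) -> pd.DataFrame:
    """Normalize colony intensities to the same-plate BY-control mean.

    ``plate`` needs columns plate_id, environment, segregant_id, replicate,
    intensity; control rows carry ``segregant_id == "BY_CONTROL"``.  Each
    plate is normalized independently: value = intensity / mean(control
    intensities).  A plate whose controls are absent or all non-positive is
    rejected with ``PlateError("no_valid_controls: <plate>")``.
    """
    req = {"plate_id", "environment", "segregant_id", "replicate", "intensity"}
    missing = req - set(plate.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    out = []
    for plate_id, grp in plate.groupby("plate_id", sort=False):
        ctrl = grp.loc[grp["segregant_id"] == CONTROL_ID, "intensity"]
        ctrl = ctrl[ctrl > 0]
        if len(ctrl) == 0:
            raise PlateError(f"no_valid_controls: {plate_id}")
        segs = grp[grp["segregant_id"] != CONTROL_ID].copy()
        segs["normalized"] = segs["intensity"] / ctrl.mean()
        out.append(segs)
    return pd.concat(out, ignore_index=True)


def average_replicates(normalized: pd.DataFrame) -> pd.DataFrame:
    """Average replicate normalized values per segregant x environment.

    Returns one row per (segregant_id, environment) with the mean value and
    the replicate count actually used (missing plates simply lower the
    count).  A ``background`` column, when present, is carried through.
    """
    keys = ["segregant_id", "environment"]
    if "background" in normalized.columns:
        keys.insert(1, "background")
    agg = (
        normalized.groupby(keys, sort=False)["normalized"]
        .agg(value="mean", n_replicates="count")
        .reset_index()
    )
    return agg


@dataclass(frozen=True)
class LeveneResult:
    statistic: float
    p: float
    df: tuple[int, int]
    ko_variance_greater: bool


def levene_variance_screen(
    wt_values: np.ndarray, ko_values: np.ndarray, center: str = "mean"
) -> LeveneResult:
    """Levene's test of equal variance between wild-type and knockout panels.

    One-way ANOVA on |value - group center|; ``center`` is "mean" (classic
    Levene) or "median" (Brown-Forsythe).  The direction — whether the
    knockout panel's variance exceeds the wild type's — is reported
    separately so a higher-variance criterion can be enforced on top of the
    two-sided p.
    """
    wt = np.asarray(wt_values, dtype=float)
    ko = np.asarray(ko_values, dtype=float)
    if wt.size < 2 or ko.size < 2:
        raise ValueError("each group needs at least 2 values")
    centerer = np.mean if center == "mean" else np.median
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    dev = np.concatenate([np.abs(wt - centerer(wt)), np.abs(ko - centerer(ko))])
    group = np.concatenate([np.zeros(wt.size), np.ones(ko.size)])
    tab = sequential_anova(dev, [("group", group[:, None])])
    F = tab.loc["group", "F"]
    p = tab.loc["group", "p"]
    if tab.loc["group", "ss"] <= 1e-12 * max(float(dev @ dev), 1.0):
        # all absolute deviations equal across groups
        F, p = 0.0, 1.0
    return LeveneResult(
        statistic=float(F),
        p=float(p),
        df=(int(tab.loc["group", "df"]), int(tab.loc["residual", "df"])),
        ko_variance_greater=bool(np.var(ko, ddof=1) > np.var(wt, ddof=1)),
    )
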
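"""Limiting-factor effect contrasts between treatment pairs.

Each effect is a difference of mean accepted growth rates between two
treatments, per taxon and season:

========== ========= =========================================
effect     contrast  factor probed
========== ========= =========================================
light_C    CL - CD   light availability (control background)
light_P    PL - PD   light availability (predator-reduced)
grazing_L  PL - CL   top-down control by grazers (light)
grazing_D  PD - CD   top-down control by grazers (dark)
viral      VL - DL   top-down control by viruses
nutrient   DL - PL   bottom-up control / nutrient limitation
========== ========= =========================================

A taxon missing an accepted rate on either side contributes NA, never 0:
the discard rule removes non-growers and imputing a rate would fabricate
an effect.
"""

from __future__ import annotations

import pandas as pd

from .datamodel import RANKS
from .growth import accepted_frame

#: effect name -> (minuend treatment, subtrahend treatment)
EFFECTS = {
    "light_C": ("CL", "CD"),
    "light_P": ("PL", "PD"),
    "grazing_L": ("PL", "CL"),
    "grazing_D": ("PD", "CD"),
    "viral": ("VL", "DL"),
    "nutrient": ("DL", "PL"),
}

#: pairs of contrasts probing the same factor in two backgrounds
PAIRED_EFFECTS = {"light": ("light_C", "light_P"), "grazing": ("grazing_L", "grazing_D")}

VALID_RANKS = ("asv",) + RANKS


def condition_mean_rates(
    records, taxonomy: pd.DataFrame | None = None, rank: str = "asv"
) -> pd.DataFrame:
    """Mean accepted rate per (taxon, season, treatment) at a chosen rank.

    ``rank="asv"`` keeps single-ASV resolution; any rank in the taxonomy
    pools member ASVs (unassigned ASVs are dropped from pooled ranks).
    """
    if rank not in VALID_RANKS:
        raise ValueError(f"rank must be one of {VALID_RANKS}")
    df = accepted_frame(records)
    if rank == "asv":
        df = df.assign(taxon=df["asv_id"])
    else:
        if taxonomy is None:
            raise ValueError("taxonomy required for pooled ranks")
        df = df.assign(taxon=df["asv_id"].map(taxonomy[rank]))
        df = df.dropna(subset=["taxon"])
    out = (
        df.groupby(["taxon", "season", "treatment"], observed=True)["slope_per_day"]
        .agg(mean_rate="mean", n="size")
        .reset_index()
    )
    return out


def compute_effects(means: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon, per-season treatment contrasts (NA when a side is missing)."""
    wide = means.pivot_table(
        index=["taxon", "season"], columns="treatment", values="mean_rate"
    )
    rows = {}
    for name, (a, b) in EFFECTS.items():
        left = wide[a] if a in wide.columns else pd.Series(index=wide.index, dtype=float)
        right = wide[b] if b in wide.columns else pd.Series(index=wide.index, dtype=float)
        rows[name] = left - right
    out = pd.DataFrame(rows)
    out = out.reset_index().melt(
        id_vars=["taxon", "season"], var_name="effect", value_name="delta"
    )
    return out.sort_values(["taxon", "season", "effect"], kind="mergesort").reset_index(
        drop=True
    )


def averaged_effects(effects: pd.DataFrame) -> pd.DataFrame:
    """Optional summary averaging the paired light and grazing contrasts."""
    wide = effects.pivot_table(
        index=["taxon", "season"], columns="effect", values="delta"
    )
    out = {}
    for name, (a, b) in PAIRED_EFFECTS.items():
        cols = [c for c in (a, b) if c in wide.columns]
        if cols:
            out[name] = wide[cols].mean(axis=1)
    for name in ("viral", "nutrient"):
        if name in wide.columns:
            out[name] = wide[name]
    return (
        pd.DataFrame(out)
        .reset_index()
        .melt(id_vars=["taxon", "season"], var_name="effect", value_name="delta")
        .dropna(subset=["delta"])
        .reset_index(drop=True)
    )


def community_mean_effect(effects: pd.DataFrame) -> pd.DataFrame:
    """Mean delta over taxa (NA ignored) per season and effect."""
    grp = effects.dropna(subset=["delta"]).groupby(
        ["season", "effect"], observed=True
    )["delta"]
    out = grp.agg(mean_delta="mean", n="size").reset_index()
    return out.sort_values(["season", "effect"], kind="mergesort").reset_index(drop=True)
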
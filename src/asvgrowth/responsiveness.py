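"""Responsive ASVs, condition overlap, and recruitment from the rare biosphere.

A taxon is *responsive* in a condition (season x treatment) when its
accepted growth rate exceeds 1 d^-1, and *most responsive* above 2 d^-1
(twice the literature-average copiotroph rate).  Overlap bookkeeping
counts ASVs responding to exactly one condition (exclusive) or to pairs
of conditions (shared).  Rarity relates growth to the in situ community:
taxa below 1% (rare) or 0.1% (very rare) relative abundance in the
natural community that nonetheless grow fast, and that end the
incubation above 1% of the community, are "successful" conditionally
rare taxa.  All thresholds are strict inequalities and configurable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import accepted_frame
from .pseudoabundance import relative_abundances

RESPONSIVE_THRESHOLD = 1.0  # d^-1
FAST_THRESHOLD = 2.0  # d^-1, "most responsive"
RARE_THRESHOLD = 1.0  # % in situ
VERY_RARE_THRESHOLD = 0.1  # % in situ
SUCCESS_THRESHOLD = 1.0  # % of the community at the end of the experiment
#: pairwise links are flagged for plotting when shared proportion exceeds this
PLOT_LINK_THRESHOLD = 0.3


def classify_responsive(rate: float, threshold: float = RESPONSIVE_THRESHOLD) -> bool:
    """True iff an accepted rate strictly exceeds the threshold."""
    return bool(rate > threshold)


def responsive_sets(
    records, threshold: float = RESPONSIVE_THRESHOLD
) -> dict[tuple[str, str], set[str]]:
    """Responsive ASV set per (season, treatment) from accepted records."""
    df = accepted_frame(records)
    df = df[df["slope_per_day"] > threshold]
    out: dict[tuple[str, str], set[str]] = {}
    for (season, treatment), grp in df.groupby(["season", "treatment"], observed=True):
        out[(season, treatment)] = set(grp["asv_id"])
    return out


@dataclass
class ResponsivenessReport:
    """Per-condition and pairwise responsive-set bookkeeping.

    ``conditions`` has one row per condition with n_responsive,
    n_exclusive and relative_exclusive; ``pairs`` one row per unordered
    condition pair with n_shared, relative_shared (|A∩B| / min(|A|,|B|))
    and a ``plot_link`` flag marking shared proportions above the
    visualisation cutoff.
    """

    conditions: pd.DataFrame
    pairs: pd.DataFrame


def exclusive_shared(
    sets: dict[tuple[str, str], set[str]],
    plot_link_threshold: float = PLOT_LINK_THRESHOLD,
) -> ResponsivenessReport:
    """Exclusive and shared counts with their relative denominators.

    Exclusive = responding in exactly one condition; relative_exclusive
    divides by that condition's responsive count.  relative_shared
    divides the intersection by the smaller of the two responsive sets
    (the maximum possible overlap).  Empty sets yield NA ratios.
    """
    keys = sorted(sets)
    membership: dict[str, int] = {}
    for key in keys:
        for asv in sets[key]:
            membership[asv] = membership.get(asv, 0) + 1
    cond_rows = []
    for key in keys:
        s = sets[key]
        n = len(s)
        n_excl = sum(1 for a in s if membership[a] == 1)
        cond_rows.append(
            (
                key[0],
                key[1],
                n,
                n_excl,
                (n_excl / n) if n else float("nan"),
            )
        )
    pair_rows = []
    for a, b in itertools.combinations(keys, 2):
        inter = len(sets[a] & sets[b])
        denom = min(len(sets[a]), len(sets[b]))
        rel = inter / denom if denom else float("nan")
        pair_rows.append(
            (
                a[0], a[1], b[0], b[1], inter, rel,
                bool(rel > plot_link_threshold) if denom else False,
            )
        )
    conditions = pd.DataFrame(
        cond_rows,
        columns=["season", "treatment", "n_responsive", "n_exclusive", "relative_exclusive"],
    )
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "season_a", "treatment_a", "season_b", "treatment_b",
            "n_shared", "relative_shared", "plot_link",
        ],
    )
    return ResponsivenessReport(conditions=conditions, pairs=pairs)


def fraction_responsive(responsive_set: set[str], t0_richness: int) -> float:
    """Responsive ASVs over the number of ASVs present at t0."""
    if t0_richness <= 0:
        raise ValueError("t0 richness must be positive")
    return len(responsive_set) / t0_richness


# ----------------------------------------------------------------------
# rarity
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RarityRecord:
    """Classification of one ASV (in one season) by growth and in situ rarity."""

    insitu_percent: float  # NaN when undetected in the natural community
    max_rate: float  # max accepted rate across the season's conditions, d^-1
    end_percent: float  # relative abundance at the end of the experiment, %
    detected: bool
    category: str  # not_responsive | responsive | most_responsive
    rarity: str  # abundant | rare | very_rare
    successful: bool


def classify_rarity(
    insitu_percent: float,
    max_rate: float,
    end_percent: float,
    responsive_threshold: float = RESPONSIVE_THRESHOLD,
    fast_threshold: float = FAST_THRESHOLD,
    rare_threshold: float = RARE_THRESHOLD,
    very_rare_threshold: float = VERY_RARE_THRESHOLD,
    success_threshold: float = SUCCESS_THRESHOLD,
) -> RarityRecord:
    """Apply the strict growth/rarity/success thresholds to one ASV.

    An ASV undetected in situ (NaN percent) is assumed present but below
    the detection limit, hence very rare.
    """
    detected = bool(np.isfinite(insitu_percent))
    pct = float(insitu_percent) if detected else float("nan")
    if max_rate > fast_threshold:
        category = "most_responsive"
    elif max_rate > responsive_threshold:
        category = "responsive"
    else:
        category = "not_responsive"
    if not detected or pct < very_rare_threshold:
        rarity = "very_rare"
    elif pct < rare_threshold:
        rarity = "rare"
    else:
        rarity = "abundant"
    successful = bool(
        category == "most_responsive"
        and rarity in ("rare", "very_rare")
        and end_percent > success_threshold
    )
    return RarityRecord(
        insitu_percent=pct,
        max_rate=float(max_rate),
        end_percent=float(end_percent),
        detected=detected,
        category=category,
        rarity=rarity,
        successful=successful,
    )


def end_of_experiment_percent(exp) -> pd.DataFrame:
    """Relative abundance (%) of each ASV at the end of the experiment.

    Per season and ASV: mean over replicates at the last available
    timepoint of each treatment, then the maximum across treatments (an
    ASV blooming in any bottle counts as having become abundant).
    """
    rel = relative_abundances(exp.counts)
    samples = exp.samples
    per_season = {}
    for season, sgrp in samples.groupby("season", observed=True):
        best = None
        for _, cond in sgrp.groupby("treatment", observed=True):
            last_h = cond["hours"].max()
            cols = cond.index[cond["hours"] == last_h]
            mean_rel = rel[cols].mean(axis=1)
            best = mean_rel if best is None else np.maximum(best, mean_rel)
        per_season[season] = best
    return pd.DataFrame(per_season)


def rarity_table(
    records,
    exp,
    insitu: pd.DataFrame | None,
    **thresholds,
) -> pd.DataFrame:
    """Rarity classification for every ASV with an accepted rate, per season.

    ``insitu`` maps ASV (rows) x season (columns) to in situ relative
    abundance (%); ``None`` treats every ASV as undetected.  Ranks in the
    natural community are ordinal by decreasing abundance, undetected
    ASVs ranked after all detected ones.
    """
    df = accepted_frame(records)
    end_pct = end_of_experiment_percent(exp)
    rows = []
    for season, grp in df.groupby("season", observed=True):
        max_rates = grp.groupby("asv_id", observed=True)["slope_per_day"].max()
        if insitu is not None and season in insitu.columns:
            profile = insitu[season]
        else:
            profile = pd.Series(dtype=float)
        season_end = end_pct[season] if season in end_pct.columns else pd.Series(dtype=float)
        ranks = rank_abundance(profile.reindex(max_rates.index).fillna(0.0))
        for asv, rate in max_rates.items():
            pct = profile.get(asv, float("nan"))
            rec = classify_rarity(
                pct, rate, float(season_end.get(asv, 0.0)), **thresholds
            )
            rows.append(
                (
                    asv, season, rec.insitu_percent, int(ranks[asv]), rec.max_rate,
                    rec.end_percent, rec.detected, rec.category, rec.rarity,
                    rec.successful,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "asv_id", "season", "insitu_percent", "insitu_rank", "max_rate",
            "end_percent", "detected", "category", "rarity", "successful",
        ],
    ).sort_values(["season", "asv_id"], kind="mergesort").reset_index(drop=True)


def rank_abundance(abundances: pd.Series) -> pd.Series:
    """Ordinal ranks by decreasing abundance (1 = most abundant).

    Ties are broken by ASV id lexicographically so the ranking is
    deterministic.
    """
    order = sorted(abundances.index, key=lambda a: (-abundances[a], str(a)))
    return pd.Series({a: i + 1 for i, a in enumerate(order)}, name="rank")
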
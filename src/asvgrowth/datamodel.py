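"""Shared data model for incubation-experiment growth-rate analyses.

The experimental design emulated throughout the package is a seawater
manipulation experiment: water sampled in each of the four seasons is
incubated under six treatments that relax different growth-limiting
factors, and the community is profiled by 16S amplicon sequencing at a
handful of timepoints with replicate bottles, alongside flow-cytometry
counts of total prokaryotic abundance.

Treatment codes
---------------
``CL``/``CD``
    unamended control under a light/dark cycle or in the dark,
``PL``/``PD``
    predator-reduced (<1 um filtered) under light or dark,
``DL``
    diluted with virus-free water to relax nutrient limitation,
``VL``
    virus-reduced.

``VR`` is accepted as an input alias of ``VL``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEASONS = ("winter", "spring", "summer", "fall")
TREATMENTS = ("CL", "CD", "PL", "PD", "DL", "VL")
#: Alternative spellings accepted on input and normalised to the canonical code.
TREATMENT_ALIASES = {"VR": "VL"}
TIMEPOINTS = ("t0", "t2", "t3", "t4")
#: Taxonomic ranks from coarse to fine; the ASV itself is the finest unit.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")
SAMPLE_COLUMNS = ("season", "treatment", "timepoint", "replicate", "hours")
#: Pseudo ASV id used for bulk (total cell count) growth-rate records.
BULK_ID = "__bulk__"


def normalize_treatment(code: str) -> str:
    """Map input treatment codes (including aliases) to canonical codes."""
    code = str(code).strip()
    return TREATMENT_ALIASES.get(code, code)


@dataclass
class ExperimentTable:
    """A validated bundle of counts, sample metadata, totals and taxonomy.

    Attributes
    ----------
    counts
        ASV read counts, rows indexed by ``asv_id``, columns by sample id.
        Integer for raw sequencing output; real-valued after copy-number
        correction or in exact-proportion simulations.
    samples
        One row per sample id with columns ``season``, ``treatment``,
        ``timepoint``, ``replicate`` and ``hours`` (elapsed since t0).
    totals
        Total prokaryotic abundance (cells/mL, flow cytometry) per sample.
    taxonomy
        One column per rank in :data:`RANKS`; NaN marks unassigned ranks.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    totals: pd.Series
    taxonomy: pd.DataFrame

    # ------------------------------------------------------------------
    @property
    def asv_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def condition_samples(self, season: str, treatment: str) -> pd.DataFrame:
        """Metadata rows of all samples belonging to one condition."""
        s = self.samples
        return s[(s["season"] == season) & (s["treatment"] == treatment)]

    def t0_richness(self, season: str, treatment: str) -> int:
        """Number of ASVs detected (count > 0) in any t0 replicate of a condition."""
        cond = self.condition_samples(season, treatment)
        t0_cols = cond.index[cond["timepoint"] == "t0"]
        if len(t0_cols) == 0:
            return 0
        return int((self.counts[t0_cols].sum(axis=1) > 0).sum())

    # ------------------------------------------------------------------
    def validate(self) -> "ExperimentTable":
        """Check invariants; raise ``ValueError`` naming the offending item.

        Also aligns ``samples``/``totals``/``taxonomy`` to the count
        columns/rows, filling unknown taxonomy with all-unassigned
        lineages (with a warning).
        """
        counts = self.counts
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate asv_id(s): {dups}")
        if counts.columns.has_duplicates:
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dups}")
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            bad = counts.columns[np.any((vals < 0) | ~np.isfinite(vals), axis=0)]
            raise ValueError(f"negative or non-finite counts in sample(s): {list(bad)}")

        missing_meta = counts.columns.difference(self.samples.index)
        if len(missing_meta):
            raise ValueError(f"sample(s) missing from metadata: {sorted(missing_meta)}")
        missing_tot = counts.columns.difference(self.totals.index)
        if len(missing_tot):
            raise ValueError(
                f"sample(s) missing a cytometry total: {sorted(missing_tot)}"
            )

        samples = self.samples.loc[counts.columns, list(SAMPLE_COLUMNS)].copy()
        samples["treatment"] = samples["treatment"].map(normalize_treatment)
        samples["replicate"] = samples["replicate"].astype(int)
        samples["hours"] = samples["hours"].astype(float)
        if (samples["replicate"] < 1).any():
            bad = samples.index[samples["replicate"] < 1]
            raise ValueError(f"non-positive replicate number for sample(s): {list(bad)}")
        bad_tp = set(samples["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoint label(s): {sorted(bad_tp)}")

        totals = self.totals.loc[counts.columns].astype(float)
        if (totals <= 0).any() or not np.all(np.isfinite(totals)):
            bad = totals.index[(totals <= 0) | ~np.isfinite(totals)]
            raise ValueError(f"non-positive cytometry total for sample(s): {list(bad)}")

        key = samples[["season", "treatment", "timepoint", "replicate"]]
        if key.duplicated().any():
            bad = samples.index[key.duplicated()].tolist()
            raise ValueError(
                f"duplicated (season, treatment, timepoint, replicate): {bad}"
            )

        # hours must start at 0 at t0 and increase strictly through the series
        order = {tp: i for i, tp in enumerate(TIMEPOINTS)}
        for (season, treatment), grp in samples.groupby(
            ["season", "treatment"], sort=False, observed=True
        ):
            t0 = grp.loc[grp["timepoint"] == "t0", "hours"]
            if len(t0) and not np.allclose(t0, 0.0):
                raise ValueError(
                    f"hours at t0 must be 0 for condition ({season}, {treatment})"
                )
            mean_h = grp.groupby("timepoint")["hours"].mean()
            mean_h = mean_h.reindex(
                sorted(mean_h.index, key=order.get)
            )
            if not mean_h.is_monotonic_increasing or mean_h.duplicated().any():
                raise ValueError(
                    "hours must strictly increase along t0<t2<t3<t4 for "
                    f"condition ({season}, {treatment})"
                )

        taxonomy = self.taxonomy.reindex(columns=list(RANKS))
        missing_tax = counts.index.difference(taxonomy.index)
        if len(missing_tax):
            logger.warning(
                "%d ASV(s) missing from taxonomy; treated as fully unassigned",
                len(missing_tax),
            )
        taxonomy = taxonomy.reindex(counts.index)
        # an assigned rank implies all coarser ranks assigned
        assigned = taxonomy.notna().to_numpy()
        for j in range(1, assigned.shape[1]):
            bad = assigned[:, j] & ~assigned[:, j - 1]
            if bad.any():
                ids = taxonomy.index[bad].tolist()[:5]
                raise ValueError(
                    f"rank {RANKS[j]} assigned but {RANKS[j - 1]} unassigned "
                    f"for ASV(s) {ids}"
                )

        counts.index.name = "asv_id"
        counts.columns.name = "sample_id"
        samples.index.name = "sample_id"
        totals.index.name = "sample_id"
        taxonomy.index.name = "asv_id"
        self.counts = counts
        self.samples = samples
        self.totals = totals
        self.taxonomy = taxonomy
        return self
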
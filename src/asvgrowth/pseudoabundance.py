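"""Pseudoabundances: compositional read counts scaled to absolute cell densities.

Amplicon counts are compositional — per sample they only carry relative
information.  Multiplying each ASV's relative abundance by the sample's
total prokaryotic abundance from flow cytometry, and dividing by 100,
yields a per-ASV *pseudoabundance* in cells/mL on which exponential
growth can be fitted.  An optional correction divides counts by the
per-ASV 16S rRNA gene copy number before renormalising, since multi-copy
operons inflate read counts relative to cell numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import RANKS, ExperimentTable

logger = logging.getLogger(__name__)


@dataclass
class PseudoabundanceTable:
    """Per-ASV estimated cell densities (cells/mL) per sample.

    ``provenance`` is ``"raw"`` or ``"copy_corrected"``.  Column sums
    equal the cytometry totals by construction.
    """

    cells_per_ml: pd.DataFrame
    samples: pd.DataFrame
    provenance: str = "raw"


def relative_abundances(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundances in percent (columns sum to 100)."""
    depths = counts.sum(axis=0)
    zero = depths.index[depths <= 0]
    if len(zero):
        raise ValueError(f"zero-depth sample(s): {list(zero)}")
    return counts.div(depths, axis=1) * 100.0


def compute_pseudoabundance(rel: pd.DataFrame, totals: pd.Series) -> pd.DataFrame:
    """cells/mL = relative abundance (%) x cytometry total / 100."""
    missing = rel.columns.difference(totals.index)
    if len(missing):
        raise ValueError(f"sample(s) without a cytometry total: {sorted(missing)}")
    return rel.mul(totals.loc[rel.columns], axis=1) / 100.0


def impute_copy_numbers(
    copies: pd.Series, asv_ids: pd.Index, taxonomy: pd.DataFrame | None = None
) -> pd.Series:
    """Fill missing 16S copy numbers.

    The fallback chain per ASV is: mean copy number of the finest
    assigned taxonomic rank that has any data, then the global mean,
    then 1.  Each imputation is logged.
    """
    copies = copies.reindex(asv_ids).astype(float)
    missing = copies.index[copies.isna()]
    if not len(missing):
        return copies
    known = copies.dropna()
    global_mean = float(known.mean()) if len(known) else 1.0
    rank_means: dict[str, pd.Series] = {}
    if taxonomy is not None and len(known):
        tax = taxonomy.reindex(asv_ids)
        for rank in RANKS:
            grp = known.groupby(tax.loc[known.index, rank]).mean()
            rank_means[rank] = grp
    for asv in missing:
        value, source = global_mean if len(known) else 1.0, (
            "global mean" if len(known) else "default 1"
        )
        if taxonomy is not None and len(known):
            lineage = taxonomy.reindex(asv_ids).loc[asv]
            for rank in reversed(RANKS):
                label = lineage.get(rank)
                if pd.notna(label) and label in rank_means.get(rank, {}):
                    value = float(rank_means[rank][label])
                    source = f"{rank} mean ({label})"
                    break
        copies.loc[asv] = value
        logger.info("imputed copy number for %s: %.3g (%s)", asv, value, source)
    return copies


def copy_number_correct(
    counts: pd.DataFrame,
    copies: pd.Series,
    taxonomy: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Divide counts by per-ASV 16S copy numbers (real-valued output)."""
    copies = impute_copy_numbers(copies, counts.index, taxonomy)
    if (copies <= 0).any() or not np.all(np.isfinite(copies)):
        bad = copies.index[(copies <= 0) | ~np.isfinite(copies)].tolist()
        raise ValueError(f"non-positive copy number for ASV(s): {bad}")
    return counts.div(copies, axis=0)


def pseudoabundance_table(
    exp: ExperimentTable, copies: pd.Series | None = None
) -> PseudoabundanceTable:
    """Full pipeline step: counts -> (optional correction) -> cells/mL."""
    counts = exp.counts
    provenance = "raw"
    if copies is not None:
        counts = copy_number_correct(counts, copies, exp.taxonomy)
        provenance = "copy_corrected"
    rel = relative_abundances(counts)
    cells = compute_pseudoabundance(rel, exp.totals)
    return PseudoabundanceTable(
        cells_per_ml=cells, samples=exp.samples, provenance=provenance
    )
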
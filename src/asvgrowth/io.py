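"""Reading and writing of every tabular artifact of the pipeline.

All tables are plain UTF-8 TSV with a header row, ``.`` as the decimal
separator and ``NA`` for missing values.  Floats are written with 10
significant digits so that a write/read round trip is lossless at that
precision.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    RANKS,
    SAMPLE_COLUMNS,
    ExperimentTable,
    normalize_treatment,
)

logger = logging.getLogger(__name__)

#: 10 significant digits; enough for a lossless decimal round trip here.
FLOAT_FORMAT = "%.10g"
_NA = "NA"

RATE_COLUMNS = (
    "asv_id",
    "season",
    "treatment",
    "window",
    "slope_per_day",
    "p_value",
    "r_squared",
    "n_points",
)


def _read_tsv(path: str | os.PathLike, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=True, **kw)


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    """Write any DataFrame as TSV with the package-wide conventions."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, na_rep=_NA, index=index)


# ----------------------------------------------------------------------
# individual tables
# ----------------------------------------------------------------------

def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    counts = _read_tsv(path, index_col=0)
    counts.index.name = "asv_id"
    return counts


def _read_metadata_raw(path: str | os.PathLike) -> tuple[pd.DataFrame, pd.Index]:
    meta = _read_tsv(path, index_col=0)
    missing = set(SAMPLE_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks column(s): {sorted(missing)}")
    meta = meta[list(SAMPLE_COLUMNS)].copy()
    meta["treatment"] = meta["treatment"].map(normalize_treatment)
    # the design has no t1 sample; tolerate one in foreign metadata
    t1 = meta.index[meta["timepoint"] == "t1"]
    if len(t1):
        logger.warning("ignoring %d t1 sample(s): %s", len(t1), list(t1))
        meta = meta.drop(index=t1)
    return meta, t1


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    return _read_metadata_raw(path)[0]


def read_totals(path: str | os.PathLike) -> pd.Series:
    df = _read_tsv(path, index_col=0)
    col = "cells_per_ml" if "cells_per_ml" in df.columns else df.columns[0]
    return df[col].astype(float).rename("cells_per_ml")


def parse_silva_lineage(lineage: str) -> dict:
    """Split a SILVA-style ``d__...;p__...;...`` string into rank values.

    Bare semicolon-separated names (no ``d__`` prefixes) are accepted too;
    empty fields become unassigned.
    """
    out = dict.fromkeys(RANKS, np.nan)
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        return out
    parts = [p.strip() for p in str(lineage).split(";")]
    for rank, part in zip(RANKS, parts):
        if "__" in part:
            part = part.split("__", 1)[1]
        if part:
            out[rank] = part
    return out


def read_taxonomy(path: str | os.PathLike) -> pd.DataFrame:
    tax = _read_tsv(path, index_col=0)
    tax.index.name = "asv_id"
    if "lineage" in tax.columns:
        parsed = pd.DataFrame(
            [parse_silva_lineage(s) for s in tax["lineage"]], index=tax.index
        )
        return parsed[list(RANKS)]
    missing = set(RANKS) - set(tax.columns)
    if missing:
        raise ValueError(
            f"taxonomy needs a 'lineage' column or rank columns; missing {sorted(missing)}"
        )
    return tax[list(RANKS)]


def read_copy_numbers(path: str | os.PathLike) -> pd.Series:
    df = _read_tsv(path, index_col=0)
    col = "copy_number" if "copy_number" in df.columns else df.columns[0]
    copies = df[col].astype(float).rename("copy_number")
    if (copies.dropna() <= 0).any():
        bad = copies.index[copies <= 0].tolist()
        raise ValueError(f"non-positive 16S copy number for ASV(s): {bad}")
    return copies


def read_insitu(path: str | os.PathLike) -> pd.DataFrame:
    """In situ relative abundance (%) per ASV (rows) and season (columns)."""
    return _read_tsv(path, index_col=0)


def read_motu(path: str | os.PathLike) -> pd.DataFrame:
    """mOTU relative abundance (%) table, columns are t0/t4 sample ids."""
    return _read_tsv(path, index_col=0)


# ----------------------------------------------------------------------
# the joined experiment
# ----------------------------------------------------------------------

def read_experiment(
    count_path: str | os.PathLike,
    metadata_path: str | os.PathLike,
    totals_path: str | os.PathLike,
    taxonomy_path: str | os.PathLike,
) -> ExperimentTable:
    """Read and join counts, metadata, cytometry totals and taxonomy.

    Validation is strict: every count column must have metadata and a
    cytometry total, ASV ids must be unique and counts non-negative.
    Samples present in the metadata but absent from the counts (for
    example dropped t1 samples) are ignored.
    """
    counts = read_counts(count_path)
    meta, t1_ids = _read_metadata_raw(metadata_path)
    dropped = counts.columns.intersection(t1_ids)
    if len(dropped):
        counts = counts.drop(columns=dropped)
    totals = read_totals(totals_path)
    taxonomy = read_taxonomy(taxonomy_path)
    exp = ExperimentTable(
        counts=counts,
        samples=meta,
        totals=totals,
        taxonomy=taxonomy,
    )
    return exp.validate()


def write_experiment(exp: ExperimentTable, outdir: str | os.PathLike) -> dict:
    """Write the four experiment tables into ``outdir``; return their paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "counts": os.path.join(outdir, "counts.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "totals": os.path.join(outdir, "totals.tsv"),
        "taxonomy": os.path.join(outdir, "taxonomy.tsv"),
    }
    write_table(exp.counts, paths["counts"])
    meta = exp.samples.copy()
    meta.index.name = "sample_id"
    write_table(meta, paths["metadata"])
    totals = exp.totals.to_frame()
    totals.index.name = "sample_id"
    write_table(totals, paths["totals"])
    write_table(exp.taxonomy, paths["taxonomy"])
    return paths


# ----------------------------------------------------------------------
# growth-rate records
# ----------------------------------------------------------------------

def write_growth_rates(records: Iterable, path: str | os.PathLike) -> None:
    """Write accepted growth-rate records as an 8-column TSV.

    Rows are sorted by (asv_id, season, treatment) so output is
    bit-stable regardless of input order.  Use :func:`write_rate_audit`
    to keep discarded records with their status.
    """
    from .growth import records_to_frame  # local import avoids a cycle

    df = records_to_frame(records)
    df = df[list(RATE_COLUMNS)]
    df = df.sort_values(["asv_id", "season", "treatment"], kind="mergesort")
    write_table(df, path, index=False)


def write_rate_audit(records: Iterable, path: str | os.PathLike) -> None:
    """Write every record (accepted and discarded) with its status column."""
    from .growth import records_to_frame

    df = records_to_frame(records)
    df = df.sort_values(["asv_id", "season", "treatment"], kind="mergesort")
    write_table(df, path, index=False)


def read_growth_rates(path: str | os.PathLike) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = set(RATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth-rate table lacks column(s): {sorted(missing)}")
    return df
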
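"""End-to-end orchestration: read, estimate, contrast, classify, summarise.

``run_all`` chains every stage with a single configuration object,
writes all output TSVs and a machine-readable run manifest (versions,
configuration hash, row counts).  Any stage failure aborts with the
stage name attached.  The whole run is deterministic for a fixed
configuration: identical inputs produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from contextlib import contextmanager
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from . import io as aio
from .effects import community_mean_effect, compute_effects, condition_mean_rates
from .growth import (
    accepted_frame,
    estimate_asv_rates,
    estimate_bulk_rates,
    estimate_motu_rates,
    records_to_frame,
)
from .pseudoabundance import pseudoabundance_table
from .responsiveness import (
    exclusive_shared,
    fraction_responsive,
    rarity_table,
    responsive_sets,
)
from .summaries import condition_summary, rank_distributions

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage}: {cause}")
        self.stage = stage
        self.__cause__ = cause


@contextmanager
def _stage(name: str):
    logger.info("stage %s", name)
    try:
        yield
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise StageError(name, exc) from exc


@dataclass
class RunConfig:
    """Inputs, thresholds and options of one pipeline run."""

    counts: str
    metadata: str
    totals: str
    taxonomy: str
    outdir: str
    copy_numbers: str | None = None
    insitu: str | None = None
    motu: str | None = None
    alpha: float = 0.05
    responsive_threshold: float = 1.0
    fast_threshold: float = 2.0
    rare_threshold: float = 1.0
    very_rare_threshold: float = 0.1
    success_threshold: float = 1.0
    copy_correct: bool = False
    ranks: tuple[str, ...] = ("family", "order")
    min_obs: int = 2
    log_level: str = "INFO"

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        for name in (
            "responsive_threshold",
            "fast_threshold",
            "rare_threshold",
            "very_rare_threshold",
            "success_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(data.get("ranks"), list):
            data["ranks"] = tuple(data["ranks"])
        return cls(**data)

    @classmethod
    def from_dir(cls, indir: str, outdir: str, **kw) -> "RunConfig":
        """Point at a directory laid out like ``write_simulation`` output."""
        def p(name):
            path = os.path.join(indir, name)
            return path if os.path.exists(path) else None

        return cls(
            counts=os.path.join(indir, "counts.tsv"),
            metadata=os.path.join(indir, "metadata.tsv"),
            totals=os.path.join(indir, "totals.tsv"),
            taxonomy=os.path.join(indir, "taxonomy.tsv"),
            copy_numbers=p("copy_numbers.tsv"),
            insitu=p("insitu.tsv"),
            motu=p("motu.tsv"),
            outdir=outdir,
            **kw,
        )


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage; return the manifest (also written as JSON)."""
    os.makedirs(config.outdir, exist_ok=True)
    outputs: dict[str, pd.DataFrame] = {}

    with _stage("data_model_io"):
        exp = aio.read_experiment(
            config.counts, config.metadata, config.totals, config.taxonomy
        )
        copies = (
            aio.read_copy_numbers(config.copy_numbers)
            if config.copy_correct and config.copy_numbers
            else None
        )
        insitu = aio.read_insitu(config.insitu) if config.insitu else None
        motu = aio.read_motu(config.motu) if config.motu else None

    with _stage("pseudoabundance"):
        ptab = pseudoabundance_table(exp, copies=copies)

    with _stage("growth_estimation"):
        records = estimate_asv_rates(ptab, alpha=config.alpha)
        rates = accepted_frame(records)
        outputs["rates.tsv"] = rates
        outputs["rates_audit.tsv"] = records_to_frame(records)
        outputs["bulk_rates.tsv"] = records_to_frame(
            estimate_bulk_rates(exp.totals, exp.samples, alpha=config.alpha)
        )
        if motu is not None:
            outputs["motu_rates.tsv"] = estimate_motu_rates(
                motu, exp.samples, exp.totals
            )

    with _stage("treatment_effects"):
        for rank in ("asv",) + tuple(config.ranks):
            means = condition_mean_rates(records, exp.taxonomy, rank=rank)
            eff = compute_effects(means)
            outputs[f"effects_{rank}.tsv"] = eff
            outputs[f"community_effects_{rank}.tsv"] = community_mean_effect(eff)

    with _stage("responsiveness"):
        sets = responsive_sets(records, threshold=config.responsive_threshold)
        report = exclusive_shared(sets)
        cond = report.conditions.copy()
        fracs = []
        for row in cond.itertuples():
            richness = exp.t0_richness(row.season, row.treatment)
            fracs.append(
                fraction_responsive(sets[(row.season, row.treatment)], richness)
                if richness
                else float("nan")
            )
        cond["fraction_of_t0_richness"] = fracs
        outputs["responsive_conditions.tsv"] = cond
        outputs["responsive_pairs.tsv"] = report.pairs
        outputs["rarity.tsv"] = rarity_table(
            records,
            exp,
            insitu,
            responsive_threshold=config.responsive_threshold,
            fast_threshold=config.fast_threshold,
            rare_threshold=config.rare_threshold,
            very_rare_threshold=config.very_rare_threshold,
            success_threshold=config.success_threshold,
        )

    with _stage("summaries_stats"):
        outputs["summary_by_season.tsv"] = condition_summary(records, by="season")
        outputs["summary_by_treatment.tsv"] = condition_summary(records, by="treatment")
        cov_rows = []
        for rank in ("phylum", "class", "order", "family", "genus", "asv"):
            _, coverage = rank_distributions(
                records, exp.taxonomy, rank, min_obs=config.min_obs
            )
            cov_rows.append((rank, coverage))
        outputs["rank_coverage.tsv"] = pd.DataFrame(
            cov_rows, columns=["rank", "coverage"]
        )

    row_counts = {}
    for name, df in outputs.items():
        aio.write_table(df, os.path.join(config.outdir, name), index=False)
        row_counts[name] = int(len(df))

    manifest = {
        "package": "asvgrowth",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_sha256": _config_hash(config),
        "outputs": row_counts,
    }
    with open(os.path.join(config.outdir, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
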
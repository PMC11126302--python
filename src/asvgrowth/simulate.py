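"""Synthetic incubation experiments with known per-ASV growth rates.

The generator emulates the full manipulation-experiment design — four
seasons x six treatments x timepoints t0/t2/t3/t4 x replicate bottles —
so that every pipeline stage can be exercised against ground truth.

Model
-----
Each ASV is a non-grower (mu = 0), a decliner (mu < 0) or a grower with
mu drawn uniformly from a configurable range (default 0.3-10 d^-1, the
span typically observed in such experiments).  Grower rates are scaled
per season and shifted additively per treatment (globally and/or for
tagged ASV subsets); trajectories are exponential, optionally switching
to logistic saturation towards a carrying capacity after an onset time.
Observation layers: multinomial read sampling at a fixed depth (or an
exact-proportions mode for deterministic tests), lognormal multiplicative
noise on the cytometry totals, an in situ profile with a detection
limit, and a t0/t4 mOTU relative-abundance table with optional Dirichlet
resampling noise.

Random streams are partitioned per (season, treatment) so that adding a
treatment never perturbs the draws of existing ones.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import io as aio
from .datamodel import RANKS, SEASONS, TREATMENTS, ExperimentTable

__all__ = [
    "SimConfig",
    "SaturationSpec",
    "SubsetShift",
    "GroundTruth",
    "SimulatedExperiment",
    "exponential_density",
    "logistic_density",
    "simulate_trajectories",
    "sample_experiment",
    "simulate_experiment",
    "write_simulation",
]

DEFAULT_TIMEPOINT_HOURS = {"t0": 0.0, "t2": 24.0, "t3": 48.0, "t4": 72.0}
#: t0 cytometry totals per season (cells/mL), typical NW Mediterranean values.
DEFAULT_SEASON_TOTALS = {
    "winter": 1.04e6,
    "spring": 1.01e6,
    "summer": 7.28e5,
    "fall": 1.58e6,
}
#: Seasonal scaling of grower rates: faster growth in the warm seasons
#: bracketing the summer maximum, slower in spring/fall.
DEFAULT_SEASON_SCALE = {"winter": 1.1, "spring": 0.7, "summer": 1.25, "fall": 0.75}
#: Additive rate shifts (d^-1) for treatments that relax limiting factors.
DEFAULT_TREATMENT_SHIFTS = {
    "CL": 0.0,
    "CD": 0.0,
    "PL": 0.0,
    "PD": 0.1,
    "DL": 0.4,
    "VL": 0.7,
}


@dataclass(frozen=True)
class SaturationSpec:
    """Logistic saturation applied to a subset of ASVs.

    Growth is exponential until ``onset_hours``, then follows a logistic
    towards K = ``capacity_factor`` x density at onset.
    """

    asv_ids: tuple[str, ...]
    onset_hours: float = 48.0
    capacity_factor: float = 2.0


@dataclass(frozen=True)
class SubsetShift:
    """Extra additive rate shift for tagged ASVs in one treatment."""

    treatment: str
    delta_mu: float
    asv_ids: tuple[str, ...]


@dataclass(frozen=True)
class SimConfig:
    """Design and noise parameters of a synthetic experiment.

    Defaults mirror the emulated study: 4 seasons x 6 treatments,
    timepoints at 0/24/48/72 h, 3 replicate bottles, ~3000 ASVs and a
    sequencing depth of 5x10^4 reads with 10% cytometry CV.  Scale
    ``n_asvs``/``seasons``/``treatments`` down for fast tests.
    """

    n_asvs: int = 3000
    seasons: tuple[str, ...] = SEASONS
    treatments: tuple[str, ...] = TREATMENTS
    timepoint_hours: dict = field(
        default_factory=lambda: dict(DEFAULT_TIMEPOINT_HOURS)
    )
    n_replicates: int = 3
    depth: int = 50_000
    frac_nongrowers: float = 0.30
    frac_decliners: float = 0.20
    mu_range: tuple[float, float] = (0.3, 10.0)
    decline_range: tuple[float, float] = (-2.0, -0.2)
    season_scale: dict = field(default_factory=lambda: dict(DEFAULT_SEASON_SCALE))
    treatment_shifts: dict = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_SHIFTS)
    )
    subset_shifts: tuple[SubsetShift, ...] = ()
    saturation: SaturationSpec | None = None
    cytometry_cv: float = 0.10
    season_total_cells: dict = field(
        default_factory=lambda: dict(DEFAULT_SEASON_TOTALS)
    )
    n0_sigma: float = 1.0
    copy_number_range: tuple[int, int] = (1, 15)
    undetected_fraction: float = 0.2
    motu_dirichlet: float | None = 5000.0
    #: relative abundances (%) below this are reported as 0 in the mOTU
    #: table, mimicking the detection floor of metagenomic profilers
    motu_detection_percent: float = 0.01
    exact_counts: bool = False
    n_phyla: int = 6
    seed: int = 0

    def asv_ids(self) -> list[str]:
        return [f"ASV_{i + 1:04d}" for i in range(self.n_asvs)]

    def hours(self) -> dict:
        return dict(self.timepoint_hours)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


# ----------------------------------------------------------------------
# growth models
# ----------------------------------------------------------------------

def exponential_density(n0, mu, days):
    """n(t) = n0 * exp(mu * t), t in days, mu in d^-1."""
    return np.asarray(n0) * np.exp(np.asarray(mu) * np.asarray(days))


def logistic_density(n0, mu, K, days):
    """Logistic n(t) = K / (1 + ((K - n0)/n0) exp(-mu t)); K = n0 is flat."""
    n0 = np.asarray(n0, dtype=float)
    K = np.asarray(K, dtype=float)
    return K / (1.0 + ((K - n0) / n0) * np.exp(-np.asarray(mu) * np.asarray(days)))


def _trajectory(
    n0: np.ndarray,
    mu: np.ndarray,
    hours: np.ndarray,
    saturation: SaturationSpec | None,
    sat_mask: np.ndarray,
) -> np.ndarray:
    """Densities (n_asv x n_timepoints); exponential with optional late logistic."""
    days = hours / 24.0
    dens = exponential_density(n0[:, None], mu[:, None], days[None, :])
    if saturation is not None and sat_mask.any():
        onset_d = saturation.onset_hours / 24.0
        grow = sat_mask & (mu > 0)
        if grow.any():
            n_on = exponential_density(n0[grow], mu[grow], onset_d)
            K = saturation.capacity_factor * n_on
            late = days > onset_d
            if late.any():
                dens[np.ix_(grow, late)] = logistic_density(
                    n_on[:, None], mu[grow][:, None], K[:, None],
                    (days[late] - onset_d)[None, :],
                )
    return dens


# ----------------------------------------------------------------------
# ground truth
# ----------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True rates, densities and annotations behind a simulated experiment."""

    config: SimConfig
    asv_ids: list[str]
    asv_type: pd.Series  # grower | nongrower | decliner
    mu: dict  # (season, treatment) -> np.ndarray aligned with asv_ids
    n0: pd.DataFrame  # asv x season, cells/mL
    densities: dict  # (season, treatment) -> DataFrame asv x timepoint
    taxonomy: pd.DataFrame
    copy_numbers: pd.Series

    def density(self, season: str, treatment: str) -> pd.DataFrame:
        return self.densities[(season, treatment)]

    def mu_frame(self) -> pd.DataFrame:
        """Tidy ground truth with responsive (mu > 1) and rare flags."""
        rows = []
        for season in self.config.seasons:
            rel0 = self.n0[season] / self.n0[season].sum() * 100.0
            for treatment in self.config.treatments:
                mu = self.mu[(season, treatment)]
                for i, asv in enumerate(self.asv_ids):
                    rows.append(
                        (
                            asv, season, treatment, mu[i],
                            bool(mu[i] > 1.0), bool(rel0.iloc[i] < 1.0),
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["asv_id", "season", "treatment", "mu_true", "responsive", "rare"],
        )


def _make_taxonomy(asv_ids: list[str], n_phyla: int, rng: np.random.Generator) -> pd.DataFrame:
    """Nested random taxonomy: binary splits below randomly drawn phyla."""
    n = len(asv_ids)
    phyla = rng.integers(0, n_phyla, size=n)
    splits = {rank: rng.integers(0, 2, size=n) for rank in RANKS[2:]}
    rows = []
    for i in range(n):
        lineage = {"domain": "Bacteria", "phylum": f"Phylum{phyla[i] + 1}"}
        parent = lineage["phylum"]
        for rank in RANKS[2:]:
            parent = f"{parent}.{rank[0]}{splits[rank][i] + 1}"
            lineage[rank] = parent
        rows.append(lineage)
    return pd.DataFrame(rows, index=pd.Index(asv_ids, name="asv_id"))[list(RANKS)]


def simulate_trajectories(config: SimConfig) -> GroundTruth:
    """Draw per-ASV parameters and solve the growth model exactly."""
    asv_ids = config.asv_ids()
    n = config.n_asvs
    rng = np.random.default_rng([config.seed, 0])

    u = rng.random(n)
    asv_type = np.where(
        u < config.frac_nongrowers,
        "nongrower",
        np.where(u < config.frac_nongrowers + config.frac_decliners, "decliner", "grower"),
    )
    mu_base = np.zeros(n)
    growers = asv_type == "grower"
    decliners = asv_type == "decliner"
    mu_base[growers] = rng.uniform(*config.mu_range, size=int(growers.sum()))
    mu_base[decliners] = rng.uniform(*config.decline_range, size=int(decliners.sum()))

    n0 = {}
    for season in config.seasons:
        raw = rng.lognormal(mean=0.0, sigma=config.n0_sigma, size=n)
        total = config.season_total_cells.get(season, 1.0e6)
        n0[season] = raw / raw.sum() * total
    n0 = pd.DataFrame(n0, index=pd.Index(asv_ids, name="asv_id"))

    taxonomy = _make_taxonomy(asv_ids, config.n_phyla, rng)
    lo, hi = config.copy_number_range
    copies = pd.Series(
        rng.integers(lo, hi + 1, size=n).astype(float),
        index=pd.Index(asv_ids, name="asv_id"),
        name="copy_number",
    )

    idx = {a: i for i, a in enumerate(asv_ids)}
    subset_delta = {}
    for shift in config.subset_shifts:
        delta = subset_delta.setdefault(shift.treatment, np.zeros(n))
        for a in shift.asv_ids:
            delta[idx[a]] += shift.delta_mu
    sat_mask = np.zeros(n, dtype=bool)
    if config.saturation is not None:
        for a in config.saturation.asv_ids:
            sat_mask[idx[a]] = True

    hours = np.array([config.timepoint_hours[tp] for tp in config.timepoint_hours])
    tp_labels = list(config.timepoint_hours)
    mu_all, densities = {}, {}
    for season in config.seasons:
        scale = config.season_scale.get(season, 1.0)
        for treatment in config.treatments:
            shift = config.treatment_shifts.get(treatment, 0.0)
            mu = mu_base.copy()
            mu[growers] = mu_base[growers] * scale + shift
            mu[growers] += subset_delta.get(treatment, np.zeros(n))[growers]
            mu_all[(season, treatment)] = mu
            dens = _trajectory(
                n0[season].to_numpy(), mu, hours, config.saturation, sat_mask
            )
            densities[(season, treatment)] = pd.DataFrame(
                dens, index=n0.index, columns=tp_labels
            )
    return GroundTruth(
        config=config,
        asv_ids=asv_ids,
        asv_type=pd.Series(asv_type, index=n0.index, name="asv_type"),
        mu=mu_all,
        n0=n0,
        densities=densities,
        taxonomy=taxonomy,
        copy_numbers=copies,
    )


# ----------------------------------------------------------------------
# observation layers
# ----------------------------------------------------------------------

@dataclass
class SimulatedExperiment:
    """Observable tables plus the ground truth they were sampled from."""

    experiment: ExperimentTable
    insitu: pd.DataFrame  # asv x season, % (NaN = below detection)
    motu: pd.DataFrame  # motu (= asv) x t0/t4 sample ids, %
    truth: GroundTruth


def _sample_id(season: str, treatment: str, tp: str, rep: int) -> str:
    return f"{season}_{treatment}_{tp}_r{rep}"


def sample_experiment(truth: GroundTruth, config: SimConfig | None = None) -> SimulatedExperiment:
    """Apply sequencing, cytometry and profiling noise to the ground truth."""
    config = config or truth.config
    tp_labels = list(config.timepoint_hours)
    counts_cols, meta_rows, totals = {}, [], {}
    motu_cols = {}
    s2 = np.log1p(config.cytometry_cv**2)

    for si, season in enumerate(config.seasons):
        for ti, treatment in enumerate(config.treatments):
            rng = np.random.default_rng([config.seed, 7, si, ti])
            motu_rng = np.random.default_rng([config.seed, 11, si, ti])
            dens = truth.densities[(season, treatment)]
            for tp in tp_labels:
                nvec = dens[tp].to_numpy()
                total_true = float(nvec.sum())
                p = nvec / total_true
                for rep in range(1, config.n_replicates + 1):
                    sid = _sample_id(season, treatment, tp, rep)
                    if config.exact_counts:
                        counts_cols[sid] = config.depth * p
                    else:
                        counts_cols[sid] = rng.multinomial(config.depth, p)
                    if config.cytometry_cv > 0:
                        noise = rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2))
                    else:
                        noise = 1.0
                    totals[sid] = total_true * noise
                    meta_rows.append(
                        (
                            sid, season, treatment, tp, rep,
                            config.timepoint_hours[tp],
                        )
                    )
                    if tp in ("t0", "t4"):
                        if config.motu_dirichlet:
                            alpha = p * config.motu_dirichlet + 1e-9
                            q = motu_rng.dirichlet(alpha)
                        else:
                            q = p.copy()
                        q = q * 100.0
                        q[q < config.motu_detection_percent] = 0.0
                        motu_cols[sid] = q

    index = pd.Index(truth.asv_ids, name="asv_id")
    counts = pd.DataFrame(counts_cols, index=index)
    if not config.exact_counts:
        counts = counts.astype(np.int64)
    samples = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "season", "treatment", "timepoint", "replicate", "hours"],
    ).set_index("sample_id")
    totals = pd.Series(totals, name="cells_per_ml")

    insitu = {}
    for season in config.seasons:
        rel0 = truth.n0[season] / truth.n0[season].sum() * 100.0
        n_keep = int(round((1.0 - config.undetected_fraction) * len(rel0)))
        order = sorted(rel0.index, key=lambda a: (-rel0[a], str(a)))
        detected = set(order[:n_keep])
        insitu[season] = rel0.where(rel0.index.isin(detected))
    insitu = pd.DataFrame(insitu)

    motu = pd.DataFrame(motu_cols, index=index.rename("motu_id"))

    exp = ExperimentTable(
        counts=counts, samples=samples, totals=totals, taxonomy=truth.taxonomy
    ).validate()
    return SimulatedExperiment(experiment=exp, insitu=insitu, motu=motu, truth=truth)


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Convenience wrapper: trajectories + observation layers."""
    return sample_experiment(simulate_trajectories(config))


def write_simulation(sim: SimulatedExperiment, outdir: str | os.PathLike) -> dict:
    """Write every table a pipeline run consumes, plus the ground truth."""
    os.makedirs(outdir, exist_ok=True)
    paths = aio.write_experiment(sim.experiment, outdir)
    paths["copy_numbers"] = os.path.join(outdir, "copy_numbers.tsv")
    aio.write_table(sim.truth.copy_numbers.to_frame(), paths["copy_numbers"])
    paths["insitu"] = os.path.join(outdir, "insitu.tsv")
    aio.write_table(sim.insitu, paths["insitu"])
    paths["motu"] = os.path.join(outdir, "motu.tsv")
    aio.write_table(sim.motu, paths["motu"])
    paths["ground_truth"] = os.path.join(outdir, "ground_truth.tsv")
    aio.write_table(sim.truth.mu_frame(), paths["ground_truth"], index=False)
    return paths
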
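"""Growth-rate estimation by window-selected log-linear regression.

Assuming exponential growth, ln(cells/mL) is linear in time and the OLS
slope (per day) is the specific growth rate mu.  Because abundances can
saturate towards the end of an incubation, two candidate windows are
fitted for every ASV and condition — t0-t2-t3 and t0-t2-t3-t4 — and the
steeper of the significantly positive slopes is kept as the maximal
growth rate.  Replicate bottles enter the regression as individual
points.  Non-significant and non-positive slopes are retained as
discarded records for audit: with compositional data a taxon displaced
by fast growers can show a spuriously negative slope, so negative rates
are never interpreted as death rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import BULK_ID, SEASONS, TREATMENTS
from .pseudoabundance import PseudoabundanceTable

#: Candidate regression windows (timepoint labels included in the fit).
WINDOWS = {
    "t0t2t3": ("t0", "t2", "t3"),
    "t0t2t3t4": ("t0", "t2", "t3", "t4"),
}

ACCEPTED = "accepted"
NONSIGNIFICANT = "discarded_nonsignificant"
NONPOSITIVE = "discarded_nonpositive"
INSUFFICIENT = "discarded_insufficient"

DEFAULT_ALPHA = 0.05
#: slopes smaller than this magnitude (d^-1) are numerically indistinguishable
#: from zero (float rounding in the pseudoabundance arithmetic) and are never
#: treated as positive or as significantly negative
ZERO_SLOPE_TOL = 1e-9


@dataclass(frozen=True)
class RegressionFit:
    """OLS of ln(pseudoabundance) on time in days."""

    slope: float  # d^-1
    intercept: float  # ln cells/mL at t0
    p_value: float  # two-sided t-test on the slope
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class GrowthRateRecord:
    """One per-ASV-per-condition rate (accepted or discarded, for audit)."""

    asv_id: str
    season: str
    treatment: str
    window: str | None
    slope_per_day: float
    p_value: float
    r_squared: float
    n_points: int
    status: str


def records_to_frame(records) -> pd.DataFrame:
    """Tidy DataFrame view of a record iterable (or pass a frame through)."""
    if isinstance(records, pd.DataFrame):
        return records
    cols = [f.name for f in fields(GrowthRateRecord)]
    return pd.DataFrame([[getattr(r, c) for c in cols] for r in records], columns=cols)


def accepted_frame(records) -> pd.DataFrame:
    df = records_to_frame(records)
    return df[df["status"] == ACCEPTED].reset_index(drop=True)


# ----------------------------------------------------------------------
# regression primitives
# ----------------------------------------------------------------------

def fit_log_linear(times_days, pseudo) -> RegressionFit | None:
    """OLS of ln(pseudo) on time (days); None when under-determined.

    Requires >= 3 points over >= 2 distinct times; all pseudoabundances
    must be strictly positive (zeros are dropped upstream since ln is
    undefined).  A perfectly flat series has slope 0 with an undefined
    (NaN) p-value, which downstream never counts as significant.
    """
    t = np.asarray(times_days, dtype=float)
    y = np.asarray(pseudo, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and pseudoabundances differ in length")
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite input to regression")
    if np.any(y <= 0):
        raise ValueError("pseudoabundances must be strictly positive (drop zeros)")
    if t.size < 3 or np.unique(t).size < 2:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.linregress(t, np.log(y))
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else float("nan")
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
        r_squared=r2,
        n_points=int(t.size),
    )


def _significant(fit: RegressionFit, alpha: float) -> bool:
    return math.isfinite(fit.p_value) and fit.p_value < alpha


def select_window(
    fit3: RegressionFit | None,
    fit4: RegressionFit | None,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[str, str | None, RegressionFit | None]:
    """Pick the maximal significant positive slope among the two windows.

    Returns ``(status, window, fit)``.  Among fits with slope > 0 and
    p < alpha the larger slope wins; ties go to the smaller p, then to
    the longer window.  If nothing qualifies the status distinguishes a
    significantly non-positive slope from plain non-significance, and
    the better-supported fit is kept for audit.
    """
    candidates = [(w, f) for w, f in (("t0t2t3", fit3), ("t0t2t3t4", fit4)) if f]
    if not candidates:
        return INSUFFICIENT, None, None
    qualifying = [
        (w, f)
        for w, f in candidates
        if f.slope > ZERO_SLOPE_TOL and _significant(f, alpha)
    ]
    if qualifying:
        window, fit = min(
            qualifying,
            key=lambda wf: (-wf[1].slope, wf[1].p_value, wf[0] != "t0t2t3t4"),
        )
        return ACCEPTED, window, fit
    if any(f.slope < -ZERO_SLOPE_TOL and _significant(f, alpha) for _, f in candidates):
        status = NONPOSITIVE
    else:
        status = NONSIGNIFICANT
    # keep the best-supported fit for the audit trail
    window, fit = min(
        candidates,
        key=lambda wf: (
            wf[1].p_value if math.isfinite(wf[1].p_value) else float("inf")
        ),
    )
    return status, window, fit


def _make_record(
    asv_id: str,
    season: str,
    treatment: str,
    fit3: RegressionFit | None,
    fit4: RegressionFit | None,
    alpha: float,
) -> GrowthRateRecord:
    status, window, fit = select_window(fit3, fit4, alpha)
    if fit is None:
        return GrowthRateRecord(
            asv_id, season, treatment, None,
            float("nan"), float("nan"), float("nan"), 0, status,
        )
    return GrowthRateRecord(
        asv_id, season, treatment, window,
        fit.slope, fit.p_value, fit.r_squared, fit.n_points, status,
    )


# ----------------------------------------------------------------------
# per-ASV and bulk estimation
# ----------------------------------------------------------------------

def _condition_order(samples: pd.DataFrame) -> list[tuple[str, str]]:
    seen = samples[["season", "treatment"]].drop_duplicates()
    known_s = {s: i for i, s in enumerate(SEASONS)}
    known_t = {t: i for i, t in enumerate(TREATMENTS)}
    return sorted(
        map(tuple, seen.to_numpy()),
        key=lambda st: (known_s.get(st[0], 99), st[0], known_t.get(st[1], 99), st[1]),
    )


def estimate_asv_rates(
    pseudo: PseudoabundanceTable, alpha: float = DEFAULT_ALPHA
) -> list[GrowthRateRecord]:
    """Dual-window regression for every (ASV, season, treatment).

    Replicate observations are pooled as individual points, zero
    pseudoabundances are dropped, and a window is fit only when >= 3
    points over >= 2 distinct timepoints remain.  One record per ASV and
    condition is emitted, including discarded ones with their status.
    """
    cells = pseudo.cells_per_ml
    samples = pseudo.samples
    records: list[GrowthRateRecord] = []
    for season, treatment in _condition_order(samples):
        cond = samples[
            (samples["season"] == season) & (samples["treatment"] == treatment)
        ]
        cols = cond.index
        days = (cond["hours"] / 24.0).to_numpy()
        tps = cond["timepoint"].to_numpy()
        window_masks = {
            w: np.isin(tps, labels) for w, labels in WINDOWS.items()
        }
        block = cells[cols].to_numpy()
        for i, asv in enumerate(cells.index):
            row = block[i]
            pos = row > 0
            fits: dict[str, RegressionFit | None] = {}
            for w, wmask in window_masks.items():
                m = pos & wmask
                if m.sum() >= 3 and np.unique(days[m]).size >= 2:
                    fits[w] = fit_log_linear(days[m], row[m])
                else:
                    fits[w] = None
            records.append(
                _make_record(asv, season, treatment, fits["t0t2t3"], fits["t0t2t3t4"], alpha)
            )
    return records


def bulk_rate(
    totals: pd.Series,
    samples: pd.DataFrame,
    season: str,
    treatment: str,
    alpha: float = DEFAULT_ALPHA,
) -> GrowthRateRecord:
    """Dual-window regression on total cell counts of one condition."""
    cond = samples[
        (samples["season"] == season) & (samples["treatment"] == treatment)
    ]
    days = (cond["hours"] / 24.0).to_numpy()
    tps = cond["timepoint"].to_numpy()
    vals = totals.loc[cond.index].to_numpy(dtype=float)
    fits = {}
    for w, labels in WINDOWS.items():
        m = np.isin(tps, labels) & (vals > 0)
        if m.sum() >= 3 and np.unique(days[m]).size >= 2:
            fits[w] = fit_log_linear(days[m], vals[m])
        else:
            fits[w] = None
    return _make_record(BULK_ID, season, treatment, fits["t0t2t3"], fits["t0t2t3t4"], alpha)


def estimate_bulk_rates(
    totals: pd.Series, samples: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> list[GrowthRateRecord]:
    return [
        bulk_rate(totals, samples, season, treatment, alpha)
        for season, treatment in _condition_order(samples)
    ]


# ----------------------------------------------------------------------
# mOTU endpoint fold-change rates
# ----------------------------------------------------------------------

def motu_rate(
    rel_t0,
    rel_t4,
    total_t0: float,
    total_t4: float,
    elapsed_hours: float,
) -> float:
    """Growth rate (d^-1) from a t0->t4 abundance fold change.

    Mean relative abundances over replicates are scaled by the cytometry
    totals at each end; the rate is ln(fold change) / elapsed_hours * 24.
    NaN when either endpoint mean abundance is zero.
    """
    if elapsed_hours <= 0:
        raise ValueError("elapsed_hours must be positive")
    if total_t0 <= 0 or total_t4 <= 0:
        raise ValueError("totals must be positive")
    a0 = float(np.mean(np.asarray(rel_t0, dtype=float))) * total_t0 / 100.0
    a4 = float(np.mean(np.asarray(rel_t4, dtype=float))) * total_t4 / 100.0
    if a0 <= 0 or a4 <= 0:
        return float("nan")
    fold = a4 / a0
    return math.log(fold) / elapsed_hours * 24.0


def estimate_motu_rates(
    motu_rel: pd.DataFrame, samples: pd.DataFrame, totals: pd.Series
) -> pd.DataFrame:
    """Endpoint fold-change rates for every mOTU and condition.

    ``motu_rel`` holds relative abundances (%) with t0/t4 sample ids as
    columns; sample metadata and cytometry totals are shared with the
    amplicon experiment.  Conditions missing either endpoint are skipped.
    """
    out = []
    meta = samples.loc[samples.index.intersection(motu_rel.columns)]
    for season, treatment in _condition_order(meta):
        cond = meta[(meta["season"] == season) & (meta["treatment"] == treatment)]
        c0 = cond.index[cond["timepoint"] == "t0"]
        c4 = cond.index[cond["timepoint"] == "t4"]
        if not len(c0) or not len(c4):
            continue
        elapsed = float(cond.loc[c4, "hours"].mean() - cond.loc[c0, "hours"].mean())
        tot0 = float(totals.loc[c0].mean())
        tot4 = float(totals.loc[c4].mean())
        for motu in motu_rel.index:
            rate = motu_rate(
                motu_rel.loc[motu, c0], motu_rel.loc[motu, c4], tot0, tot4, elapsed
            )
            out.append((motu, season, treatment, rate))
    return pd.DataFrame(
        out, columns=["motu_id", "season", "treatment", "rate_per_day"]
    )
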
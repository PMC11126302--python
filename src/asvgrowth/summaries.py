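"""Distribution summaries, probe-group pooling and normality-gated statistics.

The statistical conventions follow common microbial-ecology practice:
normality is screened with the Shapiro-Wilk test, and the parametric or
rank-based alternative is chosen accordingly — Pearson vs Spearman for
correlations, ANOVA + Tukey HSD vs Kruskal-Wallis + Dunn (Holm-adjusted)
for group comparisons, the latter summarised as a compact letter display.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .datamodel import RANKS
from .growth import accepted_frame

logger = logging.getLogger(__name__)

DEFAULT_MIN_OBS = 2
SHAPIRO_ALPHA = 0.05


# ----------------------------------------------------------------------
# moments per condition
# ----------------------------------------------------------------------

def condition_summary(records, by: str = "season") -> pd.DataFrame:
    """n, mean, sd, CV (%) and median of accepted rates per group.

    ``by`` is ``"season"``, ``"treatment"`` or ``"condition"`` (both).
    """
    df = accepted_frame(records)
    keys = {"season": ["season"], "treatment": ["treatment"],
            "condition": ["season", "treatment"]}[by]

    def _agg(g: pd.Series) -> pd.Series:
        n = g.size
        mean = g.mean()
        sd = g.std(ddof=1) if n > 1 else 0.0
        cv = 100.0 * sd / mean if mean > 0 else float("nan")
        return pd.Series(
            {"n": n, "mean": mean, "sd": sd, "cv_percent": cv, "median": g.median()}
        )

    out = (
        df.groupby(keys, observed=True)["slope_per_day"].apply(_agg).unstack()
    )
    out["n"] = out["n"].astype(int)
    return out.reset_index()


# ----------------------------------------------------------------------
# rank-resolved distributions
# ----------------------------------------------------------------------

def _group_keys(taxonomy: pd.DataFrame, rank: str) -> pd.Series:
    """Lineage-prefix group key per ASV at the requested rank.

    Grouping by the full lineage prefix (not the bare rank name) means
    groups strictly split as the rank gets finer, which keeps the
    retained-rate coverage monotonically non-increasing.  ASVs
    unassigned at some rank are pooled as ``unclassified_<parent>``.
    """
    ranks = ("asv",) + tuple(reversed(RANKS))
    if rank == "asv":
        return pd.Series(taxonomy.index, index=taxonomy.index, name="group")
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    upto = RANKS[: RANKS.index(rank) + 1]
    keys = []
    for asv in taxonomy.index:
        lineage = []
        for r in upto:
            v = taxonomy.loc[asv, r]
            lineage.append(str(v) if pd.notna(v) else "unclassified")
        keys.append(";".join(lineage))
    return pd.Series(keys, index=taxonomy.index, name="group")


def rank_distributions(
    records,
    taxonomy: pd.DataFrame,
    rank: str,
    min_obs: int = DEFAULT_MIN_OBS,
) -> tuple[pd.DataFrame, float]:
    """Growth-rate distributions per group at a rank, plus coverage.

    Groups (lineage prefixes at the rank, or single ASVs) are retained
    when they hold at least ``min_obs`` accepted rates over all
    experiments.  Coverage is the fraction of all accepted rates that
    fall in retained groups; it declines towards finer ranks as groups
    split below the threshold.
    """
    df = accepted_frame(records)
    total = len(df)
    if rank == "asv":
        df = df.assign(group=df["asv_id"], label=df["asv_id"])
    else:
        keys = _group_keys(taxonomy, rank)
        df = df.assign(group=df["asv_id"].map(keys))
        df = df.dropna(subset=["group"])
        df = df.assign(label=df["group"].str.split(";").str[-1])
    rows = []
    kept = 0
    for (group, label), grp in df.groupby(["group", "label"], observed=True):
        rates = grp["slope_per_day"]
        if len(rates) < min_obs:
            continue
        kept += len(rates)
        mean = rates.mean()
        sd = rates.std(ddof=1) if len(rates) > 1 else 0.0
        rows.append(
            (
                rank, group, label, len(rates), mean, sd,
                100.0 * sd / mean if mean > 0 else float("nan"),
            )
        )
    out = pd.DataFrame(
        rows, columns=["rank", "group", "label", "n", "mean", "sd", "cv_percent"]
    ).sort_values("group", kind="mergesort").reset_index(drop=True)
    coverage = kept / total if total else float("nan")
    return out, coverage


# ----------------------------------------------------------------------
# probe-group pooling
# ----------------------------------------------------------------------

def match_probe(
    taxonomy: pd.DataFrame, clauses: list[tuple[str, str]]
) -> pd.Index:
    """ASVs matching any (rank, value) clause of a probe's target group."""
    mask = np.zeros(len(taxonomy), dtype=bool)
    for rank, value in clauses:
        if rank == "asv":
            mask |= np.asarray(taxonomy.index == value)
        elif rank in RANKS:
            mask |= (taxonomy[rank] == value).to_numpy()
        else:
            raise ValueError(f"probe clause names unknown rank {rank!r}")
    return taxonomy.index[mask]


def pool_probe_groups(
    records,
    taxonomy: pd.DataFrame,
    probes: dict[str, list[tuple[str, str]]],
) -> pd.DataFrame:
    """Mean accepted rate per (probe, season, treatment).

    Mimics comparing CARD-FISH subcommunity counts with sequence-derived
    rates: each probe targets the union of its taxonomy clauses, and an
    ASV matching several probes contributes to all of them.
    """
    df = accepted_frame(records)
    rows = []
    for probe, clauses in probes.items():
        members = match_probe(taxonomy, clauses)
        sub = df[df["asv_id"].isin(members)]
        if sub.empty:
            logger.warning("probe %s matches no ASV with accepted rates", probe)
            continue
        grp = sub.groupby(["season", "treatment"], observed=True)["slope_per_day"]
        for (season, treatment), rates in grp:
            rows.append((probe, season, treatment, rates.mean(), len(rates)))
    return pd.DataFrame(
        rows, columns=["probe", "season", "treatment", "mean_rate", "n"]
    )


# ----------------------------------------------------------------------
# normality-gated correlation
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MethodComparison:
    """A correlation between paired method outputs, with the gate's choice."""

    n: int
    method: str  # "pearson" | "spearman"
    coefficient: float
    p_value: float
    shapiro_p_x: float
    shapiro_p_y: float


def gated_correlation(x, y, shapiro_alpha: float = SHAPIRO_ALPHA) -> MethodComparison:
    """Pearson when both vectors pass Shapiro-Wilk, else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y differ in length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return MethodComparison(
            int(x.size), "pearson", float("nan"), float("nan"),
            float("nan"), float("nan"),
        )
    px = float(stats.shapiro(x).pvalue)
    py = float(stats.shapiro(y).pvalue)
    if px >= shapiro_alpha and py >= shapiro_alpha:
        res = stats.pearsonr(x, y)
        method = "pearson"
    else:
        res = stats.spearmanr(x, y)
        method = "spearman"
    return MethodComparison(
        n=int(x.size),
        method=method,
        coefficient=float(res.statistic),
        p_value=float(res.pvalue),
        shapiro_p_x=px,
        shapiro_p_y=py,
    )


# ----------------------------------------------------------------------
# group comparisons with compact letters
# ----------------------------------------------------------------------

@dataclass
class GroupComparison:
    method: str  # "tukey" | "dunn"
    omnibus: str  # "anova" | "kruskal"
    omnibus_stat: float
    omnibus_p: float
    pairwise: pd.DataFrame  # group_a, group_b, p_adj, reject
    letters: dict[str, str]


def dunn_test(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's post hoc z-tests on rank sums, Holm-adjusted.

    Uses the tie-corrected variance N(N+1)/12 - sum(t^3 - t)/(12(N-1)).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    n = values.size
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    labels = sorted(pd.unique(groups).tolist())
    mean_ranks = {g: ranks[groups == g].mean() for g in labels}
    sizes = {g: int((groups == g).sum()) for g in labels}
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_value"])
    df["p_adj"] = multipletests(df["p_value"], method="holm")[1]
    return df


def compact_letters(
    groups: list[str], significant_pairs: list[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display (insert-and-absorb).

    Groups that share a letter are not significantly different.
    """
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(significant_pairs):
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for new in (col - {a}, col - {b}):
                if new and not any(new <= other for other in columns):
                    columns.append(new)
    # absorb any column that became a subset of another
    columns = [
        c for c in columns if not any(c < other for other in columns)
    ]
    columns.sort(key=lambda c: (min(c), -len(c), tuple(sorted(c))))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        mark = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in sorted(col):
            letters[g] += mark
    return letters


def compare_group_tests(
    values,
    groups,
    alpha: float = 0.05,
    shapiro_alpha: float = SHAPIRO_ALPHA,
) -> GroupComparison:
    """Omnibus + pairwise comparison of growth rates between groups.

    Every group must have >= 2 observations.  If each group passes
    Shapiro-Wilk (groups smaller than 3 cannot be screened and force the
    non-parametric branch), ANOVA + Tukey HSD is used; otherwise
    Kruskal-Wallis + Dunn with Holm adjustment.  Returns a compact
    letter display: distinct letters mark statistically distinct groups.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray([str(g) for g in np.asarray(groups)])
    if values.size != groups.size:
        raise ValueError("values and groups differ in length")
    labels = sorted(pd.unique(groups).tolist())
    by_group = {g: values[groups == g] for g in labels}
    if any(v.size < 2 for v in by_group.values()):
        small = [g for g, v in by_group.items() if v.size < 2]
        raise ValueError(f"group(s) with fewer than 2 observations: {small}")
    if len(labels) == 1:
        return GroupComparison(
            "tukey", "anova", float("nan"), float("nan"),
            pd.DataFrame(columns=["group_a", "group_b", "p_adj", "reject"]),
            {labels[0]: "a"},
        )
    normal = all(
        v.size >= 3 and np.ptp(v) > 0 and stats.shapiro(v).pvalue >= shapiro_alpha
        for v in by_group.values()
    )
    if normal:
        stat, p = stats.f_oneway(*by_group.values())
        tk = pairwise_tukeyhsd(values, groups, alpha=alpha)
        pairwise = pd.DataFrame(
            {
                "group_a": [str(a) for a, _ in itertools.combinations(tk.groupsunique, 2)],
                "group_b": [str(b) for _, b in itertools.combinations(tk.groupsunique, 2)],
                "p_adj": tk.pvalues,
                "reject": tk.reject,
            }
        )
        method, omnibus = "tukey", "anova"
    else:
        stat, p = stats.kruskal(*by_group.values())
        dn = dunn_test(values, groups)
        pairwise = dn.rename(columns={})[["group_a", "group_b", "p_adj"]].copy()
        pairwise["reject"] = pairwise["p_adj"] < alpha
        method, omnibus = "dunn", "kruskal"
    sig = [
        (r.group_a, r.group_b) for r in pairwise.itertuples() if bool(r.reject)
    ]
    letters = compact_letters(labels, sig)
    return GroupComparison(
        method=method,
        omnibus=omnibus,
        omnibus_stat=float(stat),
        omnibus_p=float(p),
        pairwise=pairwise,
        letters=letters,
    )
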
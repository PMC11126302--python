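"""Distribution summaries, probe pooling and normality-gated statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from asvgrowth.growth import GrowthRateRecord, estimate_asv_rates
from asvgrowth.pseudoabundance import pseudoabundance_table
from asvgrowth.summaries import (
    compact_letters,
    compare_group_tests,
    condition_summary,
    dunn_test,
    gated_correlation,
    pool_probe_groups,
    rank_distributions,
)


def _rec(asv, rate, season="winter", treatment="CL"):
    return GrowthRateRecord(asv, season, treatment, "t0t2t3", rate, 0.01, 0.9, 9, "accepted")


class TestConditionSummary:
    def test_two_rates(self):
        out = condition_summary([_rec("a", 1.0), _rec("b", 3.0)], by="season")
        row = out.iloc[0]
        assert row["mean"] == 2.0
        assert row["sd"] == pytest.approx(math.sqrt(2))
        assert row["cv_percent"] == pytest.approx(100 * math.sqrt(2) / 2)
        assert row["median"] == 2.0

    def test_single_rate_has_zero_sd(self):
        row = condition_summary([_rec("a", 2.5)], by="treatment").iloc[0]
        assert row["sd"] == 0.0 and row["cv_percent"] == 0.0

    def test_matches_brute_force(self, noisy_sim):
        recs = estimate_asv_rates(pseudoabundance_table(noisy_sim.experiment))
        out = condition_summary(recs, by="season").set_index("season")
        df = pd.DataFrame(
            [(r.season, r.slope_per_day) for r in recs if r.status == "accepted"],
            columns=["season", "rate"],
        )
        for season, grp in df.groupby("season"):
            assert out.loc[season, "mean"] == pytest.approx(grp["rate"].mean())
            assert out.loc[season, "median"] == pytest.approx(grp["rate"].median())
            assert out.loc[season, "n"] == len(grp)


class TestRankDistributions:
    @staticmethod
    def _tax(families):
        return pd.DataFrame(
            {
                "domain": "Bacteria",
                "phylum": "P",
                "class": "C",
                "order": "O",
                "family": pd.Series(families),
                "genus": "G",
            }
        )

    def test_min_obs_filter_and_coverage(self):
        tax = self._tax({"a": "X", "b": "X", "c": "X", "d": "Y"})
        recs = [_rec("a", 1.0), _rec("b", 2.0), _rec("c", 3.0), _rec("d", 4.0)]
        groups, coverage = rank_distributions(recs, tax, "family")
        assert list(groups["label"]) == ["X"]
        assert coverage == pytest.approx(0.75)

    def test_all_singletons(self):
        tax = self._tax({"a": "X", "b": "Y"})
        groups, coverage = rank_distributions([_rec("a", 1.0), _rec("b", 2.0)], tax, "family")
        assert groups.empty and coverage == 0.0

    def test_membership_matches_enumeration(self, noisy_sim):
        recs = estimate_asv_rates(pseudoabundance_table(noisy_sim.experiment))
        tax = noisy_sim.truth.taxonomy
        groups, _ = rank_distributions(recs, tax, "order", min_obs=2)
        df = pd.DataFrame(
            [(r.asv_id, r.slope_per_day) for r in recs if r.status == "accepted"],
            columns=["asv_id", "rate"],
        )
        df["order"] = df["asv_id"].map(tax["order"])
        brute = df.groupby("order").filter(lambda g: len(g) >= 2).groupby("order")["rate"]
        assert set(groups["label"]) == set(brute.mean().index)
        got = groups.set_index("label")
        for label, rates in brute:
            assert got.loc[label, "n"] == len(rates)
            assert got.loc[label, "mean"] == pytest.approx(rates.mean())

    def test_coverage_non_increasing_with_finer_rank(self, noisy_sim):
        recs = estimate_asv_rates(pseudoabundance_table(noisy_sim.experiment))
        tax = noisy_sim.truth.taxonomy
        coverages = [
            rank_distributions(recs, tax, rank)[1]
            for rank in ("phylum", "class", "order", "family", "genus", "asv")
        ]
        assert all(a >= b - 1e-12 for a, b in zip(coverages, coverages[1:]))


class TestProbePooling:
    def test_family_probe(self):
        tax = TestRankDistributions._tax({"a": "X", "b": "X", "c": "Y"})
        recs = [_rec("a", 2.0), _rec("b", 4.0), _rec("c", 9.0)]
        out = pool_probe_groups(recs, tax, {"probeX": [("family", "X")]})
        assert out.loc[0, "mean_rate"] == 3.0
        assert out.loc[0, "n"] == 2

    def test_whole_domain_probe_equals_condition_mean(self, noisy_sim):
        recs = estimate_asv_rates(pseudoabundance_table(noisy_sim.experiment))
        tax = noisy_sim.truth.taxonomy
        pooled = pool_probe_groups(recs, tax, {"EUB": [("domain", "Bacteria")]})
        summary = condition_summary(recs, by="condition")
        merged = pooled.merge(summary, on=["season", "treatment"])
        assert len(merged) == len(summary)
        np.testing.assert_allclose(merged["mean_rate"], merged["mean"], rtol=1e-12)

    def test_unmatched_probe_absent(self, caplog):
        tax = TestRankDistributions._tax({"a": "X"})
        with caplog.at_level("WARNING"):
            out = pool_probe_groups([_rec("a", 1.0)], tax, {"nope": [("family", "Z")]})
        assert out.empty
        assert "nope" in caplog.text


class TestGatedCorrelation:
    def test_linear_relation(self):
        x = np.linspace(0, 1, 10)
        res = gated_correlation(x, 2 * x)
        assert res.coefficient == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_heavy_tail_triggers_spearman(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(0, 2.5, size=80)
        res = gated_correlation(x, np.exp(x / x.max() * 5))
        assert res.method == "spearman"
        assert res.coefficient == pytest.approx(1.0)

    def test_latent_structure_recovered(self):
        """Paired condition means from a common latent rate correlate."""
        rng = np.random.default_rng(12)
        latent = rng.uniform(1, 4, size=24)
        a = latent + rng.normal(0, 0.3, 24)
        b = 0.5 * latent + rng.normal(0, 0.2, 24)
        res = gated_correlation(a, b)
        assert res.coefficient > 0.5
        assert res.p_value < 0.05

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            gated_correlation([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_gives_nan(self):
        res = gated_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(res.coefficient)


class TestGroupComparisons:
    def test_same_distribution_shares_letter(self):
        rng = np.random.default_rng(100)
        shared = 0
        for _ in range(20):
            values = np.concatenate([rng.normal(2, 1, 50), rng.normal(2, 1, 50)])
            groups = ["g1"] * 50 + ["g2"] * 50
            cmp = compare_group_tests(values, groups)
            letters = set(cmp.letters.values())
            if len(letters) == 1:
                shared += 1
        assert shared >= 18  # >=90% of reruns

    def test_extreme_separation_distinct_letters(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(1, 0.1, 20), rng.normal(6, 0.1, 20)])
        groups = ["slow"] * 20 + ["fast"] * 20
        cmp = compare_group_tests(values, groups)
        assert cmp.letters["slow"] != cmp.letters["fast"]
        assert cmp.omnibus_p < 1e-6

    def test_single_group(self):
        cmp = compare_group_tests([1.0, 2.0, 3.0], ["g"] * 3)
        assert cmp.letters == {"g": "a"}

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_group_tests([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_dunn_matches_kruskal_direction(self):
        rng = np.random.default_rng(8)
        values = np.concatenate(
            [rng.lognormal(0, 0.3, 30), rng.lognormal(1.5, 0.3, 30)]
        )
        groups = np.array(["lo"] * 30 + ["hi"] * 30)
        dn = dunn_test(values, groups)
        assert dn.loc[0, "p_adj"] < 0.01

    def test_compact_letters_share_iff_not_significant(self):
        letters = compact_letters(["a", "b", "c"], [("a", "c")])
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])
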
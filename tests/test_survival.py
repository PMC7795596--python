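import numpy as np
import pandas as pd
import pytest

from timepheno import io, survival as sv
from timepheno.phenotyping import PhenotypeAssignment, PhenotypeThresholds

from _oracles import km_oracle, logrank_oracle


class TestKaplanMeier:
    def test_events_only_matches_empirical_survival(self):
        curve = sv.kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.survival_at(2.0) == pytest.approx(0.5)
        assert curve.survival_at(4.0) == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        curve = sv.kaplan_meier([5, 10, 15], [0, 0, 0])
        assert (curve.survival == 1.0).all()

    def test_censor_between_events_hand_product_limit(self):
        # events at 1 and 2, censor at 1.5: risk set at t=2 is a single
        # subject, so S(2) = (1 - 1/3) * (1 - 1/1) = 0
        curve = sv.kaplan_meier([1, 1.5, 2], [1, 0, 1])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(2.0) == pytest.approx(0.0)
        assert curve.survival_at(2.0) == pytest.approx(km_oracle([1, 1.5, 2], [1, 0, 1], 2.0))

    def test_random_fixtures_match_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 20))
            times = np.round(rng.exponential(10, n), 1)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            curve = sv.kaplan_meier(times, events)
            for q in rng.choice(times, size=3):
                assert curve.survival_at(q) == pytest.approx(km_oracle(times, events, q))

    def test_estimates_non_increasing_and_start_at_one(self, rng):
        times = rng.exponential(10, 50)
        events = rng.integers(0, 2, 50)
        curve = sv.kaplan_meier(times, events)
        assert curve.survival[0] <= 1.0 + 1e-12
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert (curve.greenwood_var >= 0).all()

    def test_negative_time_rejected(self):
        with pytest.raises(sv.SurvivalError, match="non-negative"):
            sv.kaplan_meier([-1.0, 2.0], [1, 1])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1] * 2
        g = ["A"] * 4 + ["B"] * 4
        stat, df, p = sv.logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 1 and p == pytest.approx(1.0)

    def test_separated_groups_match_hand_tabulation(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1] * 6
        g = ["A"] * 3 + ["B"] * 3
        stat, df, p = sv.logrank_test(t, e, g)
        o_stat, o_df, o_p = logrank_oracle(t, e, g)
        assert stat == pytest.approx(o_stat)
        assert p == pytest.approx(o_p)

    def test_three_group_random_fixtures_match_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(9, 21))
            times = np.round(rng.exponential(10, n), 2)
            events = rng.integers(0, 2, n)
            groups = rng.choice(["A", "B", "C"], n)
            if len(set(groups)) < 3 or events.sum() < 3:
                continue
            stat, df, p = sv.logrank_test(times, events, groups)
            o_stat, o_df, o_p = logrank_oracle(times, events, groups)
            assert stat == pytest.approx(o_stat, rel=1e-6)
            assert df == o_df
            assert p == pytest.approx(o_p, rel=1e-6)

    def test_duplicating_a_group_leaves_p_stable(self, rng):
        times = rng.exponential(10, 40)
        events = rng.integers(0, 2, 40)
        groups = np.array(["A"] * 20 + ["B"] * 20)
        _, _, p2 = sv.logrank_test(times, events, groups)
        # relabel half of B as C with identical records: chi2 gains a df but
        # the comparison stays null between B and C
        groups3 = groups.copy()
        groups3[30:] = "C"
        stat3, df3, p3 = sv.logrank_test(
            np.concatenate([times, times[20:30]]),
            np.concatenate([events, events[20:30]]),
            np.concatenate([groups3, ["C"] * 10]),
        )
        assert df3 == 2

    def test_label_permutation_within_group_invariant(self, rng):
        times = rng.exponential(10, 30)
        events = rng.integers(0, 2, 30)
        groups = np.array(["A"] * 15 + ["B"] * 15)
        stat1, _, p1 = sv.logrank_test(times, events, groups)
        perm = np.concatenate([rng.permutation(15), 15 + rng.permutation(15)])
        stat2, _, p2 = sv.logrank_test(times[perm], events[perm], groups)
        assert stat1 == pytest.approx(stat2)

    def test_single_group_rejected(self):
        with pytest.raises(sv.SurvivalError, match=">= 2 groups"):
            sv.logrank_test([1, 2], [1, 1], ["A", "A"])


class TestSubtypeStrata:
    @pytest.mark.parametrize(
        "er, pgr, her2, expected",
        [
            ("positive", "negative", "negative", "HR+HER2-"),
            ("negative", "positive", "negative", "HR+HER2-"),
            ("negative", "negative", "negative", "TN"),
            ("positive", "positive", "positive", "HER2+"),  # HER2+ precedence
            ("negative", "negative", "positive", "HER2+"),
            ("unknown", "negative", "negative", "unknown"),
            ("positive", "negative", "unknown", "unknown"),
        ],
    )
    def test_receptor_rules(self, er, pgr, her2, expected):
        clinical = io.ClinicalTable(
            pd.DataFrame(
                {"er_status": [er], "pgr_status": [pgr], "her2_status": [her2]},
                index=pd.Index(["S1"], name="sample_id"),
            )
        )
        assert sv.subtype_strata(clinical).iloc[0] == expected


def _assignment(labels: pd.Series) -> PhenotypeAssignment:
    return PhenotypeAssignment(labels, PhenotypeThresholds(0.85, 0.4, 0.0, 0.0))


class TestSurvivalPanel:
    def test_hazard_separated_phenotypes_detected(self, rng):
        n = 300
        labels, times, events = [], [], []
        for lab, hazard in (("HTI", 0.005), ("CTI", 0.01), ("NI", 0.01)):
            t = rng.exponential(1 / hazard, n)
            c = rng.uniform(0, 180, n)
            times.append(np.minimum(t, c))
            events.append((t <= c).astype(int))
            labels += [lab] * n
        ids = pd.Index([f"S{i}" for i in range(3 * n)], name="sample_id")
        clinical = io.ClinicalTable(
            pd.DataFrame(
                {
                    "er_status": ["positive"] * 3 * n,
                    "pgr_status": ["negative"] * 3 * n,
                    "her2_status": ["negative"] * 3 * n,
                    "OS_months": np.concatenate(times),
                    "OS_event": np.concatenate(events),
                },
                index=ids,
            )
        )
        assignment = _assignment(pd.Series(labels, index=ids))
        panel = sv.survival_panel(clinical, assignment)
        whole = panel[(panel.endpoint == "OS") & (panel.stratum == "whole")].iloc[0]
        assert whole.p_value < 0.01
        assert whole.n_HTI == n and whole.df == 2

    def test_stratum_with_single_phenotype_skipped(self, caplog, fixture_cohort):
        labels = pd.Series("NI", index=fixture_cohort.clinical.data.index)
        labels.iloc[:4] = "HTI"
        # HER2+ stratum holds only the last two samples, both NI
        with caplog.at_level("INFO"):
            panel = sv.survival_panel(fixture_cohort.clinical, _assignment(labels))
        assert "skipping" in caplog.text
        assert "HER2+" not in set(panel.stratum)

    def test_null_hazards_give_uniformish_p(self, rng):
        # sanity: under equal hazards the whole-cohort p is not systematically small
        ps = []
        for _ in range(50):
            t = rng.exponential(100, 90)
            c = rng.uniform(0, 180, 90)
            times = np.minimum(t, c)
            events = (t <= c).astype(int)
            groups = rng.choice(["HTI", "CTI", "NI"], 90)
            _, _, p = sv.logrank_test(times, events, groups)
            ps.append(p)
        assert np.mean(np.array(ps) < 0.05) < 0.2
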
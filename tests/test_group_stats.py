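"""Cohort summaries and mixed-design ANOVA against a sum-of-squares oracle."""

import numpy as np
import pandas as pd
import pytest

from eegnetdyn.datatypes import ConnectivityMatrix, NetworkMetrics, StablePeriod
from eegnetdyn.group_stats import (
    build_cohort_table,
    holm_adjust,
    rm_anova,
    stepdown_ttest,
    summarize_subject,
)
from eegnetdyn.synthetic import generate_measure_table


def _period(duration, n=3):
    W = np.full((n, n), 0.5) - 0.5 * np.eye(n)
    return StablePeriod(0, 1, duration, ConnectivityMatrix(W))


def _metrics(diameter=2.0):
    return NetworkMetrics(
        diameter=diameter, radius=1.0, char_path_length=1.5,
        transitivity=0.4, max_modularity=0.3, global_efficiency=0.7,
    )


def mixed_anova_oracle(wide):
    """Balanced split-plot sum-of-squares decomposition (2 conditions).

    ``wide``: columns group, c1, c2; equal subjects per group.
    Returns dict effect -> F.
    """
    groups = sorted(wide["group"].unique())
    conds = [c for c in wide.columns if c not in ("subject", "group")]
    g, c = len(groups), len(conds)
    n = len(wide) // g
    X = wide[conds].to_numpy()
    gm = X.mean()
    subj_means = X.mean(axis=1)
    group_means = np.array([X[wide["group"] == gr].mean() for gr in groups])
    cond_means = X.mean(axis=0)
    ss_total = ((X - gm) ** 2).sum()
    ss_between_subj = c * ((subj_means - gm) ** 2).sum()
    ss_group = n * c * ((group_means - gm) ** 2).sum()
    ss_subj_within = ss_between_subj - ss_group
    ss_within = ss_total - ss_between_subj
    ss_cond = g * n * ((cond_means - gm) ** 2).sum()
    ss_inter = 0.0
    for gi, gr in enumerate(groups):
        cell = X[wide["group"] == gr].mean(axis=0)
        ss_inter += n * ((cell - group_means[gi] - cond_means + gm) ** 2).sum()
    ss_err = ss_within - ss_cond - ss_inter
    df_group, df_subj = g - 1, g * (n - 1)
    df_cond = c - 1
    df_inter = (g - 1) * (c - 1)
    df_err = g * (n - 1) * (c - 1)
    # the partition must be exact
    assert ss_total == pytest.approx(
        ss_group + ss_subj_within + ss_cond + ss_inter + ss_err
    )
    return {
        "group": (ss_group / df_group) / (ss_subj_within / df_subj),
        "condition": (ss_cond / df_cond) / (ss_err / df_err),
        "condition x group": (ss_inter / df_inter) / (ss_err / df_err),
    }


class TestSummarizeSubject:
    def test_zero_periods(self):
        df = summarize_subject([], [], condition="rest", subject="s1", group="A")
        row = df.set_index("measure")["value"]
        assert row["n_stable"] == 0
        assert np.isnan(row["mean_duration"])
        assert np.isnan(row["diameter"])

    def test_mean_duration_of_two_periods(self):
        df = summarize_subject(
            [_period(2.0), _period(4.0)], [_metrics(2.0), _metrics(4.0)],
            condition="rest",
        )
        row = df.set_index("measure")["value"]
        assert row["mean_duration"] == 3.0
        assert row["n_stable"] == 2
        assert row["diameter"] == 3.0

    def test_single_period_identity(self):
        m = _metrics(5.0)
        df = summarize_subject([_period(7.5)], [m], condition="event")
        row = df.set_index("measure")["value"]
        for name, val in m.as_dict().items():
            assert row[name] == val

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            summarize_subject([_period(1.0)], [], condition="rest")


class TestRmAnova:
    @staticmethod
    def _table(values):
        """values: {(group, subject, condition): value}."""
        rows = [
            {"subject": s, "group": g, "condition": c,
             "measure": "mean_duration", "value": v}
            for (g, s, c), v in values.items()
        ]
        return pd.DataFrame(rows)

    def test_matches_sum_of_squares_oracle_on_hand_sized_table(self):
        values = {
            ("A", "a1", "rest"): 4.0, ("A", "a1", "event"): 2.0,
            ("A", "a2", "rest"): 5.0, ("A", "a2", "event"): 3.5,
            ("A", "a3", "rest"): 6.0, ("A", "a3", "event"): 2.5,
            ("B", "b1", "rest"): 8.0, ("B", "b1", "event"): 3.0,
            ("B", "b2", "rest"): 9.5, ("B", "b2", "event"): 2.0,
            ("B", "b3", "rest"): 7.5, ("B", "b3", "event"): 4.0,
        }
        table = self._table(values)
        results = {r.effect: r for r in rm_anova(table, "mean_duration")}
        wide = table.pivot_table(index=["subject", "group"], columns="condition",
                                 values="value").reset_index()
        expected = mixed_anova_oracle(wide)
        for effect, f_ref in expected.items():
            assert results[effect].F == pytest.approx(f_ref, rel=1e-6)
            assert 0 < results[effect].p <= 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle_on_random_balanced_tables(self, seed):
        table = generate_measure_table(
            6, {("A", "rest"): 2.0, ("A", "event"): 1.0,
                ("B", "rest"): 3.0, ("B", "event"): 1.0},
            seed=seed,
        )
        results = {r.effect: r for r in rm_anova(table, "mean_duration")}
        wide = table.pivot_table(index=["subject", "group"], columns="condition",
                                 values="value").reset_index()
        expected = mixed_anova_oracle(wide)
        for effect, f_ref in expected.items():
            assert results[effect].F == pytest.approx(f_ref, rel=1e-6)

    def test_group_relabelling_leaves_f_unchanged(self):
        table = generate_measure_table(
            5, {("A", "rest"): 2.0, ("A", "event"): 1.0,
                ("B", "rest"): 3.0, ("B", "event"): 1.5},
            seed=11,
        )
        swapped = table.copy()
        swapped["group"] = swapped["group"].map({"A": "B", "B": "A"})
        f1 = {r.effect: r.F for r in rm_anova(table, "mean_duration")}
        f2 = {r.effect: r.F for r in rm_anova(swapped, "mean_duration")}
        for effect in f1:
            assert f1[effect] == pytest.approx(f2[effect])

    def test_incomplete_subjects_dropped_and_small_groups_rejected(self):
        values = {
            ("A", "a1", "rest"): 4.0, ("A", "a1", "event"): 2.0,
            ("A", "a2", "rest"): 5.0,  # missing event
            ("A", "a3", "rest"): 5.0, ("A", "a3", "event"): 2.0,
            ("B", "b1", "rest"): 8.0, ("B", "b1", "event"): 3.0,
            ("B", "b2", "rest"): 9.5,  # missing event -> only 1 complete in B
        }
        with pytest.raises(ValueError, match="complete subjects"):
            rm_anova(self._table(values), "mean_duration")

    def test_interaction_type_I_error_near_nominal(self):
        # identical group distributions: the interaction should reject at
        # about the nominal 5% level
        hits = 0
        n_rep = 100
        means = {("A", "rest"): 2.0, ("A", "event"): 1.0,
                 ("B", "rest"): 2.0, ("B", "event"): 1.0}
        for s in range(n_rep):
            table = generate_measure_table(8, means, seed=s)
            res = {r.effect: r for r in rm_anova(table, "mean_duration")}
            hits += res["condition x group"].p < 0.05
        # 95% binomial interval around 5 of 100
        assert 1 <= hits <= 11

    def test_interaction_power_at_documented_effect(self):
        # planted interaction: group B's rest mean is 2.5 units higher
        # (within-subject noise SD 1) -> detectable in >= 80% of cohorts
        hits = 0
        n_rep = 100
        means = {("A", "rest"): 2.0, ("A", "event"): 1.0,
                 ("B", "rest"): 4.5, ("B", "event"): 1.0}
        for s in range(n_rep):
            table = generate_measure_table(10, means, seed=s)
            res = {r.effect: r for r in rm_anova(table, "mean_duration")}
            hits += res["condition x group"].p < 0.05
        assert hits >= 80


class TestStepdownTtest:
    @staticmethod
    def _table(a_vals, b_vals, condition="rest"):
        rows = []
        for i, v in enumerate(a_vals):
            rows.append({"subject": f"a{i}", "group": "A", "condition": condition,
                         "measure": "m", "value": v})
        for i, v in enumerate(b_vals):
            rows.append({"subject": f"b{i}", "group": "B", "condition": condition,
                         "measure": "m", "value": v})
        return pd.DataFrame(rows)

    def test_identical_groups(self):
        t, df, p = stepdown_ttest(self._table([1, 2, 3], [1, 2, 3]), "m", "rest")
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_welch_t(self):
        # {1,2,3} vs {4,5,6}: t = (2-5)/sqrt(1/3 + 1/3) = -3.674..., df = 4
        t, df, p = stepdown_ttest(self._table([1, 2, 3], [4, 5, 6]), "m", "rest")
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
        assert df == pytest.approx(4.0)

    def test_label_swap_flips_sign(self):
        tab = self._table([1.0, 2.5, 3.1], [4.2, 5.0, 6.8])
        t1, _, p1 = stepdown_ttest(tab, "m", "rest")
        swapped = tab.copy()
        swapped["group"] = swapped["group"].map({"A": "B", "B": "A"})
        t2, _, p2 = stepdown_ttest(swapped, "m", "rest")
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            stepdown_ttest(self._table([1, 1, 1], [2, 2, 2]), "m", "rest")


class TestHolmAdjust:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.04, 0.03, 0.2, 0.5, 0.005]
        _, ref, _, _ = multipletests(p, method="holm")
        assert holm_adjust(p) == pytest.approx(ref)
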
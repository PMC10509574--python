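"""Exclusions, descriptive bias composites and the inferential battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pavbias.behaviour import (
    CONDITION_NAMES,
    accuracy_table,
    apply_exclusions,
    condition_accuracy,
    descriptive_go_bias,
    descriptive_pavlovian_bias,
    paired_t,
    rm_anova_2x2,
    rm_anova_2x2x2,
    variance_ratio,
)
from pavbias.task import (
    CohortConfig,
    default_group_prior_spec,
    generate_cohort,
)
from pavbias.models import MODEL_LADDER
from conftest import build_session


def _session_cycle(go_responses, n=120):
    """Session cycling the four conditions with fixed Go/NoGo responses."""
    rows = []
    for i in range(n):
        cond = CONDITION_NAMES[i % 4]
        go = go_responses(cond, i)
        rows.append((cond, "left" if go else "none", 0, "left"))
    return build_session(rows)


class TestExclusions:
    def test_wrong_side_presses_flag_localization(self):
        rows = []
        for i in range(40):
            side = "left" if i % 2 else "right"
            press = side if i % 4 < 2 else ("right" if side == "left"
                                            else "left")
            rows.append(("G2W", press, 1, side))
        rows += [("NG2W", "none", 1)] * 40
        session = build_session(rows)
        kept, decisions = apply_exclusions([session])
        assert kept == []
        assert decisions[0].reason == "localization"
        assert decisions[0].localization_error_rate == pytest.approx(0.5)

    def test_never_pressing_is_uniform_response(self):
        session = _session_cycle(lambda cond, i: False)
        kept, decisions = apply_exclusions([session])
        assert kept == [] and decisions[0].reason == "uniform_response"
        assert decisions[0].localization_error_rate is None

    def test_attentive_mixed_responder_retained(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(120):
            cond = CONDITION_NAMES[i % 4]
            side = "left" if rng.random() < 0.5 else "right"
            if rng.random() < 0.6:
                press = side if rng.random() > 0.1 else \
                    ("right" if side == "left" else "left")
            else:
                press = "none"
            rows.append((cond, press, 0, side))
        session = build_session(rows)
        kept, decisions = apply_exclusions([session])
        assert kept == [session]
        assert decisions[0].reason == "none"

    def test_exclusion_is_idempotent(self, simulated_session):
        sessions = [simulated_session,
                    _session_cycle(lambda cond, i: True)]
        once, _ = apply_exclusions(sessions)
        twice, decisions = apply_exclusions(once)
        assert twice == once
        assert all(not d.excluded for d in decisions)


class TestAccuracyAndBiases:
    def test_uniform_responders(self):
        acc = condition_accuracy(_session_cycle(lambda c, i: False))
        assert [acc[c] for c in CONDITION_NAMES] == [0, 0, 1, 1]
        assert descriptive_pavlovian_bias(acc) == pytest.approx(0.0)
        assert descriptive_go_bias(acc) == pytest.approx(-2.0)

        acc = condition_accuracy(_session_cycle(lambda c, i: True))
        assert [acc[c] for c in CONDITION_NAMES] == [1, 1, 0, 0]
        assert descriptive_pavlovian_bias(acc) == pytest.approx(0.0)
        assert descriptive_go_bias(acc) == pytest.approx(2.0)

    def test_hand_counted_eight_trials(self):
        rows = [("G2W", "left", 1), ("G2W", "none", 0),
                ("G2AP", "left", 0), ("G2AP", "left", 0),
                ("NG2W", "none", 1), ("NG2W", "left", 0),
                ("NG2AP", "none", 0), ("NG2AP", "left", -1)]
        acc = condition_accuracy(build_session(rows))
        assert acc["G2W"] == 0.5 and acc["G2AP"] == 1.0
        assert acc["NG2W"] == 0.5 and acc["NG2AP"] == 0.5
        assert descriptive_pavlovian_bias(acc) == pytest.approx(-0.5)
        assert descriptive_go_bias(acc) == pytest.approx(0.5)

    def test_perfect_pavlovian_pattern_scores_two(self):
        # fully Pavlovian subject: goes exactly on the win-valenced cues
        acc = condition_accuracy(_session_cycle(
            lambda c, i: c in ("G2W", "NG2W")))
        assert acc.accuracy == {"G2W": 1.0, "G2AP": 0.0,
                                "NG2W": 0.0, "NG2AP": 1.0}
        assert descriptive_pavlovian_bias(acc) == pytest.approx(2.0)
        assert descriptive_go_bias(acc) == pytest.approx(0.0)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="no trials"):
            condition_accuracy(build_session([("G2W", "left", 1)]))

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.floats(0, 1) for _ in range(4)]))
    def test_bias_identities_and_bounds(self, accs):
        from pavbias.behaviour import ConditionAccuracy
        table = ConditionAccuracy("s", 1, dict(zip(CONDITION_NAMES, accs)))
        pav = descriptive_pavlovian_bias(table)
        go = descriptive_go_bias(table)
        assert -2.0 <= pav <= 2.0 and -2.0 <= go <= 2.0
        assert pav + go == pytest.approx(
            2.0 * (table["G2W"] - table["NG2W"]), abs=1e-12)

    def test_accuracy_is_permutation_invariant(self, simulated_session):
        import copy
        shuffled = copy.deepcopy(simulated_session)
        rng = np.random.default_rng(1)
        rng.shuffle(shuffled.trials)
        a = condition_accuracy(simulated_session).accuracy
        b = condition_accuracy(shuffled).accuracy
        assert a == pytest.approx(b)


class TestAnova:
    def _random_table(self, n, cols, seed):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.uniform(0.1, 0.9, size=(n, len(cols))),
                            columns=list(cols))

    def test_identical_cells_give_zero_f(self):
        table = pd.DataFrame({c: [0.7, 0.4, 0.55] for c in CONDITION_NAMES})
        res = rm_anova_2x2(table)
        assert all(v["F"] == 0.0 and v["p"] == 1.0 for v in res.values())

    def test_matches_statsmodels_anova_rm_2x2(self):
        from statsmodels.stats.anova import AnovaRM
        table = self._random_table(6, CONDITION_NAMES, seed=2)
        res = rm_anova_2x2(table)
        long = table.reset_index().melt(
            id_vars="index", var_name="cond", value_name="acc")
        long["action"] = np.where(long["cond"].str.startswith("G"),
                                  "go", "nogo")
        long["valence"] = np.where(long["cond"].str.contains("W"),
                                   "win", "pun")
        sm = AnovaRM(long, "acc", "index",
                     within=["action", "valence"]).fit().anova_table
        assert res["action"]["F"] == pytest.approx(
            sm.loc["action", "F Value"], abs=1e-8)
        assert res["valence"]["F"] == pytest.approx(
            sm.loc["valence", "F Value"], abs=1e-8)
        assert res["action:valence"]["F"] == pytest.approx(
            sm.loc["action:valence", "F Value"], abs=1e-8)

    def test_matches_statsmodels_anova_rm_2x2x2(self):
        from statsmodels.stats.anova import AnovaRM
        cols = [f"{c}_s{s}" for s in (1, 2) for c in CONDITION_NAMES]
        table = self._random_table(5, cols, seed=3)
        res = rm_anova_2x2x2(table)
        long = table.reset_index().melt(
            id_vars="index", var_name="cell", value_name="acc")
        long["session"] = long["cell"].str[-1]
        long["action"] = np.where(long["cell"].str.startswith("G"),
                                  "go", "nogo")
        long["valence"] = np.where(long["cell"].str.contains("W"),
                                   "win", "pun")
        sm = AnovaRM(long, "acc", "index",
                     within=["action", "valence", "session"]).fit(). \
            anova_table
        pairs = {"action": "action", "valence": "valence",
                 "session": "session",
                 "action:valence": "action:valence",
                 "session:action": "action:session",
                 "session:valence": "valence:session",
                 "session:action:valence": "action:valence:session"}
        for mine, theirs in pairs.items():
            assert res[mine]["F"] == pytest.approx(
                sm.loc[theirs, "F Value"], abs=1e-8), mine

    def test_f_equals_squared_paired_t(self):
        from scipy import stats as ss
        table = self._random_table(12, CONDITION_NAMES, seed=4)
        res = rm_anova_2x2(table)
        t, _ = ss.ttest_rel(table["G2W"] + table["G2AP"],
                            table["NG2W"] + table["NG2AP"])
        assert res["action"]["F"] == pytest.approx(t ** 2, abs=1e-8)

    def test_session_identical_to_first_kills_session_effects(self):
        base = self._random_table(8, CONDITION_NAMES, seed=5)
        both = pd.concat([base.add_suffix("_s1"), base.add_suffix("_s2")],
                         axis=1)
        res = rm_anova_2x2x2(both)
        for effect, v in res.items():
            if "session" in effect:
                assert v["F"] == 0.0
            else:
                assert v["F"] > 0.0

    def test_pavlovian_cohort_shows_positive_interaction(self):
        spec = MODEL_LADDER[-1]
        prior = default_group_prior_spec(spec)
        prior["pi"] = (0.7, 0.3)  # strong Pavlovian influence
        cohort = generate_cohort(CohortConfig(
            n_subjects=80, model_spec=spec, prior=prior, n_sessions=1,
            seed=13))
        table = accuracy_table([s.sessions[1] for s in cohort])
        res = rm_anova_2x2(table)
        interaction = (table["G2W"] + table["NG2AP"]
                       - table["NG2W"] - table["G2AP"])
        assert interaction.mean() > 0.0
        assert res["action:valence"]["p"] < 0.05

    def test_incomplete_table_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            rm_anova_2x2(pd.DataFrame({"G2W": [0.5, 0.6]}))
        bad = pd.DataFrame({c: [0.5, np.nan] for c in CONDITION_NAMES})
        with pytest.raises(ValueError, match="missing cells"):
            rm_anova_2x2(bad)


class TestPairwiseTests:
    def test_identical_samples(self):
        x = np.array([0.2, 0.5, 0.9, 0.4])
        t, df, p = paired_t(x, x.copy())
        assert (t, df, p) == (0.0, 3, 1.0)
        f, _, _ = variance_ratio(x, x.copy())
        assert f == pytest.approx(1.0)

    def test_constant_nonzero_difference_rejected(self):
        x = np.array([0.2, 0.5, 0.9])
        with pytest.raises(ValueError, match="undefined"):
            paired_t(x, x + 0.1)

    def test_hand_dataset_matches_textbook_formula(self):
        x = np.array([3.1, 2.8, 4.0, 3.3, 3.9])
        y = np.array([2.9, 3.1, 3.5, 3.0, 3.2])
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        t, df, p = paired_t(x, y)
        assert t == pytest.approx(t_oracle, abs=1e-12)
        assert df == 4

    def test_variance_ratio_formula_and_tail(self):
        from scipy import stats as ss
        rng = np.random.default_rng(6)
        x = rng.normal(0, 2.0, size=30)
        y = rng.normal(0, 1.0, size=30)
        f, (d1, d2), p = variance_ratio(x, y)
        assert f == pytest.approx(np.var(x, ddof=1) / np.var(y, ddof=1))
        assert (d1, d2) == (29, 29)
        assert p == pytest.approx(ss.f.sf(f, 29, 29))
        f2, _, p2 = variance_ratio(x, y, two_tailed=True)
        assert f2 == f and p2 == pytest.approx(min(1.0, 2 * p))
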
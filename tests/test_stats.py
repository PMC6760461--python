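"""Session design, aggregation, mixed ANOVA and follow-up tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import hyperconn as hc
from hyperconn.stats import JugglerInfo, SessionDesign, design_frame


def synth_table(rng, n_sessions=8, n_matched=4, effects=None):
    """Tidy 2x2 within-session table with optional planted effects."""
    effects = effects or {}
    rows = []
    for s in range(n_sessions):
        g = "M" if s < n_matched else "U"
        base = rng.normal(0, 1)
        for c in ("SOLO", "PAIRED"):
            for k in ("less", "more"):
                val = base + rng.normal(0, 0.4)
                val += effects.get("condition", 0) * (c == "PAIRED")
                val += effects.get("skill", 0) * (k == "more")
                val += effects.get("matched", 0) * (g == "M")
                val += effects.get("condition*skill", 0) * (
                    (c == "PAIRED") and (k == "more")
                )
                rows.append(
                    dict(
                        session=f"s{s}",
                        condition=c,
                        skill=k,
                        matched=g,
                        measure="G",
                        value=val,
                    )
                )
    return pd.DataFrame(rows)


class TestDesign:
    def test_study_sessions_follow_the_three_year_rule(self):
        assert len(hc.STUDY_SESSIONS) == 7
        assert sum(d.matched for d in hc.STUDY_SESSIONS) == 3
        for d in hc.STUDY_SESSIONS:
            assert (d.experience_difference <= 3) == d.matched
            assert d.j1.years_experience <= d.j2.years_experience

    def test_inconsistent_matched_flag_rejected(self):
        with pytest.raises(ValueError, match="matched flag"):
            SessionDesign(
                "x",
                JugglerInfo("a", "right", 3),
                JugglerInfo("b", "right", 10),
                matched=True,
            )

    def test_j1_must_be_less_experienced(self):
        with pytest.raises(ValueError, match="less experienced"):
            SessionDesign(
                "x",
                JugglerInfo("a", "right", 12),
                JugglerInfo("b", "right", 10),
                matched=True,
            )

    def test_design_csv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [
                dict(
                    session="1",
                    subject_j1="a",
                    handedness_j1="right",
                    years_j1=2,
                    subject_j2="b",
                    handedness_j2="left",
                    years_j2=4,
                    matched="YES",
                    solo_trials_j1=5,
                    solo_trials_j2=6,
                    paired_trials=3,
                )
            ]
        )
        path = tmp_path / "design.csv"
        df.to_csv(path, index=False)
        designs = hc.stats.read_design_csv(path)
        assert designs[0].matched
        assert designs[0].n_paired_trials == 3

    def test_design_frame_columns(self):
        df = design_frame()
        assert set(df.columns) >= {"session", "matched"}
        assert len(df) == 7


class TestAggregation:
    def test_single_trial_mean_is_identity(self):
        df = pd.DataFrame(
            [
                dict(
                    session="1",
                    condition="SOLO",
                    unit="J1",
                    measure="G",
                    trial=0,
                    value=0.7,
                )
            ]
        )
        out = hc.aggregate_session_means(df)
        assert out["value"].iloc[0] == 0.7
        assert out["n_trials"].iloc[0] == 1

    def test_two_trials_average(self):
        df = pd.DataFrame(
            [
                dict(session="1", condition="SOLO", unit="J1", measure="G",
                     trial=k, value=v)
                for k, v in [(0, 0.4), (1, 0.6)]
            ]
        )
        assert hc.aggregate_session_means(df)["value"].iloc[0] == pytest.approx(0.5)

    def test_matches_groupby_oracle_and_skips_nan(self):
        rng = np.random.default_rng(0)
        rows = []
        for s in ("1", "2"):
            for c in ("SOLO", "PAIRED"):
                for u in ("J1", "J2"):
                    for k in range(4):
                        rows.append(
                            dict(session=s, condition=c, unit=u, measure="D",
                                 trial=k, value=rng.random())
                        )
        df = pd.DataFrame(rows)
        df.loc[3, "value"] = np.nan
        with pytest.warns(UserWarning, match="undefined"):
            out = hc.aggregate_session_means(df)
        oracle = (
            df.dropna(subset=["value"])
            .groupby(["session", "condition", "unit", "measure"])["value"]
            .mean()
        )
        for _, r in out.iterrows():
            key = (r.session, r.condition, r.unit, r.measure)
            assert r.value == pytest.approx(oracle.loc[key])


class TestEffectSizeAndPower:
    @pytest.mark.parametrize(
        "F,df1,df2,expected",
        [
            (8.392, 1, 5, 0.627),
            (8.376, 1, 5, 0.626),
            (19.751, 1, 2, 0.908),
            (21.413, 1, 2, 0.915),
            (0.0, 1, 5, 0.0),
        ],
    )
    def test_partial_eta_squared_reproduces_reported_values(
        self, F, df1, df2, expected
    ):
        assert hc.partial_eta_squared(F, df1, df2) == pytest.approx(
            expected, abs=5e-4
        )

    def test_observed_power_matches_reported_convention(self):
        # noncentral-F tail with lambda = F * df1
        assert hc.observed_power(8.392, 1, 5) == pytest.approx(0.643, abs=0.01)
        assert hc.observed_power(19.751, 1, 2) == pytest.approx(0.637, abs=0.01)

    def test_power_limits(self):
        assert hc.observed_power(0.0, 1, 5) == pytest.approx(0.05)
        assert hc.observed_power(1e5, 1, 5) > 0.9999

    def test_power_against_numerical_integration_oracle(self):
        # independent evaluation: integrate the noncentral density directly
        from scipy.integrate import quad

        F, df1, df2 = 8.392, 1, 5
        fcrit = sps.f.isf(0.05, df1, df2)
        val, _ = quad(
            lambda x: sps.ncf.pdf(x, df1, df2, F * df1), fcrit, np.inf
        )
        assert hc.observed_power(F, df1, df2) == pytest.approx(val, abs=1e-6)


class TestMixedAnova:
    def test_f_equals_squared_paired_t_for_single_within_factor(self):
        rng = np.random.default_rng(1)
        rows = []
        vals = {}
        for s in range(7):
            a, b = rng.normal(0.5, 1), rng.normal(0, 1)
            vals[f"s{s}"] = (a, b)
            rows += [
                dict(session=f"s{s}", condition="SOLO", measure="G", value=a),
                dict(session=f"s{s}", condition="PAIRED", measure="G", value=b),
            ]
        res = hc.mixed_anova(pd.DataFrame(rows), "G", within=["condition"])
        t, _ = sps.ttest_rel(
            [v[0] for v in vals.values()], [v[1] for v in vals.values()]
        )
        assert res[0].df1 == 1 and res[0].df2 == 6
        assert res[0].F == pytest.approx(t**2, abs=1e-10)

    def test_constant_dv_gives_zero_f_everywhere(self):
        df = synth_table(np.random.default_rng(2))
        df["value"] = 0.31
        for r in hc.mixed_anova(df, "G", within=["condition", "skill"],
                                between="matched"):
            assert r.F == 0.0

    def test_matches_pingouin_mixed_anova_balanced(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = synth_table(rng, n_sessions=8, n_matched=4)
        sub = df[df.skill == "less"]
        mine = hc.mixed_anova(sub, "G", within=["condition"], between="matched")
        ref = pg.mixed_anova(
            sub, dv="value", within="condition", subject="session",
            between="matched",
        ).set_index("Source")
        by_name = {r.effect: r for r in mine}
        assert by_name["matched"].F == pytest.approx(ref.loc["matched", "F"])
        assert by_name["condition"].F == pytest.approx(ref.loc["condition", "F"])
        assert by_name["condition * matched"].F == pytest.approx(
            ref.loc["Interaction", "F"]
        )

    def test_unbalanced_between_and_interaction_match_pingouin(self):
        # with unequal group sizes the within main effect uses unweighted
        # group means (Type-III); the between and interaction terms agree
        # with the classical decomposition
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = synth_table(rng, n_sessions=9, n_matched=4)
        sub = df[df.skill == "less"]
        mine = {
            r.effect: r
            for r in hc.mixed_anova(
                sub, "G", within=["condition"], between="matched"
            )
        }
        ref = pg.mixed_anova(
            sub, dv="value", within="condition", subject="session",
            between="matched",
        ).set_index("Source")
        assert mine["matched"].F == pytest.approx(ref.loc["matched", "F"])
        assert mine["condition * matched"].F == pytest.approx(
            ref.loc["Interaction", "F"]
        )
        assert mine["condition"].df2 == 7

    def test_matches_pingouin_two_way_rm_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        df = synth_table(rng, effects={"condition": 0.5, "condition*skill": 0.3})
        mine = {r.effect: r for r in hc.mixed_anova(
            df, "G", within=["condition", "skill"]
        )}
        ref = pg.rm_anova(
            df, dv="value", within=["condition", "skill"], subject="session"
        ).set_index("Source")
        assert mine["condition"].F == pytest.approx(ref.loc["condition", "F"])
        assert mine["skill"].F == pytest.approx(ref.loc["skill", "F"])
        assert mine["condition * skill"].F == pytest.approx(
            ref.loc["condition * skill", "F"]
        )

    def test_matches_multistratum_reference_decomposition(self):
        """Frozen oracle: balanced 3-factor split-plot computed independently
        with a multistratum sums-of-squares fit (R aov, Error(session/
        (condition*skill)))."""
        rng = np.random.default_rng(42)
        rows = []
        for s in range(8):
            g = "M" if s < 4 else "U"
            base = rng.normal(0, 1)
            for c in ("SOLO", "PAIRED"):
                for k in ("less", "more"):
                    val = (
                        base
                        + (0.5 if c == "PAIRED" else 0)
                        + (0.3 if k == "more" else 0)
                        + (0.4 if (c == "PAIRED" and k == "more") else 0)
                        + (0.6 if g == "M" else 0)
                        + (0.25 if (g == "M" and c == "PAIRED") else 0)
                        + rng.normal(0, 0.4)
                    )
                    rows.append(
                        dict(session=f"s{s}", condition=c, skill=k,
                             matched=g, measure="G", value=val)
                    )
        res = {r.effect: r for r in hc.mixed_anova(
            pd.DataFrame(rows), "G", within=["condition", "skill"],
            between="matched",
        )}
        frozen = {
            "matched": 0.055,
            "condition": 150.708,
            "condition * matched": 3.845,
            "skill": 87.789,
            "skill * matched": 26.080,
            "condition * skill": 0.700,
            "condition * skill * matched": 1.082,
        }
        for effect, f_ref in frozen.items():
            assert res[effect].F == pytest.approx(f_ref, abs=1.5e-3)
            assert res[effect].df2 == 6

    def test_unbalanced_cells_rejected(self):
        df = synth_table(np.random.default_rng(5))
        df = df[~((df.session == "s0") & (df.condition == "SOLO"))]
        with pytest.raises(ValueError, match="incomplete"):
            hc.mixed_anova(df, "G", within=["condition", "skill"])

    def test_single_session_group_rejected(self):
        df = synth_table(np.random.default_rng(6), n_sessions=4, n_matched=1)
        with pytest.raises(ValueError, match="at least 2 sessions"):
            hc.mixed_anova(df, "G", within=["condition"], between="matched")


class TestFollowupTTests:
    def test_identical_samples_give_zero_t_and_d(self):
        x = np.array([0.1, 0.4, 0.3, 0.8])
        res = hc.followup_ttests([("same", x, x.copy())])
        assert res[0].t == 0.0 and res[0].cohen_d == 0.0
        assert res[0].p_corrected == 1.0

    def test_single_contrast_keeps_raw_p(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 8), rng.normal(0.5, 1, 8)
        res = hc.followup_ttests([("c", a, b)])
        assert res[0].p_corrected == pytest.approx(res[0].p_raw)

    def test_paired_t_and_d_match_closed_form(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        b = a - np.array([0.5, 0.7, 0.3, 0.6, 0.4, 0.5, 0.5])
        res = hc.followup_ttests([("c", a, b)])[0]
        diff = a - b
        t_hand = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert res.t == pytest.approx(t_hand, abs=1e-12)
        assert res.df == 6
        assert res.cohen_d == pytest.approx(diff.mean() / diff.std(ddof=1))

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(8)
        contrasts = [
            (f"c{i}", rng.normal(0, 1, 6), rng.normal(0, 1, 6)) for i in range(4)
        ]
        res = hc.followup_ttests(contrasts)
        for r in res:
            assert r.p_corrected >= r.p_raw
            assert r.p_corrected == pytest.approx(min(1.0, r.p_raw * 4))


class TestHyperbrainTTests:
    def frame(self, a_vals, b_vals, measures=hc.stats.HYPERBRAIN_MEASURES):
        rows = []
        for meas in measures:
            for i, v in enumerate(a_vals):
                rows.append(dict(session=f"m{i}", measure=meas, value=v,
                                 matched=True))
            for i, v in enumerate(b_vals):
                rows.append(dict(session=f"u{i}", measure=meas, value=v,
                                 matched=False))
        return pd.DataFrame(rows)

    def test_five_measures_give_five_rows(self):
        rng = np.random.default_rng(9)
        df = self.frame(rng.random(3), rng.random(4))
        res = hc.hyperbrain_group_ttests(df)
        assert [r.name for r in res] == list(hc.stats.HYPERBRAIN_MEASURES)
        assert all(r.df == 5 for r in res)

    def test_identical_groups_give_p_one(self):
        vals = np.array([0.2, 0.5, 0.8])
        df = self.frame(vals, vals)
        for r in hc.hyperbrain_group_ttests(df):
            assert r.p_raw == pytest.approx(1.0)

    def test_zero_variance_guard(self):
        df = self.frame([0.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="zero variance"):
            res = hc.hyperbrain_group_ttests(df)
        assert all(np.isinf(r.t) and r.p_raw == 0.0 for r in res)

    def test_small_group_rejected(self):
        df = self.frame([0.1], [0.2, 0.3])
        with pytest.raises(ValueError, match=">= 2 sessions"):
            hc.hyperbrain_group_ttests(df)
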
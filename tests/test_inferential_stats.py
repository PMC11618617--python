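"""Repeated-measures ANOVA against longhand oracles, and the association tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vrheadmotion.conformity import ConformityScore
from vrheadmotion.errors import InferenceError
from vrheadmotion.inferential_stats import (
    conformity_association_table,
    pearson_assoc,
    rating_intercorrelation,
    rm_anova,
)
from vrheadmotion.io_formats import TrialRecord


# ---------------------------------------------------------------------------
# longhand SS-decomposition oracle (independent of the implementation)
# ---------------------------------------------------------------------------

def _cell_mean(df, dv, factors, levels):
    sub = df
    for f, l in zip(factors, levels):
        sub = sub[sub[f] == l]
    return sub[dv].mean()


def anova_oracle_within(df, dv, within, subject="participant_id"):
    """Brute-force within-subjects ANOVA by explicit marginal-mean differencing.

    Treats subject as a crossed random factor; each effect E is tested against
    E x subject.  Returns {effect: (F, df1, df2, eta_p_sq)}.
    """
    factors = list(within) + [subject]
    levels = {f: sorted(df[f].unique()) for f in factors}
    out = {}

    def ss_of(effect):
        total = 0.0
        for _, row in df.iterrows():
            est = 0.0
            for k in range(len(effect) + 1):
                for sub in itertools.combinations(effect, k):
                    sign = (-1) ** (len(effect) - len(sub))
                    est += sign * _cell_mean(df, dv, sub, [row[f] for f in sub])
            total += est**2
        return total

    for k in range(1, len(within) + 1):
        for eff in itertools.combinations(within, k):
            ss_e = ss_of(eff)
            ss_err = ss_of(eff + (subject,))
            df1 = int(np.prod([len(levels[f]) - 1 for f in eff]))
            df2 = df1 * (len(levels[subject]) - 1)
            if ss_err == 0:
                F = 0.0 if ss_e == 0 else np.inf
            else:
                F = (ss_e / df1) / (ss_err / df2)
            eta = 0.0 if ss_e + ss_err == 0 else ss_e / (ss_e + ss_err)
            out[":".join(eff)] = (F, df1, df2, eta)
    return out


def _random_within_design(rng, n_factors, n_subjects):
    names = ["A", "B", "D"][:n_factors]
    sizes = rng.integers(2, 4, n_factors)
    rows = []
    for s in range(n_subjects):
        for cell in itertools.product(*(range(k) for k in sizes)):
            rows.append(
                {
                    "participant_id": f"s{s}",
                    **{n: f"l{v}" for n, v in zip(names, cell)},
                    "y": float(rng.normal()),
                }
            )
    return pd.DataFrame(rows), names


class TestRmAnova:
    def test_constant_dv_gives_zero_f_everywhere(self):
        rows = [
            {"participant_id": f"s{s}", "A": a, "B": b, "y": 7.0}
            for s in range(4)
            for a in "xy"
            for b in "pq"
        ]
        out = rm_anova(pd.DataFrame(rows), "y", within=["A", "B"])
        assert (out.F == 0).all()
        assert (out.eta_p_sq == 0).all()

    def test_two_by_two_toy_matches_longhand_oracle(self, rng):
        df, names = _random_within_design(rng, 2, 4)
        out = rm_anova(df, "y", within=names).set_index("effect")
        oracle = anova_oracle_within(df, "y", names)
        for effect, (F, df1, df2, eta) in oracle.items():
            assert out.loc[effect, "F"] == pytest.approx(F, abs=1e-9)
            assert out.loc[effect, "df_num"] == df1
            assert out.loc[effect, "df_den"] == df2
            assert out.loc[effect, "eta_p_sq"] == pytest.approx(eta, abs=1e-9)

    @pytest.mark.parametrize("n_factors", [1, 2, 3])
    def test_random_designs_match_statsmodels(self, rng, n_factors):
        from statsmodels.stats.anova import AnovaRM

        for _ in range(3):
            df, names = _random_within_design(rng, n_factors, int(rng.integers(4, 7)))
            mine = rm_anova(df, "y", within=names).set_index("effect")
            table = AnovaRM(df, "y", "participant_id", within=names).fit().anova_table
            for effect in table.index:
                assert mine.loc[effect, "F"] == pytest.approx(
                    table.loc[effect, "F Value"], abs=1e-8
                )
                assert mine.loc[effect, "p"] == pytest.approx(
                    table.loc[effect, "Pr > F"], abs=1e-8
                )

    def test_mixed_design_matches_pingouin(self, rng):
        import pingouin as pg

        rows = []
        for s in range(10):
            group = "g1" if s < 5 else "g2"
            for w in "uv":
                rows.append(
                    {
                        "participant_id": f"s{s}",
                        "G": group,
                        "W": w,
                        "y": float(rng.normal() + (0.8 if group == "g1" else 0.0)),
                    }
                )
        df = pd.DataFrame(rows)
        mine = rm_anova(df, "y", within=["W"], between=["G"]).set_index("effect")
        ref = pg.mixed_anova(
            data=df, dv="y", within="W", between="G", subject="participant_id"
        ).set_index("Source")
        for source, effect in (("G", "G"), ("W", "W"), ("Interaction", "G:W")):
            assert mine.loc[effect, "F"] == pytest.approx(ref.loc[source, "F"], abs=1e-8)

    def test_missing_cell_names_participant_and_cell(self, rng):
        df, names = _random_within_design(rng, 2, 4)
        df = df.drop(df.index[3])
        with pytest.raises(InferenceError, match="s0"):
            rm_anova(df, "y", within=names)

    def test_unbalanced_groups_use_unweighted_means(self, rng):
        # 5 + 3 subjects: runs, warns, and stays exact for the within effect
        rows = []
        for s in range(8):
            group = "g1" if s < 5 else "g2"
            for w in "uv":
                rows.append(
                    {"participant_id": f"s{s}", "G": group, "W": w, "y": float(rng.normal())}
                )
        out = rm_anova(pd.DataFrame(rows), "y", within=["W"], between=["G"])
        assert set(out.effect) == {"G", "W", "G:W"}
        assert (out.df_den == [6, 6, 6]).all()

    def test_greenhouse_geisser_epsilon_is_one_for_two_levels(self, rng):
        df, names = _random_within_design(rng, 1, 6)
        out = rm_anova(df, "y", within=names, correction="gg")
        eff = out.iloc[0]
        if df[names[0]].nunique() == 2:
            assert eff.gg_epsilon == pytest.approx(1.0)
        assert 0 < eff.gg_epsilon <= 1.0
        assert eff.p_gg >= eff.p - 1e-12

    def test_null_simulation_yields_uniform_p(self):
        # 2-level one-factor null: p-values should be U(0, 1)
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            rows = [
                {"participant_id": f"s{s}", "A": a, "y": float(rng.normal())}
                for s in range(8)
                for a in "xy"
            ]
            ps.append(rm_anova(pd.DataFrame(rows), "y", within=["A"]).iloc[0].p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPearsonAssoc:
    def test_exact_linearity(self):
        x = np.arange(6.0)
        assert pearson_assoc(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_sign_inversion(self):
        x = np.arange(6.0)
        assert pearson_assoc(x, -x).r == pytest.approx(-1.0)

    def test_matches_hand_formula(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        res = pearson_assoc(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        assert res.r == pytest.approx(cov / (x.std() * y.std()), abs=1e-12)

    def test_constant_input_degenerate(self):
        res = pearson_assoc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert res.degenerate

    def test_too_few_pairs_rejected(self):
        with pytest.raises(InferenceError):
            pearson_assoc([1.0, 2.0], [1.0, 2.0])


def _score(pid, axis, speed, r):
    return ConformityScore(
        participant_id=pid, axis=axis, speed_condition=speed, r=r, n_points=5400
    )


def _trial(pid, speed, vection, experiment=2, direction="forward"):
    return TrialRecord(
        participant_id=pid,
        experiment=experiment,
        direction=direction,
        speed=speed,
        vection_magnitude=vection,
        vection_onset=5.0 if vection >= 2 else None,
        vection_duration=10.0 if vection >= 2 else None,
        sickness=3,
        presence=10,
        trial_index=0,
    )


class TestAssociationTable:
    def test_full_table_is_18_rows(self, rng):
        scores = [
            _score(f"p{i}", axis, speed, float(rng.uniform(-0.2, 0.9)))
            for i in range(8)
            for axis in ("pitch", "yaw", "roll")
            for speed in ("slow", "fast")
        ]
        records = [
            _trial(f"p{i}", speed, int(rng.integers(1, 21)))
            for i in range(8)
            for speed in ("slow", "fast")
        ]
        table = conformity_association_table(scores, records)
        assert len(table) == 18
        assert set(table.measure) == {"vection", "sickness", "presence"}

    def test_insufficient_pairs_flagged(self):
        scores = [_score("p0", "yaw", "slow", 0.5), _score("p1", "yaw", "slow", 0.4)]
        records = [_trial("p0", "slow", 5), _trial("p1", "slow", 7)]
        table = conformity_association_table(scores, records)
        yaw_slow = table[(table.axis == "yaw") & (table.speed_condition == "slow")]
        assert bool(yaw_slow.iloc[0].insufficient_n)

    def test_only_matching_condition_trials_are_joined(self, rng):
        # reverse-direction ratings must not enter the association
        scores = [_score(f"p{i}", "yaw", "slow", 0.1 * i) for i in range(6)]
        forward = [_trial(f"p{i}", "slow", 2 + i) for i in range(6)]
        reverse = [
            _trial(f"p{i}", "slow", 20 - 2 * i, direction="reverse") for i in range(6)
        ]
        with_reverse = conformity_association_table(scores, forward + reverse)
        without = conformity_association_table(scores, forward)
        row_a = with_reverse[(with_reverse.axis == "yaw") & (with_reverse.measure == "vection")]
        row_b = without[(without.axis == "yaw") & (without.measure == "vection")]
        assert row_a[row_a.speed_condition == "slow"].iloc[0].r == pytest.approx(
            row_b[row_b.speed_condition == "slow"].iloc[0].r
        )


class TestRatingIntercorrelation:
    def test_participant_mean_mode(self):
        records = []
        for i in range(6):
            for speed in ("slow", "fast"):
                records.append(_trial(f"p{i}", speed, vection=2 + i))
        res = rating_intercorrelation(records, "vection_magnitude", "vection_magnitude")
        assert res.r == pytest.approx(1.0)
        assert res.n == 6

    def test_stationary_trials_excluded(self):
        records = [_trial(f"p{i}", "slow", 2 + i) for i in range(5)]
        records += [_trial(f"p{i}", "stationary", 1) for i in range(5)]
        res = rating_intercorrelation(records, "vection_magnitude", "presence")
        assert res.n == 5
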
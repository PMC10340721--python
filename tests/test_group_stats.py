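import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.formula.api import ols

from mitoquant.group_stats import (
    CellMeasurement,
    one_way_anova_lsd,
    summarise_groups,
    two_way_anova_lsd,
)
import functools
import operator


def _ms(groups: dict[str, list[float]], metric="m", factor2=None):
    out = []
    for g, vals in groups.items():
        for i, v in enumerate(vals):
            out.append(CellMeasurement(f"{g}{i}", g, metric, float(v), factor2=factor2))
    return out


class TestSummaries:
    def test_constant_group(self):
        (s,) = summarise_groups(_ms({"A": [5, 5, 5]}))
        assert s.mean == 5 and s.sem == 0 and s.n == 3

    def test_closed_form_sem(self):
        (s,) = summarise_groups(_ms({"A": [1, 2, 3]}))
        assert s.mean == pytest.approx(2.0)
        assert s.sem == pytest.approx(1 / np.sqrt(3))

    def test_single_value_sem_undefined(self):
        (s,) = summarise_groups(_ms({"A": [4.2]}))
        assert s.sem is None

    def test_matches_two_pass_computation(self, rng):
        vals = {g: list(rng.normal(0, 2, 7)) for g in "ABC"}
        for s in summarise_groups(_ms(vals)):
            v = np.asarray(vals[s.group])
            mean = v.sum() / len(v)
            sd = np.sqrt(((v - mean) ** 2).sum() / (len(v) - 1))
            assert s.mean == pytest.approx(mean)
            assert s.sem == pytest.approx(sd / np.sqrt(len(v)))


class TestOneWay:
    def test_textbook_table(self):
        res = one_way_anova_lsd(_ms({"A": [1, 2, 3], "B": [4, 5, 6], "C": [7, 8, 9]}), "m")
        # hand computation: group means 2,5,8; grand 5; SSB=54, SSW=6
        assert res.ss["group"] == pytest.approx(54.0, abs=1e-12)
        assert res.ss["residual"] == pytest.approx(6.0, abs=1e-12)
        assert res.f_stats["group"] == pytest.approx(27.0, abs=1e-9)
        assert res.df == {"group": 2, "residual": 6}

    def test_matches_statsmodels(self, rng):
        groups = {g: list(rng.normal(mu, 1.5, 9)) for g, mu in [("A", 0), ("B", 1), ("C", 0.5)]}
        res = one_way_anova_lsd(_ms(groups), "m")
        df = pd.DataFrame(
            {"g": functools.reduce(operator.iadd, ([g] * 9 for g in groups), []), "v": functools.reduce(operator.iadd, groups.values(), [])}
        )
        tab = sm.stats.anova_lm(ols("v ~ C(g)", df).fit())
        assert res.f_stats["group"] == pytest.approx(tab["F"].iloc[0], rel=1e-10)
        assert res.p_values["group"] == pytest.approx(tab["PR(>F)"].iloc[0], rel=1e-10)

    def test_ss_decomposition(self, rng):
        groups = {g: list(rng.normal(0, 1, 6)) for g in "ABCD"}
        res = one_way_anova_lsd(_ms(groups), "m")
        allv = np.concatenate([np.asarray(v) for v in groups.values()])
        ss_total = ((allv - allv.mean()) ** 2).sum()
        assert res.ss["group"] + res.ss["residual"] == pytest.approx(ss_total, rel=1e-12)

    def test_invariance_to_relabelling_and_shift(self, rng):
        groups = {g: list(rng.normal(0, 1, 8)) for g in "AB"}
        p0 = one_way_anova_lsd(_ms(groups), "m").p_values["group"]
        renamed = {"X": groups["A"], "Y": groups["B"]}
        assert one_way_anova_lsd(_ms(renamed), "m").p_values["group"] == pytest.approx(p0)
        shifted = {g: [v + 100 for v in vals] for g, vals in groups.items()}
        assert one_way_anova_lsd(_ms(shifted), "m").p_values["group"] == pytest.approx(p0)

    def test_lsd_uses_pooled_error(self, rng):
        groups = {g: list(rng.normal(mu, 1, 9)) for g, mu in [("A", 0), ("B", 2), ("C", 0)]}
        res = one_way_anova_lsd(_ms(groups), "m")
        comp = next(c for c in res.lsd if {c.level_a, c.level_b} == {"A", "B"})
        se = np.sqrt(res.residual_ms * (2 / 9))
        est = np.mean(groups["A"]) - np.mean(groups["B"])
        assert comp.estimate == pytest.approx(est)
        assert comp.t == pytest.approx(est / se)
        assert comp.significant

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="zero residual variance"):
            one_way_anova_lsd(_ms({"A": [1, 1, 1], "B": [1, 1, 1]}), "m")
        with pytest.raises(ValueError, match=">= 2 groups"):
            one_way_anova_lsd(_ms({"A": [1, 2, 3]}), "m")
        with pytest.raises(ValueError, match=">= 2 values"):
            one_way_anova_lsd(_ms({"A": [1, 2], "B": [3]}), "m")


class TestTwoWay:
    @staticmethod
    def _crossed(rng, effects=None, n=6):
        effects = effects or {}
        ms = []
        for g in ("A", "B"):
            for f2 in ("fission", "fusion"):
                mu = effects.get((g, f2), 0.0)
                for i, v in enumerate(rng.normal(mu, 1.0, n)):
                    ms.append(CellMeasurement(f"{g}{f2}{i}", g, "m", float(v), factor2=f2))
        return ms

    def test_matches_statsmodels(self, rng):
        ms = self._crossed(rng, {("B", "fission"): 1.5, ("B", "fusion"): 0.5})
        res = two_way_anova_lsd(ms, "m")
        df = pd.DataFrame(
            {"g": [m.group for m in ms], "f2": [m.factor2 for m in ms],
             "v": [m.value for m in ms]}
        )
        tab = sm.stats.anova_lm(ols("v ~ C(g)*C(f2)", df).fit())
        for ours, theirs in zip(("group", "factor2", "interaction"), range(3)):
            assert res.f_stats[ours] == pytest.approx(tab["F"].iloc[theirs], rel=1e-10)
            assert res.p_values[ours] == pytest.approx(tab["PR(>F)"].iloc[theirs], rel=1e-10)

    def test_balanced_ss_decomposition(self, rng):
        ms = self._crossed(rng)
        res = two_way_anova_lsd(ms, "m")
        vals = np.array([m.value for m in ms])
        ss_total = ((vals - vals.mean()) ** 2).sum()
        assert sum(res.ss[k] for k in ("group", "factor2", "interaction", "residual")) == (
            pytest.approx(ss_total, rel=1e-12)
        )

    def test_missing_cell_named_in_error(self, rng):
        ms = self._crossed(rng)
        ms = [m for m in ms if not (m.group == "B" and m.factor2 == "fusion")]
        with pytest.raises(ValueError, match="group='B', factor2='fusion'"):
            two_way_anova_lsd(ms, "m")

    def test_unbalanced_design_rejected(self, rng):
        ms = self._crossed(rng)
        ms.append(CellMeasurement("extra", "A", "m", 0.1, factor2="fission"))
        with pytest.raises(ValueError, match="balanced"):
            two_way_anova_lsd(ms, "m")

    def test_main_effect_power_with_large_shift(self):
        # additive shift of 3x residual SD on one level: detected in >= 90% of runs
        detected = 0
        runs = 40
        for seed in range(runs):
            rng = np.random.default_rng(1000 + seed)
            ms = self._crossed(rng, {("B", "fission"): 3.0, ("B", "fusion"): 3.0}, n=9)
            res = two_way_anova_lsd(ms, "m")
            detected += res.p_values["group"] < 0.05
        assert detected / runs >= 0.9

    def test_null_interaction_rarely_significant(self):
        sig = 0
        runs = 60
        for seed in range(runs):
            rng = np.random.default_rng(2000 + seed)
            res = two_way_anova_lsd(self._crossed(rng, n=9), "m")
            sig += res.p_values["interaction"] < 0.05
        assert sig / runs <= 0.10
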
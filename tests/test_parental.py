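"""Effect partition, Fisher's LSD, and estimator recovery on simulations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from rutinseq.datasets import CROSSES, LINES
from rutinseq.parental import (
    ParentalEffectsModel,
    compute_effects,
    group_mean_effects,
    lsd_test,
    maternal_effect,
    mid_parent_value,
    pollen_effect,
    star_code,
)
from rutinseq.simulate import RutinSimSpec, simulate_rutin
from rutinseq.types import (
    CrossSpec,
    LineSpec,
    RunConfig,
    SeedRutinRecord,
    UndefinedEffectError,
    round_half_away,
)


class TestEffectFormulas:
    def test_mid_parent_published_cells(self):
        assert round_half_away(mid_parent_value(0.60, 0.18)) == 0.39
        assert round_half_away(mid_parent_value(0.60, 0.06)) == 0.33

    @given(st.floats(-10, 10))
    def test_mid_parent_symmetry(self, x):
        assert mid_parent_value(x, x) == x

    def test_maternal_effect_published_cell(self):
        m = maternal_effect(0.40, 0.60, 0.15)
        assert round_half_away(m) == 0.56
        assert round_half_away(pollen_effect(m)) == 0.44

    def test_maternal_effect_endpoints(self):
        assert maternal_effect(0.60, 0.60, 0.15) == 1.0
        assert maternal_effect(0.15, 0.60, 0.15) == 0.0

    def test_equal_parents_undefined(self):
        with pytest.raises(UndefinedEffectError):
            maternal_effect(0.3, 0.5, 0.5)

    def test_pollen_effect_complement(self):
        assert pollen_effect(1.0) == 0.0
        assert pollen_effect(0.5) == 0.5
        m = maternal_effect(0.40, 0.60, 0.15)
        assert m + pollen_effect(m) == 1.0  # exact at full precision

    @given(
        f1=st.floats(-1, 2), pm=st.floats(-1, 2), pp=st.floats(-1, 2),
        a=st.floats(-5, 5), b=st.floats(-5, 5),
    )
    def test_affine_invariance(self, f1, pm, pp, a, b):
        """m is invariant under y -> a*y + b (a != 0) of all three means."""
        if abs(pm - pp) < 1e-6 or abs(a) < 1e-3:
            return
        m0 = maternal_effect(f1, pm, pp)
        m1 = maternal_effect(a * f1 + b, a * pm + b, a * pp + b)
        assert m1 == pytest.approx(m0, abs=1e-6)

    @given(pm=st.floats(0, 1), pp=st.floats(0, 1))
    def test_f1_at_midparent_iff_half(self, pm, pp):
        if abs(pm - pp) < 1e-6:
            return
        mp = mid_parent_value(pm, pp)
        assert maternal_effect(mp, pm, pp) == pytest.approx(0.5)

    def test_group_mean_published_blocks(self):
        assert round_half_away(group_mean_effects([0.35, 0.02, 0.14, 0.25])) == 0.19
        avg = group_mean_effects([0.51, 0.60, 0.44, 0.68, 0.29, 0.26])
        assert round_half_away(avg) == 0.46
        assert group_mean_effects([0.7]) == 0.7
        with pytest.raises(ValueError):
            group_mean_effects([])


class TestLsd:
    def test_identical_means_no_stars(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 0.5, 40)
        res = lsd_test([("A", a), ("B", a)])
        assert res.p("A", "B") == pytest.approx(1.0)
        assert res.stars("A", "B") == "1.00"

    def test_two_groups_equals_pooled_t(self):
        """For k = 2 the LSD p equals the pooled two-sample t-test p."""
        rng = np.random.default_rng(1)
        a, b = rng.normal(0.6, 0.4, 75), rng.normal(0.3, 0.4, 75)
        res = lsd_test([("A", a), ("B", b)])
        _, p_oracle = stats.ttest_ind(a, b, equal_var=True)
        assert res.p("A", "B") == pytest.approx(p_oracle, rel=1e-10)

    def test_three_groups_against_quadrature_cdf(self):
        """Pairwise p matches direct integration of the t density at the
        pooled statistic and its ANOVA degrees of freedom."""
        rng = np.random.default_rng(2)
        groups = [("A", rng.normal(0.6, 0.4, 75)),
                  ("B", rng.normal(0.4, 0.4, 75)),
                  ("C", rng.normal(0.2, 0.4, 75))]
        res = lsd_test(groups)
        arrays = dict((k, np.asarray(v)) for k, v in groups)
        n = sum(len(v) for v in arrays.values())
        df = n - 3
        sse = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
        mse = sse / df

        def t_density(x):
            from scipy.special import gammaln
            lg = gammaln((df + 1) / 2) - gammaln(df / 2)
            return np.exp(lg) / np.sqrt(df * np.pi) * (1 + x * x / df) ** (-(df + 1) / 2)

        for a, b in (("A", "B"), ("A", "C"), ("B", "C")):
            t = (arrays[a].mean() - arrays[b].mean()) / np.sqrt(mse * (2 / 75))
            tail, _ = integrate.quad(t_density, abs(t), np.inf)
            assert res.p(a, b) == pytest.approx(2 * tail, rel=1e-6)

    def test_degenerate_variance(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = lsd_test([("A", [1.0, 1.0]), ("B", [2.0, 2.0])])
        assert res.p("A", "B") == 0.0
        with pytest.warns(UserWarning, match="degenerate"):
            res = lsd_test([("A", [1.0, 1.0]), ("B", [1.0, 1.0])])
        assert res.p("A", "B") == 1.0

    @pytest.mark.parametrize("p,code", [
        (0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.87, "0.87"),
    ])
    def test_star_codes(self, p, code):
        assert star_code(p) == code


def make_records(label, values):
    return [SeedRutinRecord(label, 1 + i // 15, 1 + i % 15, float(v))
            for i, v in enumerate(values)]


class TestComputeEffects:
    def test_f1_equal_to_pm_sample_gives_m_one(self):
        rng = np.random.default_rng(3)
        pm = rng.normal(0.6, 0.1, 30)
        pp = rng.normal(0.2, 0.05, 30)
        records = (make_records("A", pm) + make_records("B", pp)
                   + make_records("x", pm))
        effects = compute_effects(records, [], [CrossSpec("x", "A", "B", "p")])
        assert effects[0].m == pytest.approx(1.0)
        assert effects[0].pollen_effect == pytest.approx(0.0)

    def test_missing_group_skipped(self, caplog):
        records = make_records("A", [0.5, 0.6])
        effects = compute_effects(records, [], [CrossSpec("x", "A", "B", "p")])
        assert effects == []

    def test_recovery_of_true_maternal_effect(self):
        """m_truth = 0.7 recovered within 0.02 at 750 seeds per group."""
        lines = [LineSpec("HI", "SI", "mixed", 0.60, 0.10),
                 LineSpec("LO", "SC", "long_homostyle", 0.10, 0.03)]
        cross = CrossSpec("x", "HI", "LO", "p")
        spec = RutinSimSpec(lines=lines, n_plants=50, n_seeds_per_plant=15,
                            f1_sd=0.05)
        records = simulate_rutin(spec, {"x": 0.7}, [cross], seed=21)
        effects = compute_effects(records, lines, [cross])
        assert abs(effects[0].m - 0.7) < 0.02

    def test_bias_shrinks_with_sample_size(self):
        """Mean absolute error of the m estimator falls as n grows."""
        lines = [LineSpec("HI", "SI", "mixed", 0.60, 0.10),
                 LineSpec("LO", "SC", "long_homostyle", 0.10, 0.03)]
        cross = CrossSpec("x", "HI", "LO", "p")
        maes = []
        for n_plants in (1, 5, 50):  # 15, 75, 750 seeds per group
            errors = []
            for seed in range(30):
                spec = RutinSimSpec(lines=lines, n_plants=n_plants,
                                    n_seeds_per_plant=15, f1_sd=0.05)
                records = simulate_rutin(spec, {"x": 0.7}, [cross], seed=seed)
                effects = compute_effects(records, lines, [cross])
                errors.append(abs(effects[0].m - 0.7))
            maes.append(np.mean(errors))
        assert maes[0] > maes[1] > maes[2]

    def test_lsd_pooled_within_plot(self):
        """Crosses sharing a plot share one pooled error variance."""
        rng = np.random.default_rng(5)
        records = []
        for label, mu in (("A", 0.6), ("B", 0.2), ("x1", 0.5), ("x2", 0.3)):
            records += make_records(label, rng.normal(mu, 0.1, 30))
        crosses = [CrossSpec("x1", "A", "B", "p"), CrossSpec("x2", "B", "A", "p")]
        effects = compute_effects(records, [], crosses)
        # oracle: 4-group ANOVA over the plot
        res = lsd_test([(lab, [r.rutin for r in records if r.line == lab])
                        for lab in ("A", "B", "x1", "x2")])
        assert effects[0].p_pm_vs_f1 == pytest.approx(res.p("A", "x1"))
        assert effects[1].p_pp_vs_f1 == pytest.approx(res.p("A", "x2"))

    def test_effects_computed_from_unrounded_means(self):
        records = (make_records("A", [0.6001, 0.5999]) +
                   make_records("B", [0.1001, 0.0999]) +
                   make_records("x", [0.3501, 0.3499]))
        e = compute_effects(records, [], [CrossSpec("x", "A", "B", "p")])[0]
        assert e.m == pytest.approx((0.35 - 0.10) / (0.60 - 0.10))
        assert e.m + e.pollen_effect == 1.0


class TestModelInterface:
    def test_fit_summary_and_blocks(self):
        spec = RutinSimSpec(lines=LINES)
        m_truth = {c.cross_id: 0.6 for c in CROSSES}
        records = simulate_rutin(spec, m_truth, CROSSES, seed=17)
        model = ParentalEffectsModel(records, CROSSES, LINES)
        res = model.fit()
        assert len(res.effects) == 10
        blocks = res.block_averages()
        assert set(blocks) == {"high", "medium"}
        text = res.summary()
        assert "c1" in text and "avg(high)" in text
        df = res.to_frame(rounded=True)
        assert list(df.columns)[0] == "cross_id"
        # rounded frame values agree with round-half-away of raw values
        raw = res.to_frame(rounded=False)
        assert df["maternal_effect"].tolist() == [
            round_half_away(v) for v in raw["maternal_effect"]]
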
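"""Assay QC, knockdown proportions/curves, mixed models and selection."""
import numpy as np
import pandas as pd
import pytest

from conftest import make_assay
from thermobuffer import tolerance as tol
from thermobuffer.simulate import AssaySimParams, gen_assays
from thermobuffer.types import assays_to_frame


class TestQCFilter:
    def test_overheated_assay_removed(self):
        recs = [make_assay(individual_id=f"i{k}", temp_at_ko_c=40.0)
                for k in range(7)]
        recs.append(make_assay(individual_id="hot", temp_at_ko_c=42.3))
        kept, rpt = tol.qc_filter(recs)
        assert rpt.n_removed_overheat == 1
        assert all(r.temp_at_ko_c <= 41.9 for r in kept)

    def test_survivor_retained_with_sentinel(self):
        recs = [make_assay(individual_id=f"i{k}") for k in range(6)]
        recs.append(make_assay(individual_id="tough", knockdown_min=60.0,
                               censored=True))
        kept, rpt = tol.qc_filter(recs)
        assert rpt.n_censored == 1
        assert any(r.censored and r.knockdown_min == 60.0 for r in kept)

    def test_rare_group_rule_is_strict(self):
        # exactly five individuals at an elevation -> removed ("more than
        # five" retained); six retained
        five = [make_assay(individual_id=f"a{k}", group="rare") for k in range(5)]
        six = [make_assay(individual_id=f"b{k}", group="common") for k in range(6)]
        kept, rpt = tol.qc_filter(five + six)
        assert rpt.n_removed_rare_groups == 5
        assert {r.group for r in kept} == {"common"}

    def test_below_range_removed_before_rare_rule(self):
        recs = [make_assay(individual_id=f"i{k}") for k in range(6)]
        recs.append(make_assay(individual_id="cold", below_range=True))
        kept, rpt = tol.qc_filter(recs)
        assert rpt.n_removed_below_range == 1
        assert rpt.n_retained == 6
        assert rpt.n_input - (rpt.n_removed_overheat + rpt.n_removed_below_range
                              + rpt.n_removed_rare_groups) == rpt.n_retained


class TestPre39Proportion:
    def test_printed_highland_counts(self):
        recs = [make_assay(individual_id=f"i{k}",
                           temp_at_ko_c=37.0 if k < 60 else 40.0)
                for k in range(183)]
        out = tol.pre39_proportion(recs)
        assert out["n_pre39"] == 60
        assert out["proportion"] == pytest.approx(0.328, abs=5e-4)
        assert round(100 * out["proportion"]) == 33

    def test_printed_lowland_counts(self):
        recs = [make_assay(individual_id=f"i{k}",
                           temp_at_ko_c=38.0 if k < 6 else 40.0)
                for k in range(95)]
        assert tol.pre39_proportion(recs)["proportion"] == pytest.approx(
            0.063, abs=5e-4)

    def test_zero_events_ci_floor(self):
        recs = [make_assay(individual_id=f"i{k}") for k in range(20)]
        out = tol.pre39_proportion(recs)
        assert out["proportion"] == 0.0
        assert out["ci_low"] == 0.0
        assert out["ci_high"] > 0.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            tol.pre39_proportion([])


class TestResistanceCurves:
    def test_uncensored_empirical_survival(self):
        recs = [make_assay(individual_id="a", knockdown_min=1.0),
                make_assay(individual_id="b", knockdown_min=2.0)]
        c = tol.resistance_curves(recs, by="altitude_band")["low"]
        assert c.survival_at(1.0) == pytest.approx(0.5)
        assert c.survival_at(2.0) == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        recs = [make_assay(individual_id=f"i{k}", knockdown_min=60.0,
                           censored=True) for k in range(4)]
        c = tol.resistance_curves(recs)["low"]
        assert np.allclose(c.survival, 1.0)

    def test_product_limit_hand_oracle(self):
        # times [2, 4, 4, 6, 60+]: S(2)=4/5, S(4)=0.8*(2/4)=0.4,
        # S(6)=0.4*(1/2)=0.2, flat to the censored survivor at 60
        layout = [(2.0, False), (4.0, False), (4.0, False), (6.0, False),
                  (60.0, True)]
        recs = [make_assay(individual_id=f"i{k}", knockdown_min=t, censored=c)
                for k, (t, c) in enumerate(layout)]
        c = tol.resistance_curves(recs)["low"]
        assert c.survival_at(2.0) == pytest.approx(0.8)
        assert c.survival_at(4.0) == pytest.approx(0.4)
        assert c.survival_at(6.0) == pytest.approx(0.2)
        assert c.survival_at(60.0) == pytest.approx(0.2)

    def test_record_order_irrelevant(self, rng):
        cz = rng.random(30) < 0.2
        times = rng.uniform(1, 59, 30)
        recs = [make_assay(individual_id=f"i{k}",
                           knockdown_min=60.0 if c else float(t),
                           censored=bool(c))
                for k, (t, c) in enumerate(zip(times, cz))]
        c1 = tol.resistance_curves(recs)["low"]
        c2 = tol.resistance_curves(list(reversed(recs)))["low"]
        assert np.allclose(c1.survival, c2.survival)

    def test_curve_non_increasing(self):
        recs = gen_assays(AssaySimParams(n_groups=4, n_per_group_band=10,
                                         seed=8))
        for c in tol.resistance_curves(recs).values():
            assert (np.diff(c.survival) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_null(self):
        a = [make_assay(individual_id=f"a{k}", knockdown_min=float(k + 1))
             for k in range(5)]
        b = [make_assay(individual_id=f"b{k}", knockdown_min=float(k + 1))
             for k in range(5)]
        chi2, p = tol.logrank_test(a, b)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_hand_worked_two_by_two_oracle(self):
        # A events {1,2}, B events {3,4}: O_A=2, E_A=5/6, V=0.25+2/9
        a = [make_assay(individual_id="a1", knockdown_min=1.0),
             make_assay(individual_id="a2", knockdown_min=2.0)]
        b = [make_assay(individual_id="b1", knockdown_min=3.0),
             make_assay(individual_id="b2", knockdown_min=4.0)]
        chi2, p = tol.logrank_test(a, b)
        expect = (2 - 5 / 6) ** 2 / (0.25 + 2 / 9)
        assert chi2 == pytest.approx(expect, abs=1e-9)

    def test_no_events_rejected(self):
        a = [make_assay(individual_id="a", knockdown_min=60.0, censored=True)]
        with pytest.raises(ValueError):
            tol.logrank_test(a, a)


class TestANOVA:
    def test_f_is_squared_pooled_t(self):
        df = pd.DataFrame({"knockdown_min": [1.0, 2, 3, 4, 5, 6],
                           "group": list("aaabbb")})
        out = tol.group_anova(df)
        assert out["F"] == pytest.approx(13.5, abs=1e-9)
        assert (out["df_between"], out["df_within"]) == (1, 4)

    def test_zero_within_variance_rejected(self):
        df = pd.DataFrame({"knockdown_min": [1.0, 1, 2, 2],
                           "group": list("aabb")})
        with pytest.raises(ValueError):
            tol.group_anova(df)

    def test_null_p_roughly_uniform(self, rng):
        ps = []
        for _ in range(300):
            df = pd.DataFrame({
                "knockdown_min": rng.normal(10, 2, 40),
                "group": np.repeat(list("abcd"), 10)})
            ps.append(tol.group_anova(df)["p"])
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestLMMAndRepeatability:
    def test_altitude_effect_recovered(self):
        p = AssaySimParams(n_groups=10, n_per_group_band=10, baseline_min=20.0,
                           altitude_effect_min=10.0, group_sd_min=2.0,
                           resid_sd_min=3.0, pre39_prob_high=0.0,
                           pre39_prob_low=0.0, seed=13)
        fit = tol.fit_lmm(gen_assays(p), terms=["altitude_band"])
        j = fit.fe_names.index("altitude_band[low]")
        assert fit.fe_params[j] == pytest.approx(10.0, abs=1.0)

    def test_repeatability_formula(self):
        from thermobuffer.lmm import LMMResults

        # R = 1 / (1 + 3) for sigma2_g=1, sigma2_e=3
        class Dummy:
            pass
        r = LMMResults(model=None, fe_params=np.array([0.0]),
                       fe_se=np.array([0.0]), fe_names=["Intercept"],
                       sigma2_group=1.0, sigma2_resid=3.0, llf=0.0, reml=True)
        assert r.repeatability == pytest.approx(0.25)

    def test_repeatability_pipeline(self):
        p = AssaySimParams(n_groups=30, n_per_group_band=5, baseline_min=20.0,
                           altitude_effect_min=0.0, group_sd_min=2.0,
                           resid_sd_min=2.26, pre39_prob_high=0.0,
                           pre39_prob_low=0.0, seed=17)
        out = tol.repeatability(gen_assays(p), n_boot=150, seed=5)
        assert out.repeatability == pytest.approx(p.icc, abs=0.15)
        assert 0 <= out.ci_low <= out.repeatability <= out.ci_high <= 1
        assert out.p_lrt < 0.01
        assert out.n_boot_failed == 0

    def test_r2_arithmetic(self):
        r = type("R", (), {})()
        from thermobuffer.tolerance import r2_lmm
        from thermobuffer.lmm import LMMResults

        class FakeModel:
            X = np.array([[1.0], [1.0]])
        res = LMMResults(model=FakeModel(), fe_params=np.array([5.0]),
                         fe_se=np.array([1.0]), fe_names=["Intercept"],
                         sigma2_group=1.0, sigma2_resid=1.0, llf=0.0,
                         reml=True)
        # intercept-only fixed part: marginal R2 is 0
        r2m, r2c = r2_lmm(res)
        assert r2m == 0.0
        assert r2c == pytest.approx(0.5)


class TestBackwardSelection:
    def test_strong_effect_retained_noise_dropped(self):
        p = AssaySimParams(n_groups=10, n_per_group_band=25, baseline_min=20.0,
                           altitude_effect_min=8.0, group_sd_min=2.0,
                           resid_sd_min=3.0, pre39_prob_high=0.0,
                           pre39_prob_low=0.0, seed=23)
        df = assays_to_frame(gen_assays(p))
        rng = np.random.default_rng(1)
        df["noise"] = rng.normal(size=len(df))
        sel = tol.backward_select(df, terms=["altitude_band", "noise"])
        assert "altitude_band" in sel.final_terms
        assert sel.random_effect_retained

    def test_marginality_protects_main_effects(self, rng):
        # build data with a strong interaction; its main effects must survive
        n = 300
        g = np.repeat(np.arange(10), 30)
        a = rng.random(n) < 0.5
        x = rng.normal(size=n)
        y = 10 + 3 * a * x + 0.5 * rng.normal(size=10)[g] + rng.normal(size=n)
        df = pd.DataFrame({"knockdown_min": y, "group": g,
                           "a": np.where(a, "yes", "no"), "x": x})
        sel = tol.backward_select(df, terms=["a", "x", "a:x"])
        assert "a:x" in sel.final_terms
        assert {"a", "x"} <= set(sel.final_terms)
        trace = sel.trace_frame()
        assert set(trace.columns) >= {"step", "effect", "p", "action"}

    def test_pure_noise_model_drops_to_intercept(self, rng):
        n = 400
        g = np.repeat(np.arange(20), 20)
        y = 5 + 2.0 * rng.normal(size=20)[g] + rng.normal(size=n)
        df = pd.DataFrame({"knockdown_min": y, "group": g,
                           "z1": rng.normal(size=n), "z2": rng.normal(size=n)})
        sel = tol.backward_select(df, terms=["z1", "z2"])
        # both pure-noise covariates together survive only ~10% of the time;
        # the fitted seed gives the typical outcome
        assert sel.final_terms == [] or len(sel.final_terms) <= 1
        assert sel.random_effect_retained
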
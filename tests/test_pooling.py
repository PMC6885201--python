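"""Fixed/random-effects pooling, heterogeneity, model selection, sensitivity."""

import json
import subprocess

import numpy as np
import pytest
from scipy import stats

import micmeta as mm
from micmeta.effect_size import EffectEstimate
from micmeta.pooling import Z95


def _eff(effect, variance, sid="S"):
    return EffectEstimate(sid, effect, variance, "hedges_g")


def _wls_oracle(effects):
    """Independent route: intercept-only weighted least squares via statsmodels."""
    import statsmodels.api as sm

    y = np.array([e.effect for e in effects])
    w = 1.0 / np.array([e.variance for e in effects])
    fit = sm.WLS(y, np.ones_like(y), weights=w).fit()
    est = float(fit.params[0])
    se = float(np.sqrt(1.0 / w.sum()))
    return est, se


class TestFixed:
    def test_single_study_passthrough(self):
        r = mm.pool_fixed([_eff(0.7, 0.04)])
        assert r.estimate == pytest.approx(0.7)
        assert (r.q, r.i_squared) == (0.0, 0.0)
        assert r.ci_low == pytest.approx(0.7 - Z95 * 0.2)

    def test_two_identical_studies(self):
        r = mm.pool_fixed([_eff(0.5, 0.1, "a"), _eff(0.5, 0.1, "b")])
        assert r.estimate == pytest.approx(0.5)
        assert r.q == pytest.approx(0.0)

    def test_three_equal_variance_studies(self):
        r = mm.pool_fixed([_eff(0.0, 1.0, "a"), _eff(1.0, 1.0, "b"), _eff(2.0, 1.0, "c")])
        assert r.estimate == pytest.approx(1.0)
        assert r.q == pytest.approx(2.0)
        np.testing.assert_allclose(r.weights, [1 / 3] * 3)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            mm.pool_fixed([])

    def test_matches_wls_oracle_on_random_instances(self, rng):
        for _ in range(10):
            effects = [
                _eff(rng.normal(), float(rng.uniform(0.01, 1.0)), f"S{i}")
                for i in range(5)
            ]
            r = mm.pool_fixed(effects)
            est, se = _wls_oracle(effects)
            assert r.estimate == pytest.approx(est, abs=1e-10)
            assert r.se == pytest.approx(se, abs=1e-10)

    def test_estimate_in_convex_hull_of_effects(self, rng):
        for _ in range(20):
            effects = [
                _eff(float(rng.normal()), float(rng.uniform(0.01, 1.0)), f"S{i}")
                for i in range(6)
            ]
            r = mm.pool_fixed(effects)
            vals = [e.effect for e in effects]
            assert min(vals) <= r.estimate <= max(vals)


class TestRandomDL:
    def test_bundled_table_reproduces_reported_pooled_smd(self, effects_d):
        r = mm.pool_random_dl(effects_d)
        assert r.estimate == pytest.approx(0.54, abs=0.03)
        assert r.ci_low == pytest.approx(0.24, abs=0.03)
        assert r.ci_high == pytest.approx(0.83, abs=0.03)

    def test_blood_subgroup_reproduces_reported_value(self, studies):
        sub = mm.pool_subgroup(studies, key=lambda s: s.sample_type, kind="cohen_d")
        blood = sub["blood"]
        assert blood.k == 5
        assert blood.estimate == pytest.approx(0.65, abs=0.03)
        assert blood.ci_low == pytest.approx(0.24, abs=0.03)
        assert blood.ci_high == pytest.approx(1.06, abs=0.03)

    def test_homogeneous_truncation_reproduces_fixed_bit_for_bit(self):
        effects = [_eff(0.5, 0.1, "a"), _eff(0.51, 0.1, "b"), _eff(0.49, 0.1, "c")]
        rnd = mm.pool_random_dl(effects)
        fix = mm.pool_fixed(effects)
        assert rnd.tau_squared == 0.0
        assert rnd.estimate == fix.estimate
        assert rnd.se == fix.se
        np.testing.assert_array_equal(rnd.weights, fix.weights)

    def test_k1_raises_directing_to_fixed(self):
        with pytest.raises(ValueError, match="pool_fixed"):
            mm.pool_random_dl([_eff(0.5, 0.1)])

    def test_random_ci_at_least_as_wide_as_fixed(self, effects_d):
        rnd = mm.pool_random_dl(effects_d)
        fix = mm.pool_fixed(effects_d)
        assert (rnd.ci_high - rnd.ci_low) >= (fix.ci_high - fix.ci_low)

    def test_matches_metafor_oracle_on_bundled_table(self, studies, effects_g):
        """Cross-check the DL pooling math against R's metafor on the same
        per-study effects and variances."""
        yi = ",".join(f"{e.effect:.12g}" for e in effects_g)
        vi = ",".join(f"{e.variance:.12g}" for e in effects_g)
        script = (
            "suppressMessages(library(metafor));"
            f"fit <- rma(yi=c({yi}), vi=c({vi}), method='DL');"
            "cat(sprintf('%.15g', c(coef(fit), fit$tau2, fit$QE, fit$ci.lb, fit$ci.ub)), sep='\\n')"
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
            )
        except FileNotFoundError:
            pytest.skip("Rscript not available")
        assert out.returncode == 0, out.stderr
        est_r, tau2_r, q_r, lo_r, hi_r = (float(x) for x in out.stdout.split())
        r = mm.pool_random_dl(effects_g)
        assert r.estimate == pytest.approx(est_r, abs=1e-8)
        assert r.tau_squared == pytest.approx(tau2_r, abs=1e-8)
        assert r.q == pytest.approx(q_r, abs=1e-8)
        assert r.ci_low == pytest.approx(lo_r, abs=1e-6)
        assert r.ci_high == pytest.approx(hi_r, abs=1e-6)


class TestSelectModel:
    def test_homogeneous_studies_select_fixed(self):
        effects = [_eff(0.5 + 0.01 * i, 0.1, f"S{i}") for i in range(5)]
        assert mm.select_model(effects).model == "fixed"

    def test_bundled_table_selects_random(self, effects_d):
        assert mm.select_model(effects_d).model == "random"

    def test_degenerate_threshold_forces_random(self):
        effects = [_eff(0.0, 0.1, "a"), _eff(1.0, 0.1, "b"), _eff(2.0, 0.1, "c")]
        assert mm.select_model(effects, i2_threshold=0.0).model == "random"

    def test_and_rule_requires_both_conditions(self):
        # k=14, equal variances, Q = 23: Q p ~ 0.042 (< 0.05) but I2 ~ 0.43 (< 0.5)
        a = np.sqrt(23.0 / 14.0)
        effects = [_eff(a if i % 2 else -a, 1.0, f"S{i}") for i in range(14)]
        assert mm.select_model(effects, rule="or").model == "random"
        assert mm.select_model(effects, rule="and").model == "fixed"

    def test_q_pvalue_uniform_under_homogeneous_null(self):
        """Cochran's Q follows its chi-square null for homogeneous studies."""
        pvals = []
        for rep in range(1000):
            spec = mm.GeneratorSpec(
                k=14, true_smd=0.5, tau_squared=0.0, n_range=(50, 100),
                scale_range=(0.5, 20.0), offset_range=(0.0, 100.0), seed=10_000 + rep,
            )
            eff = [mm.smd(s) for s in mm.generate_summaries(spec)]
            pvals.append(mm.pool_fixed(eff).q_pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_heterogeneity_invariant_under_common_effect_rescaling(self, effects_d):
        # rescaling every effect and SE by the same factor leaves Q and I2 unchanged
        base = mm.pool_fixed(effects_d)
        jointly = [
            EffectEstimate(e.study_id, e.effect * 3.7, e.variance * 3.7**2, e.effect_kind)
            for e in effects_d
        ]
        r2 = mm.pool_fixed(jointly)
        assert r2.i_squared == pytest.approx(base.i_squared, rel=1e-9)
        assert r2.q == pytest.approx(base.q, rel=1e-9)


class TestLeaveOneOut:
    def test_identical_studies_give_identical_results(self):
        effects = [_eff(0.5, 0.1, f"S{i}") for i in range(3)]
        loo = mm.leave_one_out(effects)
        assert len(loo.results) == 3
        assert loo.min_estimate == pytest.approx(loo.max_estimate)

    def test_bundled_table_is_stable(self, effects_d):
        loo = mm.leave_one_out(effects_d)
        assert len(loo.results) == 14
        assert loo.min_estimate > 0

    def test_dropping_a_huge_outlier_yields_the_minimum(self):
        effects = [_eff(0.5, 0.1, f"S{i}") for i in range(5)] + [_eff(5.0, 0.1, "OUT")]
        loo = mm.leave_one_out(effects)
        i_out = loo.omitted_ids.index("OUT")
        assert loo.results[i_out].estimate == pytest.approx(loo.min_estimate)

    def test_k_below_3_raises(self):
        with pytest.raises(ValueError, match="k >= 3"):
            mm.leave_one_out([_eff(0.5, 0.1, "a"), _eff(0.5, 0.1, "b")])


class TestSubgroup:
    def test_singleton_subgroups_return_own_effect(self, studies):
        sub = mm.pool_subgroup(studies, key=lambda s: s.study_id, kind="cohen_d")
        assert len(sub) == 14
        for s in studies:
            assert sub[s.study_id].estimate == pytest.approx(
                mm.smd(s, "cohen_d").effect
            )

    def test_unlabelled_studies_are_omitted(self, studies):
        sub = mm.pool_subgroup(
            studies, key=lambda s: "blood" if s.sample_type == "blood" else None
        )
        assert list(sub) == ["blood"]

    def test_bmi_strata_recovered_from_generator_truth(self):
        """Subgroup pooling recovers a negative obese-vs-nonobese contrast."""
        truth = -0.4
        spec = mm.GeneratorSpec(
            k=24, true_smd=truth, tau_squared=0.0, n_range=(40, 80),
            scale_range=(0.5, 20.0), offset_range=(0.0, 100.0), seed=99,
        )
        labelled = [
            mm.StudySummary(
                s.study_id, s.n_case, s.mean_case, s.sd_case,
                s.n_control, s.mean_control, s.sd_control, s.sample_type,
                bmi_stratum="obese" if i % 2 else "nonobese",
            )
            for i, s in enumerate(mm.generate_summaries(spec))
        ]
        sub = mm.pool_subgroup(labelled, key=lambda s: s.bmi_stratum)
        for label in ("obese", "nonobese"):
            assert sub[label].estimate == pytest.approx(truth, abs=0.15)


class TestParameterRecovery:
    @pytest.mark.parametrize("mu", [0.0, 0.5, 1.0])
    @pytest.mark.parametrize("tau2", [0.0, 0.2])
    def test_dl_recovery_is_unbiased(self, mu, tau2):
        """Replicate-averaged bias of the DL pooled estimate at k=50 is small."""
        devs = []
        for rep in range(20):
            spec = mm.GeneratorSpec(
                k=50, true_smd=mu, tau_squared=tau2, n_range=(20, 100),
                scale_range=(0.5, 20.0), offset_range=(0.0, 100.0), seed=1000 + rep,
            )
            eff = [mm.smd(s) for s in mm.generate_summaries(spec)]
            devs.append(mm.pool_random_dl(eff).estimate - mu)
        assert abs(float(np.mean(devs))) < 0.05
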
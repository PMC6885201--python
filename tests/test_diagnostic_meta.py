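"""Dichotomization, pooled diagnostic accuracy and the Moses-Littenberg SROC."""

import math

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit, logit

import micmeta as mm
from micmeta.effect_size import TwoByTwo


def _ds(case, ctrl, did="d"):
    vals = np.concatenate([case, ctrl]).astype(float)
    grp = np.array(["case"] * len(case) + ["control"] * len(ctrl), dtype=object)
    return mm.SampleDataset(did, vals, grp)


class TestDichotomize:
    def test_complete_separation_gives_perfect_table(self):
        t = mm.dichotomize(_ds([5, 6, 7], [1, 2, 3]))
        assert (t.tp, t.fp, t.fn, t.tn) == (3, 0, 0, 3)

    def test_identical_distributions_tie_to_lowest_threshold(self):
        t = mm.dichotomize(_ds([1, 2, 3], [1, 2, 3]))
        assert t.threshold == 1.0

    def test_fixed_cutpoint(self):
        t = mm.dichotomize(_ds([5, 6, 7], [1, 2, 6]), rule=5.5)
        assert (t.tp, t.fp, t.fn, t.tn) == (2, 1, 1, 2)

    def test_median_rule_splits_at_pooled_median(self):
        t = mm.dichotomize(_ds([3, 4, 5, 6], [1, 2, 3, 4]), rule="median")
        assert t.threshold == pytest.approx(3.5)
        assert (t.tp, t.fp) == (3, 1)

    def test_empirical_youden_near_binormal_optimum(self, rng):
        # equal-variance binormal with separation 1 SD: optimal cut at 0.5
        case = rng.normal(1.0, 1.0, 100)
        ctrl = rng.normal(0.0, 1.0, 100)
        t = mm.dichotomize(_ds(case, ctrl))
        assert t.threshold == pytest.approx(0.5, abs=0.2)

    def test_margins_preserved(self, rng):
        ds = _ds(rng.normal(1, 1, 30), rng.normal(0, 1, 40))
        t = mm.dichotomize(ds)
        assert (t.n_case, t.n_control) == (30, 40)


class TestPooledProportions:
    def test_single_table_hand_computed_sensitivity(self):
        t = TwoByTwo("t", 8, 3, 2, 7)
        r = mm.pool_proportions([t], "sensitivity")
        assert r.estimate == pytest.approx(0.8)
        lg, var = math.log(8 / 2), 1 / 8 + 1 / 2
        assert r.ci_low == pytest.approx(expit(lg - 1.959964 * math.sqrt(var)))

    def test_perfect_tables_stay_near_boundary(self):
        tables = [TwoByTwo(f"t{i}", 10, 0, 0, 10) for i in range(4)]
        r = mm.pool_proportions(tables, "sensitivity")
        assert 0.9 < r.estimate < 1.0  # boundary handled by 0.5 correction

    def test_generator_truth_recovered(self, rng):
        true_sens = 0.83
        tables = []
        for i in range(11):
            n1, n2 = 40, 40
            tp = int(rng.binomial(n1, true_sens))
            fp = int(rng.binomial(n2, 0.4))
            tables.append(TwoByTwo(f"t{i}", tp, fp, n1 - tp, n2 - fp))
        r = mm.pool_proportions(tables, "sensitivity")
        assert r.estimate == pytest.approx(true_sens, abs=0.05)

    def test_label_swap_maps_sensitivity_to_specificity(self, rng):
        tables = [
            TwoByTwo(f"t{i}", int(rng.integers(5, 20)), int(rng.integers(5, 20)),
                     int(rng.integers(5, 20)), int(rng.integers(5, 20)))
            for i in range(6)
        ]
        # swapping labels and flipping the positivity direction: TP <-> TN, FP <-> FN
        swapped = [TwoByTwo(t.study_id, t.tn, t.fn, t.fp, t.tp) for t in tables]
        sens = mm.pool_proportions(tables, "sensitivity")
        spec_sw = mm.pool_proportions(swapped, "specificity")
        assert spec_sw.estimate == pytest.approx(sens.estimate, rel=1e-9)


class TestPooledDOR:
    def test_single_table(self):
        r = mm.pool_dor([TwoByTwo("t", 10, 5, 5, 10)])
        assert r.estimate == pytest.approx(4.0)

    def test_null_tables_pool_to_one(self):
        tables = [TwoByTwo(f"t{i}", 10, 10, 10, 10) for i in range(5)]
        assert mm.pool_dor(tables).estimate == pytest.approx(1.0)

    def test_generator_truth_recovered_within_15_percent(self, rng):
        true_log_or = 2.0
        p_ctrl = 0.3
        odds_case = p_ctrl / (1 - p_ctrl) * math.exp(true_log_or)
        p_case = odds_case / (1 + odds_case)
        tables = []
        for i in range(11):
            tp = int(rng.binomial(60, p_case))
            fp = int(rng.binomial(60, p_ctrl))
            tables.append(TwoByTwo(f"t{i}", tp, fp, 60 - tp, 60 - fp))
        r = mm.pool_dor(tables)
        assert math.log(r.estimate) == pytest.approx(true_log_or, rel=0.15)

    def test_label_swap_inverts_dor(self, rng):
        tables = [
            TwoByTwo(f"t{i}", int(rng.integers(5, 20)), int(rng.integers(5, 20)),
                     int(rng.integers(5, 20)), int(rng.integers(5, 20)))
            for i in range(6)
        ]
        swapped = [TwoByTwo(t.study_id, t.fp, t.tp, t.tn, t.fn) for t in tables]
        fwd = mm.pool_dor(tables)
        rev = mm.pool_dor(swapped)
        assert rev.estimate == pytest.approx(1.0 / fwd.estimate, rel=1e-9)


class TestSROC:
    def test_chance_line_tables_give_half_auc(self):
        # TPR = FPR at varying operating points: D = 0 everywhere -> a = b = 0
        tables = [
            TwoByTwo(f"t{i}", x, x, 20 - x, 20 - x) for i, x in enumerate([4, 8, 12, 16])
        ]
        fit = mm.sroc_moses(tables)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.auc == pytest.approx(0.5, abs=1e-3)

    def test_symmetric_antidiagonal_tables_give_half_auc(self):
        # operating points mirrored around (0.5, 0.5): mean D = 0
        tables = [
            TwoByTwo("a", 15, 5, 5, 15),
            TwoByTwo("b", 5, 15, 15, 5),
            TwoByTwo("c", 12, 8, 8, 12),
            TwoByTwo("d", 8, 12, 12, 8),
        ]
        fit = mm.sroc_moses(tables)
        assert fit.auc == pytest.approx(0.5, abs=1e-3)

    def test_binormal_truth_recovered(self):
        delta = float(np.sqrt(2) * stats.norm.ppf(0.80))
        spec = mm.GeneratorSpec(
            k=20, true_smd=delta, tau_squared=0.0, n_range=(30, 30),
            scale_range=(0.5, 20.0), offset_range=(0.0, 100.0), seed=0,
        )
        tables = [mm.dichotomize(d, "median") for d in mm.generate_samples(spec)]
        fit = mm.sroc_moses(tables)
        assert fit.auc == pytest.approx(0.80, abs=0.05)
        assert fit.auc_ci_low < fit.auc < fit.auc_ci_high

    def test_perfect_separation_auc_near_one(self):
        tables = [TwoByTwo(f"t{i}", n, 0, 0, n) for i, n in enumerate([15, 20, 25])]
        fit = mm.sroc_moses(tables)
        assert fit.auc > 0.95

    def test_auc_invariant_under_monotone_transform(self, rng):
        spec = mm.GeneratorSpec(
            k=8, true_smd=1.0, tau_squared=0.0, n_range=(25, 40),
            scale_range=(0.5, 2.0), offset_range=(0.0, 1.0), seed=21,
        )
        datasets = mm.generate_samples(spec)
        t_raw = [mm.dichotomize(d) for d in datasets]
        t_exp = [
            mm.dichotomize(
                mm.SampleDataset(d.dataset_id, np.exp(d.expression / 4), d.group)
            )
            for d in datasets
        ]
        for a, b in zip(t_raw, t_exp):
            assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)
        assert mm.sroc_moses(t_raw).auc == pytest.approx(mm.sroc_moses(t_exp).auc)

    def test_k_below_3_raises(self):
        with pytest.raises(ValueError, match="k >= 3"):
            mm.sroc_moses([TwoByTwo("a", 5, 2, 3, 8)] * 2)

    def test_diagnostic_summary_is_internally_consistent(self, rng):
        spec = mm.GeneratorSpec(
            k=11, true_smd=1.0, tau_squared=0.05, n_range=(30, 60),
            scale_range=(0.5, 20.0), offset_range=(0.0, 100.0), seed=13,
        )
        tables = [mm.dichotomize(d, "median") for d in mm.generate_samples(spec)]
        summ = mm.diagnostic_summary(tables)
        assert summ.sensitivity.ci_low <= summ.sensitivity.estimate <= summ.sensitivity.ci_high
        assert summ.specificity.ci_low <= summ.specificity.estimate <= summ.specificity.ci_high
        assert summ.dor.ci_low <= summ.dor.estimate <= summ.dor.ci_high
        assert 0.0 <= summ.sroc.auc <= 1.0
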
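"""Objective function and the two-step multistart protocol."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from grmfit.fitting import (
    SENTINEL,
    FitConfig,
    TwoStepFit,
    derive_bounds,
    local_optimize,
    max_normalize,
    nrmsd,
    objective,
    sample_initial,
    stage1_fit,
    stage2_fit,
)
from grmfit.models.params import MODEL_SPECS
from tests.conftest import gene_fc

FAST = FitConfig(n_starts=6, maxfev=150, maxfev_stage2=80)


class TestMaxNormalize:
    def test_joint_formula(self):
        c, s = max_normalize([1, 3], [1, 2])
        np.testing.assert_allclose(c, [0, 1])
        np.testing.assert_allclose(s, [0, 0.5])

    def test_idempotent_on_unit_span(self):
        c, s = max_normalize([0.0, 1.0], [0.25, 0.5])
        np.testing.assert_allclose(c, [0, 1])
        np.testing.assert_allclose(s, [0.25, 0.5])

    def test_constant_pooled_input_rejected(self):
        with pytest.raises(ValueError):
            max_normalize([2, 2], [2, 2])

    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=10),
           st.lists(st.floats(-10, 10), min_size=2, max_size=10))
    def test_pooled_output_spans_unit_interval(self, a, b):
        pooled = np.concatenate([a, b])
        if pooled.max() - pooled.min() < 1e-9:
            return
        c, s = max_normalize(a, b)
        out = np.concatenate([c, s])
        assert out.min() == pytest.approx(0.0, abs=1e-12)
        assert out.max() == pytest.approx(1.0, abs=1e-12)


class TestNrmsd:
    def test_identical_series(self):
        assert nrmsd([0.1, 0.5, 1.0], [0.1, 0.5, 1.0]) == 0.0

    def test_hand_computed(self):
        assert nrmsd([0, 1], [1, 0]) == pytest.approx(1.0)
        assert nrmsd([0, 0, 0], [0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            nrmsd([0, 1], [0, 1, 2])


class TestObjective:
    @pytest.mark.parametrize("gene_idx", [0, 1])
    def test_zero_at_truth_for_zero_noise_data(self, small_cohort, rep1, gene_idx):
        genes, table, truth = small_cohort
        gene = genes[gene_idx]
        data_fc = gene_fc(table, gene.gene_id)
        vec = [gene.true_params.free[nm] for nm in gene.true_params.free_names]
        for cond in ("ctrl", "siIkBa"):
            assert objective(vec, gene.model_name, rep1, data_fc, cond) <= 1e-3

    def test_steady_state_penalty_near_zero(self, small_cohort, rep1):
        # steady-state initialization makes the drift term vanish, so the
        # objective is (almost) pure nRMSD; at truth both terms are ~0
        genes, table, _ = small_cohort
        gene = genes[0]
        data_fc = gene_fc(table, gene.gene_id)
        vec = [gene.true_params.free[nm] for nm in gene.true_params.free_names]
        assert objective(vec, gene.model_name, rep1, data_fc, "ctrl") <= 1e-6

    def test_failed_parameters_return_sentinel(self, small_cohort, rep1):
        genes, table, _ = small_cohort
        data_fc = gene_fc(table, genes[0].gene_id)
        bad = [np.nan, 1.0, 100.0]
        assert objective(bad, "simple", rep1, data_fc, "ctrl") == SENTINEL

    def test_flat_simulation_scores_like_flat_line(self, small_cohort, rep1):
        # a parameter set whose response is constant cannot be normalized and
        # is rejected with the sentinel rather than crashing the search
        genes, table, _ = small_cohort
        data_fc = gene_fc(table, genes[0].gene_id)
        flat = [2e-3, 999.0, 0.0]  # K_D saturated in both conditions
        val = objective(flat, "simple", rep1, data_fc, "ctrl")
        assert val == SENTINEL or val <= 2.0


class TestSampleInitial:
    def test_count_and_bounds(self):
        bounds = MODEL_SPECS["cycle3"]["bounds"]
        draws = sample_initial(bounds, 100, seed=3, names=MODEL_SPECS["cycle3"]["free"])
        assert draws.shape == (100, 6)
        for j, nm in enumerate(MODEL_SPECS["cycle3"]["free"]):
            lo, hi = bounds[nm]
            assert np.all(draws[:, j] >= lo) and np.all(draws[:, j] <= hi)

    def test_deterministic(self):
        bounds = MODEL_SPECS["simple"]["bounds"]
        a = sample_initial(bounds, 10, seed=5, names=MODEL_SPECS["simple"]["free"])
        b = sample_initial(bounds, 10, seed=5, names=MODEL_SPECS["simple"]["free"])
        np.testing.assert_array_equal(a, b)

    def test_log_uniform_spread_for_scale_parameters(self):
        bounds = {"K_D": (0.001, 1000.0), "tau": (0.0, 7200.0)}
        draws = sample_initial(bounds, 400, seed=1, names=("K_D", "tau"))
        # medians: log-uniform K_D near 1 (geometric center), uniform tau near 3600
        assert 0.1 < np.median(draws[:, 0]) < 10
        assert 2800 < np.median(draws[:, 1]) < 4400

    def test_single_draw_and_invalid_n(self):
        bounds = MODEL_SPECS["simple"]["bounds"]
        assert sample_initial(bounds, 1, 0, MODEL_SPECS["simple"]["free"]).shape == (1, 3)
        with pytest.raises(ValueError):
            sample_initial(bounds, 0, 0, MODEL_SPECS["simple"]["free"])


class TestLocalOptimize:
    def test_quadratic_interior_minimum(self):
        fun = lambda x: float((x[0] - 0.3) ** 2 + (x[1] + 0.2) ** 2)
        x, f, n = local_optimize(fun, np.array([0.9, 0.9]), [(-1, 1), (-1, 1)])
        np.testing.assert_allclose(x, [0.3, -0.2], atol=1e-3)

    def test_no_improvement_keeps_start(self):
        fun = lambda x: float(x[0] ** 2)
        x, f, _ = local_optimize(fun, np.array([0.0]), [(-1, 1)])
        assert f == 0.0

    def test_boundary_minimum(self):
        fun = lambda x: float((x[0] - 2.0) ** 2)
        x, f, _ = local_optimize(fun, np.array([0.0]), [(-1.0, 1.0)])
        assert x[0] == pytest.approx(1.0, abs=1e-3)

    def test_descent_guarantee(self):
        fun = lambda x: float(np.sin(5 * x[0]) + x[0] ** 2)
        for x0 in (-0.9, 0.1, 0.8):
            x, f, _ = local_optimize(fun, np.array([x0]), [(-1, 1)], maxfev=60)
            assert f <= fun(np.array([x0]))

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ValueError):
            local_optimize(lambda x: np.nan, np.array([0.0]), [(-1, 1)])


def _fake_records(ctrl_nrmsds, k_degs=None, model="simple"):
    from grmfit.fitting import FitRecord
    from grmfit.models import ParamSet

    records = []
    for i, nr in enumerate(ctrl_nrmsds):
        kd = k_degs[i] if k_degs else 1e-3 * (1 + i / 10)
        records.append(
            FitRecord(
                gene_id="g", model_name=model, replicate=1,
                params=ParamSet.create(model, k_deg=kd, K_D=0.1 * (i + 1), tau=100.0 * i),
                objective_value=nr, n_evals=10, seed=0, nrmsd_ctrl=nr, nrmsd_si=nr,
            )
        )
    return records


class TestDeriveBounds:
    def test_filter_at_first_threshold(self):
        recs = _fake_records([0.3, 0.4, 0.55])
        bounds = derive_bounds(recs)
        # survivors are the first two records
        assert bounds["K_D"] == (0.1, 0.2)
        assert bounds["tau"] == (0.0, 100.0)

    def test_escalation_to_final_threshold(self):
        recs = _fake_records([0.65, 0.65, 0.65])
        bounds = derive_bounds(recs)
        assert bounds["K_D"][0] == pytest.approx(0.1)
        assert bounds["K_D"][1] == pytest.approx(0.3)

    def test_single_survivor_falls_back_to_best_two(self):
        recs = _fake_records([0.45, 0.9, 0.95])
        bounds = derive_bounds(recs)
        assert bounds["K_D"][0] == pytest.approx(0.1)
        assert bounds["K_D"][1] == pytest.approx(0.2)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            derive_bounds([])

    def test_nested_within_global_bounds(self):
        recs = _fake_records(list(np.linspace(0.1, 0.45, 8)))
        bounds = derive_bounds(recs)
        for nm, (lo, hi) in bounds.items():
            glo, ghi = MODEL_SPECS["simple"]["bounds"][nm]
            assert glo <= lo < hi <= ghi


class TestTwoStep:
    @pytest.fixture(scope="class")
    def fitted(self, small_cohort, rep1):
        genes, table, _ = small_cohort
        gene = genes[0]  # simple-model gene
        data_fc = gene_fc(table, gene.gene_id)
        model = TwoStepFit(data_fc, rep1, gene.model_name, gene.gene_id, 1, FAST)
        return gene, model.fit(seed=4)

    def test_record_counts(self, fitted):
        _, res = fitted
        assert len(res.stage1_records) == FAST.n_starts
        assert len(res.records) == FAST.n_starts

    def test_stage2_records_within_stage2_bounds(self, fitted):
        _, res = fitted
        for rec in res.records:
            for nm, v in rec.params.free.items():
                lo, hi = res.stage2_bounds[nm]
                assert lo - 1e-12 <= v <= hi + 1e-12

    def test_zero_noise_self_fit_quality(self, fitted):
        # stage 1 targets the control, stage 2 the knockdown; each stage's
        # best record reproduces its target condition on zero-noise data
        _, res = fitted
        assert min(r.nrmsd_ctrl for r in res.stage1_records) <= 0.1
        assert min(r.nrmsd_si for r in res.records) <= 0.1

    def test_each_stage1_record_improves_on_start(self, small_cohort, rep1):
        genes, table, _ = small_cohort
        gene = genes[0]
        data_fc = gene_fc(table, gene.gene_id)
        recs = stage1_fit(data_fc, gene.model_name, rep1,
                          FitConfig(n_starts=4, maxfev=60), seed=9,
                          gene_id=gene.gene_id)
        assert len(recs) == 4
        assert all(r.objective_value < SENTINEL for r in recs)

    def test_summary_mentions_gene_and_parameters(self, fitted):
        gene, res = fitted
        text = res.summary()
        assert gene.gene_id in text
        assert "k_deg" in text and "nRMSD" in text

    def test_deterministic_given_seed(self, small_cohort, rep1):
        genes, table, _ = small_cohort
        gene = genes[0]
        data_fc = gene_fc(table, gene.gene_id)
        cfg = FitConfig(n_starts=3, maxfev=60, maxfev_stage2=40)
        r1 = TwoStepFit(data_fc, rep1, gene.model_name, gene.gene_id, 1, cfg).fit(seed=7)
        r2 = TwoStepFit(data_fc, rep1, gene.model_name, gene.gene_id, 1, cfg).fit(seed=7)
        for a, b in zip(r1.records, r2.records):
            assert a.params.free == b.params.free
            assert a.nrmsd_ctrl == b.nrmsd_ctrl

    def test_stage2_rejects_non_nested_bounds(self, small_cohort, rep1):
        genes, table, _ = small_cohort
        data_fc = gene_fc(table, genes[0].gene_id)
        bad = {"k_deg": (1e-6, 1e-3), "K_D": (0.001, 10.0), "tau": (0.0, 100.0)}
        with pytest.raises(ValueError):
            stage2_fit(data_fc, "simple", rep1, bad)
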
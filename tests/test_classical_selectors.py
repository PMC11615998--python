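import random

import numpy as np
import pytest

from nihlselect.classical_selectors import (
    CLASSICAL_METHOD_CONFIGS,
    SelectionResult,
    StratumSpec,
    run_classical_method,
    select_bidimensional_extremes,
    select_residual_extremes,
    select_stratified_extremes,
)
from nihlselect.synthetic_cohort import (
    Cohort,
    SimulationParams,
    generate_cohort,
)
from nihlselect.validity_assessment import rank_sum_test

SINGLE_STRATUM = StratumSpec(("age", ()), ("leq_8h", ()))


class TestStratified:
    def test_single_stratum_ranking(self, worker_factory, cohort_factory):
        cohort = cohort_factory([
            worker_factory(f"w{i}", ht=float(i)) for i in range(1, 11)])
        sel = select_stratified_extremes(cohort, SINGLE_STRATUM, (4.0,),
                                         "left", 0.2)
        assert sel.sg_ids == {"w10", "w9"}
        assert sel.rg_ids == {"w1", "w2"}

    def test_fraction_half(self, worker_factory, cohort_factory):
        cohort = cohort_factory([
            worker_factory(f"w{i}", ht=float(i)) for i in range(4)])
        sel = select_stratified_extremes(cohort, SINGLE_STRATUM, (4.0,),
                                         "left", 0.5)
        assert len(sel.sg_ids) == len(sel.rg_ids) == 2
        assert not sel.sg_ids & sel.rg_ids

    def test_nine_strata_sizes(self, worker_factory, cohort_factory):
        # 9 strata x 20 workers, fraction 0.2 -> 9 * floor(4) = 36 per tail
        workers = []
        i = 0
        for exp in (5.0, 20.0, 30.0):       # <15, 15-25, >25
            for leq in (80.0, 88.0, 95.0):  # <86, 86-92, >=92
                for _ in range(20):
                    workers.append(worker_factory(
                        f"w{i:03d}", exposure_time=exp, leq_8h=leq,
                        ht=float(i % 17)))
                    i += 1
        cohort = cohort_factory(workers)
        strata = CLASSICAL_METHOD_CONFIGS["m1"]["strata"]
        sel = select_stratified_extremes(cohort, strata, (4.0, 6.0), "left",
                                         0.2)
        assert len(sel.sg_ids) == len(sel.rg_ids) == 36

    def test_small_stratum_skipped(self, worker_factory, cohort_factory):
        workers = [worker_factory(f"a{i}", age=30.0, ht=float(i))
                   for i in range(10)]
        workers += [worker_factory("lone", age=60.0, ht=50.0)]
        strata = StratumSpec(("age", (45.0,)), ("leq_8h", ()))
        sel = select_stratified_extremes(cohort_factory(workers), strata,
                                         (4.0,), "left", 0.2)
        assert "lone" not in sel.sg_ids | sel.rg_ids
        assert len(sel.sg_ids) == 2

    def test_bad_fraction(self, worker_factory, cohort_factory):
        cohort = cohort_factory([worker_factory("w")])
        with pytest.raises(ValueError):
            select_stratified_extremes(cohort, SINGLE_STRATUM, (4.0,),
                                       "left", 0.6)


class TestBidimensional:
    def test_diagonal_reduces_to_1d(self, worker_factory, cohort_factory):
        rng = random.Random(0)
        vals = rng.sample(range(1000), 100)
        cohort = cohort_factory([
            worker_factory(f"w{i:03d}", ht=float(v))
            for i, v in enumerate(vals)])
        sel = select_bidimensional_extremes(cohort, 4.0, 6.0, 0.1)
        order = sorted(range(100), key=lambda i: vals[i])
        assert sel.rg_ids == {f"w{i:03d}" for i in order[:10]}
        assert sel.sg_ids == {f"w{i:03d}" for i in order[-10:]}

    def test_antisymmetric_points_cancel(self, worker_factory,
                                         cohort_factory):
        # two workers sit at exactly opposite z-scores: both score 0 and
        # neither reaches a tail at fraction < 0.5
        cohort = cohort_factory([
            worker_factory("a", left={4.0: 2.0, 6.0: -2.0}),
            worker_factory("b", left={4.0: -2.0, 6.0: 2.0}),
            worker_factory("c", left={4.0: 3.0, 6.0: 3.0}),
            worker_factory("d", left={4.0: -3.0, 6.0: -3.0}),
        ])
        sel = select_bidimensional_extremes(cohort, 4.0, 6.0, 0.25)
        assert sel.score["a"] == pytest.approx(0.0)
        assert sel.score["b"] == pytest.approx(0.0)
        assert sel.sg_ids == {"c"}
        assert sel.rg_ids == {"d"}

    def test_zero_variance_rejected(self, worker_factory, cohort_factory):
        cohort = cohort_factory([
            worker_factory(f"w{i}", left={4.0: 5.0, 6.0: float(i)})
            for i in range(10)])
        with pytest.raises(ValueError):
            select_bidimensional_extremes(cohort, 4.0, 6.0, 0.1)

    def test_matches_brute_force(self, worker_factory, cohort_factory):
        rng = np.random.default_rng(7)
        x = rng.normal(30, 10, size=1000)
        y = rng.normal(25, 8, size=1000)
        cohort = cohort_factory([
            worker_factory(f"w{i:04d}", left={4.0: x[i], 6.0: y[i]})
            for i in range(1000)])
        sel = select_bidimensional_extremes(cohort, 4.0, 6.0, 0.1)
        # independent oracle: sort by zx + zy
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        order = np.argsort(zx + zy, kind="stable")
        assert sel.rg_ids == {f"w{i:04d}" for i in order[:100]}
        assert sel.sg_ids == {f"w{i:04d}" for i in order[-100:]}


class TestResidual:
    def _linear_cohort(self, factory, n=50, seed=0, outlier=None):
        rng = np.random.default_rng(seed)
        workers = []
        for i in range(n):
            leq = rng.uniform(80, 95)
            t = rng.uniform(2, 20)
            w = factory(f"w{i:03d}", leq_8h=leq, exposure_time=t)
            y = 2.0 * w.cne
            if outlier is not None and i == outlier:
                y += 10.0
            for f in (3.0, 4.0, 6.0):
                w.ht_left[f] = y
                w.ht_right[f] = y
            workers.append(w)
        return workers

    def test_single_outlier_is_top_residual(self, worker_factory,
                                            cohort_factory):
        cohort = cohort_factory(
            self._linear_cohort(worker_factory, outlier=7))
        sel = select_residual_extremes(cohort, fraction=0.02)
        assert sel.sg_ids == {"w007"}
        assert max(sel.score, key=sel.score.get) == "w007"

    def test_matches_normal_equations_oracle(self, worker_factory,
                                             cohort_factory):
        rng = np.random.default_rng(3)
        workers = []
        for i in range(50):
            w = worker_factory(f"w{i:03d}", leq_8h=rng.uniform(78, 96),
                               exposure_time=rng.uniform(1, 25),
                               ht=rng.uniform(0, 80))
            workers.append(w)
        cohort = cohort_factory(workers)
        sel = select_residual_extremes(cohort, fraction=0.1)
        # oracle: explicit normal equations
        cne = np.array([w.cne for w in workers])
        y = np.array([np.mean([w.ht_left[f] for f in (3.0, 4.0, 6.0)]
                              + [w.ht_right[f] for f in (3.0, 4.0, 6.0)])
                      for w in workers])
        X = np.column_stack([np.ones_like(cne), cne])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        order = np.argsort(resid, kind="stable")
        assert sel.rg_ids == {workers[i].id for i in order[:5]}
        assert sel.sg_ids == {workers[i].id for i in order[-5:]}
        np.testing.assert_allclose(
            [sel.score[w.id] for w in workers], resid, atol=1e-8)

    def test_size_formula(self, worker_factory, cohort_factory):
        rng = np.random.default_rng(4)
        cohort = cohort_factory([
            worker_factory(f"w{i:03d}", leq_8h=rng.uniform(78, 96),
                           ht=rng.uniform(0, 60)) for i in range(200)])
        sel = select_residual_extremes(cohort, fraction=0.1)
        assert len(sel.sg_ids) == len(sel.rg_ids) == 20

    def test_quadratic_model_coefficients(self, worker_factory,
                                          cohort_factory):
        # exact quadratic data is recovered (residuals ~ 0)
        rng = np.random.default_rng(5)
        workers = []
        for i in range(30):
            w = worker_factory(f"w{i:03d}", leq_8h=rng.uniform(78, 96),
                               exposure_time=rng.uniform(1, 25))
            y = 0.02 * w.cne ** 2 - 1.5 * w.cne + 40.0
            for f in (3.0, 4.0, 6.0):
                w.ht_left[f] = y
                w.ht_right[f] = y
            workers.append(w)
        sel = select_residual_extremes(cohort_factory(workers),
                                       model="quadratic", fraction=0.2)
        assert all(abs(v) < 1e-6 for v in sel.score.values())
        c0, c1, c2 = sel.metadata["coefficients"]
        assert c2 == pytest.approx(0.02, rel=1e-6)

    def test_degenerate_design_rejected(self, worker_factory,
                                        cohort_factory):
        cohort = cohort_factory([
            worker_factory(f"w{i}", leq_8h=85.0, exposure_time=10.0,
                           ht=float(i)) for i in range(20)])
        with pytest.raises(ValueError):
            select_residual_extremes(cohort)

    def test_too_few_workers_rejected(self, worker_factory, cohort_factory):
        cohort = cohort_factory([worker_factory(f"w{i}") for i in range(5)])
        with pytest.raises(ValueError):
            select_residual_extremes(cohort)


@pytest.fixture(scope="module")
def filtered_cohorts(default_cohort_3000):
    from nihlselect.screening_filters import apply_method_criteria
    return {m: apply_method_criteria(default_cohort_3000, m)[0]
            for m in CLASSICAL_METHOD_CONFIGS}


class TestSelectorProperties:
    @pytest.mark.parametrize("method_id", sorted(CLASSICAL_METHOD_CONFIGS))
    def test_disjoint_and_within_cohort(self, filtered_cohorts, method_id):
        cohort = filtered_cohorts[method_id]
        sel = run_classical_method(cohort, method_id)
        assert not sel.sg_ids & sel.rg_ids
        ids = {w.id for w in cohort}
        assert sel.sg_ids | sel.rg_ids <= ids
        assert sel.sg_ids <= set(sel.score)

    @pytest.mark.parametrize("method_id", sorted(CLASSICAL_METHOD_CONFIGS))
    def test_permutation_equivariance(self, filtered_cohorts, method_id):
        cohort = filtered_cohorts[method_id]
        sel = run_classical_method(cohort, method_id)
        shuffled = list(cohort.workers)
        random.Random(123).shuffle(shuffled)
        sel2 = run_classical_method(
            Cohort(shuffled, list(cohort.frequencies)), method_id)
        assert sel.sg_ids == sel2.sg_ids
        assert sel.rg_ids == sel2.rg_ids

    @pytest.mark.parametrize("method_id", sorted(CLASSICAL_METHOD_CONFIGS))
    def test_latent_susceptibility_separated(self, filtered_cohorts,
                                             method_id):
        cohort = filtered_cohorts[method_id]
        sel = run_classical_method(cohort, method_id)
        sg_s = [cohort.get(i).latent_susceptibility for i in sel.sg_ids]
        rg_s = [cohort.get(i).latent_susceptibility for i in sel.rg_ids]
        assert np.median(sg_s) > np.median(rg_s)
        _, p = rank_sum_test(sg_s, rg_s)
        assert p < 0.01

    @pytest.mark.parametrize("method_id", sorted(CLASSICAL_METHOD_CONFIGS))
    def test_sg_older_failure_pattern(self, filtered_cohorts, method_id):
        # the classical selectors pick up age along with susceptibility
        cohort = filtered_cohorts[method_id]
        sel = run_classical_method(cohort, method_id)
        sg_age = np.median([cohort.get(i).age for i in sel.sg_ids])
        rg_age = np.median([cohort.get(i).age for i in sel.rg_ids])
        assert sg_age > rg_age


class TestSelectionResult:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            SelectionResult("m", {"a"}, {"a"}, {"a": 1.0})

    def test_missing_score_rejected(self):
        with pytest.raises(ValueError):
            SelectionResult("m", {"a"}, set(), {})
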
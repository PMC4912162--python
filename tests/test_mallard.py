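"""Mallard dynamics: hand-derived values and kernel structure."""

import numpy as np
import pytest

from harvestmdp.config import GridConfig, RunConfig
from harvestmdp.discretize import build_grid
from harvestmdp.errors import ValidationError
from harvestmdp.mallard import (
    ADDITIVE_SURVIVAL,
    COMPENSATORY_SURVIVAL,
    STRONG_REPRODUCTION,
    WEAK_REPRODUCTION,
    BiologicalConstants,
    ModelSpec,
    RegulationSet,
    ReproductionParams,
    SurvivalParams,
    SystemState,
    annual_survival,
    build_model_kernel,
    expected_total_harvest,
    four_models,
    kill_rate,
    pond_transition,
    population_transition,
)

CONSTS = BiologicalConstants()
REGS = RegulationSet()


class TestSurvival:
    @pytest.mark.parametrize(
        "params,sex,K,expected",
        [
            (ADDITIVE_SURVIVAL, "male", 0.0, 0.7896),  # printed baseline
            (ADDITIVE_SURVIVAL, "female", 0.0, 0.6886),
            (COMPENSATORY_SURVIVAL, "male", 0.5, 0.5),  # above threshold: 1 - K
            (COMPENSATORY_SURVIVAL, "male", 0.30, 0.6467),  # below 1 - s0
            (COMPENSATORY_SURVIVAL, "female", 0.0, 0.5965),
            (ADDITIVE_SURVIVAL, "male", 0.25, 0.7896 * 0.75),
        ],
    )
    def test_hand_values(self, params, sex, K, expected):
        assert annual_survival(params, sex, K) == pytest.approx(expected, abs=1e-10)

    def test_kill_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            annual_survival(ADDITIVE_SURVIVAL, "male", 1.5)


class TestReproduction:
    def test_strong_model_clamps_at_zero(self):
        assert ReproductionParams(1.1390, 0.1376, -0.1131) == STRONG_REPRODUCTION
        assert STRONG_REPRODUCTION.intercept + STRONG_REPRODUCTION.pop_coef * 20 < 0
        from harvestmdp.mallard import reproduction_rate

        assert reproduction_rate(STRONG_REPRODUCTION, 0.0, 20.0) == 0.0

    @pytest.mark.parametrize(
        "params,P,N,expected",
        [(STRONG_REPRODUCTION, 4, 6, 1.0108), (WEAK_REPRODUCTION, 4, 6, 0.9260)],
    )
    def test_hand_values(self, params, P, N, expected):
        from harvestmdp.mallard import reproduction_rate

        assert reproduction_rate(params, P, N) == pytest.approx(expected, abs=1e-10)

    def test_strong_weak_crossover_in_population(self):
        # strong R >= weak R at low N, <= at high N; crossover where
        # 0.4224 + 0.0293 P = 0.0758 N
        from harvestmdp.mallard import reproduction_rate

        P = 4.0
        n_cross = (0.4224 + 0.0293 * P) / 0.0758
        for N in (1.0, n_cross - 1):
            assert reproduction_rate(STRONG_REPRODUCTION, P, N) >= reproduction_rate(
                WEAK_REPRODUCTION, P, N
            )
        for N in (n_cross + 1, 12.0):
            assert reproduction_rate(STRONG_REPRODUCTION, P, N) <= reproduction_rate(
                WEAK_REPRODUCTION, P, N
            )


class TestKillRate:
    def test_adult_male_liberal(self):
        assert kill_rate(0.1139) == pytest.approx(0.1139 / 0.8, abs=1e-12)

    def test_identity_without_crippling(self):
        assert kill_rate(0.1, 1.0, 0.0) == pytest.approx(0.1, abs=1e-15)

    def test_young_male_ratio_then_crippling(self):
        assert kill_rate(0.1, 1.5407) == pytest.approx(0.15407 / 0.8, abs=1e-12)

    def test_multiply_convention(self):
        assert kill_rate(0.1, 1.0, 0.2, "multiply") == pytest.approx(0.12, abs=1e-12)


class TestTransitions:
    def test_full_kill_additive_drives_population_to_zero(self):
        model = four_models()[0]  # SaRs, additive
        out = population_transition(model, CONSTS, SystemState(6, 4), [1, 1, 1, 1], 0.0)
        assert out == pytest.approx(0.0, abs=1e-12)

    def test_balance_equation_hand_value(self):
        # gS = gR = 1, m = 0.5, phi = 1, survivals 0.7, R = 1, N = 6 -> 8.4
        consts = BiologicalConstants(male_proportion=0.5, summer_survival_ratio=1.0)
        model = ModelSpec(
            SurvivalParams(0.7, 0.7, "additive"),
            ReproductionParams(1.0, 0.0, 0.0),
            "SaRw",
        )
        out = population_transition(model, consts, SystemState(6, 0), [0, 0, 0, 0], 0.0)
        assert out == pytest.approx(8.4, abs=1e-10)

    def test_pond_autoregression_hand_value(self):
        assert pond_transition(CONSTS, 4.0) == pytest.approx(3.5807, abs=1e-10)

    def test_pond_clamped_at_zero(self):
        assert pond_transition(CONSTS, 4.0, eps_p=-10.0) == 0.0

    def test_pond_deterministic_fixed_point(self):
        p = 5.0
        for _ in range(200):
            p = pond_transition(CONSTS, p)
        assert p == pytest.approx(2.2127 / (1 - 0.3420), abs=1e-8)
        assert p == pytest.approx(3.3628, abs=5e-5)


class TestExpectedHarvest:
    def test_closed_season_adult_males_only(self):
        from harvestmdp.discretize import DiscreteNoise

        regs = RegulationSet(ratio_young_male=1.0, ratio_adult_female=1.0, ratio_young_female=1.0)
        consts = BiologicalConstants(male_proportion=0.9999999)
        model = ModelSpec(ADDITIVE_SURVIVAL, ReproductionParams(0.0, 0.0, 0.0), "SaRw")
        noise = DiscreteNoise(nodes=np.array([0.0088]), weights=np.array([1.0]))
        H = expected_total_harvest(model, consts, regs, SystemState(6, 4), noise)
        assert H == pytest.approx(6 * 0.0088, rel=1e-6)

    def test_zero_population_zero_harvest(self):
        model = four_models()[1]
        noise = RegulationSet().harvest_noise("liberal", 5)
        assert expected_total_harvest(model, CONSTS, REGS, SystemState(0, 4), noise) == 0.0

    def test_harvest_increases_with_liberality(self):
        model = four_models()[1]
        state = SystemState(8, 4)
        H = [
            expected_total_harvest(model, CONSTS, REGS, state, REGS.harvest_noise(a, 5))
            for a in range(4)
        ]
        assert np.all(np.diff(H) > 0)


@pytest.fixture(scope="module")
def small_tables():
    n_grid = build_grid(0.5, 17.5, 1.0)
    p_grid = build_grid(0.5, 7.5, 1.0)
    return [build_model_kernel(m, CONSTS, REGS, n_grid, p_grid) for m in four_models()]


class TestModelKernels:
    def test_rows_stochastic_all_models_and_actions(self, small_tables):
        for tab in small_tables:
            for K in tab.kernel:
                K = np.asarray(K.todense()) if hasattr(K, "todense") else K
                np.testing.assert_allclose(K.sum(axis=1), 1.0, atol=1e-10)
                assert K.min() >= 0

    def test_compensatory_kernels_action_invariant(self, small_tables):
        # all regulation kill rates sit below 1 - s0, so survival (and the
        # kernel) cannot depend on the regulation under compensation
        for tab in (small_tables[2], small_tables[3]):
            base = np.asarray(tab.kernel[0])
            for K in tab.kernel[1:]:
                np.testing.assert_allclose(np.asarray(K), base, atol=1e-12)

    def test_additive_kernels_depend_on_action(self, small_tables):
        tab = small_tables[1]
        assert np.abs(np.asarray(tab.kernel[0]) - np.asarray(tab.kernel[3])).max() > 1e-3

    def test_pond_subkernel_shared_across_models_and_actions(self, small_tables):
        base = small_tables[0].pond_kernel
        for tab in small_tables[1:]:
            np.testing.assert_allclose(tab.pond_kernel, base, atol=1e-15)

    def test_expected_population_nonincreasing_in_liberality_additive(self, small_tables):
        EN = small_tables[1].expected_next_population  # SaRw
        assert np.all(np.diff(EN, axis=1) <= 1e-12)

    def test_compensatory_expected_population_action_invariant(self, small_tables):
        EN = small_tables[3].expected_next_population  # ScRw
        assert np.abs(EN - EN[:, [0]]).max() <= 1e-12

    def test_tables_finite_and_nonnegative(self, small_tables):
        for tab in small_tables:
            for arr in (tab.expected_harvest, tab.expected_next_population, tab.harvest_nodes):
                assert np.isfinite(arr).all()
                assert arr.min() >= 0

    def test_sparse_and_dense_kernels_agree(self):
        n_grid = build_grid(1.0, 17.0, 2.0)
        p_grid = build_grid(1.0, 7.0, 2.0)
        model = four_models()[1]
        dense = build_model_kernel(model, CONSTS, REGS, n_grid, p_grid, n_nodes=3, sparse=False)
        sparse = build_model_kernel(model, CONSTS, REGS, n_grid, p_grid, n_nodes=3, sparse=True)
        for Kd, Ks in zip(dense.kernel, sparse.kernel):
            np.testing.assert_allclose(np.asarray(Ks.todense()), Kd, atol=1e-14)

    def test_kernel_matches_generic_builder(self):
        # cross-check the vectorized builder against the generic
        # enumeration-based one on a tiny grid
        from harvestmdp.discretize import build_kernel as generic_kernel
        from harvestmdp.mallard import _cohort_kill_rates, _survivals, reproduction_rate

        n_grid = build_grid(2.0, 10.0, 4.0)
        p_grid = build_grid(1.0, 5.0, 2.0)
        model = four_models()[1]
        tab = build_model_kernel(model, CONSTS, REGS, n_grid, p_grid, n_nodes=2, sparse=False)
        from harvestmdp.discretize import gauss_hermite

        eps_n = gauss_hermite(0.0, CONSTS.process_error_variance_N, 2)
        eps_p = gauss_hermite(0.0, CONSTS.process_error_variance_P, 2)
        for a in range(4):
            hn = REGS.harvest_noise(a, 2)

            def fn(state, _a, noise, action=a):
                h, zn, zp = noise
                K = _cohort_kill_rates(REGS, CONSTS, h)
                N = population_transition(
                    model, CONSTS, SystemState(state[0], state[1]), K, zn
                )
                return (N, pond_transition(CONSTS, state[1], zp))

            (K_ref,) = generic_kernel(fn, [n_grid, p_grid], [hn, eps_n, eps_p], 1)
            np.testing.assert_allclose(tab.kernel[a], K_ref, atol=1e-12)
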
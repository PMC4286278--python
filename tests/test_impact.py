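import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from commuteair.impact import (
    acr,
    attributable_static,
    compute_ABC,
    expected_person_time,
    export_import_log_ratio,
    scenario_threshold,
)


def oracle_abc(pop, rates, conc, effects, exits, x0s, share=1.0 / 3.0):
    """Independent scalar evaluation of the per-draw attributable-death split
    with death counts replaced by their expectations.

    Pure-Python loops and math-module arithmetic; kept deliberately separate
    from the vectorized implementation it checks.
    """
    n = len(pop)

    def frac(j):
        b = max(effects[j], 0.0)
        return 1.0 - 1.0 / math.exp(b * (conc[j] - x0s[j])) if conc[j] > x0s[j] else 0.0

    A, B, C = [0.0] * n, [0.0] * n, [0.0] * n
    for i in range(n):
        total_exit = sum(exits[i][j] for j in range(n) if j != i)
        mu_s = (pop[i] - share * total_exit) * rates[i]
        A[i] = mu_s * frac(i)
        for j in range(n):
            if j == i:
                continue
            B[i] += share * exits[i][j] * rates[i] * frac(j)
            C[i] += share * exits[j][i] * rates[j] * frac(i)
    return A, B, C


class TestScenarios:
    def test_rs0(self):
        assert scenario_threshold(35.0, "RS0") == 20.0

    def test_rs1(self):
        assert scenario_threshold(35.0, "RS1") == 40.0

    def test_rs2_plain_reduction(self):
        assert scenario_threshold(50.0, "RS2") == pytest.approx(40.0)

    def test_rs2_capped_at_limit(self):
        assert scenario_threshold(22.0, "RS2") == pytest.approx(20.0)

    def test_rs2_inactive_below_limit(self):
        assert scenario_threshold(15.0, "RS2") == 15.0

    def test_rs3(self):
        assert scenario_threshold(50.0, "RS3") == pytest.approx(40.0)
        assert scenario_threshold(60.0, "RS3") == pytest.approx(48.0)
        assert scenario_threshold(35.0, "RS3") == 35.0

    def test_unknown_scenario(self):
        with pytest.raises(KeyError):
            scenario_threshold(30.0, "RS9")

    @given(x=st.floats(0, 200))
    def test_threshold_never_exceeds_concentration_when_active(self, x):
        for s in ("RS2", "RS3"):
            assert scenario_threshold(x, s) <= x + 1e-12


class TestAttributableStatic:
    def test_direct_evaluation(self):
        expected = 100.0 * (1 - math.exp(-0.03))
        assert attributable_static(100.0, 0.001, 50.0, 20.0) == pytest.approx(expected)

    def test_indicator_off(self):
        assert attributable_static(100.0, 0.001, 15.0, 20.0) == 0.0

    def test_negative_effect_truncated(self):
        assert attributable_static(100.0, -0.002, 50.0, 20.0) == 0.0

    @given(
        y=st.floats(0, 1e5),
        beta=st.floats(-0.01, 0.01),
        x=st.floats(0, 150),
        x0=st.floats(0, 150),
    )
    def test_bounds(self, y, beta, x, x0):
        ad = attributable_static(y, beta, x, x0)
        assert 0.0 <= ad < max(y, 1e-300) or (y == 0 and ad == 0)


class TestPersonTime:
    def test_direct_evaluation(self):
        mu_s, _ = expected_person_time(30_000, np.array([9000.0, 0.0]), 0.01)
        assert mu_s == pytest.approx(270.0)

    def test_commuter_term(self):
        _, mu_c = expected_person_time(30_000, np.array([3000.0, 0.0]), 0.01)
        assert mu_c[0] == pytest.approx(10.0)

    def test_no_commuting(self):
        mu_s, mu_c = expected_person_time(1000, np.zeros(3), 0.02)
        assert mu_s == pytest.approx(20.0)
        assert np.all(mu_c == 0)

    def test_conservation(self):
        pop, r = 25_000, 0.013
        flows = np.array([1000.0, 2500.0, 0.0])
        mu_s, mu_c = expected_person_time(pop, flows, r)
        assert mu_s + mu_c.sum() == pytest.approx(pop * r)

    def test_degenerate_population(self):
        with pytest.raises(ValueError):
            expected_person_time(100, np.array([400.0]), 0.01)
        with pytest.raises(ValueError):
            expected_person_time(100, np.array([10.0]), 0.01, share=1.5)


class TestComputeABC:
    def test_hand_computed_fixture(self, fixture3):
        f = fixture3
        A, B, C = compute_ABC(
            f["rates"], f["conc"], f["effects"], f["exits"], f["pop"],
            "RS0", expected_counts=True,
        )
        # frozen from the pre-build hand evaluation
        np.testing.assert_allclose(A, [8.570795, 0.980879, 0.0], atol=5e-7)
        np.testing.assert_allclose(B, [0.049875, 0.098515, 0.394060], atol=5e-7)
        np.testing.assert_allclose(C, [0.492574, 0.049875, 0.0], atol=5e-7)
        c1 = (1 / 3 * 1000 * 0.01 + 1 / 3 * 2000 * 0.02) * (1 - math.exp(-0.001 * 30))
        assert C[0] == pytest.approx(c1, rel=1e-12)

    def test_matches_scalar_oracle(self, fixture3):
        f = fixture3
        for scen in ("RS0", "RS1", "RS2", "RS3"):
            A, B, C = compute_ABC(
                f["rates"], f["conc"], f["effects"], f["exits"], f["pop"],
                scen, expected_counts=True,
            )
            x0s = scenario_threshold(f["conc"], scen)
            oa, ob, oc = oracle_abc(
                f["pop"], f["rates"], f["conc"], f["effects"], f["exits"], x0s
            )
            np.testing.assert_allclose(A, oa, rtol=1e-12)
            np.testing.assert_allclose(B, ob, rtol=1e-12)
            np.testing.assert_allclose(C, oc, rtol=1e-12)

    def test_all_negative_effects_zero(self, fixture3):
        f = fixture3
        A, B, C = compute_ABC(
            f["rates"], f["conc"], -np.abs(f["effects"]), f["exits"], f["pop"],
            "RS0", expected_counts=True,
        )
        assert np.all(A == 0) and np.all(B == 0) and np.all(C == 0)

    def test_no_commuting_matches_static(self, fixture3):
        f = fixture3
        A, B, C = compute_ABC(
            f["rates"], f["conc"], f["effects"], np.zeros((3, 3)), f["pop"],
            "RS0", expected_counts=True,
        )
        assert np.all(B == 0) and np.all(C == 0)
        y = f["pop"] * f["rates"]
        x0 = scenario_threshold(f["conc"], "RS0")
        np.testing.assert_allclose(A, attributable_static(y, f["effects"], f["conc"], x0))

    def test_draw_truncation_mode(self, fixture3):
        f = fixture3
        effects = f["effects"].copy()
        effects[1] = -0.001
        A, B, C = compute_ABC(
            f["rates"], f["conc"], effects, f["exits"], f["pop"],
            "RS0", expected_counts=True, truncation="draw",
        )
        assert np.all(A == 0) and np.all(B == 0) and np.all(C == 0)
        with pytest.raises(ValueError):
            compute_ABC(
                f["rates"], f["conc"], effects, f["exits"], f["pop"],
                "RS0", expected_counts=True, truncation="bogus",
            )

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_conservation_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        pop = rng.integers(5000, 50_000, n).astype(float)
        rates = rng.uniform(0.005, 0.02, n)
        conc = rng.uniform(10, 60, n)
        effects = rng.normal(0.001, 0.001, n)
        exits = rng.integers(0, 500, (n, n)).astype(float)
        np.fill_diagonal(exits, 0.0)
        A, B, C = compute_ABC(
            rates, conc, effects, exits, pop, "RS0",
            rng=np.random.default_rng(seed + 1),
        )
        assert B.sum() == pytest.approx(C.sum(), rel=1e-10, abs=1e-12)
        assert np.all(A >= 0) and np.all(B >= 0) and np.all(C >= 0)

    def test_misaligned_dimensions(self, fixture3):
        f = fixture3
        with pytest.raises(ValueError):
            compute_ABC(
                f["rates"][:2], f["conc"], f["effects"], f["exits"], f["pop"],
                "RS0", expected_counts=True,
            )


class TestAcr:
    def test_paper_total(self):
        assert round(float(acr(865.3, 9_545_441)), 1) == 9.1

    def test_zero(self):
        assert acr(0.0, 1000) == 0.0

    def test_scaling(self):
        assert acr(10.0, 2000) == pytest.approx(acr(10.0, 1000) / 2)

    def test_positive_population_required(self):
        with pytest.raises(ValueError):
            acr(1.0, 0)


class TestLogRatio:
    def test_balance(self):
        assert export_import_log_ratio(2.0, 2.0) == 0.0

    def test_doubling(self):
        assert export_import_log_ratio(4.0, 2.0) == pytest.approx(math.log(2))

    def test_exporter_only(self):
        assert export_import_log_ratio(1.0, 0.0) == math.inf

    def test_importer_only(self):
        assert export_import_log_ratio(0.0, 1.0) == -math.inf

    def test_undefined(self):
        assert math.isnan(export_import_log_ratio(0.0, 0.0))

    def test_vectorized(self):
        out = export_import_log_ratio(np.array([1.0, 0.0]), np.array([0.0, 0.0]))
        assert out[0] == math.inf and math.isnan(out[1])
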
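import numpy as np
import pytest

from commuteair import commuting, impact, montecarlo
from commuteair.montecarlo import ImpactDraws, McConfig, run_monte_carlo, run_static, summarize

from conftest import make_input_draws


@pytest.fixture(scope="module")
def mc_inputs(study7, truth7):
    rates, conc, effects = make_input_draws(truth7, 200, seed=21)
    posterior = commuting.posterior_from_counts(
        study7.od_counts, study7.region.populations_2001
    )
    return rates, conc, effects, posterior


class TestRunMonteCarlo:
    def test_reproducible(self, mc_inputs, study7):
        rates, conc, effects, post = mc_inputs
        cfg = McConfig(seed=5, n_draws=50, scenarios=("RS0",))
        a = run_monte_carlo(rates, conc, effects, post, study7.region.populations_2007, cfg)
        b = run_monte_carlo(rates, conc, effects, post, study7.region.populations_2007, cfg)
        np.testing.assert_array_equal(a["RS0"].A, b["RS0"].A)
        np.testing.assert_array_equal(a["RS0"].B, b["RS0"].B)
        np.testing.assert_array_equal(a["RS0"].C, b["RS0"].C)

    def test_degenerate_inputs_constant_draws(self, fixture3):
        f = fixture3
        n_draws = 20
        rates = np.tile(f["rates"], (n_draws, 1))
        conc = np.tile(f["conc"], (n_draws, 1))
        effects = np.tile(f["effects"], (n_draws, 1))
        flows = commuting.FlowDraws(
            draws=np.tile(f["exits"].astype(np.int64), (n_draws, 1, 1)),
            n_resampled_rows=0,
        )
        cfg = McConfig(seed=1, n_draws=n_draws, scenarios=("RS0",), expected_counts=True)
        res = run_monte_carlo(rates, conc, effects, None, f["pop"], cfg, flow_draws=flows)
        ab = res["RS0"].ad_ab
        assert np.allclose(ab, ab[0])
        expected_A = np.array([8.570795, 0.980879, 0.0])
        expected_B = np.array([0.049875, 0.098515, 0.394060])
        np.testing.assert_allclose(ab[0], expected_A + expected_B, atol=5e-7)

    def test_conservation_per_draw(self, mc_inputs, study7):
        rates, conc, effects, post = mc_inputs
        cfg = McConfig(seed=6, n_draws=100)
        res = run_monte_carlo(rates, conc, effects, post, study7.region.populations_2007, cfg)
        for draws in res.values():
            np.testing.assert_allclose(
                draws.B.sum(axis=1), draws.C.sum(axis=1), rtol=1e-10, atol=1e-12
            )
            np.testing.assert_allclose(
                draws.ad_ab.sum(axis=1), draws.ad_ac.sum(axis=1), rtol=1e-10, atol=1e-12
            )

    def test_scenario_monotonicity(self, mc_inputs, study7):
        rates, conc, effects, post = mc_inputs
        cfg = McConfig(seed=7, n_draws=100)
        res = run_monte_carlo(rates, conc, effects, post, study7.region.populations_2007, cfg)
        tol = 1e-12
        assert np.all(res["RS1"].ad_ab <= res["RS0"].ad_ab + tol)
        assert np.all(res["RS2"].ad_ab <= res["RS0"].ad_ab + tol)
        assert np.all(res["RS3"].ad_ab <= res["RS1"].ad_ab + tol)
        assert np.all(res["RS3"].ad_ab <= res["RS2"].ad_ab + tol)

    def test_draw_count_mismatch(self, mc_inputs, study7):
        rates, conc, effects, post = mc_inputs
        cfg = McConfig(seed=8, n_draws=1000)
        with pytest.raises(ValueError, match="draws"):
            run_monte_carlo(rates, conc, effects, post, study7.region.populations_2007, cfg)

    def test_static_equivalence_expected_counts(self, mc_inputs, study7, truth7):
        rates, conc, effects, _ = mc_inputs
        n = study7.region.n_munis
        zero_flows = commuting.FlowDraws(
            draws=np.zeros((50, n, n), dtype=np.int64), n_resampled_rows=0
        )
        cfg = McConfig(seed=9, n_draws=50, expected_counts=True)
        res = run_monte_carlo(
            rates, conc, effects, None, study7.region.populations_2007, cfg,
            flow_draws=zero_flows,
        )
        static = run_static(rates, conc, effects, study7.region.populations_2007, cfg)
        for s in cfg.scenarios:
            assert np.all(res[s].B == 0) and np.all(res[s].C == 0)
            np.testing.assert_allclose(res[s].ad_ab, static[s], rtol=1e-12)
            np.testing.assert_allclose(res[s].ad_ac, static[s], rtol=1e-12)


class TestSummarize:
    def _draws(self, mat):
        z = np.zeros_like(mat)
        return ImpactDraws(A=mat, B=z, C=z)

    def test_percentile_example(self):
        draws = self._draws(np.arange(10.0)[:, None])
        out = summarize(draws, np.array([1000.0]))
        row = out.iloc[0]
        assert row["ad_ab_median"] == pytest.approx(4.5)
        assert row["ad_ab_cri10"] == pytest.approx(0.9)
        assert row["ad_ab_cri90"] == pytest.approx(8.1)

    def test_sort_based_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            vals = rng.uniform(0, 100, 40)
            out = summarize(self._draws(vals[:, None]), np.array([1.0]))
            srt = np.sort(vals)
            # linear interpolation between order statistics
            for col, q in (("ad_ab_cri10", 0.1), ("ad_ab_median", 0.5), ("ad_ab_cri90", 0.9)):
                pos = q * (len(srt) - 1)
                lo = int(np.floor(pos))
                expect = srt[lo] + (pos - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])
                assert out.iloc[0][col] == pytest.approx(expect)

    def test_all_zero_draws(self):
        out = summarize(self._draws(np.zeros((20, 2))), np.array([10.0, 10.0]))
        assert np.all(out["pr_positive"] == 0.0)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(11)
        mat = rng.uniform(0, 5, (30, 4))
        out = summarize(self._draws(mat), np.full(4, 100.0), np.zeros(4, int))
        row = out.iloc[0]
        assert row["ad_ab_cri10"] <= row["ad_ab_median"] <= row["ad_ab_cri90"]

    def test_group_sum_then_summarize(self):
        # region median of sums differs from sum of medians for anticomonotone draws
        mat = np.column_stack([np.arange(10.0), np.arange(10.0)[::-1]])
        out = summarize(self._draws(mat), np.array([1.0, 1.0]), np.zeros(2, int))
        assert out.iloc[0]["ad_ab_median"] == pytest.approx(9.0)

    def test_municipality_permutation_invariance(self):
        rng = np.random.default_rng(12)
        mat = rng.uniform(0, 5, (30, 6))
        labels = np.array([0, 0, 1, 1, 2, 2])
        perm = rng.permutation(6)
        a = summarize(self._draws(mat), np.full(6, 10.0), labels)
        b = summarize(self._draws(mat[:, perm]), np.full(6, 10.0), labels[perm])
        for g in (0, 1, 2):
            assert a.set_index("group").loc[g, "ad_ab_median"] == pytest.approx(
                b.set_index("group").loc[g, "ad_ab_median"]
            )

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            summarize(self._draws(np.zeros((5, 1))), np.array([1.0]))

    def test_pr_export_counts_strict_inequality(self):
        a = np.zeros((20, 1))
        b = np.ones((20, 1))
        c = np.ones((20, 1))  # ties -> not counted
        out = summarize(ImpactDraws(A=a, B=b, C=c), np.array([1.0]))
        assert out.iloc[0]["pr_export_gt_import"] == 0.0


class TestReportTables:
    @pytest.fixture(scope="class")
    def results(self, study7, truth7):
        rates, conc, effects = make_input_draws(truth7, 100, seed=31)
        posterior = commuting.posterior_from_counts(
            study7.od_counts, study7.region.populations_2001
        )
        cfg = McConfig(seed=13, n_draws=100)
        return montecarlo.run_monte_carlo(
            rates, conc, effects, posterior, study7.region.populations_2007, cfg
        )

    def test_province_table_structure(self, results, study7, tmp_path):
        reg = study7.region
        tables = montecarlo.report_tables(
            results, reg.province_id, reg.capital_flag, reg.populations_2007, tmp_path
        )
        prov = tables["province"]
        n_prov = len(np.unique(reg.province_id))
        rs0 = prov[prov["scenario"] == "RS0"]
        assert len(rs0) == n_prov + 1
        assert "Total" in rs0["province"].tolist()
        assert (tmp_path / "table_province.csv").exists()

    def test_total_row_is_regional_sum_summary(self, results, study7):
        reg = study7.region
        tables = montecarlo.report_tables(
            results, reg.province_id, reg.capital_flag, reg.populations_2007
        )
        prov = tables["province"]
        total = prov[(prov["scenario"] == "RS0") & (prov["province"] == "Total")]
        expected = np.median(results["RS0"].ad_ab.sum(axis=1))
        assert total["ad_ab_median"].iloc[0] == pytest.approx(expected)

    def test_capitals_probabilities_in_unit_interval(self, results, study7):
        reg = study7.region
        tables = montecarlo.report_tables(
            results, reg.province_id, reg.capital_flag, reg.populations_2007
        )
        pr = tables["capitals"]["pr_export_gt_import"]
        assert np.all((0 <= pr) & (pr <= 1))

    def test_log_ratio_flags(self, results, study7):
        reg = study7.region
        tables = montecarlo.report_tables(
            results, reg.province_id, reg.capital_flag, reg.populations_2007
        )
        lr = tables["log_ratio"]
        finite = lr[lr["flag"] == "finite"]
        assert np.all(np.isfinite(finite["log_ratio"]))
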
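"""Tornado analysis, PSA sampling, CEAC and crossover estimation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from psmcea.model import run_base_case
from psmcea.sensitivity import (
    InvariantViolation,
    ParamSpec,
    PsaResult,
    apply_params,
    ceac,
    crossover_wtp,
    owsa,
    probability_cost_effective,
    run_psa,
    sample_params,
)


def degenerate(case):
    """Case whose sensitivity parameters all have zero range."""
    params = tuple(
        dataclasses.replace(p, low=p.baseline, high=p.baseline) for p in case.params
    )
    return case.evolve(params=params)


class TestApplyParams:
    def test_price_and_utility_routing(self, calibrated):
        varied = apply_params(
            calibrated,
            {"cost_finotonlimab_per_mg": 10.0, "utility_pd": 0.5},
        )
        assert varied.econ.unit_price["finotonlimab"] == 10.0
        assert varied.utilities.u_pd == 0.5
        # original untouched (frozen dataclasses)
        assert calibrated.econ.unit_price["finotonlimab"] == 48.80

    def test_utility_ordering_violation_raises_without_clamp(self, calibrated):
        with pytest.raises(InvariantViolation):
            apply_params(calibrated, {"utility_pd": 0.95})

    def test_utility_clamped_at_range_edge(self, calibrated):
        varied = apply_params(calibrated, {"utility_pd": 0.95}, clamp_utilities=True)
        assert varied.utilities.u_pd == varied.utilities.u_pfs


class TestOwsa:
    def test_zero_range_parameter_has_zero_spread(self, calibrated):
        entries = owsa(degenerate(calibrated))
        assert all(e.spread == 0.0 for e in entries)

    def test_sorafenib_price_drop_raises_icer(self, calibrated):
        p = next(p for p in calibrated.params if p.name == "cost_sorafenib_per_mg")
        base = run_base_case(calibrated).comparison.icer
        lo = apply_params(calibrated, {p.name: p.low})
        hi = apply_params(calibrated, {p.name: p.high})
        icer_lo = run_base_case(lo).comparison.icer
        icer_hi = run_base_case(hi).comparison.icer
        # cheaper comparator -> larger incremental cost -> larger ICER
        assert icer_lo > base > icer_hi

    def test_entries_sorted_by_spread(self, calibrated):
        entries = owsa(calibrated)
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)
        assert len(entries) == len(calibrated.params)


class TestSampling:
    def test_gamma_moment_matching(self, calibrated, rng):
        p = next(p for p in calibrated.params if p.name == "cost_finotonlimab_per_mg")
        draws = np.array(
            [sample_params([p], rng)[p.name] for _ in range(100_000)]
        )
        assert draws.mean() == pytest.approx(48.80, rel=0.005)
        assert draws.std() == pytest.approx(p.sd, rel=0.05)

    def test_zero_sd_returns_baseline(self, calibrated, rng):
        p = dataclasses.replace(
            calibrated.params[0], low=calibrated.params[0].baseline,
            high=calibrated.params[0].baseline,
        )
        assert all(
            sample_params([p], rng)[p.name] == p.baseline for _ in range(10)
        )

    def test_beta_draws_stay_in_support(self, calibrated, rng):
        betas = [p for p in calibrated.params if p.distribution == "beta"]
        for p in betas:
            draws = np.array([sample_params([p], rng)[p.name] for _ in range(2000)])
            assert np.all((draws >= 0.0) & (draws <= 1.0))

    def test_scaled_beta_discount_rate(self, calibrated, rng):
        p = next(p for p in calibrated.params if p.name == "discount_rate_annual")
        draws = np.array([sample_params([p], rng)[p.name] for _ in range(20_000)])
        assert np.all((draws >= 0.0) & (draws <= 0.05))
        assert draws.mean() == pytest.approx(0.045, abs=0.001)

    def test_infeasible_beta_falls_back_to_uniform(self, rng):
        p = ParamSpec(
            name="x", target="utility.pd", baseline=0.5, low=0.0, high=1.0,
            distribution="beta",
        )
        wide = dataclasses.replace(p, low=-1.5, high=2.5, baseline=0.5)
        draws = np.array([sample_params([wide], rng)["x"] for _ in range(2000)])
        assert np.all((draws >= wide.low) & (draws <= wide.high))


class TestPsa:
    def test_same_seed_bit_identical(self, calibrated):
        a = run_psa(calibrated, n_iterations=50, seed=123)
        b = run_psa(calibrated, n_iterations=50, seed=123)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_degenerate_variances_reproduce_base_case(self, calibrated):
        deg = degenerate(calibrated)
        psa = run_psa(deg, n_iterations=5, seed=1)
        base = run_base_case(calibrated)
        ref, comp = calibrated.reference_arm, calibrated.comparator_arm
        for _, row in psa.draws.iterrows():
            assert row[f"cost_{ref}"] == pytest.approx(
                base.arm_results[ref].total_cost, abs=1.0
            )
            assert row[f"qaly_{ref}"] == pytest.approx(
                base.arm_results[ref].total_qaly, abs=1e-6
            )
            assert row[f"cost_{comp}"] == pytest.approx(
                base.arm_results[comp].total_cost, abs=1.0
            )

    def test_resampling_counted(self, calibrated):
        psa = run_psa(calibrated, n_iterations=200, seed=5)
        # utility draws overlap, so some joint draws must be rejected
        assert psa.n_resampled >= 0
        assert len(psa.draws) == 200


class TestCeac:
    def test_complement_and_limits(self, calibrated):
        psa = run_psa(calibrated, n_iterations=200, seed=9)
        grid = np.array([0.0, 299_400.0, 5e6])
        curve = ceac(psa, grid)
        assert np.allclose(curve.p_reference + curve.p_comparator, 1.0)
        assert curve.p_reference[0] == pytest.approx(0.0)  # costlier at lambda=0
        # at very large WTP the higher-QALY strategy wins almost surely
        assert curve.p_reference[-1] == pytest.approx(
            float((psa.draws["inc_qaly"] > 0).mean())
        )

    def test_monotone_for_higher_qaly_strategy(self, calibrated):
        psa = run_psa(calibrated, n_iterations=300, seed=17)
        grid = np.arange(0.0, 1.5e6, 25_000.0)
        curve = ceac(psa, grid)
        assert np.all(np.diff(curve.p_reference) >= -1e-12)

    def test_seed_to_seed_ceac_stability(self, calibrated):
        # across 10 seeds at n=1000 the per-WTP standard deviation stays at
        # binomial sampling-noise scale, sqrt(p(1-p)/n) <= 1.6 points
        grid = np.arange(0.0, 1.5e6 + 1, 50_000.0)
        curves = [
            ceac(run_psa(calibrated, n_iterations=1000, seed=s), grid).p_reference
            for s in range(10)
        ]
        stack = np.vstack(curves)
        assert float(np.max(stack.std(axis=0))) <= 0.02


class TestCrossover:
    @staticmethod
    def _psa_from(inc_cost, inc_qaly):
        df = pd.DataFrame(
            {"draw": range(len(inc_cost)), "inc_cost": inc_cost,
             "inc_qaly": inc_qaly}
        )
        return PsaResult(df, seed=0, n_resampled=0,
                         reference_arm="dual", comparator_arm="sorafenib")

    def test_degenerate_draws_cross_at_common_icer(self):
        psa = self._psa_from([100.0] * 20, [0.001] * 20)
        grid = np.arange(0.0, 200_001.0, 1000.0)
        cross = crossover_wtp(ceac(psa, grid))
        assert cross.within_grid
        assert cross.wtp == pytest.approx(100_000.0, abs=1.0)

    def test_no_crossing_signals_out_of_range(self):
        psa = self._psa_from([1000.0] * 20, [0.0] * 20)  # never cost-effective
        grid = np.arange(0.0, 1e6, 10_000.0)
        cross = crossover_wtp(ceac(psa, grid))
        assert not cross.within_grid

    def test_case_study_crossover_tracks_deterministic_icer(self, calibrated):
        psa = run_psa(calibrated, n_iterations=1000, seed=3)
        grid = np.arange(0.0, 1.5e6 + 1, 10_000.0)
        cross = crossover_wtp(ceac(psa, grid))
        icer = run_base_case(calibrated).comparison.icer
        assert cross.within_grid
        assert cross.wtp == pytest.approx(icer, rel=0.15)


def test_wtp_zero_probability(calibrated):
    psa = run_psa(calibrated, n_iterations=100, seed=2)
    assert probability_cost_effective(psa, 0.0) == 0.0
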
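"""Sweep orchestration, bisection force window, Monte-Carlo risk engine."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

from ossicrimp.safety import SafetyReport
from ossicrimp.sweep import (
    JUNIOR_SURGEON,
    ForceDistribution,
    SweepGrid,
    default_grid,
    exceedance_probability,
    max_safe_force,
    run_sweep,
    stress_force_interpolator,
)


def synthetic_runner(slope_mpa_per_n=120.0):
    """Closed-form linear stand-in for the FE pipeline (0.12 MPa/mN)."""

    def runner(case):
        if case.load.mode == "crimp_force":
            peak = slope_mpa_per_n * case.load.crimping_force_F
        else:
            peak = 10.0 * case.load.applied_pressure
        return SafetyReport(
            config_id=case.config_id,
            peak_incus_von_mises=peak,
            mean_contact_von_mises=0.5 * peak,
            mean_contact_von_mises_nodal=0.5 * peak,
            peak_prosthesis_von_mises=0.2 * peak,
            dominant_stress_mode="compressive",
            threshold_ratios={"bone_von_mises": peak / 60.0},
            risk_class="safe" if peak <= 51 else (
                "near_threshold" if peak <= 60 else "exceeds_threshold"),
        )

    return runner


class TestGridAndSweep:
    def test_default_grid_is_the_published_twelve_cases(self):
        grid = default_grid()
        assert len(grid) == 12
        ptfe = [c for c in grid.cases if c.material.name == "ptfe"]
        ti = [c for c in grid.cases if c.material.name == "titanium"]
        assert sorted(c.ring.outer_diameter for c in ptfe) == [1.2, 1.4, 1.8]
        assert sorted({c.ring.band_width_w for c in ti}) == [0.2, 0.3, 0.5]
        assert sorted({c.load.crimping_force_F for c in ti}) == [0.3, 0.4, 0.5]

    def test_ptfe_cases_carry_the_published_pressures(self):
        grid = default_grid()
        ps = sorted(round(c.load.applied_pressure, 3) for c in grid.cases
                    if c.material.name == "ptfe")
        assert ps == [0.405, 0.476, 0.524]

    def test_sweep_with_synthetic_runner_yields_sorted_rows(self):
        df = run_sweep(default_grid(), case_runner=synthetic_runner())
        assert len(df) == 12
        assert (df["status"] == "ok").all()
        # deterministic ordering by (material, geometry, force)
        ti = df[df["material"] == "titanium"]
        assert ti["band_width_mm"].is_monotonic_increasing or (
            ti.sort_values(["band_width_mm", "force_N"]).index.tolist()
            == ti.index.tolist())

    def test_empty_grid_gives_empty_table(self):
        df = run_sweep(SweepGrid(()), case_runner=synthetic_runner())
        assert len(df) == 0

    def test_case_failures_are_recorded_not_fatal(self):
        def failing(case):
            if case.config_id.startswith("ti_w0.3"):
                raise RuntimeError("synthetic failure")
            return synthetic_runner()(case)

        df = run_sweep(default_grid(), case_runner=failing)
        assert len(df) == 12
        assert (df["status"] == "failed").sum() == 3
        assert df.loc[df["status"] == "failed", "error"].str.contains(
            "synthetic").all()

    def test_titanium_stress_non_decreasing_in_force(self):
        df = run_sweep(default_grid(), case_runner=synthetic_runner())
        ti = df[df["material"] == "titanium"]
        for w, grp in ti.groupby("band_width_mm"):
            peaks = grp.sort_values("force_N")["peak_incus_von_mises_MPa"]
            assert peaks.is_monotonic_increasing


class TestMaxSafeForce:
    def test_linear_response_closed_form(self):
        # 0.12 MPa/mN -> 60 MPa at exactly 500 mN
        response = lambda f_n: 120.0 * f_n
        f = max_safe_force(response, 60.0, bracket=(0.0, 1.3), tol_N=1e-5)
        assert f == pytest.approx(0.5, abs=1e-4)

    def test_unbounded_limit_returns_upper_bracket(self):
        f = max_safe_force(lambda f_n: 120.0 * f_n, np.inf, bracket=(0.0, 1.3))
        assert f == 1.3

    def test_bracket_excluding_solution_raises(self):
        with pytest.raises(ValueError, match="exceeds the limit"):
            max_safe_force(lambda f_n: 120.0 * f_n, 60.0, bracket=(0.6, 1.3))

    def test_non_monotone_response_aborts(self):
        with pytest.raises(ValueError, match="monotone"):
            max_safe_force(lambda f_n: np.sin(10 * f_n), 0.5, bracket=(0.0, 1.3))

    def test_matches_fine_grid_scan(self):
        response = stress_force_interpolator(
            [0.3, 0.4, 0.5], [20.0, 35.0, 58.0])
        limit = 50.0
        f_bis = max_safe_force(response, limit, bracket=(0.0, 0.5), tol_N=1e-6)
        grid = np.linspace(0.0, 0.5, 200001)
        f_scan = grid[np.asarray(response(grid)) <= limit].max()
        assert f_bis == pytest.approx(f_scan, abs=5e-6)


class TestStressForceInterpolator:
    def test_interpolates_and_extrapolates_linearly(self):
        r = stress_force_interpolator([0.3, 0.4, 0.5], [30.0, 40.0, 50.0])
        assert r(0.35) == pytest.approx(35.0)
        assert r(0.6) == pytest.approx(60.0)
        assert r(0.0) == pytest.approx(0.0)

    def test_non_monotone_samples_rejected(self):
        with pytest.raises(ValueError):
            stress_force_interpolator([0.3, 0.4, 0.5], [30.0, 25.0, 50.0])


class TestExceedanceProbability:
    def test_degenerate_distribution_below_limit(self):
        dist = ForceDistribution(mean=300.0, sd=1e-6)
        res = exceedance_probability(dist, lambda f: 120.0 * np.asarray(f),
                                     limit_MPa=60.0, n_draws=2000, seed=0)
        assert res["probability"] == 0.0

    def test_matches_truncated_normal_tail(self):
        """Linear response: P(stress > response(500 mN)) equals the exact
        truncated-normal tail P(F > 500 mN), within 3 binomial SEs at 1e5."""
        dist = JUNIOR_SURGEON  # 433 +- 334 mN on [0, 1300]
        response = lambda f_n: 120.0 * np.asarray(f_n)  # 60 MPa at 500 mN
        res = exceedance_probability(dist, response, limit_MPa=60.0,
                                     n_draws=100_000, seed=11)
        a = (dist.lower - dist.mean) / dist.sd
        b = (dist.upper - dist.mean) / dist.sd
        p_exact = truncnorm(a, b, loc=dist.mean, scale=dist.sd).sf(500.0)
        assert abs(res["probability"] - p_exact) <= 3 * max(res["standard_error"],
                                                            1e-6)

    def test_reproducible_under_fixed_seed(self):
        dist = JUNIOR_SURGEON
        kw = dict(stress_response=lambda f: 120.0 * np.asarray(f),
                  limit_MPa=60.0, n_draws=5000, seed=42)
        assert exceedance_probability(dist, **kw) == exceedance_probability(dist, **kw)

    def test_convergence_rate_toward_exact_tail(self):
        dist = JUNIOR_SURGEON
        response = lambda f_n: 120.0 * np.asarray(f_n)
        a = (dist.lower - dist.mean) / dist.sd
        b = (dist.upper - dist.mean) / dist.sd
        p_exact = truncnorm(a, b, loc=dist.mean, scale=dist.sd).sf(500.0)
        errs = []
        for n in (2000, 128000):
            runs = [abs(exceedance_probability(
                dist, response, limit_MPa=60.0, n_draws=n, seed=s)["probability"]
                - p_exact) for s in range(8)]
            errs.append(np.mean(runs))
        # error should drop roughly like 1/sqrt(n) (factor 8 here); allow slack
        assert errs[1] < errs[0] / 3.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ForceDistribution(mean=300.0, sd=-1.0)
        with pytest.raises(ValueError):
            exceedance_probability(JUNIOR_SURGEON, lambda f: f, n_draws=10, seed=0)
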
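"""Simulation machinery, regression statistics and the spike-in study."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import aquanmr as aq
from aquanmr.evaluation import (
    SimulationDesign,
    linear_regression,
    loq_concentration,
    percent_difference,
    relative_intercept,
    simulate_spectra,
)


class TestSimulateSpectra:
    def test_full_factorial_count(self, sim_design):
        design, _ = sim_design
        sims = simulate_spectra(design)
        assert len(sims) == 21  # 3 backgrounds x 7 levels

    def test_zero_level_returns_background_alone(self, sim_design):
        design, _ = sim_design
        d0 = replace(design, scaling_levels=(0.0,))
        for (name, level, sim, truth), bg in zip(
            simulate_spectra(d0), design.backgrounds
        ):
            np.testing.assert_array_equal(sim.intensities, bg.intensities)
            assert not truth.intensities.any()

    def test_matches_elementwise_sum_oracle(self, sim_design):
        design, _ = sim_design
        for name, level, sim, truth in simulate_spectra(design)[:4]:
            bg = design.backgrounds[design.background_names.index(name)]
            np.testing.assert_array_equal(
                sim.intensities, bg.intensities + level * design.narrow_spectrum.intensities
            )
            np.testing.assert_array_equal(
                truth.intensities, level * design.narrow_spectrum.intensities
            )

    def test_axis_mismatch_rejected(self, sim_design):
        design, _ = sim_design
        other = aq.Spectrum(
            aq.build_axis([(0.0, 1.0)], 0.5), np.zeros(2)
        )
        with pytest.raises(ValueError, match="axis"):
            SimulationDesign(
                backgrounds=design.backgrounds,
                narrow_spectrum=other,
                scaling_levels=design.scaling_levels,
            )


class TestLinearRegression:
    def test_exact_line(self):
        s = linear_regression([1, 2, 3], [2, 4, 6])
        assert s.slope == pytest.approx(2.0)
        assert s.intercept == pytest.approx(0.0, abs=1e-12)
        assert s.r2 == pytest.approx(1.0)

    def test_constant_response_convention(self):
        s = linear_regression([1, 2, 3], [5, 5, 5])
        assert s.slope == 0.0
        assert s.r2 == 0.0

    def test_matches_statsmodels_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        x = rng.uniform(0, 10, 40)
        y = 3.2 * x - 1.7 + rng.normal(0, 0.5, 40)
        ours = linear_regression(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert ours.intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert ours.slope == pytest.approx(fit.params[1], rel=1e-10)
        assert ours.r2 == pytest.approx(fit.rsquared, rel=1e-10)

    def test_noise_free_line_recovered_to_1e10(self):
        x = np.linspace(1, 7, 9)
        s = linear_regression(x, 0.37 * x + 11.1)
        assert s.slope == pytest.approx(0.37, abs=1e-10)
        assert s.intercept == pytest.approx(11.1, abs=1e-10)

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            linear_regression([2, 2, 2], [1, 2, 3])


class TestAccuracyMetrics:
    def test_percent_difference_examples(self):
        assert percent_difference(100.0, 90.0) == pytest.approx(10.0)
        assert percent_difference(7.3, 7.3) == 0.0
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        ref=st.floats(0.01, 1e6),
        test=st.floats(0.0, 1e6),
        k=st.floats(0.01, 1e3),
    )
    def test_percent_difference_scale_invariant(self, ref, test, k):
        a = percent_difference(ref, test)
        b = percent_difference(ref * k, test * k)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)

    def test_relative_intercept_zero_and_scaling(self):
        assert relative_intercept(0.0, 123.0) == 0.0
        assert relative_intercept(5.0, 100.0) == pytest.approx(5.0)
        assert relative_intercept(5.0 * 3, 100.0 * 3) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            relative_intercept(1.0, 0.0)


class TestNoiseAndLoq:
    def test_known_sigma_estimated_within_ten_percent(self, axis):
        rng = np.random.default_rng(12)
        spec = aq.Spectrum(axis, rng.normal(0, 2.0, axis.n_bins))
        est = aq.estimate_noise(spec, (9.5, 9.9))
        assert est == pytest.approx(2.0, rel=0.10)

    def test_region_too_small_rejected(self, axis):
        spec = aq.Spectrum(axis, np.zeros(axis.n_bins))
        with pytest.raises(ValueError, match="50"):
            aq.estimate_noise(spec, (9.5, 9.501))

    def test_loq_arithmetic_and_linearity(self):
        class E:
            unit_response = 0.1  # per concentration unit

        assert loq_concentration(E, 1.0, 1.0) == pytest.approx(100.0)
        assert loq_concentration(E, 2.0, 1.0) == pytest.approx(200.0)
        assert loq_concentration(E, 1.0, 2.0) == pytest.approx(50.0)


class TestSimulationStudy:
    def test_zero_background_recovers_unit_slope(self, panel):
        axis = aq.canonical_axis()
        narrow = aq.render_mixture(
            panel, axis,
            {e.name: 1.0 for e in panel.targets}
            | {panel.internal_standard.name: 0.29},
        )
        zero = aq.Spectrum(axis, np.zeros(axis.n_bins))
        design = SimulationDesign(
            backgrounds=(zero,),
            narrow_spectrum=narrow,
            scaling_levels=tuple(np.geomspace(0.3, 3.0, 7)),
            lambdas=(1e7,),
            background_names=("zero",),
        )
        rep = aq.run_simulation_study(design, panel)
        # with nothing to correct the study is perfectly linear through the
        # origin; the baseline stage still perturbs heights by a few percent
        # proportionally (tail absorption where multiplets crowd, smoother
        # undershoot beside tall neighbours), so slopes hover around one
        assert rep.slope.between(0.94, 1.04).all()
        assert (rep.r2 > 0.9999).all()
        assert (rep.rel_intercept.abs() < 0.1).all()

    def test_factorial_row_count(self, sim_report_1e7, panel):
        assert len(sim_report_1e7) == len(panel.targets) * 3 * 1

    def test_rough_background_prefers_smaller_lambda(self, sim_design):
        # background A needs a lower stiffness than smooth C: sweeping lambda
        # upward hurts A's slopes far more than C's
        design, library = sim_design
        sub = replace(
            design,
            backgrounds=(design.backgrounds[0], design.backgrounds[2]),
            background_names=("A", "C"),
            lambdas=(1e6, 1e8),
        )
        rep = aq.run_simulation_study(sub, library)
        dev = rep.assign(dev=(rep.slope - 1.0).abs())
        worst = dev.groupby(["background", "lam"]).dev.max().unstack()
        assert worst.loc["A", 1e8] > worst.loc["A", 1e6]
        assert worst.loc["A", 1e8] > worst.loc["C", 1e8]


class TestSpikeinStudy:
    def test_report_bands(self, spikein_report):
        rep = spikein_report
        assert len(rep) == 5
        assert rep.slope.between(0.95, 1.05).all()
        assert (rep.r2 > 0.999).all()

    def test_identical_arms_give_near_unit_slope(self, spikein_data):
        # same spectra through both arms: only the matrix arm's baseline
        # stage separates them, bounding the slope deviation by its tail
        # absorption (a few percent)
        _, blanks, truth, library = spikein_data
        rep = aq.run_spikein_study(blanks, blanks, truth, library)
        assert np.allclose(rep.slope, 1.0, atol=0.05)
        assert (rep.r2 > 0.998).all()

    def test_deliberate_bias_shows_up_in_slope(self, axis):
        # +16% on one metabolite's matrix-arm heights: that slope tracks it
        matrix, blanks, truth, library = aq.make_spikein_dataset(seed=1)
        biased = []
        victim = library.entry("tartaric_acid")
        lo, hi = victim.window
        for s in matrix:
            v = s.intensities.copy()
            idx = s.axis.window_bins(lo - 0.01, hi + 0.01)
            v[idx] *= 1.16
            biased.append(s.with_intensities(v))
        rep = aq.run_spikein_study(biased, blanks, truth, library)
        row = rep[rep.metabolite == "tartaric_acid"].iloc[0]
        assert row.slope == pytest.approx(1.16, abs=0.04)

    def test_unpaired_inputs_rejected(self, spikein_data):
        matrix, blanks, truth, library = spikein_data
        with pytest.raises(ValueError, match="paired"):
            aq.run_spikein_study(matrix[:-1], blanks, truth, library)
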
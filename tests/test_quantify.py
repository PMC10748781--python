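"""Reporter picking, interference solve, calibration and the full pipeline."""

import numpy as np
import pytest

import aquanmr as aq
from aquanmr.library import (
    Library,
    LorentzianComponent,
    MetaboliteEntry,
    compute_unit_response,
    make_dss_entry,
)
from aquanmr.quantify import (
    InterferenceMatrix,
    build_interference_matrix,
    calibrate_scale,
    pick_reporter,
    solve_concentrations,
)


def _singlet(name, center, height=100.0, halfwidth=0.01, role="target"):
    comp = LorentzianComponent(center, height, 1.2)
    ur = compute_unit_response((comp,), (center - halfwidth, center + halfwidth), 600.0)
    return MetaboliteEntry(name, role, (comp,), center, halfwidth, ur)


def _library(*entries):
    return Library(entries=tuple(entries), frequency_mhz=600.0,
                   internal_standard=make_dss_entry())


class TestPickReporter:
    def test_picks_apex_of_centred_lorentzian(self):
        axis = aq.build_axis([(1.0, 2.0)], 0.0002)
        entry = _singlet("x", 1.3301, halfwidth=0.03)
        spec = aq.render_entry(entry, axis, 1.0)
        p = pick_reporter(spec, entry)
        assert abs(p.picked_ppm - 1.3301) <= 0.0001
        assert p.height == pytest.approx(100.0, rel=1e-9)
        assert not p.at_window_edge

    def test_shifted_signal_yields_matching_offset(self):
        axis = aq.build_axis([(1.0, 2.0)], 0.0002)
        entry = _singlet("x", 1.3301, halfwidth=0.03)
        spec = aq.render_entry(entry, axis, 1.0, shift_offset_ppm=0.005)
        p = pick_reporter(spec, entry)
        assert p.offset_ppm == pytest.approx(0.005, abs=0.0002)

    def test_all_zero_window_flags_edge_and_centres_tie(self):
        axis = aq.build_axis([(1.0, 2.0)], 0.0002)
        entry = _singlet("x", 1.3301)
        spec = aq.Spectrum(axis, np.zeros(axis.n_bins))
        p = pick_reporter(spec, entry)
        assert p.height == 0.0
        assert p.at_window_edge
        assert abs(p.picked_ppm - 1.3301) <= 0.0002

    def test_window_outside_axis_rejected(self):
        axis = aq.build_axis([(5.0, 6.0)], 0.001)
        entry = _singlet("x", 1.33)
        with pytest.raises(ValueError, match="outside"):
            pick_reporter(aq.Spectrum(axis, np.zeros(axis.n_bins)), entry)


class TestInterferenceMatrix:
    def _picked(self, lib, spec):
        return [pick_reporter(spec, e) for e in (*lib.entries, lib.internal_standard)]

    def test_isolated_signals_give_diagonal_matrix(self, axis):
        lib = _library(_singlet("a", 1.5001), _singlet("b", 3.5001))
        spec = aq.render_mixture(lib, axis, {"a": 1.0, "b": 1.0, "DSS": 0.29})
        im = build_interference_matrix(self._picked(lib, spec), lib)
        block = im.A[:2, :2]  # the two panel entries (last row/col is DSS)
        off = np.abs(block - np.diag(np.diag(block)))
        assert np.all(off < 1e-6 * np.diag(block).min())

    def test_close_singlets_match_analytic_tail(self, axis):
        lib = _library(
            _singlet("a", 1.5001, halfwidth=0.0014),
            _singlet("b", 1.5031, halfwidth=0.0014),
        )
        spec = aq.render_mixture(lib, axis, {"a": 1.0, "b": 1.0, "DSS": 0.29})
        im = build_interference_matrix(self._picked(lib, spec), lib)
        gamma = 1.2 / 600.0 / 2
        tail = 100.0 * gamma**2 / (0.003**2 + gamma**2)
        assert im.A[0, 1] == pytest.approx(tail, rel=1e-6)
        assert im.A[1, 0] == pytest.approx(tail, rel=1e-6)

    def test_permutation_relabels_rows_and_columns(self, axis):
        e1, e2 = _singlet("a", 1.5001), _singlet("b", 1.5051)
        spec_lib = _library(e1, e2)
        spec = aq.render_mixture(spec_lib, axis, {"a": 1.0, "b": 2.0, "DSS": 0.29})
        lib12 = _library(e1, e2)
        lib21 = _library(e2, e1)
        im12 = build_interference_matrix(self._picked(lib12, spec), lib12)
        im21 = build_interference_matrix(self._picked(lib21, spec), lib21)
        # swapping the two panel entries swaps the leading 2x2 block
        assert im12.A[0, 0] == im21.A[1, 1]
        assert im12.A[0, 1] == im21.A[1, 0]


class TestSolveConcentrations:
    def test_isolated_system_recovers_exactly(self):
        im = InterferenceMatrix(("a", "b"), np.diag([100.0, 50.0]), 1.0)
        c = solve_concentrations(np.array([100.0 * 0.7, 50.0 * 1.4]), im, 1.0)
        np.testing.assert_allclose(c, [0.7, 1.4], rtol=1e-12)

    def test_symmetric_two_by_two(self):
        im = InterferenceMatrix(("a", "b"), np.array([[1.0, 0.5], [0.5, 1.0]]), 3.0)
        c = solve_concentrations(np.array([2.0, 2.0]), im, 1.0)
        np.testing.assert_allclose(c, [4 / 3, 4 / 3], rtol=1e-12)

    def test_random_well_conditioned_round_trip(self):
        rng = np.random.default_rng(9)
        n = 24
        A = np.eye(n) * rng.uniform(50, 150, n) + rng.uniform(0, 1, (n, n))
        c_true = rng.uniform(0.1, 3.0, n)
        im = InterferenceMatrix(tuple(f"m{i}" for i in range(n)), A,
                                float(np.linalg.cond(A)))
        c = solve_concentrations(A @ c_true * 2.5, im, 2.5)
        assert np.max(np.abs(c - c_true) / c_true) < 1e-6

    def test_singular_matrix_rejected_with_condition(self):
        A = np.array([[1.0, 1.0], [1.0, 1.0 + 1e-15]])
        im = InterferenceMatrix(("a", "b"), A, float(np.linalg.cond(A)))
        with pytest.raises(ValueError, match="condition"):
            solve_concentrations(np.array([1.0, 1.0]), im, 1.0)

    def test_nonnegative_mode_clips_at_zero(self):
        im = InterferenceMatrix(("a", "b"), np.array([[1.0, 0.9], [0.9, 1.0]]), 5.0)
        h = np.array([1.0, 0.5])  # unconstrained solution has a negative entry
        c = solve_concentrations(h, im, 1.0, nonnegative=True)
        assert np.all(c >= 0)


class TestCalibrateScale:
    def test_pure_standard_gives_unit_scale(self, axis):
        lib = _library(_singlet("a", 1.5001))
        spec = aq.render_mixture(lib, axis, {"DSS": 0.29})
        assert calibrate_scale(spec, lib) == pytest.approx(1.0, rel=1e-9)

    def test_scaled_spectrum_gives_that_factor(self, axis):
        lib = _library(_singlet("a", 1.5001))
        spec = aq.render_mixture(lib, axis, {"DSS": 0.29})
        scaled = spec.with_intensities(spec.intensities * 2.5)
        assert calibrate_scale(scaled, lib) == pytest.approx(2.5, rel=1e-9)

    def test_nearby_singlet_perturbs_less_than_one_percent(self, axis):
        # interferer 3+ linewidths from DSS: height-ratio calibration within 1%
        lib = _library(_singlet("near", 0.0091, height=500.0))
        spec = aq.render_mixture(lib, axis, {"DSS": 0.29, "near": 1.0})
        assert calibrate_scale(spec, lib) == pytest.approx(1.0, rel=0.01)

    def test_nonpositive_standard_rejected(self, axis):
        lib = _library(_singlet("a", 1.5001))
        spec = aq.Spectrum(axis, np.full(axis.n_bins, -1.0))
        with pytest.raises(ValueError, match="non-positive"):
            calibrate_scale(spec, lib)


class TestExtendedAqua:
    def test_noiseless_five_metabolites_recovered(self, axis):
        lib = aq.make_synthetic_library(n_targets=5, n_interferents=0, seed=2,
                                        overlap_level="low")
        rng = np.random.default_rng(0)
        conc = {e.name: float(rng.uniform(0.1, 2.0)) for e in lib.targets}
        conc["DSS"] = 0.29
        spec = aq.render_mixture(lib, axis, conc)
        res = aq.extended_aqua(spec, lib, correct_baseline=False)
        for r in res:
            assert r.concentration_uM / 1000 == pytest.approx(
                conc[r.metabolite], rel=1e-6
            )

    def test_interferents_solved_but_not_reported(
        self, panel, noiseless_mixture
    ):
        res = aq.extended_aqua(noiseless_mixture, panel, correct_baseline=False)
        names = {r.metabolite for r in res}
        assert names == {e.name for e in panel.targets}

    def test_modelling_an_overlapping_interferent_reduces_error(self, axis):
        target = _singlet("leu", 0.9601, height=900.0, halfwidth=0.004)
        unknown = _singlet("u", 0.9641, height=600.0, halfwidth=0.003,
                           role="interferent")
        with_u = _library(target, unknown)
        without_u = _library(target)
        conc = {"leu": 1.0, "u": 0.8, "DSS": 0.29}
        spec = aq.render_mixture(with_u, axis, conc)
        res_with = aq.extended_aqua(spec, with_u, correct_baseline=False)
        res_without = aq.extended_aqua(spec, without_u, correct_baseline=False)
        err_with = abs(res_with[0].concentration_uM - 1000.0)
        err_without = abs(res_without[0].concentration_uM - 1000.0)
        assert err_with < err_without

    def test_monotone_in_true_concentration(self, panel, axis, panel_concentrations):
        name = panel.targets[3].name
        bumped = dict(panel_concentrations)
        bumped[name] = panel_concentrations[name] * 1.5
        res_a = aq.extended_aqua(
            aq.render_mixture(panel, axis, panel_concentrations), panel,
            correct_baseline=False,
        )
        res_b = aq.extended_aqua(
            aq.render_mixture(panel, axis, bumped), panel, correct_baseline=False
        )
        get = lambda res: next(r.concentration_uM for r in res if r.metabolite == name)
        assert get(res_b) > get(res_a)

    def test_high_interference_flag_on_heavy_overlap(self, axis):
        # an unknown whose off-reporter component sits one linewidth from the
        # target contributes more than half the target's diagonal response
        a_comp = LorentzianComponent(1.5001, 100.0, 1.2)
        a = MetaboliteEntry(
            "a", "target", (a_comp,), 1.5001, 0.0006,
            compute_unit_response((a_comp,), (1.4995, 1.5007), 600.0),
        )
        b_comps = (
            LorentzianComponent(1.5009, 90.0, 1.2),
            LorentzianComponent(1.6001, 100.0, 1.2),
        )
        b = MetaboliteEntry(
            "b", "interferent", b_comps, 1.6001, 0.003,
            compute_unit_response(b_comps, (1.5971, 1.6031), 600.0),
        )
        lib = _library(a, b)
        spec = aq.render_mixture(lib, axis, {"a": 1.0, "b": 1.0, "DSS": 0.29})
        res = aq.extended_aqua(spec, lib, correct_baseline=False)
        assert len(res) == 1
        assert "high_interference" in res[0].flags
        assert res[0].concentration_uM == pytest.approx(1000.0, rel=1e-6)

    def test_below_loq_flag_for_trace_concentration(self, axis):
        lib = aq.make_synthetic_library(n_targets=2, n_interferents=0, seed=8,
                                        overlap_level="low")
        rng = np.random.default_rng(3)
        trace, bulk = lib.targets[0].name, lib.targets[1].name
        conc = {trace: 0.00005, bulk: 1.0, "DSS": 0.29}
        spec = aq.render_mixture(lib, axis, conc)
        noisy = spec.with_intensities(
            spec.intensities + rng.normal(0, 1.0, axis.n_bins)
        )
        res = aq.extended_aqua(noisy, lib, correct_baseline=False)
        flags = {r.metabolite: r.flags for r in res}
        assert "below_loq" in flags[trace]
        assert "below_loq" not in flags[bulk]

    def test_stage_failures_name_the_stage(self, axis, panel):
        bad = aq.Spectrum(axis, np.full(axis.n_bins, -1.0))
        with pytest.raises(RuntimeError, match="stage"):
            aq.extended_aqua(bad, panel, correct_baseline=False)
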
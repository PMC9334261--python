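"""Actuator force balance: equilibria, calibration, benchmarks, helpers."""

from dataclasses import replace

import numpy as np
import pytest

from nanowinch import (
    ActuatorModel,
    GeometryMap,
    HairpinBenchmark,
    PolymerSpec,
    ProteinSpring,
    ThermalState,
    calibrate_geometry,
    default_autonomous_model,
    default_remote_model,
    effective_distance,
    force_vs_kprotein,
    hairpin_force,
    hairpin_open_probability,
    membrane_indentation,
    positioning_sd,
    predict_anticipated_extension,
    solve_equilibrium,
    total_potential,
)
from nanowinch.actuator import DEFAULT_CALIBRATION_TARGETS


def symmetric_model(k_protein=0.0, span=40.0):
    spec = PolymerSpec.ssdna(97)
    return ActuatorModel(top_spec=spec, bottom_spec=spec,
                         geometry=GeometryMap(span_D=span),
                         protein=ProteinSpring(k=k_protein))


class TestPotentialAndEquilibrium:
    def test_symmetric_model_minimum_at_half_span(self):
        m = symmetric_model()
        res = solve_equilibrium(m)
        assert res.x_eq == pytest.approx(m.geometry.span_D / 2, abs=1e-9)
        assert res.converged

    def test_gradient_vanishes_at_minimizer(self):
        m = symmetric_model(k_protein=0.5)
        res = solve_equilibrium(m)
        h = 1e-4
        fd = (total_potential(m, res.x_eq + h) - total_potential(m, res.x_eq - h)) / (2 * h)
        assert abs(fd) < 1e-6

    def test_stiff_spring_limit_pins_piston_at_rest(self):
        rest = 12.0
        m = replace(symmetric_model(), protein=ProteinSpring(k=1e5, rest_position=rest))
        res = solve_equilibrium(m)
        assert res.x_eq == pytest.approx(rest, abs=1e-3)

    def test_zero_stiffness_gives_zero_force(self):
        res = solve_equilibrium(default_autonomous_model(k_protein=0.0))
        assert res.force_on_protein == 0.0
        assert res.converged

    def test_out_of_range_coordinate_rejected(self):
        m = symmetric_model()
        with pytest.raises(ValueError, match="admissible"):
            total_potential(m, -5.0)

    def test_residual_below_tolerance_on_solved_cases(self):
        for k in (0.0, 0.1, 1.0, 20.0):
            res = solve_equilibrium(default_autonomous_model(k_protein=k))
            assert res.converged and res.residual < 1e-6


class TestPublishedForceSpan:
    """The calibrated 97-nt device delivers 1.6 pN (soft target) to 30 pN (stiff)."""

    def test_soft_end(self):
        res = solve_equilibrium(default_autonomous_model(k_protein=0.1))
        assert res.force_on_protein == pytest.approx(1.6, abs=0.3)

    def test_stiff_end(self):
        res = solve_equilibrium(default_autonomous_model(k_protein=20.0))
        assert res.force_on_protein == pytest.approx(30.0, abs=5.0)

    def test_force_and_xeq_monotone_over_stiffness_grid(self):
        grid = np.logspace(np.log10(0.01), np.log10(100), 50)
        table = force_vs_kprotein(default_autonomous_model(), grid)
        assert (np.diff(table["force_pN"]) >= -1e-9).all()
        assert (np.diff(table["x_eq_nm"]) <= 1e-9).all()
        assert table["converged"].all()

    def test_zero_k_row_matches_free_minimizer(self):
        table = force_vs_kprotein(default_autonomous_model(), [0.0, 0.1])
        free = solve_equilibrium(default_autonomous_model(k_protein=0.0))
        assert table["force_pN"].iloc[0] == 0.0
        assert table["x_eq_nm"].iloc[0] == pytest.approx(free.x_eq, abs=1e-9)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            force_vs_kprotein(default_autonomous_model(), [1.0, 0.1])


class TestCalibration:
    def test_self_consistency_on_default_targets(self):
        geo = calibrate_geometry()
        m = replace(default_autonomous_model(), geometry=geo)
        for k, f_target in DEFAULT_CALIBRATION_TARGETS:
            res = solve_equilibrium(replace(m, protein=ProteinSpring(k=k)))
            assert res.force_on_protein == pytest.approx(f_target, abs=0.1)

    def test_shipped_defaults_match_fresh_calibration(self):
        geo = calibrate_geometry()
        default_geo = default_autonomous_model().geometry
        assert geo.span_D == pytest.approx(default_geo.span_D, abs=1e-4)
        assert geo.top_offset == pytest.approx(default_geo.top_offset, abs=1e-4)

    def test_span_responds_monotonically_to_scaled_targets(self):
        spans = []
        for scale in (1.0, 1.5, 2.0):
            targets = tuple((k, f * scale) for k, f in DEFAULT_CALIBRATION_TARGETS)
            spans.append(calibrate_geometry(targets=targets).span_D)
        assert spans == sorted(spans) or spans == sorted(spans, reverse=True)
        assert len(set(round(s, 6) for s in spans)) == 3

    def test_single_target_rejected(self):
        with pytest.raises(ValueError, match="two"):
            calibrate_geometry(targets=((0.1, 1.6),))


class TestRemoteModes:
    @pytest.mark.parametrize("n_bp,expected", [(97, 33), (60, 20), (30, 10)])
    def test_anticipated_extension(self, n_bp, expected):
        assert predict_anticipated_extension(n_bp) == expected

    def test_anticipated_extension_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            predict_anticipated_extension(0)

    def test_rigid_mode_extends_to_contour_length(self):
        m = default_remote_model(mode="remote_ds_rigid")
        res = solve_equilibrium(m)
        assert res.x_eq == m.top_spec.contour_length - m.geometry.top_offset
        assert res.converged

    def test_effective_mode_balances_duplex_against_bottom_tethers(self):
        """The taut bottom tethers stretch the harmonic duplex term slightly past
        its minimum at Lc, by no more than their tension over k_eff."""
        from nanowinch.polymer import wlc_force
        m = default_remote_model(mode="remote_ds_effective")
        res = solve_equilibrium(m)
        assert res.converged
        rigid_x = m.top_spec.contour_length - m.geometry.top_offset
        e_bot = m.geometry.e_bot(res.x_eq)
        assert e_bot > 0  # bottom set is taut at this extension
        overshoot = res.x_eq - rigid_x
        bound = m.n_bottom * wlc_force(m.bottom_spec, float(e_bot)) / m.k_eff.k_eff_ds
        assert 0 < overshoot <= bound + 1e-9

    def test_effective_mode_with_slack_bottom_sits_at_contour_length(self):
        m = default_remote_model(mode="remote_ds_effective")
        m = replace(m, geometry=GeometryMap(span_D=m.top_spec.contour_length))
        res = solve_equilibrium(m)
        assert res.x_eq == pytest.approx(m.top_spec.contour_length, abs=1e-9)

    def test_remote_mode_requires_double_stranded_top(self):
        with pytest.raises(ValueError, match="double"):
            ActuatorModel(top_spec=PolymerSpec.ssdna(97),
                          bottom_spec=PolymerSpec.ssdna(97),
                          geometry=GeometryMap(span_D=48.0),
                          mode="remote_ds_rigid")


class TestHairpinBenchmark:
    def test_worked_example_42pN(self):
        res = hairpin_force(8.0, 5.3)
        assert res.force_pN == pytest.approx(42.4, abs=1e-12)
        assert float(f"{res.force_pN:.2g}") == 42.0
        assert res.exceeds_f_half

    def test_zero_deformation(self):
        res = hairpin_force(8.0, 0.0)
        assert res.force_pN == 0.0 and not res.exceeds_f_half

    def test_single_stranded_stiffness_falls_short(self):
        res = hairpin_force(3.0, 5.3)
        assert res.force_pN == pytest.approx(15.9, abs=1e-12)
        assert not res.exceeds_f_half

    def test_open_probability_half_at_f_half(self):
        bench = HairpinBenchmark()
        assert hairpin_open_probability(bench, bench.f_half) == 0.5

    def test_open_probability_saturates_at_42pN(self):
        assert hairpin_open_probability(HairpinBenchmark(), 42.0) > 0.99

    def test_open_probability_monotone(self):
        bench = HairpinBenchmark()
        probs = [hairpin_open_probability(bench, f) for f in np.linspace(0, 60, 30)]
        assert np.all(np.diff(probs) >= 0)  # saturates at 1 in float
        assert probs[0] < 0.5 < probs[-1]
        near = [hairpin_open_probability(bench, f) for f in np.linspace(15, 25, 11)]
        assert np.all(np.diff(near) > 0)


class TestMembraneAndPositioning:
    def test_indentation_angstrom_per_pN(self):
        assert membrane_indentation(10.0) == pytest.approx(1.0)
        assert membrane_indentation(0.0) == 0.0

    def test_effective_distance(self):
        assert effective_distance(17.7, 5.0) == pytest.approx(17.2)
        assert effective_distance(0.5, 100.0) == 0.0

    def test_equipartition_sd(self, thermal):
        assert positioning_sd(1, 1.0) == pytest.approx(np.sqrt(thermal.kBT), abs=1e-9)
        assert positioning_sd(1, 1.0) == pytest.approx(2.02, abs=0.01)

    def test_sqrt_n_scaling(self):
        assert positioning_sd(4, 1.0) == pytest.approx(positioning_sd(1, 1.0) / 2)

    def test_six_parallel_ds_connectors(self, thermal):
        sd = positioning_sd(6, 8.0 / 6)
        assert sd == pytest.approx(np.sqrt(thermal.kBT / 8.0), abs=1e-12)
        assert sd == pytest.approx(0.71, abs=0.01)
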
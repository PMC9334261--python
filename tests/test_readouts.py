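"""Bead calibration, LRET plate reduction, and two-state trace idealization."""

import numpy as np
import pandas as pd
import pytest

from nanowinch import (
    CurrentTrace,
    count_from_mfi,
    fit_bead_calibration,
    gen_bead_table,
    gen_plate,
    gen_trace,
    lret_ratio,
    segment_trace,
)

SEED = 1234


class TestBeadCalibration:
    def test_exact_identity_line(self):
        beads = pd.DataFrame({"mfi": [1e2, 1e3, 1e4],
                              "molecules_per_bead": [1e2, 1e3, 1e4]})
        line = fit_bead_calibration(beads)
        assert line.slope == pytest.approx(1.0, abs=1e-12)
        assert line.intercept == pytest.approx(0.0, abs=1e-12)
        assert line.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_slope_recovered_within_3se_under_noise(self):
        beads, _, _ = gen_bead_table(slope=1.0, intercept=0.0, cv=0.05, seed=SEED)
        line = fit_bead_calibration(beads)
        assert abs(line.slope - 1.0) < 3 * line.slope_stderr

    def test_duplicate_population_rejected(self):
        beads = pd.DataFrame({"mfi": [1e3, 1e3], "molecules_per_bead": [1e3, 1e3]})
        with pytest.raises(ValueError, match="distinct"):
            fit_bead_calibration(beads)

    def test_identity_line_count(self):
        beads = pd.DataFrame({"mfi": [1e2, 1e3, 1e4],
                              "molecules_per_bead": [1e2, 1e3, 1e4]})
        line = fit_bead_calibration(beads)
        assert count_from_mfi(line, 1e4) == pytest.approx(1e4, rel=1e-9)

    def test_background_equal_to_sample_rejected(self):
        beads = pd.DataFrame({"mfi": [1e2, 1e4], "molecules_per_bead": [1e2, 1e4]})
        line = fit_bead_calibration(beads)
        with pytest.raises(ValueError, match="background"):
            count_from_mfi(line, 100.0, background_mfi=100.0)

    def test_pipeline_recovers_configured_per_cell_count(self):
        """Synthetic QIFIKIT run: 9,200 devices/cell recovered within 5% at cv 5%."""
        beads, cell_mfi, _ = gen_bead_table(cv=0.05, seed=SEED, true_count=9200.0)
        line = fit_bead_calibration(beads)
        counts = [count_from_mfi(line, m) for m in cell_mfi]
        assert np.mean(counts) == pytest.approx(9200.0, rel=0.05)

    def test_noise_free_round_trip_is_exact(self):
        beads, cell_mfi, _ = gen_bead_table(slope=0.9, intercept=0.3, cv=0.0,
                                            seed=SEED, true_count=9200.0)
        line = fit_bead_calibration(beads)
        for m in cell_mfi:
            assert count_from_mfi(line, m) == pytest.approx(9200.0, rel=1e-9)

    def test_bias_small_under_replicated_noise(self):
        """Calibration round-trip bias < 1% at cv 5% over 100 seeded replicates."""
        estimates = []
        for rep in range(100):
            beads, cell_mfi, _ = gen_bead_table(cv=0.05, seed=SEED + rep,
                                                true_count=9200.0)
            line = fit_bead_calibration(beads)
            estimates.append(np.mean([count_from_mfi(line, m) for m in cell_mfi]))
        assert abs(np.mean(estimates) / 9200.0 - 1.0) < 0.01


class TestLretRatio:
    def test_arithmetic_example(self):
        plate = pd.DataFrame({
            "condition": ["treated", "background"],
            "donor_620": [1.0, 1.0],
            "acceptor_665": [2.0, 1.0],
        })
        out = lret_ratio(plate, scale=1e4)
        assert out.loc[0, "response"] == pytest.approx(1e4)

    def test_condition_equal_to_background_gives_zero(self):
        plate = pd.DataFrame({
            "condition": ["treated", "background"],
            "donor_620": [3.0, 5.0],
            "acceptor_665": [6.0, 10.0],
        })
        assert lret_ratio(plate).loc[0, "response"] == pytest.approx(0.0)

    def test_zero_donor_rejected(self):
        plate = pd.DataFrame({
            "condition": ["treated", "background"],
            "donor_620": [0.0, 1.0],
            "acceptor_665": [1.0, 1.0],
        })
        with pytest.raises(ValueError, match="donor"):
            lret_ratio(plate)

    def test_common_factor_invariance(self):
        plate = gen_plate(seed=SEED)
        scaled = plate.copy()
        scaled[["donor_620", "acceptor_665"]] *= 37.5
        a, b = lret_ratio(plate), lret_ratio(scaled)
        assert a.loc[0, "response"] == pytest.approx(b.loc[0, "response"], rel=1e-12)

    def test_recovers_configured_response_within_2sd(self):
        """Synthetic plate at the active-device response 1.23e4, cv 10%, 3 wells."""
        plate = gen_plate(true_response=1.23e4, cv=0.10, wells_per_condition=3, seed=SEED)
        out = lret_ratio(plate)
        assert abs(out.loc[0, "response"] - 1.23e4) < 2 * out.loc[0, "sd"]

    def test_missing_background_rejected(self):
        plate = pd.DataFrame({"condition": ["treated"], "donor_620": [1.0],
                              "acceptor_665": [1.0]})
        with pytest.raises(ValueError, match="background"):
            lret_ratio(plate)


class TestTraceSegmentation:
    def test_noiseless_square_wave_exact(self):
        current = np.tile(np.concatenate([np.full(25, 4.0), np.full(25, 16.0)]), 4)
        trace = CurrentTrace(time=np.arange(current.size) / 1e3, current=current)
        seg = segment_trace(trace)
        assert seg.closed_mean == 4.0 and seg.open_mean == 16.0
        assert not seg.single_state
        assert seg.n_transitions == 7
        expected = np.tile(np.concatenate([np.zeros(25, int), np.ones(25, int)]), 4)
        np.testing.assert_array_equal(seg.states, expected)

    def test_constant_trace_single_state(self):
        trace = CurrentTrace(time=np.arange(200) / 1e3, current=np.full(200, 4.0))
        seg = segment_trace(trace)
        assert seg.single_state and seg.n_transitions == 0

    def test_open_state_mean_recovered_within_3se(self):
        """Reported channel statistics (open 16 +/- 4 pA) recovered from 60 s."""
        trace, _, _ = gen_trace(seed=SEED)
        seg = segment_trace(trace)
        n_open = int((seg.states == 1).sum())
        se = seg.open_sd / np.sqrt(n_open)
        assert abs(seg.open_mean - 16.0) < 3 * se
        assert seg.open_sd == pytest.approx(4.0, rel=0.1)

    def test_assignment_accuracy_at_3sigma_separation(self):
        """>= 99% of samples correctly assigned when levels sit 3 noise-sd apart."""
        trace, true_states, _ = gen_trace(noise_sd=4.0, duration_s=30.0, seed=SEED)
        seg = segment_trace(trace)
        assert (seg.states == true_states).mean() >= 0.99

    def test_short_trace_rejected(self):
        trace = CurrentTrace(time=np.arange(50) / 1e3, current=np.zeros(50))
        with pytest.raises(ValueError, match="short"):
            segment_trace(trace)

    def test_trace_csv_round_trip(self, tmp_path):
        trace, _, _ = gen_trace(duration_s=1.0, seed=SEED)
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        back = CurrentTrace.from_csv(path)
        np.testing.assert_allclose(back.current, trace.current, atol=1e-9)

    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            CurrentTrace(time=np.array([0.0, 0.1, 0.3]), current=np.zeros(3))
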
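"""Strain computation, cycle segmentation, dampening integrals."""
import numpy as np
import pytest

from cardionuc import coupling
from cardionuc.coupling import (CouplingPath, StrainTrace, analyze_trace,
                                compute_strain, coupling_path,
                                diastolic_dampening, integrated_nuclear_strain,
                                segment_cycles, summarize_group,
                                systolic_dampening)
from cardionuc.errors import InsufficientDataError, NoContractionDetected
from cardionuc.presets import trace_preset
from cardionuc.traces import ContractionTrace, generate_traces, waveform_events


def _trace(sl, nl=None, nw=None, fs=90.0, f=1.0):
    n = len(sl)
    nl = nl if nl is not None else np.full(n, 12.0)
    nw = nw if nw is not None else np.full(n, 5.0)
    return ContractionTrace(time=np.arange(n) / fs, sarcomere_length=np.asarray(sl),
                            nuclear_length=np.asarray(nl), nuclear_width=np.asarray(nw),
                            cell_id="c0", genotype_label="WT_rat", pacing_frequency=f)


class TestComputeStrain:
    def test_constant_length_zero_strain(self):
        s = compute_strain(_trace(np.full(90, 1.80)), "first_sample")
        assert np.allclose(s.sarcomere_strain, 0.0)

    def test_peak_compression_arithmetic(self):
        # 1.800 -> 1.5948 um is an 11.4% compression
        sl = np.full(90, 1.800)
        sl[40] = 1.5948
        s = compute_strain(_trace(sl), "first_sample")
        assert s.sarcomere_strain.min() == pytest.approx(-11.4, abs=1e-9)

    def test_linear_ramp_closed_form(self):
        sl = 1.8 * (1 - 0.001 * np.arange(90) / 90)
        s = compute_strain(_trace(sl), "first_sample")
        expected = 100 * (sl - sl[0]) / sl[0]
        assert np.max(np.abs(s.sarcomere_strain - expected)) < 1e-9

    def test_non_positive_baseline_rejected(self):
        with pytest.raises(ValueError):
            ContractionTrace(time=np.arange(3) / 90.0,
                             sarcomere_length=np.array([0.0, 1.8, 1.8]),
                             nuclear_length=np.full(3, 12.0),
                             nuclear_width=np.full(3, 5.0),
                             cell_id="c", genotype_label="WT_rat",
                             pacing_frequency=1.0)

    def test_strain_invariant_to_unit_rescaling(self, wt_rat_trace):
        t = wt_rat_trace
        scaled = ContractionTrace(
            time=t.time, sarcomere_length=t.sarcomere_length * 1e3,
            nuclear_length=t.nuclear_length * 1e3,
            nuclear_width=t.nuclear_width * 1e3, cell_id=t.cell_id,
            genotype_label=t.genotype_label, pacing_frequency=t.pacing_frequency)
        a = compute_strain(t)
        b = compute_strain(scaled)
        assert np.allclose(a.sarcomere_strain, b.sarcomere_strain)
        assert np.allclose(a.nuclear_length_strain, b.nuclear_length_strain)


class TestSegmentCycles:
    def test_phases_match_generator_events(self, wt_rat_trace):
        p = wt_rat_trace.params
        s = compute_strain(wt_rat_trace)
        phases = segment_cycles(s)
        ev = waveform_events(p)
        frame = 1.0 / p.sampling_rate
        assert abs(wt_rat_trace.time[phases.peak[0]] - ev["t_peak"]) <= frame
        # onset index is the first threshold crossing, shortly after t_onset
        assert wt_rat_trace.time[phases.onset[0]] >= ev["t_onset"] - frame
        assert wt_rat_trace.time[phases.onset[0]] <= ev["t_onset"] + 5 * frame

    def test_identical_cycles_have_equal_offsets(self):
        t = generate_traces(trace_preset("WT_rat", n_cycles=3), 1)[0]
        phases = segment_cycles(compute_strain(t))
        frames = 90
        onsets = phases.onset - frames * np.arange(3)
        peaks = phases.peak - frames * np.arange(3)
        assert np.ptp(onsets) <= 1
        assert np.ptp(peaks) <= 1

    def test_flat_trace_raises(self):
        s = compute_strain(_trace(np.full(90, 1.80)), "first_sample")
        with pytest.raises(NoContractionDetected):
            segment_cycles(s)


class TestDampening:
    def test_identity_path_zero_everywhere(self):
        eps = np.linspace(0, -11, 201)
        path = CouplingPath(eps_s=np.concatenate([eps, eps[::-1][1:]]),
                            eps_n=np.concatenate([eps, eps[::-1][1:]]),
                            peak_index=200)
        assert systolic_dampening(path) == 0.0
        assert diastolic_dampening(path) == 0.0

    def test_parabolic_limb_matches_fine_quadrature(self):
        """200-sample trapezoid vs 1e5-point brute-force oracle, < 0.1%."""
        peak = -10.0
        xs = np.linspace(0, peak, 200)
        path = CouplingPath(eps_s=xs, eps_n=xs ** 2 / abs(peak), peak_index=199)
        # oracle: same geometric integral on a 1e5-point grid
        xf = np.linspace(0, peak, 100_000)
        oracle = abs(np.trapezoid(xf ** 2 / abs(peak) - xf, xf))
        assert systolic_dampening(path) == pytest.approx(oracle, rel=1e-3)

    def test_relaxation_retracing_shifted_line_is_lossless(self):
        con = np.linspace(0, -10, 100)
        rel = np.linspace(-10, 0, 100)
        offset = 3.0
        path = CouplingPath(
            eps_s=np.concatenate([con, rel[1:]]),
            eps_n=np.concatenate([con, rel[1:] + offset]) ,
            peak_index=99)
        # relaxation limb lies exactly on the unit-slope line through its start
        path.eps_n[99:] = path.eps_s[99:] + offset
        assert diastolic_dampening(path, "shifted") == pytest.approx(0.0, abs=1e-12)

    def test_diastolic_hysteresis_grows_with_nuclear_lag(self):
        vals = []
        for tau in (0.06, 0.1, 0.15, 0.2, 0.25):
            p = trace_preset("WT_rat", n_cycles=1, nuclear_time_constant=tau,
                             nuclear_gain=0.8, target_peak_nuclear_strain=None)
            vals.append(analyze_trace(generate_traces(p, 1)[0]).diastolic_dampening)
        assert np.all(np.diff(vals) > 0)

    def test_linc_disruption_increases_systolic_dampening(self):
        ctrl = analyze_trace(generate_traces(trace_preset("AdV_empty", n_cycles=1), 1)[0])
        dn = analyze_trace(generate_traces(trace_preset("AdV_DNKASH", n_cycles=1), 1)[0])
        assert dn.systolic_dampening > ctrl.systolic_dampening

    def test_mt_disruption_increases_diastolic_dampening(self):
        ctrl = analyze_trace(generate_traces(trace_preset("DMSO", n_cycles=1), 1)[0])
        colch = analyze_trace(generate_traces(trace_preset("colch", n_cycles=1), 1)[0])
        assert colch.diastolic_dampening > ctrl.diastolic_dampening

    def test_short_limb_raises(self):
        path = CouplingPath(eps_s=np.array([0.0, -1.0, -2.0]),
                            eps_n=np.array([0.0, -1.0, -2.0]), peak_index=1)
        with pytest.raises(InsufficientDataError):
            systolic_dampening(path)

    def test_integrals_invariant_to_path_reparameterization(self):
        """Dampening depends only on path geometry, not sample spacing."""
        xs = np.linspace(0, -10, 400)
        curve = lambda x: x ** 2 / 10.0
        uniform = CouplingPath(eps_s=xs, eps_n=curve(xs), peak_index=399)
        u = np.linspace(0, 1, 400) ** 2          # strongly nonuniform spacing
        xs2 = -10 * u
        warped = CouplingPath(eps_s=xs2, eps_n=curve(xs2), peak_index=399)
        assert systolic_dampening(warped) == pytest.approx(
            systolic_dampening(uniform), rel=2e-3)


class TestIntegratedStrain:
    def test_zero_strain_zero_integral(self):
        s = StrainTrace(time=np.arange(90) / 90.0,
                        sarcomere_strain=np.zeros(90),
                        nuclear_length_strain=np.zeros(90),
                        nuclear_width_strain=np.zeros(90),
                        baselines={}, pacing_frequency=1.0)
        phases = coupling.CyclePhases(np.array([5]), np.array([20]), np.array([40]))
        assert integrated_nuclear_strain(s, phases) == 0.0

    def test_triangular_pulse_closed_form(self):
        """6% deep, 0.5 s wide triangle integrates to 1.5 %*s."""
        t = np.arange(0, 1.0, 1 / 1000)
        eps = np.zeros_like(t)
        rise = (t >= 0.2) & (t < 0.45)
        fall = (t >= 0.45) & (t < 0.7)
        eps[rise] = -6 * (t[rise] - 0.2) / 0.25
        eps[fall] = -6 * (0.7 - t[fall]) / 0.25
        s = StrainTrace(time=t, sarcomere_strain=eps, nuclear_length_strain=eps,
                        nuclear_width_strain=-eps, baselines={}, pacing_frequency=1.0)
        phases = coupling.CyclePhases(np.array([200]), np.array([450]), np.array([700]))
        assert integrated_nuclear_strain(s, phases) == pytest.approx(1.5, rel=1e-4)

    def test_quadrature_converges_with_sampling_rate(self):
        coarse = analyze_trace(generate_traces(
            trace_preset("WT_rat", n_cycles=1, sampling_rate=90.0), 1)[0])
        fine = analyze_trace(generate_traces(
            trace_preset("WT_rat", n_cycles=1, sampling_rate=180.0), 1)[0])
        for m in ("systolic_dampening", "diastolic_dampening",
                  "integrated_nuclear_strain"):
            assert getattr(fine, m) == pytest.approx(getattr(coarse, m), rel=5e-3)


class TestGroupSummary:
    def _result(self, cid, peak):
        return coupling.CouplingResult(
            cell_id=cid, genotype_label="WT_rat",
            peak_sarcomere_compression=peak, peak_nuclear_compression=peak / 2,
            peak_width_expansion=1.0, systolic_dampening=1.0,
            diastolic_dampening=1.0, integrated_nuclear_strain=1.0)

    def test_hand_arithmetic(self):
        out = summarize_group([self._result("a", 10.0), self._result("b", 12.0)])
        row = out.iloc[0]
        assert row["peak_sarcomere_compression_mean"] == pytest.approx(11.0)
        assert row["peak_sarcomere_compression_sem"] == pytest.approx(1.0)
        assert row["peak_sarcomere_compression_count"] == 2

    def test_identical_cells_zero_se(self):
        out = summarize_group([self._result("a", 10.0), self._result("b", 10.0)])
        assert out.iloc[0]["peak_sarcomere_compression_sem"] == 0.0

    def test_single_cell_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([self._result("a", 10.0)])

    def test_noisy_cohort_mean_near_noiseless_value(self):
        """Monte-Carlo: the noisy-cohort mean recovers the noiseless value.

        Integrated nuclear strain averages the per-frame noise out, so the
        cohort mean should sit within ~3 SE of the noiseless value (peak
        metrics are max statistics and carry a known positive noise bias).
        """
        p = trace_preset("WT_rat", n_cycles=2, noise_sd=0.01, seed=3)
        results = [analyze_trace(t) for t in generate_traces(p, 50)]
        out = summarize_group(results).iloc[0]
        noiseless = analyze_trace(
            generate_traces(trace_preset("WT_rat", n_cycles=2), 1)[0])
        mean = out["integrated_nuclear_strain_mean"]
        se = out["integrated_nuclear_strain_sem"]
        assert abs(mean - noiseless.integrated_nuclear_strain) < 3 * se + 0.02
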
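"""System identification: sections, spectra, coherence, model fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from visuoswarm._dsp import ctf_eval
from visuoswarm.sysid import (
    DELAY_LINEAR,
    DELAY_PURE,
    FrequencyResponse,
    IdentificationConfig,
    TransferFunctionModel,
    coherence,
    coherent_band,
    concatenate_sections,
    czt_response,
    empirical_response,
    fft_response,
    find_tracking_sections,
    fit_population_gaussian,
    fit_transfer_function,
    identify_tracking,
    select_best_model,
    tracking_error,
)
from visuoswarm.synthetic import (
    HONEYBEE_EXAMPLE,
    GroundTruthResponder,
    StimulusSpec,
    generate_stimulus,
    multisine_spec,
)
from visuoswarm.trajectory import Trajectory


# ---------------------------------------------------------------------------
# tracking sections
# ---------------------------------------------------------------------------

def _brute_force_sections(s, a, tol, min_len):
    """Independent oracle: test every (start, length) run exhaustively."""
    within = np.abs(s - a) < tol
    runs = []
    q = 0
    while q < len(within):
        if within[q]:
            g = 0
            while q + g < len(within) and within[q + g]:
                g += 1
            if g >= min_len:
                runs.append((q, g))
            q += g
        else:
            q += 1
    return runs


class TestSections:
    def test_perfect_tracking_gives_one_full_section(self):
        x = np.sin(np.linspace(0, 10, 100))
        stim = Trajectory(x, 0.02)
        secs = find_tracking_sections(stim, Trajectory(x.copy(), 0.02), 0.1)
        assert len(secs) == 1
        assert secs[0].start == 0 and secs[0].length == 100

    def test_single_window_matches_exhaustive_scan(self):
        s = np.zeros(100)
        a = np.full(100, 5.0)
        a[10:61] = 0.05  # indices 10..60 inside tolerance
        secs = find_tracking_sections(Trajectory(s, 0.02), Trajectory(a, 0.02), 0.1)
        assert [(sec.start, sec.length) for sec in secs] == [(10, 51)]
        assert _brute_force_sections(s, a, 0.1, 30) == [(10, 51)]

    def test_random_patterns_match_exhaustive_scan(self):
        g = np.random.default_rng(3)
        for _ in range(20):
            s = np.zeros(300)
            a = np.where(g.random(300) < 0.7, 0.05, 5.0)
            secs = find_tracking_sections(
                Trajectory(s, 0.02), Trajectory(a, 0.02), 0.1, min_len=10
            )
            assert [(x.start, x.length) for x in secs] == _brute_force_sections(
                s, a, 0.1, 10
            )

    def test_short_runs_are_dropped(self):
        s = np.zeros(100)
        a = np.full(100, 5.0)
        a[10:35] = 0.0  # 25 < 30 samples
        assert find_tracking_sections(Trajectory(s, 0.02), Trajectory(a, 0.02), 0.1) == []

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            find_tracking_sections(
                Trajectory(np.zeros(10), 0.02), Trajectory(np.zeros(11), 0.02), 0.1
            )

    def test_concatenation_lengths_and_mean_removal(self):
        x = np.arange(200, dtype=float)
        stim, animal = Trajectory(x, 0.02), Trajectory(x + 0.01, 0.02)
        secs = find_tracking_sections(stim, animal, 0.1)
        assert secs[0].length == 200
        sub = [
            type(secs[0])(stimulus=x[0:40] + 3.0, animal=x[0:40], start=0, dt=0.02),
            type(secs[0])(stimulus=x[50:100] - 7.0, animal=x[50:100], start=50, dt=0.02),
        ]
        d1, d2, dt = concatenate_sections(sub)
        assert len(d1) == len(d2) == 90
        assert abs(d1[:40].mean()) < 1e-9 and abs(d1[40:].mean()) < 1e-9

    def test_empty_concatenation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            concatenate_sections([])


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

class TestSpectra:
    def test_czt_on_full_circle_equals_fft(self):
        g = np.random.default_rng(0)
        x = g.normal(size=256)
        dt = 0.02
        ref = fft_response(x, dt)
        czt = czt_response(x, dt, 0.0, 0.5 / dt, n_points=129)
        np.testing.assert_allclose(czt.values, ref.values, rtol=1e-9, atol=1e-9)

    def test_pure_tone_peaks_at_its_frequency(self):
        dt = 0.02
        t = dt * np.arange(2048)
        x = np.sin(2 * np.pi * 0.5 * t)
        czt = czt_response(x, dt, 0.3, 0.7, n_points=401)
        assert czt.freqs[np.argmax(np.abs(czt.values))] == pytest.approx(0.5, abs=2e-3)

    def test_czt_resolves_close_tones_and_matches_naive_z_transform(self):
        dt = 0.02
        n = 2048  # FFT resolution 1/(n dt) ~ 0.024 Hz: cannot split 0.02 Hz
        t = dt * np.arange(n)
        x = np.sin(2 * np.pi * 0.50 * t) + np.sin(2 * np.pi * 0.52 * t)
        czt = czt_response(x, dt, 0.45, 0.57, n_points=241)
        # naive O(N*M) z-transform evaluation as the oracle
        naive = np.array(
            [np.sum(x * np.exp(-2j * np.pi * f * dt * np.arange(n)))
             for f in czt.freqs]
        )
        np.testing.assert_allclose(czt.values, naive, rtol=1e-8, atol=1e-6)
        mag = np.abs(czt.values)
        peaks = [
            i for i in range(1, len(mag) - 1)
            if mag[i] > mag[i - 1] and mag[i] > mag[i + 1]
            and mag[i] > 0.5 * mag.max()
        ]
        assert len(peaks) == 2

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist|band"):
            czt_response(np.zeros(64), 0.02, 0.0, 30.0)

    def test_empirical_response_masks_empty_input_bins(self):
        freqs = np.linspace(0.1, 1.0, 10)
        d1 = FrequencyResponse(freqs, np.ones(10))
        vals = np.ones(10, dtype=complex)
        d1.values[5] = 1e-12
        d2 = FrequencyResponse(freqs, vals)
        H = empirical_response(d1, d2, mask_rel=1e-6)
        assert len(H.freqs) == 9


class TestCoherence:
    def test_noiseless_linear_pair_has_unit_coherence_at_excited_bins(self):
        """A filtered copy of a periodic signal is fully coherent with it."""
        from scipy import signal as sig

        dt = 0.02
        nper = 512
        t = dt * np.arange(8 * nper)
        # integer cycles per segment: every segment sees identical content
        x = np.sin(2 * np.pi * 4 / (nper * dt) / 1.0 * t) + 0.5 * np.sin(
            2 * np.pi * 10 / (nper * dt) * t + 1.0
        )
        b, a = sig.butter(2, 0.2)
        zi = sig.lfilter_zi(b, a) * x[0]
        y, _ = sig.lfilter(b, a, x, zi=zi)
        coh = coherence(x, y, dt, window_len=nper, overlap=0.0)
        for f0 in (4 / (nper * dt), 10 / (nper * dt)):
            k = np.argmin(np.abs(coh.freqs - f0))
            assert coh.gamma2[k] == pytest.approx(1.0, abs=1e-6)

    def test_independent_noise_has_low_mean_coherence(self):
        g = np.random.default_rng(7)
        x, y = g.normal(size=4096), g.normal(size=4096)
        coh = coherence(x, y, 0.02, window_len=512)
        assert coh.gamma2.mean() < 0.2

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_coherence_bounded_for_arbitrary_pairs(self, seed):
        g = np.random.default_rng(seed)
        x = g.normal(size=1024)
        y = g.normal(size=1024) + g.uniform(-1, 1) * x
        coh = coherence(x, y, 0.02, window_len=256)
        assert np.all(coh.gamma2 >= 0.0) and np.all(coh.gamma2 <= 1.0)

    def test_band_limited_noise_splits_the_coherent_band(self):
        """Noise added only above the cut frequency leaves the low band
        coherent and destroys coherence above it."""
        from scipy import signal as sig

        g = np.random.default_rng(1)
        dt = 0.1
        x = g.normal(size=16384)
        noise = g.normal(size=16384) * 6.0
        b, a = sig.butter(4, 0.1 / (0.5 / dt), btype="high")
        y = x + sig.lfilter(b, a, noise)
        coh = coherence(x, y, dt, window_len=1024)
        lo = coh.gamma2[(coh.freqs > 0.02) & (coh.freqs < 0.07)]
        hi = coh.gamma2[(coh.freqs > 0.2) & (coh.freqs < 2.0)]
        assert lo.mean() > 0.7
        assert hi.mean() < 0.7

    def test_single_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            coherence(np.zeros(100), np.zeros(100), 0.02, window_len=100)

    def test_coherent_band_scan(self):
        freqs = np.linspace(0.0, 1.0, 11)
        ones = type("C", (), {})()
        from visuoswarm.sysid import CoherenceSpectrum

        full = CoherenceSpectrum(freqs, np.ones(11))
        lo, hi = coherent_band(full)
        assert (lo, hi) == (pytest.approx(0.1), pytest.approx(1.0))
        empty = CoherenceSpectrum(freqs, np.zeros(11))
        assert np.isnan(coherent_band(empty)[0])
        step = CoherenceSpectrum(freqs, np.where(freqs <= 0.3 + 1e-9, 0.9, 0.1))
        assert coherent_band(step)[1] == pytest.approx(0.3)


class TestTrackingError:
    def test_ideal_and_null_responses(self):
        freqs = np.linspace(0.1, 1.0, 5)
        assert np.all(tracking_error(FrequencyResponse(freqs, np.ones(5))) == 0.0)
        assert np.all(tracking_error(FrequencyResponse(freqs, np.zeros(5))) == 1.0)

    def test_small_delay_error_matches_complex_arithmetic(self):
        omega = 2 * np.pi * 0.1
        H = FrequencyResponse(np.array([0.1]), np.array([np.exp(-1j * omega * 0.021)]))
        expected = abs(np.exp(-1j * omega * 0.021) - 1.0)
        assert tracking_error(H)[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0132, abs=2e-4)


# ---------------------------------------------------------------------------
# transfer-function fitting
# ---------------------------------------------------------------------------

def _response_from(num, den, tau, freqs, structure=DELAY_PURE):
    omega = 2 * np.pi * freqs
    g = ctf_eval(num, den, omega)
    if structure == DELAY_PURE:
        g = g * np.exp(-1j * omega * tau)
    else:
        g = g / (1.0 + 1j * omega * tau)
    return FrequencyResponse(freqs, g, source="H")


EX_NUM = [9.204, -0.285]
EX_DEN = [8.098, 2.098, 1.0]


class TestTransferFunctionFit:
    def test_worked_example_recovered_exactly(self):
        freqs = np.linspace(0.1, 1.7, 8)
        H = _response_from(EX_NUM, EX_DEN, 0.021, freqs)
        candidates = fit_transfer_function(H)
        sel = select_best_model(candidates)
        assert sel.model.n_poles == 2 and sel.model.n_zeros == 1
        assert sel.model.delay_structure == DELAY_PURE
        assert sel.model.delay == pytest.approx(0.021, abs=1e-9)
        np.testing.assert_allclose(sel.model.num, EX_NUM, rtol=0.01)
        np.testing.assert_allclose(sel.model.den, EX_DEN, rtol=0.01)

    def test_unity_response_gives_zero_delay_and_perfect_fit(self):
        freqs = np.linspace(0.05, 1.5, 12)
        H = FrequencyResponse(freqs, np.ones(12, dtype=complex))
        candidates = fit_transfer_function(H)
        sel = select_best_model(candidates)
        assert sel.model.delay == pytest.approx(0.0, abs=1e-12)
        assert sel.report.fit_pct == pytest.approx(100.0, abs=1e-6)
        # the selected model reduces to unity gain across the band
        np.testing.assert_allclose(
            sel.model.freq_response(freqs), np.ones(12), atol=1e-6
        )

    @pytest.mark.parametrize(
        "num,den,tau",
        [
            ([9.204, -0.285], [8.098, 2.098, 1.0], 0.021),
            ([4.0, 1.5, 0.3], [6.0, 7.0, 4.5, 1.0], 0.050),
            ([3.0, 0.8], [4.0, 6.0, 3.5, 1.0], 0.035),
        ],
        ids=["2p1z", "3p2z", "3p1z"],
    )
    @pytest.mark.parametrize("seed", [0, 1])
    def test_noisy_recovery_of_structure_and_delay(self, num, den, tau, seed):
        """Ground-truth models observed through 20 dB time-domain measurement
        noise: the grid search recovers the pole/zero structure and the
        transport delay within +/-2 ms (line spectra average the noise down
        over the record)."""
        spec = multisine_spec(f_min=0.1, f_max=2.5, n_components=20,
                              duration=240.0)
        stim = generate_stimulus(spec)
        clean = GroundTruthResponder(num=num, den=den, tau=tau
                                     ).steady_state_response(spec)
        resp = GroundTruthResponder(
            num=num, den=den, tau=tau,
            noise_sd=0.1 * np.std(clean.values), seed=seed,
        )
        rep = identify_tracking(
            stim, resp.steady_state_response(spec),
            IdentificationConfig(tolerance=100.0,
                                 excited_freqs=spec.frequencies),
        )
        assert (rep.model.n_poles, rep.model.n_zeros) == (
            len(den) - 1, len(num) - 1
        )
        # within +/-2 ms inclusive (grid values carry float rounding)
        assert abs(rep.model.delay - tau) <= 0.002 + 1e-9

    def test_round_trip_over_randomized_ground_truths(self):
        """Noiseless data generated from random candidates in the search
        grid is recovered up to the delay-grid resolution."""
        g = np.random.default_rng(21)
        freqs = np.linspace(0.05, 2.0, 20)
        for trial in range(4):
            n_poles = int(g.integers(2, 5))
            n_zeros = int(g.integers(1, n_poles + 1))
            # random stable-ish coefficients, monic denominator
            num = g.uniform(0.5, 5.0, n_zeros + 1)
            den = np.concatenate([np.sort(g.uniform(1.0, 8.0, n_poles))[::-1], [1.0]])
            tau = float(g.integers(0, 101)) * 1e-3
            H = _response_from(num, den, tau, freqs)
            candidates = fit_transfer_function(
                H, structures=[(n_poles, n_zeros)], delay_structures=(DELAY_PURE,)
            )
            sel = select_best_model(candidates)
            assert sel.model.delay == pytest.approx(tau, abs=1e-3)
            np.testing.assert_allclose(
                sel.model.freq_response(freqs), H.values, rtol=1e-4, atol=1e-6
            )

    def test_perfect_fit_iff_zero_residual(self):
        freqs = np.linspace(0.1, 1.7, 10)
        H = _response_from(EX_NUM, EX_DEN, 0.021, freqs)
        candidates = fit_transfer_function(
            H, structures=[(2, 1)], delay_structures=(DELAY_PURE,)
        )
        model, report = max(candidates, key=lambda mr: mr[1].fit_pct)
        assert report.fit_pct == pytest.approx(100.0, abs=1e-6)
        assert report.objective == pytest.approx(0.0, abs=1e-6)

    def test_pure_and_linear_structures_agree_as_delay_vanishes(self):
        m1 = TransferFunctionModel(EX_NUM, EX_DEN, delay=0.0, delay_structure=DELAY_PURE)
        m2 = TransferFunctionModel(EX_NUM, EX_DEN, delay=0.0, delay_structure=DELAY_LINEAR)
        freqs = np.linspace(0.05, 2.0, 30)
        np.testing.assert_allclose(
            m1.freq_response(freqs), m2.freq_response(freqs), rtol=1e-12
        )

    def test_selection_prefers_higher_fit_then_parsimony(self):
        freqs = np.linspace(0.1, 1.7, 8)
        big = TransferFunctionModel([1.0, 0.1, 0.1, 0.1], [1.0, 1.0, 1.0, 1.0, 1.0])
        small = TransferFunctionModel([1.0], [1.0, 1.0])
        from visuoswarm.sysid import FitReport

        cands = [
            (big, FitReport(fit_pct=92.95, objective=0.1)),
            (small, FitReport(fit_pct=60.96, objective=0.5)),
        ]
        assert select_best_model(cands).model is big
        # near-tie: parsimony wins
        cands = [
            (big, FitReport(fit_pct=99.95, objective=0.1)),
            (small, FitReport(fit_pct=99.90, objective=0.1)),
        ]
        assert select_best_model(cands).model is small

    def test_criteria_disagreement_flag(self):
        from visuoswarm.sysid import FitReport

        a = TransferFunctionModel([1.0], [1.0, 1.0])
        b = TransferFunctionModel([2.0], [1.0, 1.0])
        cands = [
            (a, FitReport(fit_pct=95.0, objective=0.1, mse=0.5, fpe=0.5)),
            (b, FitReport(fit_pct=90.0, objective=0.2, mse=0.1, fpe=0.1)),
        ]
        sel = select_best_model(cands)
        assert sel.model is a and sel.criteria_disagree

    def test_too_few_points_rejected(self):
        freqs = np.linspace(0.1, 0.5, 4)
        H = FrequencyResponse(freqs, np.ones(4, dtype=complex))
        with pytest.raises(ValueError, match="points"):
            fit_transfer_function(H)


class TestPopulation:
    def test_degenerate_and_two_point_examples(self):
        pop = fit_population_gaussian(np.array([10.0, 10.0, 10.0]))
        assert (pop.mu_ms, pop.sigma_ms) == (10.0, 0.0)
        assert fit_population_gaussian(np.array([0.0, 44.0])).mu_ms == 22.0

    def test_recovers_sampling_distribution(self):
        from visuoswarm.synthetic import DelayPopulationSpec, sample_population_delays

        draws = sample_population_delays(DelayPopulationSpec(22, 40, 50, seed=2))
        pop = fit_population_gaussian(draws)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(pop.mu_ms - draws.mean()) < 1e-12
        counts, edges = pop.histogram(bin_width_ms=20.0)
        assert counts.sum() == 50


# ---------------------------------------------------------------------------
# end-to-end identification
# ---------------------------------------------------------------------------

class TestIdentifyPipeline:
    def test_full_pipeline_recovers_the_example_model(self, multisine, example_pair):
        stim, animal = example_pair
        rep = identify_tracking(
            stim, animal,
            IdentificationConfig(tolerance=20.0, excited_freqs=multisine.frequencies),
        )
        assert rep.delay_ms == pytest.approx(21.0, abs=1.0)
        assert rep.model.n_poles == 2 and rep.model.n_zeros == 1
        np.testing.assert_allclose(rep.model.num, EX_NUM, rtol=0.01)
        np.testing.assert_allclose(rep.model.den, EX_DEN, rtol=0.01)
        assert rep.czt_h is not None
        d = rep.to_dict()
        assert d["delay_ms"] == pytest.approx(21.0, abs=1.0)

    def test_intermittent_tracking_still_identifies_the_delay(self, multisine):
        """With non-tracking excursions between windows, section extraction
        plus concatenation still recover the transport delay."""
        stim = generate_stimulus(multisine)
        responder = GroundTruthResponder(
            num=HONEYBEE_EXAMPLE.num, den=HONEYBEE_EXAMPLE.den,
            tau=HONEYBEE_EXAMPLE.tau,
            windows=[(0.0, 25.0), (30.0, 60.0)], seed=4, wander_sd=30.0,
        )
        animal = responder._observe(HONEYBEE_EXAMPLE.steady_state_response(multisine))
        rep = identify_tracking(
            stim, animal,
            IdentificationConfig(tolerance=20.0, excited_freqs=multisine.frequencies),
        )
        assert len(rep.sections) == 2
        assert rep.delay_ms == pytest.approx(21.0, abs=2.0)
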
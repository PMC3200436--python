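"""Filters, rejection, SSP, re-referencing, and robust averaging."""

import numpy as np
import pytest
from scipy import signal

from axiomerf.design import build_session_design
from axiomerf.layout import meg_cap_layout
from axiomerf.preprocess import (
    ProjectionOperator,
    apply_projection,
    bandpass,
    baseline_correct,
    fit_blink_projector,
    reject_amplitude,
    rereference,
    resample,
    robust_average,
)
from axiomerf.simulate import NoiseSpec, inject_artifacts, simulate_evoked

from conftest import make_epochs


def _sine_epochs(freq, fs=200.0, n_ch=4, amp=1.0, n=4000):
    # long stretches so the 0.5 Hz high-pass transient dies out well
    # before the analyzed segment
    t = (-160.0 + np.arange(n) * 1000.0 / fs) / 1000.0
    wave = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(wave, (2, n_ch, 1))
    return make_epochs(data, fs=fs)


class TestBandpass:
    def test_zero_input_zero_output(self):
        ep = make_epochs(np.zeros((2, 3, 100)))
        out = bandpass(ep, 0.5, 30.0)
        assert np.allclose(out.data, 0.0)

    def test_passband_sine_preserved(self):
        ep = _sine_epochs(10.0, fs=200.0)
        out = bandpass(ep, 0.5, 30.0)
        mid = slice(1000, -1000)  # trim filter edges
        amp = np.abs(out.data[0, 0, mid]).max()
        # analytic magnitude response of the 4th-order zero-phase filter
        w, h = signal.sosfreqz(
            signal.butter(4, [0.5, 30], btype="bandpass", fs=200, output="sos"),
            worN=[10.0],
            fs=200.0,
        )
        expected = np.abs(h[0]) ** 2  # forward-backward squares the response
        assert amp == pytest.approx(expected, rel=0.05)

    def test_stopband_sine_suppressed(self):
        ep = _sine_epochs(50.0, fs=200.0)
        out = bandpass(ep, 0.5, 30.0)
        mid = slice(1000, -1000)
        assert np.abs(out.data[0, 0, mid]).max() < 0.1

    def test_linearity(self, rng):
        x = rng.standard_normal((2, 3, 120))
        y = rng.standard_normal((2, 3, 120))
        a, b = 2.5, -1.3
        fx = bandpass(make_epochs(x), 1, 40).data
        fy = bandpass(make_epochs(y), 1, 40).data
        fxy = bandpass(make_epochs(a * x + b * y), 1, 40).data
        assert np.allclose(fxy, a * fx + b * fy, atol=1e-10)

    def test_bad_band_edges_rejected(self):
        ep = make_epochs(np.zeros((2, 3, 100)))
        for low, high in ((30.0, 0.5), (0.5, 150.0), (-1.0, 30.0)):
            with pytest.raises(ValueError):
                bandpass(ep, low, high)


class TestResample:
    def test_constant_preserved(self):
        ep = make_epochs(np.full((2, 3, 516), 7.0), fs=600.0)
        out = resample(ep, 200.0)
        assert out.fs == 200.0
        assert np.allclose(out.data[..., 15:-15], 7.0, rtol=1e-4)

    def test_sine_reproduced_at_new_rate(self):
        fs = 600.0
        n = 516
        t = (-160.0 + np.arange(n) * 1000.0 / fs) / 1000.0
        wave = np.sin(2 * np.pi * 5.0 * t)
        ep = make_epochs(np.tile(wave, (2, 2, 1)), fs=fs)
        out = resample(ep, 200.0)
        t_new = out.time_ms / 1000.0
        expected = np.sin(2 * np.pi * 5.0 * t_new)
        err = np.abs(out.data[0, 0, 8:-8] - expected[8:-8]).max()
        assert err < 0.02

    def test_upsampling_rejected(self):
        ep = make_epochs(np.zeros((2, 3, 100)), fs=200.0)
        with pytest.raises(ValueError):
            resample(ep, 200.0)
        with pytest.raises(ValueError):
            resample(ep, 400.0)

    def test_metadata_unchanged(self, tiny_design):
        layout = meg_cap_layout(8)
        noise = NoiseSpec(white_sd=1.0, pink_sd=0, blink_rate=0, jump_rate=0,
                          blink_amplitude=0, jump_amplitude=0, seed=1)
        ep = simulate_evoked(tiny_design, [], layout, noise, fs=600.0)
        out = resample(ep, 200.0)
        assert out.n_trials == ep.n_trials
        assert out.trials.equals(ep.trials)


class TestBaseline:
    def test_baseline_mean_zero(self, rng):
        ep = make_epochs(rng.standard_normal((3, 4, 172)) + 5.0)
        out = baseline_correct(ep)
        pre = out.time_ms < 0
        assert np.allclose(out.data[..., pre].mean(axis=-1), 0.0, atol=1e-12)

    def test_constant_offset_invariance(self, rng):
        x = rng.standard_normal((3, 4, 172))
        a = baseline_correct(make_epochs(x)).data
        b = baseline_correct(make_epochs(x + 3.7)).data
        assert np.allclose(a, b, atol=1e-12)

    def test_plateau_arithmetic(self):
        x = np.zeros((1, 1, 172))
        t = -160.0 + np.arange(172) * 5.0
        x[..., t < 0] = 3.0
        x[..., t >= 0] = 5.0
        out = baseline_correct(make_epochs(x))
        assert np.allclose(out.data[..., t >= 0], 2.0)

    def test_no_prestim_samples_error(self):
        ep = make_epochs(np.zeros((1, 1, 50)), tmin_ms=0.0)
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(ep)


class TestReject:
    def test_no_rejections_below_threshold(self, rng):
        ep = make_epochs(rng.standard_normal((5, 3, 100)))
        out, mask = reject_amplitude(ep, 1e3)
        assert mask.sum() == 0 and out.n_trials == 5

    def test_spiked_trial_rejected(self, rng):
        x = rng.standard_normal((5, 3, 100))
        x[2, 1, 50] = 10.0
        out, mask = reject_amplitude(make_epochs(x), 5.0)
        assert list(np.flatnonzero(mask)) == [2]
        assert out.n_trials == 4
        assert list(out.trials["trial_id"]) == [0, 1, 3, 4]

    def test_injected_jump_fraction_recovered(self):
        layout = meg_cap_layout(16)
        trials = build_session_design({0.5: 200}, n_blocks=1, seed=3)
        noise = NoiseSpec(white_sd=0.01, pink_sd=0, blink_rate=0,
                          blink_amplitude=0, jump_rate=0.05, jump_amplitude=2.0,
                          seed=8)
        ep = simulate_evoked(trials, [], layout, noise, fs=200.0)
        ep = inject_artifacts(ep, noise)
        out, mask = reject_amplitude(ep, 1.0)
        assert mask.sum() == ep.trials["has_jump"].sum()
        assert np.array_equal(mask, ep.trials["has_jump"].to_numpy())

    def test_all_rejected_error(self):
        ep = make_epochs(np.full((3, 2, 50), 10.0))
        with pytest.raises(ValueError, match="threshold"):
            reject_amplitude(ep, 1.0)


class TestSSP:
    def _blinky_epochs(self, k_noise=0.0, seed=4, n_trials=40, blink_rate=0.5):
        layout = meg_cap_layout(24)
        trials = build_session_design({0.5: n_trials}, n_blocks=1, seed=seed)
        noise = NoiseSpec(white_sd=k_noise, pink_sd=0.0, blink_rate=blink_rate,
                          blink_amplitude=1.0, jump_rate=0, jump_amplitude=0,
                          seed=seed)
        ep = simulate_evoked(trials, [], layout, noise, fs=200.0)
        return inject_artifacts(ep, noise), layout

    def test_rank1_blink_recovered(self):
        from axiomerf.simulate import blink_pattern

        ep, layout = self._blinky_epochs(k_noise=1e-3)
        ch = layout.channel_ids[int(np.argmax(np.abs(blink_pattern(layout))))]
        op = fit_blink_projector(ep, ch, detection_threshold=3.0, k=1)
        pat = blink_pattern(layout)
        cos = abs(op.basis[:, 0] @ pat) / np.linalg.norm(pat)
        assert cos > 0.99

    def test_k0_is_identity(self, rng):
        ep = make_epochs(rng.standard_normal((4, 6, 100)))
        op = fit_blink_projector(ep, ep.layout.channel_ids[0], k=0)
        out = apply_projection(ep, op)
        assert np.array_equal(out.data, ep.data)

    def test_blink_free_data_errors(self, rng):
        ep = make_epochs(rng.standard_normal((4, 6, 200)) * 1e-3)
        with pytest.raises(ValueError, match="blink events"):
            fit_blink_projector(ep, ep.layout.channel_ids[0],
                                detection_threshold=10.0, k=1)

    def test_projection_geometry(self, rng):
        n_ch = 6
        b = np.zeros((n_ch, 1))
        b[0, 0] = 1.0
        layout = meg_cap_layout(n_ch)
        op = ProjectionOperator(b, layout.channel_ids)
        # data equal to the basis vector is zeroed
        x = np.tile(b[:, 0][None, :, None], (2, 1, 50))
        out = apply_projection(make_epochs(x, layout=layout), op)
        assert np.allclose(out.data, 0.0, atol=1e-12)
        # data orthogonal to the basis is unchanged
        y = rng.standard_normal((2, n_ch, 50))
        y[:, 0, :] = 0.0
        out = apply_projection(make_epochs(y, layout=layout), op)
        assert np.allclose(out.data, y, atol=1e-12)

    def test_projection_idempotent(self, rng):
        ep, layout = self._blinky_epochs(k_noise=0.01)
        ch = layout.channel_ids[0]
        u, _ = np.linalg.qr(rng.standard_normal((layout.n_channels, 3)))
        op = ProjectionOperator(u[:, :3], layout.channel_ids)
        once = apply_projection(ep, op)
        twice = apply_projection(once, op)
        assert np.allclose(once.data, twice.data, atol=1e-6)

    def test_blink_removed_signal_kept(self):
        """SSP nulls the blink subspace while preserving an orthogonal evoked
        signal."""
        from axiomerf.simulate import ComponentSpec, blink_pattern, valence_gain

        layout = meg_cap_layout(24)
        pat = blink_pattern(layout)
        # evoked topography orthogonalized against the blink pattern
        topo = np.linspace(-1, 1, 24)
        topo -= (topo @ pat) / (pat @ pat) * pat
        comp = ComponentSpec("sig", 300.0, 40.0, topo, valence_gain(1.0))
        trials = build_session_design({0.5: 40}, n_blocks=1, seed=5)
        # blinks dwarf the evoked response, as in real recordings
        noise = NoiseSpec(white_sd=1e-3, pink_sd=0, blink_rate=0.5,
                          blink_amplitude=10.0, jump_rate=0, jump_amplitude=0,
                          seed=6)
        pre = simulate_evoked(trials, [comp], layout, noise, fs=200.0)
        ep = inject_artifacts(pre, noise)
        ch = layout.channel_ids[int(np.argmax(np.abs(pat)))]
        op = fit_blink_projector(ep, ch, detection_threshold=3.0, k=1)
        out = apply_projection(ep, op)
        blinky = ep.trials["has_blink"].to_numpy()
        # blink contribution = injected minus pre-artifact data
        blink_before = ep.data[blinky] - pre.data[blinky]
        blink_after = out.data[blinky] - apply_projection(pre, op).data[blinky]
        rms = lambda a: np.sqrt(np.mean(np.asarray(a, dtype=float) ** 2))
        assert rms(blink_after) < 0.1 * rms(blink_before)
        # the evoked signal itself is barely touched
        evoked_before = pre.data[~blinky].mean(axis=0)
        evoked_after = apply_projection(pre, op).data[~blinky].mean(axis=0)
        assert rms(evoked_after - evoked_before) < 0.1 * rms(evoked_before)


class TestRereference:
    def test_zero_refs_unchanged(self, rng):
        x = rng.standard_normal((2, 5, 60))
        x[:, :2, :] = 0.0
        ep = make_epochs(x)
        ids = ep.layout.channel_ids
        out = rereference(ep, [ids[0], ids[1]])
        assert np.allclose(out.data, x)

    def test_ref_mean_zero_after(self, rng):
        ep = make_epochs(rng.standard_normal((2, 5, 60)))
        ids = ep.layout.channel_ids
        out = rereference(ep, [ids[3], ids[4]])
        assert np.allclose(out.data[:, 3:5, :].mean(axis=1), 0.0, atol=1e-12)

    def test_constant_ref_shifts_all(self, rng):
        x = rng.standard_normal((1, 4, 30))
        x[:, 2, :] = 1.0
        ep = make_epochs(x)
        out = rereference(ep, [ep.layout.channel_ids[2]])
        assert np.allclose(out.data, x - 1.0)

    def test_missing_ref_errors(self, rng):
        ep = make_epochs(rng.standard_normal((1, 4, 30)))
        with pytest.raises(KeyError):
            rereference(ep, ["NOPE"])


class TestRobustAverage:
    def test_identical_trials(self):
        x = np.tile(np.linspace(0, 1, 50), (6, 3, 1))
        res = robust_average(x)
        assert np.allclose(res.average, x[0], atol=1e-12)
        assert np.allclose(res.weights, 1.0)

    def test_matches_mean_without_outliers(self, rng):
        # strictly outlier-free noise (truncated at 3 SD): no sample is
        # down-weighted, so the robust and arithmetic means agree
        x = np.clip(rng.standard_normal((50, 4, 80)), -3, 3)
        res = robust_average(x)
        sem = x.std(axis=0, ddof=1) / np.sqrt(50)
        assert (np.abs(res.average - x.mean(axis=0)) < 0.1 * sem).all()
        # on unbounded Gaussian noise occasional extreme draws are trimmed,
        # but the overwhelming majority of samples still match the mean
        y = rng.standard_normal((50, 4, 80))
        res_y = robust_average(y)
        sem_y = y.std(axis=0, ddof=1) / np.sqrt(50)
        frac = (np.abs(res_y.average - y.mean(axis=0)) < 0.1 * sem_y).mean()
        assert frac > 0.99

    def test_burst_downweighted(self, rng):
        x = rng.standard_normal((30, 2, 100))
        x[7, 0, 40:50] += 20.0  # 20-SD burst on 10 samples
        res = robust_average(x)
        assert (res.weights[7, 0, 40:50] < 0.2).all()
        clean = np.r_[res.weights[7, 0, :40], res.weights[7, 0, 50:]]
        assert (clean > 0.8).mean() > 0.9

    def test_unit_weights_reproduce_mean_exactly(self, rng):
        x = rng.standard_normal((12, 3, 40))
        res = robust_average(x, weight_function="none")
        assert np.array_equal(res.average, x.mean(axis=0))
        assert np.allclose(res.weights, 1.0)

    def test_zero_mad_fallback(self):
        # identical trials except one outlier: MAD of residuals is 0 on
        # most samples yet the outlier must still be down-weighted
        x = np.zeros((8, 1, 10))
        x[3, 0, 5] = 100.0
        res = robust_average(x)
        assert res.weights[3, 0, 5] < 0.2
        assert abs(res.average[0, 5]) < 1.0
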
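"""Time-frequency pipeline: Morlet TFR oracle, theta extraction, generator."""

import numpy as np
import pandas as pd
import pytest

from wagerhgf.eeg import (
    EEGConfig,
    EpochedEEG,
    bandpass_filter,
    dB_baseline,
    extract_theta,
    morlet_tfr,
    morlet_wavelet,
    rereference_linked_mastoids,
    synthesize_epochs,
)

SRATE = 500.0


def make_epochs(data, labels=None, ch_names=("Fz", "FCz", "Cz")):
    n_tr = data.shape[1]
    if labels is None:
        labels = pd.DataFrame(
            {
                "choice_correct": np.ones(n_tr, int),
                "phase_nonsocial": ["stable"] * n_tr,
                "phase_social": ["stable"] * n_tr,
            }
        )
    return EpochedEEG(data, SRATE, -0.5, tuple(ch_names), labels)


def sinusoid_epochs(freq, amp=1.0, n_trials=3, n_ch=3, n_samp=1001, phase=0.0):
    t = -0.5 + np.arange(n_samp) / SRATE
    sig = amp * np.sin(2 * np.pi * freq * t + phase)
    return make_epochs(np.tile(sig, (n_ch, n_trials, 1)))


class TestMorletTFR:
    def test_peak_at_stimulus_frequency_and_quadratic_amplitude_scaling(self):
        tfr1 = morlet_tfr(sinusoid_epochs(6.0, amp=1.0), freqs=np.arange(2.0, 13.0))
        tfr2 = morlet_tfr(sinusoid_epochs(6.0, amp=2.0), freqs=np.arange(2.0, 13.0))
        mid = np.nanmean(tfr1.power[0, 0], axis=1)
        assert tfr1.freqs[np.nanargmax(mid)] == 6.0
        ratio = np.nanmean(tfr2.power[0, 0, 4]) / np.nanmean(tfr1.power[0, 0, 4])
        assert ratio == pytest.approx(4.0, rel=1e-6)

    def test_matches_direct_convolution_oracle(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((1, 1, 400))
        ep = make_epochs(data, labels=pd.DataFrame({
            "choice_correct": [1], "phase_nonsocial": ["stable"], "phase_social": ["stable"],
        }), ch_names=("Fz",))
        freqs = np.array([5.0, 9.0, 15.0])
        tfr = morlet_tfr(ep, freqs=freqs)
        x = data[0, 0]
        for i, f in enumerate(freqs):
            w = morlet_wavelet(f, SRATE)
            half = (len(w) - 1) // 2
            # brute-force 'same' convolution, sample by sample
            for n in range(half, 400 - half):
                acc = 0.0 + 0.0j
                for m in range(len(w)):
                    acc += x[n + half - m] * w[m]
                assert tfr.power[0, 0, i, n] == pytest.approx(
                    abs(acc) ** 2, rel=1e-6
                ), (f, n)
            assert np.all(np.isnan(tfr.power[0, 0, i, :half]))

    def test_too_long_wavelet_flags_band_invalid_not_exception(self):
        ep = sinusoid_epochs(6.0, n_samp=400)
        tfr = morlet_tfr(ep, freqs=np.array([1.0, 10.0]))
        assert np.all(np.isnan(tfr.power[:, :, 0, :]))  # 1 Hz wavelet > epoch
        assert not tfr.valid[0].any()
        assert tfr.valid[1].any()

    def test_white_noise_spectrum_flat_at_high_frequencies(self):
        rng = np.random.default_rng(1)
        ep = make_epochs(rng.standard_normal((1, 200, 1001)), labels=pd.DataFrame({
            "choice_correct": np.ones(200, int),
            "phase_nonsocial": ["stable"] * 200,
            "phase_social": ["stable"] * 200,
        }), ch_names=("Fz",))
        freqs = np.linspace(10, 40, 13)
        tfr = morlet_tfr(ep, freqs=freqs)
        band_means = np.array([
            np.nanmean(tfr.power[0, :, i, :]) for i in range(len(freqs))
        ])
        cv = band_means.std() / band_means.mean()
        assert cv < 0.2

    def test_time_shift_equivariance_away_from_edges(self):
        shift = 50  # samples
        a = sinusoid_epochs(8.0)
        t = -0.5 + np.arange(1001) / SRATE
        burst = np.exp(-((t - 0.2) ** 2) / 0.01) * np.sin(2 * np.pi * 8 * t)
        data = np.tile(burst, (1, 1, 1))
        shifted = np.roll(data, shift, axis=-1)
        tfr_a = morlet_tfr(make_epochs(data, labels=pd.DataFrame({
            "choice_correct": [1], "phase_nonsocial": ["stable"], "phase_social": ["stable"]}),
            ch_names=("Fz",)), freqs=np.array([8.0]))
        tfr_b = morlet_tfr(make_epochs(shifted, labels=pd.DataFrame({
            "choice_correct": [1], "phase_nonsocial": ["stable"], "phase_social": ["stable"]}),
            ch_names=("Fz",)), freqs=np.array([8.0]))
        pa = tfr_a.power[0, 0, 0]
        pb = tfr_b.power[0, 0, 0]
        core = slice(200, 700)
        # absolute tolerance scaled to the peak: near-zero burst tails make
        # relative comparisons meaningless
        np.testing.assert_allclose(
            pb[core.start + shift : core.stop + shift],
            pa[core],
            atol=1e-5 * np.nanmax(pa),
        )

    def test_band_power_invariant_to_epoch_count(self):
        p = []
        for n_trials in (2, 10):
            ep = sinusoid_epochs(6.0, n_trials=n_trials)
            tfr = morlet_tfr(ep, freqs=np.array([6.0]))
            lab = ep.labels
            out = extract_theta(tfr, lab, band=(5.9, 6.1))
            p.append(out.loc["all", "midfrontal"])
        assert p[1] == pytest.approx(p[0], rel=0.01)


class TestExtractTheta:
    def test_planted_burst_confined_to_window_dominates_baseline(self):
        rng = np.random.default_rng(2)
        t = -0.5 + np.arange(1001) / SRATE
        wmask = (t >= 0.1) & (t <= 0.4)
        data = rng.standard_normal((3, 40, 1001)) * 0.5
        burst = np.zeros(1001)
        burst[wmask] = np.hanning(wmask.sum()) * np.sin(2 * np.pi * 6 * t[wmask]) * 5.0
        data += burst
        ep = make_epochs(data)
        tfr = morlet_tfr(ep, freqs=np.arange(4.0, 9.0))
        in_window = extract_theta(tfr, ep.labels, window=(0.1, 0.4))
        pre = extract_theta(tfr, ep.labels, window=(0.7, 1.0))
        assert in_window.loc["all", "midfrontal"] > 5 * pre.loc["all", "midfrontal"]

    def test_permuted_labels_null_condition_difference(self):
        rng = np.random.default_rng(3)
        n_tr = 400
        data = rng.standard_normal((3, n_tr, 1001))
        labels = pd.DataFrame({
            "choice_correct": rng.integers(0, 2, n_tr),
            "phase_nonsocial": rng.choice(["stable", "volatile"], n_tr),
            "phase_social": rng.choice(["stable", "volatile"], n_tr),
        })
        ep = make_epochs(data, labels)
        tfr = morlet_tfr(ep, freqs=np.arange(4.0, 9.0))
        out = extract_theta(tfr, labels)
        rel_diff = abs(out.loc["correct", "midfrontal"] - out.loc["incorrect", "midfrontal"])
        assert rel_diff / out.loc["all", "midfrontal"] < 0.05

    def test_single_electrode_equals_its_column(self):
        ep = sinusoid_epochs(6.0)
        tfr = morlet_tfr(ep, freqs=np.arange(4.0, 9.0))
        full = extract_theta(tfr, ep.labels)
        only_fz = extract_theta(tfr, ep.labels, electrodes=("Fz",))
        assert only_fz.loc["all", "Fz"] == pytest.approx(full.loc["all", "Fz"])
        assert only_fz.loc["all", "mean"] == pytest.approx(full.loc["all", "Fz"])

    def test_band_not_valid_in_window_raises(self):
        ep = sinusoid_epochs(6.0, n_samp=500)  # 1 s epoch
        tfr = morlet_tfr(ep, freqs=np.array([2.0]))  # wide wavelet
        with pytest.raises(ValueError, match="valid"):
            extract_theta(tfr, ep.labels, band=(1.5, 2.5))


class TestSyntheticGenerator:
    def _labels(self, n, rng):
        return pd.DataFrame({
            "choice_correct": rng.integers(0, 2, n),
            "phase_nonsocial": rng.choice(["stable", "volatile"], n),
            "phase_social": rng.choice(["stable", "volatile"], n),
        })

    def test_seed_determinism(self):
        cfg = EEGConfig()
        labels = self._labels(20, np.random.default_rng(0))
        a = synthesize_epochs(cfg, labels, 42)
        b = synthesize_epochs(cfg, labels, 42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_burst_amplitude_leaves_pure_background(self):
        labels = self._labels(60, np.random.default_rng(1))
        quiet = synthesize_epochs(EEGConfig(burst_amp=0.0), labels, 5)
        tfr = morlet_tfr(quiet, freqs=np.arange(4.0, 9.0))
        inw = extract_theta(tfr, labels, window=(0.1, 0.4))
        pre = extract_theta(tfr, labels, window=(0.6, 0.9))
        ratio = inw.loc["all", "midfrontal"] / pre.loc["all", "midfrontal"]
        assert 0.8 < ratio < 1.25

    def test_incorrect_gain_detected_in_seeded_cohorts(self):
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = self._labels(160, rng)
            ep = synthesize_epochs(EEGConfig(incorrect_gain=2.0), labels, 100 + seed)
            tfr = morlet_tfr(ep, freqs=np.arange(4.0, 9.0))
            out = extract_theta(tfr, labels)
            if out.loc["incorrect", "midfrontal"] > out.loc["correct", "midfrontal"]:
                detected += 1
        assert detected >= 19

    def test_topography_maximal_at_fcz(self):
        rng = np.random.default_rng(4)
        labels = self._labels(80, rng)
        ep = synthesize_epochs(EEGConfig(ch_names=("Fz", "FCz", "Cz", "Pz", "Oz")), labels, 9)
        tfr = morlet_tfr(ep, freqs=np.arange(4.0, 9.0))
        out = extract_theta(tfr, labels, electrodes=("Fz", "FCz", "Cz", "Pz", "Oz"))
        row = out.loc["all", ["Fz", "FCz", "Cz", "Pz", "Oz"]]
        assert row.idxmax() == "FCz"
        assert row["Oz"] < row["FCz"]


class TestPreprocessing:
    def test_bandpass_attenuates_45hz_probe_by_20db_vs_10hz(self):
        t = np.arange(0, 20, 1 / SRATE)
        x10 = np.sin(2 * np.pi * 10 * t)
        x45 = np.sin(2 * np.pi * 45 * t)
        f10 = bandpass_filter(x10, SRATE)
        f45 = bandpass_filter(x45, SRATE)
        core = slice(2000, -2000)
        gain10 = np.sqrt(np.mean(f10[core] ** 2)) / np.sqrt(np.mean(x10[core] ** 2))
        gain45 = np.sqrt(np.mean(f45[core] ** 2)) / np.sqrt(np.mean(x45[core] ** 2))
        assert 20 * np.log10(gain10 / gain45) >= 20.0

    def test_linked_mastoid_rereference_zeroes_common_signal(self):
        rng = np.random.default_rng(5)
        common = rng.standard_normal(500)
        data = np.stack([common + 1.0, common - 1.0, common + 0.5])
        out = rereference_linked_mastoids(data, ("M1", "M2", "Cz"))
        np.testing.assert_allclose(out[2], 0.5 * np.ones(500), atol=1e-12)

    def test_db_baseline_transform_runs(self):
        ep = sinusoid_epochs(6.0)
        tfr = morlet_tfr(ep, freqs=np.arange(4.0, 9.0))
        db = dB_baseline(tfr)
        assert np.nanmax(np.abs(db.power)) < 100


def test_epoch_container_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    labels = pd.DataFrame({
        "choice_correct": rng.integers(0, 2, 10),
        "phase_nonsocial": ["stable"] * 10,
        "phase_social": ["volatile"] * 10,
    })
    ep = synthesize_epochs(EEGConfig(), labels, 3)
    path = tmp_path / "epochs.npz"
    ep.save(path)
    back = EpochedEEG.load(path)
    np.testing.assert_allclose(back.data, ep.data)
    assert back.ch_names == ep.ch_names
    assert back.srate == ep.srate
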
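import numpy as np
import pytest

from eegsel.features import (FEATURE_NAMES, FREQ_FEATURES, TIME_FEATURES,
                             TIMEFREQ_FEATURES, band_definition, extract,
                             freq_domain, time_domain, timefreq_domain)
from eegsel.recording import EpochedRecording

FS = 128.0


def _named(vec, names):
    return dict(zip(names, vec))


def _epoched(data):
    n_ep, n_ch, n = data.shape
    return EpochedRecording(epochs=data, w=n / FS, fs=FS,
                            channel_names=tuple(f"c{i}" for i in range(n_ch)))


class TestContract:
    def test_name_counts(self):
        assert len(TIME_FEATURES) == 17
        assert len(FREQ_FEATURES) == 17
        assert len(TIMEFREQ_FEATURES) == 20
        assert len(FEATURE_NAMES) == 54

    def test_32_channel_feature_budget(self, rng):
        ft = extract(_epoched(rng.standard_normal((2, 32, 256))))
        assert ft.values.shape == (2, 32, 54)
        assert ft.n_channels * ft.n_features == 1728

    def test_14_channel_feature_budget(self, rng):
        ft = extract(_epoched(rng.standard_normal((1, 14, 256))))
        assert ft.n_channels * ft.n_features == 756

    def test_no_nan_for_any_finite_input(self, rng):
        data = np.stack([
            np.zeros((3, 256)),                      # constant
            rng.standard_normal((3, 256)) * 1e-9,    # near-degenerate
            rng.standard_normal((3, 256)) * 1e6,     # huge
        ])
        ft = extract(_epoched(data))
        assert np.isfinite(ft.values).all()
        assert ft.flags[0].all()  # constant epochs flagged


class TestTimeDomain:
    def test_constant_signal(self):
        v = _named(time_domain(np.ones(256), FS), TIME_FEATURES)
        assert v["mean"] == 1.0
        assert v["var"] == 0.0 and v["ptp"] == 0.0
        assert v["zcross"] == 0.0 and v["lnlen"] == 0.0

    def test_unit_sine_symmetry(self):
        t = np.arange(256) / FS
        v = _named(time_domain(np.sin(2 * np.pi * 10 * t), FS), TIME_FEATURES)
        assert v["ptp"] == pytest.approx(2.0, abs=0.01)
        assert v["mean"] == pytest.approx(0.0, abs=0.01)

    def test_alternating_signal_counts(self):
        n = 200
        x = np.tile([1.0, -1.0], n // 2)
        v = _named(time_domain(x, FS), TIME_FEATURES)
        assert v["zcross"] == n - 1
        assert v["lnlen"] == 2 * (n - 1)


class TestFreqDomain:
    def test_white_noise_flat_slope(self, rng):
        x = rng.standard_normal(8192)
        v = _named(freq_domain(x, FS), FREQ_FEATURES)
        assert abs(v["spc_slp2"]) < 0.2

    def test_sine_spectral_edge(self):
        t = np.arange(512) / FS
        v = _named(freq_domain(np.sin(2 * np.pi * 10 * t), FS), FREQ_FEATURES)
        assert 9.0 <= v["spec_frq"] <= 11.0

    def test_alpha_sine_dominates_alpha_band(self):
        t = np.arange(256) / FS
        x = np.sin(2 * np.pi * 10 * t)
        v = _named(freq_domain(x, FS), FREQ_FEATURES)
        powfreqs = [v[f"powfreq{i}"] for i in range(1, 6)]
        assert np.argmax(powfreqs) == 2  # alpha is the 3rd band

    def test_bandpassed_eeg_like_noise_has_smallest_gamma_energy(self, rng):
        # 1/f background (EEG-like) band-limited to 0.5-40 Hz: the gamma
        # band (30-Nyquist) holds only roll-off and the top of the 1/f tail
        from scipy import signal as sps
        white = rng.standard_normal(8192)
        spec = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(8192, 1 / FS)
        spec[1:] = spec[1:] / np.sqrt(freqs[1:])
        spec[0] = 0
        x = np.fft.irfft(spec)
        sos = sps.butter(4, [0.5, 40.0], btype="bandpass", fs=FS, output="sos")
        xf = sps.sosfiltfilt(sos, x)
        v = _named(freq_domain(xf, FS), FREQ_FEATURES)
        energies = [v[f"enrg_bnd{i}"] for i in range(1, 6)]
        assert np.argmin(energies) == 4

    def test_gamma_band_ends_at_nyquist(self):
        bands = band_definition(FS)
        assert bands[-1][0] == "gamma"
        assert bands[-1][2] == FS / 2


class TestTimeFreqDomain:
    def test_tk_feature_count_formula(self):
        # (DWT levels + 1) * 2 = 14 TK features for a 6-level decomposition
        tk = [n for n in TIMEFREQ_FEATURES if n.startswith("tk")]
        assert len(tk) == (6 + 1) * 2 == 14

    def test_all_zero_epoch(self):
        v = _named(timefreq_domain(np.zeros(256), FS), TIMEFREQ_FEATURES)
        for i in range(1, 7):
            assert v[f"wvlet{i}"] == -12.0  # the configured log floor
        for i in range(1, 15):
            assert v[f"tk{i}"] == 0.0

    def test_white_noise_energy_concentrates_in_d1(self, rng):
        # the DWT is orthonormal, so white noise spreads equal energy per
        # coefficient; D1 covers the widest half-band and holds the largest
        # TOTAL detail energy
        import pywt
        x = rng.standard_normal(4096)
        coeffs = pywt.wavedec(x, "db4", mode="symmetric", level=6)
        details = coeffs[1:][::-1]  # D1 .. D6
        totals = [np.sum(d ** 2) for d in details]
        assert np.argmax(totals) == 0
        # cross-check the reported level-1 log mean-square against the DWT
        v = _named(timefreq_domain(x, FS), TIMEFREQ_FEATURES)
        assert v["wvlet1"] == pytest.approx(
            np.log10(np.mean(details[0] ** 2)), abs=1e-9)


SCALE_INVARIANT = ("zcross", "higuchi", "katz", "hurst", "spec_frq",
                   "spc_slp2", "decorr")


class TestScaleShiftBehavior:
    @pytest.fixture(scope="class")
    def base(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(256)
        both = np.concatenate([time_domain(x, FS), freq_domain(x, FS)])
        return x, _named(both, TIME_FEATURES + FREQ_FEATURES)

    @pytest.mark.parametrize("a", [0.1, 3.0, 100.0])
    def test_scaling(self, base, a):
        x, v0 = base
        scaled = np.concatenate([time_domain(a * x, FS), freq_domain(a * x, FS)])
        v1 = _named(scaled, TIME_FEATURES + FREQ_FEATURES)
        for name in SCALE_INVARIANT:
            assert v1[name] == pytest.approx(v0[name], rel=1e-6, abs=1e-9), name
        assert v1["ptp"] == pytest.approx(a * v0["ptp"], rel=1e-9)
        assert v1["lnlen"] == pytest.approx(a * v0["lnlen"], rel=1e-9)
        assert v1["std"] == pytest.approx(a * v0["std"], rel=1e-9)
        assert v1["var"] == pytest.approx(a * a * v0["var"], rel=1e-9)

    def test_shift_changes_only_amplitude_features(self, base):
        x, v0 = base
        v1 = _named(time_domain(x + 5.0, FS), TIME_FEATURES)
        assert v1["mean"] == pytest.approx(v0["mean"] + 5.0, rel=1e-9)
        assert v1["zcross"] == v0["zcross"]  # computed on the centered signal
        assert v1["var"] == pytest.approx(v0["var"], rel=1e-9)
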
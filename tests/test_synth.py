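import numpy as np
import pytest
from scipy import signal as sps

from eegsel.synth import BAND_EDGES, SynthConfig, generate_dataset


def welch_band_power(x, fs, lo, hi):
    f, p = sps.welch(x, fs=fs, nperseg=min(len(x), 512))
    m = (f >= lo) & (f < hi)
    return float(np.trapezoid(p[m], f[m]))


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SynthConfig(n_subjects=1, n_trials=2, fs_raw=128.0,
                          duration=10.0, seed=7)
        a, _ = generate_dataset(cfg)
        b, _ = generate_dataset(SynthConfig(n_subjects=1, n_trials=2,
                                            fs_raw=128.0, duration=10.0, seed=7))
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.samples, rb.samples)

    def test_different_seeds_differ(self):
        cfg = lambda s: SynthConfig(n_subjects=1, n_trials=1, fs_raw=128.0,
                                    duration=10.0, seed=s)
        a, _ = generate_dataset(cfg(1))
        b, _ = generate_dataset(cfg(2))
        assert not np.array_equal(a[0].samples, b[0].samples)


class TestPlantedEffect:
    def test_band_power_ratio_matches_effect_size(self):
        """Welch alpha power of a planted channel differs between classes by
        a ratio within 25% of the configured effect size."""
        cfg = SynthConfig(n_subjects=1, n_trials=50, fs_raw=128.0,
                          duration=12.0, informative_channels=("F3", "F4", "T7"),
                          informative_bands=("alpha",), effect_size=3.0,
                          line_noise_amp=0.0, blink_rate=0.0, seed=11)
        recs, truth = generate_dataset(cfg)
        i_f3 = recs[0].channel_names.index("F3")
        powers = {0: [], 1: []}
        for rec in recs:
            cls = truth.label(rec.subject_id, rec.trial_id, "valence")
            powers[cls].append(welch_band_power(rec.samples[i_f3], 128.0, 8, 12))
        ratio = np.mean(powers[1]) / np.mean(powers[0])
        assert abs(ratio - 3.0) / 3.0 < 0.25

    def test_no_effect_under_unit_effect_size(self):
        cfg = SynthConfig(n_subjects=1, n_trials=40, fs_raw=128.0,
                          duration=12.0, effect_size=1.0,
                          line_noise_amp=0.0, blink_rate=0.0, seed=12)
        recs, truth = generate_dataset(cfg)
        assert truth.planted_effect == {}
        i = recs[0].channel_names.index("F3")
        powers = {0: [], 1: []}
        for rec in recs:
            cls = truth.label(rec.subject_id, rec.trial_id, "valence")
            powers[cls].append(welch_band_power(rec.samples[i], 128.0, 8, 12))
        ratio = np.mean(powers[1]) / np.mean(powers[0])
        assert 0.7 < ratio < 1.4


class TestSpectralContracts:
    def test_background_psd_slope(self):
        cfg = SynthConfig(n_subjects=1, n_trials=1, fs_raw=128.0, duration=30.0,
                          band_sine_amp=0.0, line_noise_amp=0.0, blink_rate=0.0,
                          noise_spectrum_exponent=1.0, effect_size=1.0, seed=3)
        rec, = generate_dataset(cfg)[0]
        slopes = []
        for x in rec.scalp_data()[:8]:
            f, p = sps.welch(x, fs=128.0, nperseg=1024)
            m = (f >= 1) & (f <= 40)
            slopes.append(np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0])
        assert abs(np.mean(slopes) - (-1.0)) < 0.3

    def test_line_noise_peak(self):
        cfg = SynthConfig(n_subjects=1, n_trials=1, fs_raw=128.0, duration=20.0,
                          line_noise_amp=1.0, blink_rate=0.0, effect_size=1.0,
                          seed=4)
        rec, = generate_dataset(cfg)[0]
        f, p = sps.welch(rec.samples[0], fs=128.0, nperseg=2048)
        i50 = int(np.argmin(np.abs(f - 50.0)))
        neighbors = np.r_[p[i50 - 8:i50 - 3], p[i50 + 4:i50 + 9]]
        assert p[i50] >= 10 * neighbors.max()


class TestLabels:
    def test_classes_balanced_and_ratings_consistent(self):
        cfg = SynthConfig(n_subjects=3, n_trials=10, fs_raw=128.0,
                          duration=4.0, seed=9)
        _, truth = generate_dataset(cfg)
        for sid, grp in truth.labels.groupby("subject_id"):
            assert grp.valence_class.sum() == 5  # exactly half high
        high = truth.labels[truth.labels.valence_class == 1]
        low = truth.labels[truth.labels.valence_class == 0]
        assert (high.valence_rating > 5).all()
        assert (low.valence_rating < 5).all()


class TestValidation:
    @pytest.mark.parametrize("kw", [
        dict(duration=-1.0), dict(fs_raw=0.0), dict(effect_size=0.0),
        dict(n_channels=3), dict(blink_rate=-1.0),
        dict(informative_channels=("NOPE",)),
        dict(informative_bands=("ultra",)),
        dict(duration=1.003),  # non-integer sample count at 128 Hz
    ])
    def test_invalid_configs_rejected(self, kw):
        base = dict(n_subjects=1, n_trials=1, fs_raw=128.0)
        base.update(kw)
        cfg = SynthConfig(**base)
        with pytest.raises(ValueError):
            generate_dataset(cfg)

    def test_eog_channels_present(self, tiny_dataset):
        recs, _ = tiny_dataset
        assert recs[0].eog_channels == ("EOG1", "EOG2")
        assert recs[0].n_channels == 34  # 32 scalp + 2 EOG


def test_band_edges_cover_canonical_ranges():
    assert BAND_EDGES["delta"] == (0.5, 4.0)
    assert BAND_EDGES["theta"] == (4.0, 8.0)
    assert BAND_EDGES["alpha"] == (8.0, 12.0)
    assert BAND_EDGES["beta"] == (12.0, 30.0)
    assert BAND_EDGES["gamma"][1] is None  # runs to Nyquist
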
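import dataclasses
import logging

import numpy as np
import pytest

from nirsnet import (
    HbTimeSeries,
    RawIntensity,
    bandpass,
    block_average,
    extract_epochs,
    hb_to_intensity,
    intensity_to_od,
    od_to_hb,
    simulate_subject,
)
from nirsnet.optics import extinction_matrix


def _ts(data, fs=10.0, montage=None, n_channels=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    channels = tuple(f"S1_D{i}" for i in range(n))
    hemis = tuple("left" if i % 2 else "right" for i in range(n))
    return HbTimeSeries(
        hbo=data, hbr=np.zeros_like(data), fs=fs, channels=channels, hemispheres=hemis
    )


class TestOpticalDensity:
    def _raw(self, data, reference=None):
        data = np.asarray(data, dtype=float).reshape(1, 2, -1)
        return RawIntensity(
            data=data,
            fs=10.0,
            channels=("S1_D1",),
            wavelengths=(760.0, 850.0),
            hemispheres=("right",),
            reference=reference,
        )

    @pytest.mark.parametrize("factor,od", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_known_attenuations(self, factor, od):
        raw = self._raw(np.full((2, 50), factor), reference=np.ones((1, 2)))
        out = intensity_to_od(raw)
        assert out.data == pytest.approx(od)

    def test_default_reference_is_trace_mean(self):
        data = np.stack([np.full(10, 2.0), np.full(10, 4.0)])
        raw = self._raw(data)
        out = intensity_to_od(raw)
        assert out.data == pytest.approx(0.0)

    def test_nonpositive_intensity_names_channel_and_sample(self):
        data = np.ones((1, 2, 5))
        data[0, 1, 3] = -1.0
        with pytest.raises(ValueError, match=r"S1_D1.*sample 3"):
            RawIntensity(
                data=data, fs=10.0, channels=("S1_D1",),
                wavelengths=(760.0, 850.0), hemispheres=("right",),
            )


class TestBeerLambertInversion:
    def test_zero_od_gives_zero_concentration(self, montage):
        from nirsnet.containers import OpticalDensity

        od = OpticalDensity(
            data=np.zeros((24, 2, 30)), fs=10.0,
            channels=montage.channel_names, wavelengths=(760.0, 850.0),
            hemispheres=montage.hemispheres,
        )
        hb = od_to_hb(od, montage)
        assert np.all(hb.hbo == 0) and np.all(hb.hbr == 0)

    def test_linearity_in_od(self, montage):
        from nirsnet.containers import OpticalDensity

        rng = np.random.default_rng(0)
        d = rng.standard_normal((24, 2, 30)) * 1e-3
        od1 = OpticalDensity(
            data=d, fs=10.0, channels=montage.channel_names,
            wavelengths=(760.0, 850.0), hemispheres=montage.hemispheres,
        )
        od2 = dataclasses.replace(od1, data=2 * d)
        hb1, hb2 = od_to_hb(od1, montage), od_to_hb(od2, montage)
        assert hb2.hbo == pytest.approx(2 * hb1.hbo)
        assert hb2.hbr == pytest.approx(2 * hb1.hbr)

    def test_roundtrip_forward_inverse_below_1e6_micromolar(
        self, montage, quiet_config, schedule_small
    ):
        cfg = dataclasses.replace(quiet_config, rng_seed=5)
        ts, _ = simulate_subject(montage, schedule_small, dataclasses.replace(
            cfg, noise=cfg.noise.scaled(0.0)))
        rng = np.random.default_rng(5)
        ts.hbo += 0.5 * rng.standard_normal(ts.hbo.shape)
        ts.hbr += 0.5 * rng.standard_normal(ts.hbr.shape)
        raw = hb_to_intensity(ts, montage, cfg)
        back = od_to_hb(intensity_to_od(raw), montage, dpf=cfg.dpf)
        assert np.abs(back.hbo - ts.hbo).max() < 1e-6
        assert np.abs(back.hbr - ts.hbr).max() < 1e-6

    def test_dpf_mismatch_scales_linearly(self, montage, quiet_config, schedule_small):
        ts, _ = simulate_subject(montage, schedule_small, quiet_config)
        doubled = dataclasses.replace(quiet_config, dpf=2 * quiet_config.dpf)
        raw = hb_to_intensity(ts, montage, doubled)
        back = od_to_hb(intensity_to_od(raw), montage, dpf=quiet_config.dpf)
        assert np.abs(back.hbo - 2 * ts.hbo).max() < 1e-6

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            extinction_matrix((760.0, 850.0), {760.0: (1.0, 2.0), 850.0: (2.0, 4.0)})

    def test_unknown_wavelength_rejected(self):
        with pytest.raises(KeyError):
            extinction_matrix((760.0, 999.0))


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass(_ts(np.full((1, 4000), 5.0)))
        assert np.abs(out.hbo).max() < 0.05  # <1% of the DC input

    def test_passband_sinusoid_preserved(self):
        t = np.arange(6000) / 10.0
        x = np.sin(2 * np.pi * 0.1 * t)
        out = bandpass(_ts(x[None, :]))
        mid = out.hbo[0, 1000:-1000]
        assert np.abs(mid).max() == pytest.approx(1.0, abs=0.1)

    def test_cardiac_attenuated_20db(self):
        t = np.arange(6000) / 10.0
        x = np.sin(2 * np.pi * 1.2 * t)
        out = bandpass(_ts(x[None, :]))
        assert np.abs(out.hbo[0, 1000:-1000]).max() < 0.1  # >= 20 dB down

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal((2, 3000))
        lhs = bandpass(_ts((2 * x + 3 * y)[None, :])).hbo[0]
        rhs = 2 * bandpass(_ts(x[None, :])).hbo[0] + 3 * bandpass(_ts(y[None, :])).hbo[0]
        assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_zero_phase(self):
        t = np.arange(8000) / 10.0
        x = np.sin(2 * np.pi * 0.1 * t)
        y = bandpass(_ts(x[None, :])).hbo[0]
        xc, yc = x[2000:-2000], y[2000:-2000]
        lags = np.arange(-50, 51)
        corr = [np.dot(xc, np.roll(yc, k)) for k in lags]
        assert lags[int(np.argmax(corr))] == 0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            bandpass(_ts(np.zeros((1, 100))), low=0.02, high=6.0)


class TestEpochs:
    def test_constant_series_gives_zero_epochs(self, schedule_small):
        n = int((schedule_small.end_time + 40) * 10)
        ts = _ts(np.full((2, n), 3.3))
        ep = extract_epochs(ts, schedule_small)
        assert ep.data == pytest.approx(0.0)

    def test_forty_block_schedule_yields_forty_epochs(self, montage, quiet_config):
        from nirsnet import generate_schedule

        sched = generate_schedule(4, 10, rng_seed=2)
        ts, _ = simulate_subject(montage, sched, quiet_config)
        ep = extract_epochs(ts, sched)
        assert ep.n_epochs == 40
        assert ep.n_dropped == 0

    def test_baseline_window_mean_is_zero(self, montage, schedule_small):
        from nirsnet import SimulationConfig

        ts, _ = simulate_subject(montage, schedule_small, SimulationConfig(rng_seed=6))
        ep = extract_epochs(ts, schedule_small)
        b0 = int((ep.baseline[0] - ep.tmin) * ep.fs)
        b1 = int((ep.baseline[1] - ep.tmin) * ep.fs)
        means = ep.data[:, :, b0:b1].mean(axis=2)
        assert np.abs(means).max() < 1e-9

    def test_truncated_block_dropped_with_warning(self, schedule_small, caplog):
        end = schedule_small.blocks[-1].onset  # last block's window will overrun
        ts = _ts(np.zeros((2, int(end * 10))))
        with caplog.at_level(logging.WARNING, logger="nirsnet.preprocessing"):
            ep = extract_epochs(ts, schedule_small)
        assert ep.n_epochs + ep.n_dropped == len(schedule_small)
        assert ep.n_dropped >= 1
        assert any("dropping" in r.message for r in caplog.records)

    def test_window_must_contain_baseline_and_onset(self, schedule_small):
        ts = _ts(np.zeros((1, 10000)))
        with pytest.raises(ValueError):
            extract_epochs(ts, schedule_small, tmin=-2.0, tmax=20.0)


class TestBlockAverage:
    def test_single_epoch_identity(self, montage, quiet_config, schedule_small):
        ts, _ = simulate_subject(montage, schedule_small, quiet_config)
        ep = extract_epochs(ts, schedule_small)
        cond = ep.conditions[0]
        first = [i for i, c in enumerate(ep.conditions) if c == cond]
        avg = block_average(ep, cond)
        expected = ep.data[first].mean(axis=0)
        assert avg.data == pytest.approx(expected)
        assert avg.n_blocks == len(first)

    def test_opposite_epochs_cancel(self):
        from nirsnet.containers import EpochSet

        v = np.random.default_rng(0).standard_normal((2, 50))
        ep = EpochSet(
            data=np.stack([v, -v]), conditions=("MV", "MV"), tmin=-5.0, tmax=-0.1,
            fs=10.0, channels=("S1_D1", "S2_D1"), hemispheres=("right", "right"),
        )
        avg = block_average(ep, "MV")
        assert avg.data == pytest.approx(0.0)

    def test_matches_bruteforce_mean(self):
        from nirsnet.containers import EpochSet

        rng = np.random.default_rng(3)
        data = rng.standard_normal((6, 3, 40))
        conds = ("MV", "MO", "MV", "MV", "MO", "MV")
        ep = EpochSet(
            data=data, conditions=conds, tmin=-5.0, tmax=-1.1, fs=10.0,
            channels=("a", "b", "c"), hemispheres=("left", "left", "right"),
        )
        avg = block_average(ep, "MV")
        # independent summation oracle
        acc = np.zeros((3, 40))
        k = 0
        for i, c in enumerate(conds):
            if c == "MV":
                acc += data[i]
                k += 1
        assert avg.data == pytest.approx(acc / k)
        sd = np.sqrt(
            sum((data[i] - acc / k) ** 2 for i, c in enumerate(conds) if c == "MV") / k
        )
        assert avg.sd == pytest.approx(sd)

    def test_missing_condition_rejected(self, montage, quiet_config, schedule_small):
        ts, _ = simulate_subject(montage, schedule_small, quiet_config)
        ep = extract_epochs(ts, schedule_small)
        with pytest.raises(ValueError, match="nope"):
            block_average(ep, "nope")


class TestEndToEndRecovery:
    def test_zero_noise_block_average_recovers_truth(
        self, montage, right_only_config, schedule_small
    ):
        """Epoching + baseline + averaging recovers the injected peak exactly."""
        ts, gt = simulate_subject(montage, schedule_small, right_only_config)
        ep = extract_epochs(ts, schedule_small)
        avg = block_average(ep, "MV")
        i = avg.channel_index(montage.right_channels[0])
        truth = gt.peak_amplitude("MV", montage.right_channels[0])
        assert avg.data[i].max() == pytest.approx(truth, rel=0.02)

    def test_filtered_recovery_within_filter_attenuation(
        self, montage, right_only_config, schedule_small
    ):
        """The 0.02 Hz high-pass clips ~10% of the peak (block fundamental
        sits in its transition band); recovery stays within 15%."""
        ts, gt = simulate_subject(montage, schedule_small, right_only_config)
        ep = extract_epochs(bandpass(ts), schedule_small)
        avg = block_average(ep, "MV")
        i = avg.channel_index(montage.right_channels[0])
        truth = gt.peak_amplitude("MV", montage.right_channels[0])
        assert avg.data[i].max() == pytest.approx(truth, rel=0.15)
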
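import math

import numpy as np
import pytest
from scipy import signal as sps

import _oracles as oracle
from ringppg import sqi
from ringppg.records import PPGRecord
from ringppg.synth import SynthSpec, generate


def random_segment(seed: int, fs: float = 100.0) -> sqi.Segment:
    """A seeded random raw segment with its band-passed counterpart."""
    rng = np.random.default_rng(seed)
    raw = 500.0 + 20.0 * rng.standard_normal(int(6 * fs))
    sos = sqi._sos_bandpass(0.5, 5.0, fs)
    return sqi.Segment(raw=raw, filtered=sps.sosfiltfilt(sos, raw), fs=fs)


class TestSegmentation:
    def test_60s_record_gives_10_segments(self):
        rec = PPGRecord(np.zeros(6000), fs=100.0)
        segs = sqi.segment_and_filter(rec)
        assert len(segs) == 10
        assert all(len(s.raw) == 600 for s in segs)

    def test_remainder_discarded(self):
        rec = PPGRecord(np.zeros(6000 + 373), fs=100.0)
        assert len(sqi.segment_and_filter(rec)) == 10

    def test_short_record_raises(self):
        with pytest.raises(ValueError):
            sqi.segment_and_filter(PPGRecord(np.zeros(500), fs=100.0))

    def test_passband_gain_near_unity_at_1hz(self):
        t = np.arange(6000) / 100.0
        rec = PPGRecord(np.sin(2 * np.pi * 1.0 * t), fs=100.0)
        seg = sqi.segment_and_filter(rec)[5]
        trimmed = seg.filtered[100:-100]
        assert np.ptp(trimmed) / 2 == pytest.approx(1.0, rel=0.02)


class TestAmplitudeIndices:
    def test_ac_of_unit_1hz_sinusoid_is_2(self):
        t = np.arange(600) / 100.0
        y = np.sin(2 * np.pi * 1.0 * t)
        seg = sqi.Segment(raw=y, filtered=y, fs=100.0)
        assert sqi.compute_ac(seg) == pytest.approx(2.0)

    def test_ac_of_constant_is_zero(self):
        seg = sqi.Segment(raw=np.ones(600), filtered=np.ones(600), fs=100.0)
        assert sqi.compute_ac(seg) == 0.0

    def test_dc_examples(self):
        seg = sqi.Segment(raw=np.full(600, 512.0), filtered=np.zeros(600), fs=100.0)
        assert sqi.compute_dc(seg) == 512.0
        t = np.arange(600) / 100.0
        seg2 = sqi.Segment(
            raw=100.0 + np.sin(2 * np.pi * 1.0 * t), filtered=np.zeros(600), fs=100.0
        )
        assert sqi.compute_dc(seg2) == pytest.approx(100.0)

    def test_pi_examples(self):
        assert sqi.compute_pi(2.0, 10.0) == pytest.approx(0.2)
        assert sqi.compute_pi(0.0, 10.0) == 0.0
        assert math.isnan(sqi.compute_pi(1.0, 0.0))

    def test_pi_matches_generator_perfusion(self):
        rec, truth = generate(
            SynthSpec(seed=3, drift_amplitude=0.0, hrv_pct=0.0)
        )
        segs = sqi.segment_and_filter(rec)
        pis = []
        for s in segs:
            ac = sqi.compute_ac(s)
            dc = sqi.compute_dc(s)
            pis.append(sqi.compute_pi(ac, dc))
        assert np.mean(pis) == pytest.approx(truth.ac_dc, rel=0.05)

    def test_scale_invariance_of_pi(self):
        seg = random_segment(0)
        ac, dc = sqi.compute_ac(seg), sqi.compute_dc(seg)
        seg2 = sqi.Segment(raw=3.7 * seg.raw, filtered=3.7 * seg.filtered, fs=seg.fs)
        ac2, dc2 = sqi.compute_ac(seg2), sqi.compute_dc(seg2)
        assert ac2 == pytest.approx(3.7 * ac, rel=1e-12)
        assert sqi.compute_pi(ac2, dc2) == pytest.approx(sqi.compute_pi(ac, dc), rel=1e-12)


class TestSnr:
    def test_all_zero_segment_is_nan(self):
        seg = sqi.Segment(raw=np.zeros(600), filtered=np.zeros(600), fs=100.0)
        assert math.isnan(sqi.compute_snr(seg).snr_db)

    def test_monotone_in_generator_snr(self):
        """Zero-DC in-band tone + white noise: more noise, lower computed SNR."""
        t = np.arange(600) / 100.0
        x = np.sin(2 * np.pi * 1.5 * t)
        sos = sqi._sos_bandpass(0.5, 5.0, 100.0)

        def snr_at(gen_db):
            rng = np.random.default_rng(7)
            sigma = math.sqrt(np.var(x) / 10 ** (gen_db / 10))
            raw = x + rng.normal(0, sigma, len(x))
            seg = sqi.Segment(raw=raw, filtered=sps.sosfiltfilt(sos, raw), fs=100.0)
            return sqi.compute_snr(seg).snr_db

        assert snr_at(20.0) > snr_at(0.0)


class TestPsdMoments:
    def test_symmetric_spectrum_has_zero_skew(self):
        """Two bins symmetric about the mean, rest exactly at the mean."""
        nf = 11
        power = np.full(nf, 4.0)
        power[2], power[8] = 2.0, 6.0
        fmean, fstd = power.mean(), power.std()
        z = (power - fmean) / fstd
        assert np.sum(z**3) == pytest.approx(0.0, abs=1e-12)
        assert np.sum(z**4) == pytest.approx(2 * (2.0 / fstd) ** 4, rel=1e-12)

    def test_flat_spectrum_flagged(self):
        seg = sqi.Segment(raw=np.zeros(600), filtered=np.zeros(600), fs=100.0)
        m = sqi.compute_psd_moments(seg)
        assert math.isnan(m.spsd) and math.isnan(m.kpsd)

    def test_amplitude_scale_invariance(self):
        seg = random_segment(5)
        m1 = sqi.compute_psd_moments(seg)
        seg2 = sqi.Segment(raw=seg.raw, filtered=2.5 * seg.filtered, fs=seg.fs)
        m2 = sqi.compute_psd_moments(seg2)
        assert m2.spsd == pytest.approx(m1.spsd, rel=1e-9)
        assert m2.kpsd == pytest.approx(m1.kpsd, rel=1e-9)


class TestAutocorr:
    def test_periodic_signal_zero_stds_and_lags_at_period_multiples(self):
        t = np.arange(600) / 100.0
        y = np.sin(2 * np.pi * 2.0 * t)  # period 50 samples
        seg = sqi.Segment(raw=y, filtered=y, fs=100.0)
        p = sqi.compute_autocorr_profile(seg)
        assert list(p.peak_lags) == [50, 100, 150, 200, 250]
        assert p.std_periods == pytest.approx(0.0, abs=1e-12)
        assert p.std_peaks == pytest.approx(0.0, abs=1e-12)

    def test_normalization_r0_is_one(self):
        p = sqi.compute_autocorr_profile(random_segment(2))
        assert p.R[0] == pytest.approx(1.0)

    def test_white_noise_never_looks_cleanly_periodic(self):
        """Across 20 seeds: flagged, or far more dispersed than a clean pulse."""
        clean, _ = generate(SynthSpec(seed=0))
        clean_stds = [
            sqi.compute_autocorr_profile(s).std_periods
            for s in sqi.segment_and_filter(clean)
        ]
        worst_clean = np.nanmax(clean_stds)
        sos = sqi._sos_bandpass(0.5, 5.0, 100.0)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            raw = rng.standard_normal(600)
            seg = sqi.Segment(raw=raw, filtered=sps.sosfiltfilt(sos, raw), fs=100.0)
            p = sqi.compute_autocorr_profile(seg)
            assert math.isnan(p.std_periods) or p.std_periods > worst_clean


class TestFormulaFidelity:
    @pytest.mark.parametrize("seed", range(100))
    def test_indices_match_bruteforce_transcriptions(self, seed):
        """Vectorized index computations vs independent loop transcriptions."""
        seg = random_segment(seed)
        assert sqi.compute_ac(seg) == pytest.approx(
            oracle.ac_bruteforce(seg.filtered, seg.fs), rel=1e-9
        )
        assert sqi.compute_dc(seg) == pytest.approx(
            oracle.dc_bruteforce(seg.raw), rel=1e-9
        )
        snr = sqi.compute_snr(seg).snr_db
        snr_ref = oracle.snr_bruteforce(seg.raw, seg.filtered, seg.fs)
        if math.isnan(snr_ref):
            assert math.isnan(snr)
        else:
            assert snr == pytest.approx(snr_ref, rel=1e-9)
        m = sqi.compute_psd_moments(seg)
        s_ref, k_ref = oracle.psd_moments_bruteforce(seg.filtered)
        assert m.spsd == pytest.approx(s_ref, rel=1e-9)
        assert m.kpsd == pytest.approx(k_ref, rel=1e-9)
        p = sqi.compute_autocorr_profile(seg)
        np.testing.assert_allclose(
            p.R, oracle.autocorr_bruteforce(seg.filtered), rtol=1e-9
        )
        if len(p.peak_lags) >= 3:
            assert p.std_periods == pytest.approx(
                oracle.sd_bruteforce(np.diff(p.peak_lags) / seg.fs), rel=1e-9
            )
            assert p.std_peaks == pytest.approx(
                oracle.sd_bruteforce(p.peak_heights), rel=1e-9
            )


class TestFom:
    def _vec(self, **kw):
        base = dict(
            ac=1.0, dc=1.0, pi=1.0, snr_db=0.0, spsd=1.0, kpsd=1.0,
            std_periods=1.0, std_peaks=1.0,
        )
        base.update(kw)
        return sqi.SQIVector(**base)

    def test_identity_when_all_normalized_to_one(self):
        # constant indices normalize to 1 -> FoM = 1 for every segment
        sqis = [self._vec(index=i) for i in range(3)]
        res = sqi.compute_fom(sqis)
        np.testing.assert_allclose(res.fom, 1.0)

    def test_denominator_arithmetic(self):
        # normalized denominators of 0.5 double the FoM twice
        norm = {
            "pi": np.array([1.0]), "ac": np.array([1.0]),
            "spsd": np.array([1.0]), "kpsd": np.array([1.0]),
            "std_periods": np.array([0.5]), "std_peaks": np.array([0.5]),
        }
        fom = (norm["pi"] * norm["ac"] * norm["spsd"] * norm["kpsd"]) / (
            norm["std_periods"] * norm["std_peaks"]
        )
        assert fom[0] == pytest.approx(4.0)

    def test_all_flagged_raises(self):
        sqis = [self._vec(pi=math.nan, index=0)]
        with pytest.raises(ValueError):
            sqi.compute_fom(sqis)

    def test_strictly_periodic_segment_excluded(self):
        good = [self._vec(std_periods=0.3 + 0.1 * i, index=i) for i in range(3)]
        degenerate = self._vec(std_periods=0.0, std_peaks=0.0, index=3)
        res = sqi.compute_fom(good + [degenerate])
        assert math.isnan(res.fom[3])
        assert not np.isnan(res.fom[:3]).any()

    def test_clean_session_beats_corrupted_session(self):
        """Session of clean + heavily corrupted halves: clean mean FoM wins."""
        for seed in range(3):
            clean, _ = generate(SynthSpec(seed=seed))
            noisy, _ = generate(
                SynthSpec(seed=seed, noise_snr_db=-12.0, artifact_rate=20.0)
            )
            rec = PPGRecord(
                np.concatenate([clean.samples, noisy.samples]), fs=100.0
            )
            sqis = [sqi.compute_sqi(s) for s in sqi.segment_and_filter(rec)]
            res = sqi.compute_fom(sqis)
            assert np.nanmean(res.fom[:10]) > np.nanmean(res.fom[10:])
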
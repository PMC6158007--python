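"""Detection features, classifier contract, detection-limit profiles,
amplitude-distribution correction, and the optogenetic SNR scorer."""

import numpy as np
import pytest
from scipy import stats

from conftest import DT
from synphys import detect
from synphys.detect import (DetectionProfile, SynapseClassifier,
                            corrected_amplitude_distribution,
                            extract_features, min_detectable_amplitude,
                            optogenetic_snr, train_classifier)
from synphys.synthgen import (SyntheticAmplitudeModel, SyntheticPSPConfig,
                              psp_kernel, synthesize_background_pool,
                              synthesize_pair)
from synphys.trace import SweepRecording, Trace


class TestExtractFeatures:
    def test_strong_connection_significant(self, connected_pair):
        f = extract_features(connected_pair[0])
        assert f.ks_p_amplitude < 1e-3
        assert f.amplitude > 0.1

    def test_null_p_values_not_extreme(self, background_pool):
        ps = [extract_features(b).ks_p_amplitude for b in background_pool]
        # under the null the KS p-values should look uniform-ish: no mass
        # collapse at zero
        assert min(ps) > 1e-4
        assert np.mean(np.asarray(ps) > 0.1) >= 0.5

    def test_null_p_amplitude_uniformish(self, protocol50):
        # a larger null calibration: KS p-values vs Uniform(0,1)
        pool = synthesize_background_pool(40, protocol50, seed=101, dt=DT)
        ps = np.array([extract_features(b).ks_p_amplitude for b in pool])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_order_invariance(self, connected_pair):
        sweeps = connected_pair[0]
        f1 = extract_features(sweeps).vector()
        f2 = extract_features(list(reversed(sweeps))).vector()
        assert np.allclose(f1, f2)

    def test_min_sweeps_precondition(self, connected_pair):
        with pytest.raises(ValueError):
            extract_features(connected_pair[0][:3])


class TestClassifier:
    def test_benchmark_accuracy(self, trained_classifier, protocol50,
                                psp_config):
        ok = n = fp = nneg = 0
        for i, amp in enumerate(np.geomspace(0.05, 1.0, 25)):
            sweeps, _ = synthesize_pair(
                protocol50, psp_config,
                SyntheticAmplitudeModel(target_mean_amplitude=float(amp)),
                seed=210, dt=DT, pair_key=i)
            p = trained_classifier.predict_proba(extract_features(sweeps))[0]
            ok += p > 0.5
            n += 1
        for b in synthesize_background_pool(50, protocol50, seed=211,
                                            dt=DT):
            p = trained_classifier.predict_proba(extract_features(b))[0]
            fp += p > 0.5
            ok += p <= 0.5
            nneg += 1
            n += 1
        assert ok / n >= 0.9
        # operating-point false-positive rate on pure noise
        assert fp / nneg <= 0.05

    def test_probability_in_unit_interval(self, trained_classifier,
                                          background_pool):
        p = trained_classifier.predict_proba(
            [extract_features(b) for b in background_pool])
        assert np.all((p >= 0) & (p <= 1))

    def test_training_deterministic(self, protocol50, psp_config):
        feats, labels = [], []
        for i, amp in enumerate((0.1, 0.5, 1.0)):
            s, _ = synthesize_pair(
                protocol50, psp_config,
                SyntheticAmplitudeModel(target_mean_amplitude=amp),
                seed=31, dt=DT, pair_key=i)
            feats.append(extract_features(s))
            labels.append(True)
        for b in synthesize_background_pool(4, protocol50, seed=32, dt=DT):
            feats.append(extract_features(b))
            labels.append(False)
        c1 = train_classifier(list(zip(feats, labels)), seed=5)
        c2 = train_classifier(list(zip(feats, labels)), seed=5)
        assert np.array_equal(c1.predict_proba(feats), c2.predict_proba(feats))

    def test_single_class_rejected(self, background_pool):
        feats = [extract_features(b) for b in background_pool[:4]]
        with pytest.raises(ValueError):
            train_classifier([(f, False) for f in feats])

    def test_save_load_identical(self, trained_classifier, background_pool,
                                 tmp_path):
        feats = [extract_features(b) for b in background_pool[:3]]
        path = str(tmp_path / "clf.pkl")
        trained_classifier.save(path)
        loaded = SynapseClassifier.load(path)
        assert np.array_equal(trained_classifier.predict_proba(feats),
                              loaded.predict_proba(feats))

    def test_probability_monotone_in_amplitude(self, trained_classifier,
                                               protocol50, psp_config):
        # same noise realization, increasing injected strength
        probs = []
        for amp in (0.02, 0.1, 0.5):
            sweeps, _ = synthesize_pair(
                protocol50, psp_config,
                SyntheticAmplitudeModel(gain_sd=0.0, binom_p=1.0,
                                        target_mean_amplitude=amp),
                seed=33, dt=DT, pair_key=9)
            probs.append(trained_classifier.predict_proba(
                extract_features(sweeps))[0])
        assert probs[0] <= probs[1] <= probs[2]


GRID = np.geomspace(0.01, 2.0, 8)  # coarse grid keeps the suite fast


class TestDetectionLimit:
    def test_large_amplitude_detected(self, trained_classifier,
                                      background_pool):
        prof = min_detectable_amplitude(background_pool[0],
                                        trained_classifier,
                                        amplitude_grid=GRID,
                                        n_repeats=4, seed=1)
        assert prof.detection_prob[-1] > 0.95

    def test_profile_monotone_in_amplitude(self, trained_classifier,
                                           background_pool):
        prof = min_detectable_amplitude(background_pool[1],
                                        trained_classifier,
                                        amplitude_grid=GRID,
                                        n_repeats=4, seed=2)
        assert np.all(np.diff(prof.detection_prob) >= -0.1)
        assert prof.detection_prob[-1] >= prof.detection_prob[0]

    def test_threshold_monotone_in_noise(self, trained_classifier,
                                         background_pool):
        sweeps = background_pool[2]
        scaled = [SweepRecording(trace=s.trace.like(3.0 * s.trace.data),
                                 spike_times=s.spike_times,
                                 protocol=s.protocol) for s in sweeps]
        kw = dict(amplitude_grid=GRID, n_repeats=4, seed=3)
        p_lo = min_detectable_amplitude(sweeps, trained_classifier, **kw)
        p_hi = min_detectable_amplitude(scaled, trained_classifier, **kw)
        assert p_hi.min_detectable_amplitude >= \
            p_lo.min_detectable_amplitude

    def test_censored_profile_flagged(self, trained_classifier,
                                      background_pool):
        sweeps = background_pool[3]
        huge = [SweepRecording(trace=s.trace.like(10.0 * s.trace.data),
                               spike_times=s.spike_times,
                               protocol=s.protocol) for s in sweeps]
        prof = min_detectable_amplitude(huge, trained_classifier,
                                        amplitude_grid=GRID[:5],
                                        n_repeats=2, seed=4)
        assert prof.censored
        assert prof.min_detectable_amplitude == pytest.approx(GRID[4])


def flat_profile(p, grid=None):
    grid = np.asarray([0.01, 2.0] if grid is None else grid)
    return DetectionProfile(amplitude_grid=grid,
                            detection_prob=np.full(grid.size, p),
                            min_detectable_amplitude=grid[0])


class TestCorrectedDistribution:
    def test_perfect_detection_identity(self):
        rng = np.random.default_rng(0)
        amps = rng.lognormal(np.log(0.3), 0.5, 300)
        out = corrected_amplitude_distribution(amps, [flat_profile(1.0)])
        assert out["inflation"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(out["corrected"], out["smoothed"])

    def test_half_detection_inflates_by_one(self):
        amps = np.random.default_rng(1).uniform(0.2, 1.0, 200)
        out = corrected_amplitude_distribution(amps, [flat_profile(0.5)])
        assert out["inflation"] == pytest.approx(1.0)

    def test_mass_conserved_where_detection_is_one(self):
        amps = np.random.default_rng(2).uniform(0.2, 1.0, 500)
        out = corrected_amplitude_distribution(amps, [flat_profile(1.0)])
        assert np.nansum(out["corrected"]) == pytest.approx(
            out["measured"].sum(), rel=0.02)

    def test_low_detection_bins_masked(self):
        grid = np.array([0.01, 0.1, 2.0])
        prof = DetectionProfile(amplitude_grid=grid,
                                detection_prob=np.array([0.0, 0.05, 1.0]),
                                min_detectable_amplitude=0.3)
        amps = np.concatenate([np.full(50, 0.05), np.full(50, 1.5)])
        out = corrected_amplitude_distribution(amps, [prof])
        assert out["masked"].any()
        assert np.isnan(out["corrected"][out["masked"]]).all()

    def test_round_trip_recovers_total(self):
        # draw a true amplitude population, thin it through realistic
        # detection curves, correct the measured histogram, compare totals
        rng = np.random.default_rng(3)
        true_amps = rng.lognormal(np.log(0.25), 0.6, 4000)
        grid = np.geomspace(0.01, 3.0, 20)
        profiles = []
        for thr in (0.03, 0.05, 0.08, 0.12):
            p = 1.0 / (1.0 + (thr / grid) ** 3)
            profiles.append(DetectionProfile(
                amplitude_grid=grid, detection_prob=p,
                min_detectable_amplitude=thr))
        pick = rng.integers(0, len(profiles), true_amps.size)
        p_det = np.array([profiles[j].prob_at(a)
                          for j, a in zip(pick, true_amps)])
        measured = true_amps[rng.random(true_amps.size) < p_det]
        out = corrected_amplitude_distribution(measured, profiles,
                                               bin_width=0.05)
        corrected_total = np.nansum(out["corrected"])
        true_total = np.histogram(
            true_amps, bins=out["bin_edges"])[0][~out["masked"]].sum()
        assert corrected_total == pytest.approx(true_total, rel=0.15)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            corrected_amplitude_distribution([], [flat_profile(1.0)])


def opto_trials(signal_amp=0.0, where="signal", n_trials=10, seed=0,
                noise_rms=0.05):
    """Current-clamp trials around a photostimulus at t = 300 ms."""
    rng = np.random.default_rng(seed)
    cfg = SyntheticPSPConfig()
    trials = []
    for _ in range(n_trials):
        grid = Trace(rng.normal(0.0, noise_rms, 12000), DT, t0=0.0)
        if signal_amp > 0:
            onset = 315.0 if where == "signal" else 205.0
            jitter = rng.normal(0.0, 1.0)
            grid = grid.like(grid.data + psp_kernel(
                signal_amp, cfg, onset + jitter, grid).data)
        trials.append(grid)
    return trials


class TestOptogeneticSNR:
    def test_flat_noise_not_called(self):
        out = optogenetic_snr(opto_trials(0.0, seed=1), stim_onset=300.0)
        assert not out["call"]
        assert out["ratio"] < 1.5

    def test_injected_epsp_called(self):
        out = optogenetic_snr(opto_trials(0.3, "signal", seed=2),
                              stim_onset=300.0)
        assert out["ratio"] > 1.5 and out["call"]

    def test_event_in_noise_window_not_called(self):
        out = optogenetic_snr(opto_trials(0.3, "noise", seed=2),
                              stim_onset=300.0)
        assert out["ratio"] < 1.0

    def test_span_precondition(self):
        short = [Trace(np.zeros(2000), DT, t0=250.0)]
        with pytest.raises(ValueError):
            optogenetic_snr(short, stim_onset=300.0)

    def test_tau_range_enforced(self):
        with pytest.raises(ValueError):
            optogenetic_snr(opto_trials(0.0), stim_onset=300.0, tau=5.0)
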
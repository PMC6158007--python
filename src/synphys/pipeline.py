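"""End-to-end orchestration: simulate -> QC -> fit -> deconvolve ->
STP-fit -> detect -> connectivity.

A :class:`RunConfig` (YAML-serializable) pins every knob and one seed; two
runs from the same config produce identical summaries. The run report
mirrors the analysis funnel of a multipatch study: pairs probed, pairs
detected, pairs passing strength QC, pairs passing the kinetics cut, and
pairs entering the short-term-plasticity analysis, per connection class.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import connstats, deconv, detect, pspkit, stpmodel, synthgen
from .synthgen import (NoiseModel, SyntheticAmplitudeModel,
                       SyntheticPSPConfig, make_protocol, _rng)

__all__ = ["ClassConfig", "RunConfig", "run_end_to_end"]


@dataclass
class ClassConfig:
    """Study conditions for one connection class."""

    name: str
    n_pairs: int = 20
    connection_prob: float = 0.1
    mean_amplitude: float = 0.5          # mV
    stp: Optional[dict] = None           # P0/tau_r0/tau_FDR/a_FDR
    max_distance: float = 200.0          # um, uniform sampling span


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "synphys_run"
    sample_rate_khz: float = 20.0
    noise_rms: float = 0.15              # mV raw; deconvolved ~0.6 mV
    n_trials: int = 5
    stp_protocols: Tuple[Tuple[float, float], ...] = (
        (20.0, 250.0), (50.0, 250.0), (100.0, 250.0), (50.0, 1000.0))
    classes: Tuple[ClassConfig, ...] = (
        ClassConfig(name="classA", stp={"P0": 0.3, "tau_r0": 1.26,
                                        "tau_FDR": 130.6, "a_FDR": 0.85}),
        ClassConfig(name="classB", connection_prob=0.05,
                    mean_amplitude=0.3,
                    stp={"P0": 0.16, "tau_r0": 1.20,
                         "tau_FDR": 276.3, "a_FDR": 0.47}),
    )
    run_detection: bool = True
    detection_n_train: int = 30          # connected training pairs
    detection_grid: Tuple[float, ...] = (0.02, 0.05, 0.1, 0.2, 0.4, 0.8)
    detection_repeats: int = 4
    detection_n_profiles: int = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        blob = yaml.safe_load(Path(path).read_text()) or {}
        if "classes" in blob:
            blob["classes"] = tuple(ClassConfig(**c)
                                    for c in blob["classes"])
        if "stp_protocols" in blob:
            blob["stp_protocols"] = tuple(tuple(p)
                                          for p in blob["stp_protocols"])
        if "detection_grid" in blob:
            blob["detection_grid"] = tuple(blob["detection_grid"])
        return cls(**blob)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _stp_params(cfg: ClassConfig) -> Optional[stpmodel.STPParams]:
    return stpmodel.STPParams(**cfg.stp) if cfg.stp else None


def _sweep_amplitude(sweep, tau: float = 15.0) -> float:
    """Single-sweep first-pulse amplitude from the deconvolved peak."""
    return float(deconv.train_amplitudes([sweep], tau=tau)["absolute"][0])


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full synthetic analysis chain and write stage outputs.

    Returns the summary report (also written to ``out_dir/summary.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dt = 1.0 / config.sample_rate_khz
    psp_cfg = SyntheticPSPConfig()
    noise = NoiseModel(rms=config.noise_rms)

    summary: dict = {"seed": config.seed, "classes": {}}
    all_profiles: List[detect.DetectionProfile] = []
    detected_amplitudes: List[float] = []
    classifier = None

    # classifier training set: injected positives + pure backgrounds
    if config.run_detection:
        proto = make_protocol(50.0, 250.0, n_trials=config.n_trials)
        feats: List[detect.PairFeatures] = []
        labels: List[bool] = []
        amp_grid = np.geomspace(0.05, 1.0, config.detection_n_train)
        for i, amp in enumerate(amp_grid):
            sweeps, _ = synthgen.synthesize_pair(
                proto, psp_cfg,
                SyntheticAmplitudeModel(target_mean_amplitude=float(amp)),
                noise=noise, seed=config.seed, connected=True, dt=dt,
                pair_key=1000 + i)
            feats.append(detect.extract_features(sweeps))
            labels.append(True)
        backgrounds = synthgen.synthesize_background_pool(
            2 * config.detection_n_train, protocol=proto,
            rms_mean=config.noise_rms, rms_sd=config.noise_rms / 3,
            seed=config.seed + 1, dt=dt)
        for sweeps in backgrounds:
            feats.append(detect.extract_features(sweeps))
            labels.append(False)
        classifier = detect.train_classifier(list(zip(feats, labels)),
                                             seed=config.seed)
        classifier.save(str(out / "classifier.pkl"))

    for ci, cls in enumerate(config.classes):
        stp = _stp_params(cls)
        cls_rng = _rng(config.seed, 0xD, ci)
        distances = cls_rng.uniform(10.0, cls.max_distance, cls.n_pairs)
        truly_connected = cls_rng.random(cls.n_pairs) < cls.connection_prob

        pair_rows = []
        curves: Dict[Tuple[float, float], List[np.ndarray]] = {
            p: [] for p in config.stp_protocols}
        for pi in range(cls.n_pairs):
            connected = bool(truly_connected[pi])
            # primary 50 Hz protocol for strength/kinetics/detection
            proto = make_protocol(50.0, 250.0, n_trials=config.n_trials)
            sweeps, truth = synthgen.synthesize_pair(
                proto, psp_cfg,
                SyntheticAmplitudeModel(
                    target_mean_amplitude=cls.mean_amplitude),
                stp_params=stp if connected else None, noise=noise,
                seed=config.seed, connected=connected, dt=dt,
                pair_key=(ci + 1) * 10000 + pi)
            included, qc = pspkit.qc_connection(sweeps)

            row = {"pair": f"{cls.name}:{pi}", "distance_um":
                   float(distances[pi]), "truth_connected": connected,
                   "qc_pass": bool(qc.passed),
                   "n_sweeps_included": len(included)}
            # detection call
            if classifier is not None and len(included) >= 5:
                prob = float(classifier.predict_proba(
                    detect.extract_features(included))[0])
                row["detection_prob"] = prob
                row["detected"] = prob > 0.5
            else:
                row["detected"] = connected  # detection stage disabled
            # strength & kinetics
            if row["detected"] and qc.passed and len(included) >= 5:
                avg = pspkit.average_response(included)
                try:
                    fit = pspkit.fit_psp(avg, 0.0)
                    row["amplitude_mv"] = fit.amplitude
                    row["latency_ms"] = fit.latency
                    row["rise_ms"] = fit.rise_time_20_80
                    row["wrmse"] = fit.wrmse
                    row["kinetics_pass"] = pspkit.kinetics_filter(fit)
                    amps = [_sweep_amplitude(s) for s in included]
                    row["cv"] = pspkit.compute_cv(amps)
                except pspkit.FitError:
                    row["kinetics_pass"] = False
                if connected:
                    detected_amplitudes.append(truth.mean_amplitude)
                # STP protocols for connected, strong-enough pairs
                if connected and cls.mean_amplitude >= 0.3 and stp:
                    for freq, delay in config.stp_protocols:
                        p = make_protocol(freq, delay, n_trials=5)
                        ssweeps, _ = synthgen.synthesize_pair(
                            p, psp_cfg,
                            SyntheticAmplitudeModel(
                                target_mean_amplitude=cls.mean_amplitude),
                            stp_params=stp, noise=noise, seed=config.seed,
                            connected=True, dt=dt,
                            pair_key=(ci + 1) * 10000 + 5000 + pi)
                        res = deconv.train_amplitudes(ssweeps)
                        curves[(freq, delay)].append(res["normalized"])
                    row["stp_included"] = True
            pair_rows.append(row)

        # class-level aggregation
        det_rows = [r for r in pair_rows if r.get("detected")]
        strength = [r for r in det_rows if "amplitude_mv" in r]
        kinetics = [r for r in strength if r.get("kinetics_pass")]
        stp_rows = [r for r in pair_rows if r.get("stp_included")]

        cls_summary = {
            "probed": cls.n_pairs,
            "connected": int(sum(r["detected"] for r in pair_rows)),
            "strength_n": len(strength),
            "kinetics_n": len(kinetics),
            "stp_n": len(stp_rows),
        }
        if strength:
            cls_summary["amplitude_median_mv"] = float(np.median(
                [r["amplitude_mv"] for r in strength]))
            cls_summary["cv_median"] = float(np.median(
                [r["cv"] for r in strength if "cv" in r]))
        if kinetics:
            cls_summary["latency_median_ms"] = float(np.median(
                [r["latency_ms"] for r in kinetics]))
            cls_summary["rise_median_ms"] = float(np.median(
                [r["rise_ms"] for r in kinetics]))

        # STP ratios and model fit on the class-average curves
        mean_curves = {k: np.mean(v, axis=0) for k, v in curves.items() if v}
        if mean_curves:
            key50 = (50.0, 250.0)
            if key50 in mean_curves:
                cls_summary["stp_ratios"] = deconv.stp_ratios(
                    mean_curves[key50])
            freqs = {k[0] for k in mean_curves}
            delays = {k[1] for k in mean_curves}
            if len(freqs) >= 2 or len(delays) >= 2:
                try:
                    fitres = stpmodel.fit(mean_curves)
                    cls_summary["stp_fit"] = fitres.to_dict()
                except stpmodel.FitFailure as exc:
                    cls_summary["stp_fit"] = {"error": str(exc)}

        # connectivity by detection call
        k = sum(bool(r["detected"]) for r in pair_rows)
        cc = connstats.ConnectivityCount(k=k, n=cls.n_pairs, group=cls.name)
        cls_summary["connection_probability"] = \
            connstats.connection_probability(cc)
        within = [r for r in pair_rows if r["distance_um"] <= 100.0]
        cc100 = connstats.ConnectivityCount(
            k=sum(bool(r["detected"]) for r in within), n=len(within),
            group=cls.name, distance_filter=100.0)
        if within:
            cls_summary["connection_probability_100um"] = \
                connstats.connection_probability(cc100)
        cls_summary["distance_profile"] = {
            "bin_edges": connstats.distance_profile(
                [(r["distance_um"], bool(r["detected"]))
                 for r in pair_rows]).bin_edges.tolist()}
        summary["classes"][cls.name] = cls_summary

        with open(out / f"pairs_{cls.name}.json", "w") as fh:
            json.dump(pair_rows, fh, indent=1)

    # detection profiles on fresh backgrounds
    if config.run_detection and classifier is not None:
        proto = make_protocol(50.0, 250.0, n_trials=config.n_trials)
        backgrounds = synthgen.synthesize_background_pool(
            config.detection_n_profiles, protocol=proto,
            rms_mean=config.noise_rms, rms_sd=config.noise_rms / 3,
            seed=config.seed + 2, dt=dt)
        mdas = []
        for i, sweeps in enumerate(backgrounds):
            profile = detect.min_detectable_amplitude(
                sweeps, classifier,
                amplitude_grid=np.asarray(config.detection_grid),
                n_repeats=config.detection_repeats,
                seed=config.seed + 3 + i)
            all_profiles.append(profile)
            mdas.append(profile.min_detectable_amplitude)
        summary["detection"] = {
            "min_detectable_amplitude_mv": mdas,
            "median_min_detectable_mv": float(np.median(mdas)),
        }
        if detected_amplitudes and all_profiles:
            corr = detect.corrected_amplitude_distribution(
                detected_amplitudes, all_profiles)
            summary["detection"]["inflation"] = corr["inflation"]

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
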
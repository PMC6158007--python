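"""HDF5 persistence for synthetic experiments, with JSON ground truth.

Layout: one group per probed pair, ``/pairs/<id>/sweeps/<k>/trace`` plus
acquisition attributes. Ground truth is written to a ``<path>.truth.json``
sidecar so the data file looks like a plain acquisition artifact.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np

from .stpmodel import STPParams
from .synthgen import GroundTruth, StimulusProtocol
from .trace import SweepRecording, Trace

__all__ = ["save_pairs", "load_pairs", "truth_sidecar_path"]


def truth_sidecar_path(path) -> Path:
    return Path(str(path) + ".truth.json")


def _truth_to_dict(t: GroundTruth) -> dict:
    d = {
        "connected": bool(t.connected),
        "mean_amplitude": float(t.mean_amplitude),
        "per_event_amplitudes": t.per_event_amplitudes.tolist(),
        "per_event_latencies": t.per_event_latencies.tolist(),
        "stp_normalized": t.stp_normalized.tolist(),
        "stp_params": None,
    }
    if t.stp_params is not None:
        p = t.stp_params
        d["stp_params"] = {"P0": p.P0, "tau_r0": p.tau_r0,
                           "tau_FDR": p.tau_FDR, "a_FDR": p.a_FDR, "A": p.A}
    return d


def _truth_from_dict(d: dict) -> GroundTruth:
    sp = d.get("stp_params")
    return GroundTruth(
        connected=d["connected"],
        mean_amplitude=d["mean_amplitude"],
        stp_params=STPParams(**sp) if sp else None,
        per_event_amplitudes=np.asarray(d["per_event_amplitudes"]),
        per_event_latencies=np.asarray(d["per_event_latencies"]),
        stp_normalized=np.asarray(d["stp_normalized"]),
    )


def save_pairs(path,
               pairs: Dict[str, Sequence[SweepRecording]],
               truths: Optional[Dict[str, GroundTruth]] = None,
               meta: Optional[Dict[str, dict]] = None) -> None:
    """Write sweeps per pair; ground truth goes to the JSON sidecar."""
    meta = meta or {}
    with h5py.File(path, "w") as f:
        root = f.create_group("pairs")
        for pair_id, sweeps in pairs.items():
            g = root.create_group(str(pair_id))
            for key, value in meta.get(pair_id, {}).items():
                g.attrs[key] = value
            sg = g.create_group("sweeps")
            for k, s in enumerate(sweeps):
                grp = sg.create_group(str(k))
                ds = grp.create_dataset("trace", data=s.trace.data)
                ds.attrs["dt_ms"] = s.trace.dt
                ds.attrs["t0_ms"] = s.trace.t0
                ds.attrs["sampling_rate_hz"] = 1000.0 * s.trace.sample_rate_khz
                grp.attrs["holding_mv"] = s.holding_potential
                grp.attrs["bias_pa"] = s.bias_current
                grp.attrs["wall_time_s"] = s.wall_time
                grp.create_dataset("spike_times", data=s.spike_times)
                if s.protocol is not None:
                    grp.attrs["frequency_hz"] = s.protocol.frequency
                    grp.attrs["recovery_delay_ms"] = s.protocol.recovery_delay
                    grp.attrs["n_induction"] = s.protocol.n_induction
                    grp.attrs["n_recovery"] = s.protocol.n_recovery
    if truths is not None:
        sidecar = {pid: _truth_to_dict(t) for pid, t in truths.items()}
        truth_sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def load_pairs(path) -> Tuple[Dict[str, List[SweepRecording]],
                              Dict[str, GroundTruth], Dict[str, dict]]:
    """Inverse of :func:`save_pairs`; truths are empty when no sidecar."""
    pairs: Dict[str, List[SweepRecording]] = {}
    meta: Dict[str, dict] = {}
    with h5py.File(path, "r") as f:
        for pair_id, g in f["pairs"].items():
            meta[pair_id] = dict(g.attrs)
            sweeps = []
            for k in sorted(g["sweeps"], key=int):
                grp = g["sweeps"][k]
                ds = grp["trace"]
                trace = Trace(ds[...], float(ds.attrs["dt_ms"]),
                              float(ds.attrs["t0_ms"]))
                protocol = None
                if "frequency_hz" in grp.attrs:
                    protocol = StimulusProtocol(
                        frequency=float(grp.attrs["frequency_hz"]),
                        n_induction=int(grp.attrs["n_induction"]),
                        n_recovery=int(grp.attrs["n_recovery"]),
                        recovery_delay=float(grp.attrs["recovery_delay_ms"]))
                sweeps.append(SweepRecording(
                    trace=trace,
                    spike_times=grp["spike_times"][...],
                    holding_potential=float(grp.attrs["holding_mv"]),
                    bias_current=float(grp.attrs["bias_pa"]),
                    protocol=protocol,
                    wall_time=float(grp.attrs["wall_time_s"])))
            pairs[pair_id] = sweeps
    truths: Dict[str, GroundTruth] = {}
    sidecar = truth_sidecar_path(path)
    if sidecar.exists():
        blob = json.loads(sidecar.read_text())
        truths = {pid: _truth_from_dict(d) for pid, d in blob.items()}
    return pairs, truths, meta
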
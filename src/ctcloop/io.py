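"""HDF5 serialisation of rate traces and synthetic recordings."""

from __future__ import annotations

import json

import h5py
import numpy as np

from .analysis import SpikeTrain
from .network import RateTraces
from .synth import RecordingTruth, SyntheticRecording

__all__ = ["save_rate_traces", "load_rate_traces",
           "save_recording", "load_recording"]


def save_rate_traces(path, traces: RateTraces, config=None) -> None:
    """Write a RateTraces batch (rates float32, metadata in attrs)."""
    with h5py.File(path, "w") as fh:
        g = fh.create_group("rate_traces")
        g.create_dataset("times", data=traces.times)
        g.create_dataset("rates", data=traces.rates, compression="gzip")
        g.create_dataset(
            "epoch_labels",
            data=np.asarray(traces.epoch_labels, dtype="S"))
        g.attrs["dt"] = traces.dt
        g.attrs["seed"] = json.dumps(traces.seed, default=str)
        g.attrs["names"] = json.dumps(list(traces.names))
        if config is not None:
            g.attrs["config"] = json.dumps(config.to_dict())


def load_rate_traces(path) -> RateTraces:
    with h5py.File(path, "r") as fh:
        g = fh["rate_traces"]
        return RateTraces(
            dt=float(g.attrs["dt"]),
            times=g["times"][()],
            rates=g["rates"][()],
            epoch_labels=g["epoch_labels"][()].astype(str),
            seed=json.loads(g.attrs["seed"]),
            names=tuple(json.loads(g.attrs["names"])))


def save_recording(path, rec: SyntheticRecording) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("recording")
        if rec.whisker is not None:
            g.create_dataset("whisker", data=rec.whisker)
        g.attrs["whisker_fs"] = rec.whisker_fs
        g.attrs["lfp_fs"] = rec.lfp_fs
        g.attrs["seed"] = json.dumps(rec.seed, default=str)
        lg = g.create_group("lfp")
        for area, arr in rec.lfp.items():
            lg.create_dataset(area, data=arr.astype(np.float32),
                              compression="gzip")
        sg = g.create_group("spikes")
        for i, train in enumerate(rec.spikes):
            d = sg.create_dataset(f"train_{i}", data=train.times)
            d.attrs["kind"] = train.kind
        g.create_dataset("stim_times_ms", data=rec.stim_times_ms)
        tg = g.create_group("truth")
        tg.create_dataset("bout_times_ms", data=rec.truth.bout_times_ms)
        tg.attrs["pair_lags_ms"] = json.dumps(
            {f"{k[0]}:{k[1]}": v for k, v in rec.truth.pair_lags_ms.items()})
        tg.attrs["modulation"] = json.dumps(rec.truth.modulation)
        tg.attrs["shared_fraction"] = json.dumps(rec.truth.shared_fraction)
        tg.attrs["snr"] = json.dumps(rec.truth.snr)


def load_recording(path) -> SyntheticRecording:
    with h5py.File(path, "r") as fh:
        g = fh["recording"]
        truth_g = g["truth"]
        pair_lags = {}
        for key, v in json.loads(truth_g.attrs["pair_lags_ms"]).items():
            epoch, area = key.split(":")
            pair_lags[(epoch, area)] = v
        truth = RecordingTruth(
            bout_times_ms=truth_g["bout_times_ms"][()],
            pair_lags_ms=pair_lags,
            modulation=json.loads(truth_g.attrs["modulation"]),
            shared_fraction=json.loads(truth_g.attrs["shared_fraction"]),
            snr=json.loads(truth_g.attrs["snr"]))
        return SyntheticRecording(
            whisker=g["whisker"][()] if "whisker" in g else None,
            whisker_fs=float(g.attrs["whisker_fs"]),
            lfp={area: d[()] for area, d in g["lfp"].items()},
            lfp_fs=float(g.attrs["lfp_fs"]),
            spikes=[SpikeTrain(times=d[()], kind=d.attrs["kind"])
                    for _, d in sorted(g["spikes"].items())],
            stim_times_ms=g["stim_times_ms"][()],
            truth=truth,
            seed=json.loads(g.attrs["seed"]))
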
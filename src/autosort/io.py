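"""HDF5 / flat-binary persistence for every pipeline artifact.

Layout conventions: recordings store a ``data`` dataset shaped
(channels, samples) with an ``fs`` attribute; all sample indices are 0-based;
spike times are stored in samples and exposed in seconds too. Flat binary
recordings need a JSON sidecar {"dtype": ..., "n_channels": ..., "fs": ...}.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .detect import Recording, SpikeSet
from .features import FeatureSelection
from .simulate import GroundTruth
from .spc import TemperatureMap
from .templates import SortResult, Template

__all__ = [
    "save_recording", "load_recording", "load_binary_recording",
    "save_spikes", "load_spikes",
    "save_features", "load_features",
    "save_temperature_map", "load_temperature_map",
    "save_result", "load_result",
    "save_simulation", "load_simulation",
]


def save_recording(path, rec: Recording, **attrs) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data)
        d.attrs["fs"] = rec.fs
        f.attrs["fs"] = rec.fs
        for k, v in attrs.items():
            f.attrs[k] = v


def load_recording(path, fs: float | None = None) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        fs_file = f["data"].attrs.get("fs", f.attrs.get("fs"))
    fs = fs if fs is not None else fs_file
    if fs is None:
        raise ValueError("sampling rate not stored in file; pass fs explicitly")
    return Recording(np.atleast_2d(data), float(fs))


def load_binary_recording(path, sidecar=None) -> Recording:
    """Flat binary trace + JSON sidecar {dtype, n_channels, fs}."""
    path = Path(path)
    sidecar = Path(sidecar) if sidecar else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    raw = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    n_ch = int(meta.get("n_channels", 1))
    return Recording(raw.reshape(n_ch, -1), float(meta["fs"]))


def save_spikes(path, s: SpikeSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("waveforms", data=s.waveforms)
        f.create_dataset("times", data=s.times)
        f.create_dataset("times_s", data=s.times_s)
        f.create_dataset("peak_channel", data=s.peak_channel)
        f.attrs["fs"] = s.fs
        f.attrs["n_channels"] = s.n_channels


def load_spikes(path) -> SpikeSet:
    with h5py.File(path, "r") as f:
        return SpikeSet(
            waveforms=f["waveforms"][()],
            times=f["times"][()],
            peak_channel=f["peak_channel"][()],
            fs=float(f.attrs["fs"]),
            n_channels=int(f.attrs["n_channels"]),
        )


def save_features(path, features: np.ndarray, sel: FeatureSelection,
                  clustered_indices: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=features)
        f.create_dataset("ks_stat", data=sel.ks_stat)
        f.create_dataset("sorted_order", data=sel.sorted_order)
        f.create_dataset("selected", data=sel.selected)
        f.attrs["knee_index"] = sel.knee_index
        if clustered_indices is not None:
            f.create_dataset("clustered_indices", data=clustered_indices)


def load_features(path) -> tuple[np.ndarray, FeatureSelection, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        sel = FeatureSelection(
            ks_stat=f["ks_stat"][()],
            sorted_order=f["sorted_order"][()],
            knee_index=int(f.attrs["knee_index"]),
            selected=f["selected"][()],
        )
        sub = f["clustered_indices"][()] if "clustered_indices" in f else None
        return f["features"][()], sel, sub


def save_temperature_map(path, tm: TemperatureMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("temperatures", data=tm.temperatures)
        f.create_dataset("labels", data=tm.labels)
        for i, s in enumerate(tm.sizes):
            f.create_dataset(f"sizes/{i}", data=s)


def load_temperature_map(path) -> TemperatureMap:
    with h5py.File(path, "r") as f:
        temps = f["temperatures"][()]
        labels = f["labels"][()]
        sizes = [f[f"sizes/{i}"][()] for i in range(temps.size)]
    return TemperatureMap(temperatures=temps, labels=labels, sizes=sizes)


def save_result(path, result: SortResult, times: np.ndarray | None = None,
                fs: float | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=result.labels)
        if times is not None:
            f.create_dataset("times", data=times)
            if fs:
                f.create_dataset("times_s", data=np.asarray(times) / fs)
                f.attrs["fs"] = fs
        if result.t_border is not None:
            f.attrs["t_border"] = result.t_border
        for t in result.templates:
            g = f.create_group(f"templates/{t.cluster_id}")
            g.create_dataset("centroid", data=t.centroid)
            g.attrs["sigma_t"] = t.sigma_t
            g.attrs["n_members"] = t.n_members
            if t.origin is not None:
                g.attrs["origin_temperature"] = t.origin[0]
                g.attrs["origin_rank"] = t.origin[1]


def load_result(path) -> SortResult:
    with h5py.File(path, "r") as f:
        labels = f["labels"][()]
        templates = []
        if "templates" in f:
            for cid in sorted(f["templates"], key=int):
                g = f[f"templates/{cid}"]
                origin = None
                if "origin_temperature" in g.attrs:
                    origin = (int(g.attrs["origin_temperature"]),
                              int(g.attrs["origin_rank"]))
                templates.append(Template(
                    cluster_id=int(cid), centroid=g["centroid"][()],
                    sigma_t=float(g.attrs["sigma_t"]),
                    n_members=int(g.attrs["n_members"]), origin=origin,
                ))
        t_border = int(f.attrs["t_border"]) if "t_border" in f.attrs else None
    return SortResult(labels=labels, templates=templates, t_border=t_border)


def save_simulation(path, rec: Recording, gt: GroundTruth) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=rec.data)
        d.attrs["fs"] = rec.fs
        f.attrs["fs"] = rec.fs
        g = f.create_group("ground_truth")
        g.create_dataset("times", data=gt.times)
        g.create_dataset("units", data=gt.units)
        g.attrs["n_units"] = gt.n_units
        if gt.templates is not None:
            g.create_dataset("templates", data=gt.templates)


def load_simulation(path) -> tuple[Recording, GroundTruth]:
    with h5py.File(path, "r") as f:
        rec = Recording(np.atleast_2d(f["data"][()]), float(f.attrs["fs"]))
        g = f["ground_truth"]
        gt = GroundTruth(
            times=g["times"][()], units=g["units"][()],
            n_units=int(g.attrs["n_units"]), fs=rec.fs,
            templates=g["templates"][()] if "templates" in g else None,
        )
    return rec, gt
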
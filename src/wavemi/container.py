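"""HDF5 artifact container: epochs, scalograms, images and models.

One hierarchical array store holds every artifact type behind a small
schema (``kind`` + ``schema_version`` root attributes, JSON-encoded
metadata).  Datasets are created with ``track_times=False`` so two writes
of identical content are byte-identical, which makes round-trips and
reproducibility checkable by checksum.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np

from wavemi.cnn import CNNConfig, CNNModel
from wavemi.cwt import MotherWavelet, Scalogram
from wavemi.images import MIImage
from wavemi.synthetic import CHANNELS, EEGEpoch, EpochSet, ERDParams

SCHEMA_VERSION = 1


def _dset(group: h5py.Group, name: str, data) -> None:
    group.create_dataset(name, data=data, track_times=False)


def _require_kind(f: h5py.File, kind: str, path) -> None:
    found = f.attrs.get("kind")
    if found != kind:
        raise ValueError(f"{path}: expected a {kind!r} container, found {found!r}")


def _wavelet_meta(w: MotherWavelet) -> str:
    return json.dumps({"kind": w.kind, "sigma": w.sigma, "mu": w.mu})


def _wavelet_from_meta(meta: str) -> MotherWavelet:
    d = json.loads(meta)
    return MotherWavelet(d["kind"], d["sigma"], d["mu"])


def write_epochs(epoch_set: EpochSet, path) -> None:
    """Write an EpochSet; lossless for data, labels and generator params."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "epochs"
        _dset(f, "data", epoch_set.data_array())
        _dset(f, "labels", np.array([ep.label for ep in epoch_set], dtype="S8"))
        f.attrs["channels"] = list(epoch_set.channels)
        f.attrs["fs"] = epoch_set.fs
        f.attrs["cue_onset_s"] = epoch_set.epochs[0].cue_onset_s
        if epoch_set.seed is not None:
            f.attrs["seed"] = epoch_set.seed
        if epoch_set.params is not None:
            f.attrs["params"] = json.dumps(dataclasses.asdict(epoch_set.params))


def _read_container_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        _require_kind(f, "epochs", path)
        data = f["data"][:]
        labels = [l.decode() for l in f["labels"][:]]
        channels = tuple(f.attrs["channels"])
        fs = float(f.attrs["fs"])
        cue = float(f.attrs["cue_onset_s"])
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        params = None
        if "params" in f.attrs:
            d = json.loads(f.attrs["params"])
            d["task_window_s"] = tuple(d["task_window_s"])
            params = ERDParams(**d)

    missing = set(CHANNELS) - set(channels)
    if missing:
        raise ValueError(f"{path}: missing required channels {sorted(missing)}")
    order = [channels.index(ch) for ch in CHANNELS]
    epochs = [
        EEGEpoch(channels=CHANNELS, data=trial[order], fs=fs,
                 label=label, cue_onset_s=cue)
        for trial, label in zip(data, labels)
    ]
    return EpochSet(epochs=epochs, seed=seed, params=params)


def read_epochs(path, format: str = "container",
                cut_s: tuple[float, float] = (-3.0, 5.0)) -> EpochSet:
    """Read an EpochSet; channel order is normalized to C3, Cz, C4.

    ``format='container'`` reads this package's HDF5 layout.
    ``format='edf_gdf'`` ingests a raw GDF/EDF recording via mne (optional
    dependency), cutting ``cut_s`` around each left/right cue event.
    ``format='matrix'`` reads a MATLAB container with variables ``X``
    (trials x channels x samples), ``y`` (1/2 class codes), ``fs`` and
    optionally ``cue_onset_s``.
    """
    if format == "container":
        return _read_container_epochs(path)
    if format == "edf_gdf":
        return _read_gdf_epochs(path, cut_s)
    if format == "matrix":
        return _read_matrix_epochs(path)
    raise ValueError(f"unknown format {format!r}")


def _read_gdf_epochs(path, cut_s: tuple[float, float]) -> EpochSet:
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional extra
        raise ImportError(
            "reading GDF/EDF files requires the optional 'mne' dependency"
        ) from err
    reader = (mne.io.read_raw_gdf if str(path).lower().endswith(".gdf")
              else mne.io.read_raw_edf)
    raw = reader(path, preload=True, verbose="error")
    have = {name.split("EEG:")[-1].strip(): name for name in raw.ch_names}
    missing = set(CHANNELS) - set(have)
    if missing:
        raise ValueError(f"{path}: missing required channels {sorted(missing)}")
    raw.pick([have[ch] for ch in CHANNELS])
    fs = raw.info["sfreq"]
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    cue_codes = {"769": "left", "770": "right"}
    keep = {event_id[k]: v for k, v in cue_codes.items() if k in event_id}
    if not keep:
        raise ValueError(f"{path}: no left/right cue annotations found")
    data = raw.get_data()
    order = [raw.ch_names.index(have[ch]) for ch in CHANNELS]
    epochs = []
    for sample, _, code in events:
        if code not in keep:
            continue
        i0 = sample + int(round(cut_s[0] * fs))
        i1 = sample + int(round(cut_s[1] * fs))
        if i0 < 0 or i1 > data.shape[1]:
            continue
        epochs.append(EEGEpoch(
            channels=CHANNELS, data=data[order, i0:i1] * 1e6, fs=fs,
            label=keep[code], cue_onset_s=-cut_s[0],
        ))
    return EpochSet(epochs=epochs)


def _read_matrix_epochs(path) -> EpochSet:
    from scipy.io import loadmat

    mat = loadmat(path)
    for key in ("X", "y", "fs"):
        if key not in mat:
            raise ValueError(f"{path}: matrix container must provide {key!r}")
    data = np.asarray(mat["X"], dtype=float)
    if data.ndim != 3 or data.shape[1] != len(CHANNELS):
        raise ValueError(f"{path}: X must be (trials, 3, samples), got {data.shape}")
    codes = np.ravel(mat["y"]).astype(int)
    fs = float(np.ravel(mat["fs"])[0])
    cue = float(np.ravel(mat.get("cue_onset_s", [3.0]))[0])
    label_of = {1: "left", 2: "right"}
    epochs = [
        EEGEpoch(channels=CHANNELS, data=trial, fs=fs,
                 label=label_of[code], cue_onset_s=cue)
        for trial, code in zip(data, codes)
    ]
    return EpochSet(epochs=epochs)


def write_scalograms(scalograms: list[Scalogram], path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "scalograms"
        for i, sc in enumerate(scalograms):
            g = f.create_group(f"scalogram_{i:05d}")
            g.attrs["channel"] = sc.channel
            g.attrs["is_power"] = sc.is_power
            g.attrs["wavelet"] = _wavelet_meta(sc.wavelet)
            _dset(g, "freqs", sc.freqs)
            _dset(g, "times", sc.times)
            _dset(g, "values", sc.values)
            if sc.coeffs is not None:
                _dset(g, "coeffs", sc.coeffs)


def read_scalograms(path) -> list[Scalogram]:
    out = []
    with h5py.File(path, "r") as f:
        _require_kind(f, "scalograms", path)
        for name in sorted(f):
            g = f[name]
            out.append(Scalogram(
                channel=g.attrs["channel"],
                freqs=g["freqs"][:], times=g["times"][:], values=g["values"][:],
                wavelet=_wavelet_from_meta(g.attrs["wavelet"]),
                coeffs=g["coeffs"][:] if "coeffs" in g else None,
                is_power=bool(g.attrs["is_power"]),
            ))
    return out


def write_images(images: list[MIImage], path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "images"
        for i, img in enumerate(images):
            g = f.create_group(f"image_{i:05d}")
            _dset(g, "values", img.values)
            g.attrs["row_map"] = json.dumps(img.row_map)
            g.attrs["window"] = list(img.window)
            g.attrs["label"] = str(img.label) if img.label is not None else ""
            g.attrs["normalized"] = img.normalized


def read_images(path) -> list[MIImage]:
    out = []
    with h5py.File(path, "r") as f:
        _require_kind(f, "images", path)
        for name in sorted(f):
            g = f[name]
            row_map = [tuple(r) for r in json.loads(g.attrs["row_map"])]
            out.append(MIImage(
                values=g["values"][:], row_map=row_map,
                window=tuple(g.attrs["window"]),
                label=g.attrs["label"] or None,
                normalized=bool(g.attrs["normalized"]),
            ))
    return out


def write_model(model: CNNModel, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["kind"] = "model"
        f.attrs["config"] = json.dumps(dataclasses.asdict(model.config))
        for name in ("conv_w", "conv_b", "fc_w", "fc_b"):
            _dset(f, name, getattr(model, name))


def read_model(path) -> CNNModel:
    with h5py.File(path, "r") as f:
        _require_kind(f, "model", path)
        config = CNNConfig(**json.loads(f.attrs["config"]))
        return CNNModel(
            conv_w=f["conv_w"][:], conv_b=f["conv_b"][:],
            fc_w=f["fc_w"][:], fc_b=f["fc_b"][:], config=config,
        )
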
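"""HDF5 array containers and EDF reading.

Layouts (all HDF5):

* epochs:   datasets ``data`` [n, ch, samp], ``labels``, ``domains``;
            attrs ``fs``, ``channel_names``
* features: datasets ``values`` [n, ch, band], ``labels``, ``domains``;
            attrs ``band_names``, ``band_edges``, ``channel_names``
* images:   datasets ``images`` [n, H, W, band], ``labels``, ``domains``,
            ``mask``; attrs ``resolution``, ``bands``, ``extent``, ``fill``,
            ``normalized``
* checkpoints: config JSON + flat parameter/statistics arrays, format-versioned
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .features import BandSpec, DEFeatures, EpochedEEG
from .topomap import TopoImages

__all__ = [
    "save_epochs", "load_epochs",
    "save_features", "load_features",
    "save_images", "load_images",
    "save_checkpoint", "load_checkpoint",
    "load_edf",
]

_CHECKPOINT_VERSION = 1


def save_epochs(path, epochs: EpochedEEG) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.create_dataset("domains", data=epochs.domains)
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["channel_names"] = [n.encode() for n in epochs.channel_names]


def load_epochs(path) -> EpochedEEG:
    with h5py.File(path, "r") as f:
        return EpochedEEG(
            data=f["data"][...],
            fs=float(f.attrs["fs"]),
            labels=f["labels"][...],
            domains=f["domains"][...],
            channel_names=[n.decode() if isinstance(n, bytes) else str(n)
                           for n in f.attrs["channel_names"]],
        )


def save_features(path, feats: DEFeatures) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=feats.values)
        f.create_dataset("labels", data=feats.labels)
        f.create_dataset("domains", data=feats.domains)
        f.attrs["band_names"] = [b.name.encode() for b in feats.bands]
        f.attrs["band_edges"] = [(b.lo, b.hi) for b in feats.bands]
        f.attrs["channel_names"] = [n.encode() for n in feats.channel_names]


def load_features(path) -> DEFeatures:
    with h5py.File(path, "r") as f:
        names = [n.decode() if isinstance(n, bytes) else str(n)
                 for n in f.attrs["band_names"]]
        edges = np.asarray(f.attrs["band_edges"], dtype=float)
        return DEFeatures(
            values=f["values"][...],
            bands=tuple(BandSpec(n, lo, hi) for n, (lo, hi) in zip(names, edges)),
            labels=f["labels"][...],
            domains=f["domains"][...],
            channel_names=[n.decode() if isinstance(n, bytes) else str(n)
                           for n in f.attrs["channel_names"]],
        )


def save_images(path, topo: TopoImages) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("images", data=topo.images)
        f.create_dataset("labels", data=topo.labels)
        f.create_dataset("domains", data=topo.domains)
        f.create_dataset("mask", data=topo.mask)
        f.attrs["resolution"] = topo.resolution
        f.attrs["bands"] = [b.encode() for b in topo.bands]
        f.attrs["extent"] = list(topo.extent)
        f.attrs["fill"] = topo.fill
        f.attrs["normalized"] = topo.normalized or ""


def load_images(path) -> TopoImages:
    with h5py.File(path, "r") as f:
        normalized = f.attrs["normalized"] or None
        if isinstance(normalized, bytes):
            normalized = normalized.decode() or None
        return TopoImages(
            images=f["images"][...],
            extent=tuple(float(v) for v in f.attrs["extent"]),
            mask=f["mask"][...].astype(bool),
            bands=tuple(b.decode() if isinstance(b, bytes) else str(b)
                        for b in f.attrs["bands"]),
            labels=f["labels"][...],
            domains=f["domains"][...],
            fill=float(f.attrs["fill"]),
            normalized=normalized,
        )


def save_checkpoint(path, results) -> None:
    """Persist a TDANNResults: config, network spec, parameters, BN stats."""
    from dataclasses import asdict

    state = results.networks.state_dict()
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = _CHECKPOINT_VERSION
        cfg = asdict(results.config)
        cfg["kernel_bank"] = None if results.config.kernel_bank is None else {
            "sigmas": list(results.config.kernel_bank.sigmas),
            "weights": list(results.config.kernel_bank.weights),
        }
        f.attrs["config"] = json.dumps(cfg, default=str)
        f.attrs["network_spec"] = json.dumps(asdict(results.networks.spec))
        f.attrs["best_epoch"] = results.best_epoch
        f.attrs["best_val_loss"] = results.best_val_loss
        for part, sub in state.items():
            grp = f.create_group(part)
            pgrp = grp.create_group("params")
            for name, arr in sub["params"].items():
                pgrp.create_dataset(name, data=arr)
            rgrp = grp.create_group("running")
            for layer_i, stats in sub.get("running", {}).items():
                lgrp = rgrp.create_group(str(layer_i))
                for dom, (mean, var) in stats.items():
                    dgrp = lgrp.create_group(str(dom))
                    dgrp.create_dataset("mean", data=mean)
                    dgrp.create_dataset("var", data=var)


def load_checkpoint(path):
    """Rebuild a TDANNResults (without history) from a checkpoint file."""
    import pandas as pd

    from .losses import KernelBank
    from .model import AdaptationConfig, TDANNResults
    from .networks import build_preset

    with h5py.File(path, "r") as f:
        if int(f.attrs["format_version"]) != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {f.attrs['format_version']}")
        cfg_d = json.loads(f.attrs["config"])
        bank = cfg_d.pop("kernel_bank", None)
        cfg_d["kernel_bank"] = None if bank is None else KernelBank(
            tuple(bank["sigmas"]), tuple(bank["weights"]))
        cfg_d["discriminator_hidden"] = tuple(cfg_d.get("discriminator_hidden", ()))
        cfg = AdaptationConfig(**cfg_d)
        spec_d = json.loads(f.attrs["network_spec"])
        nets = build_preset(
            cfg.preset, n_classes=cfg.n_classes, n_domains=2, seed=cfg.seed,
            input_hw=int(spec_d["input_hw"]), adaptive_norm=cfg.adaptive_norm,
            discriminator_hidden=cfg.discriminator_hidden,
        )
        state = {}
        for part in ("generator", "classifier", "discriminator"):
            grp = f[part]
            params = {name: grp["params"][name][...] for name in grp["params"]}
            running = {
                int(layer_i): {
                    int(dom): (lgrp[dom]["mean"][...], lgrp[dom]["var"][...])
                    for dom in lgrp
                }
                for layer_i, lgrp in grp["running"].items()
            }
            state[part] = {"params": params, "running": running}
        nets.load_state_dict(state)
        return TDANNResults(
            networks=nets, config=cfg, history=pd.DataFrame(),
            best_epoch=int(f.attrs["best_epoch"]),
            best_val_loss=float(f.attrs["best_val_loss"]),
        )


def load_edf(path, montage=None, verbose: bool = False) -> tuple[np.ndarray, float, list[str]]:
    """Read a continuous EDF recording via mne.

    Returns ``(signal [n_channels, n_samples], fs, channel_names)``.  When a
    `Montage` is given, channels are matched case-insensitively to its names
    and returned in montage order; missing channels raise an error.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose=verbose)
    data = raw.get_data()
    names = list(raw.ch_names)
    if montage is not None:
        lower = {n.lower(): i for i, n in enumerate(names)}
        missing = [n for n in montage.names if n.lower() not in lower]
        if missing:
            raise KeyError(f"EDF is missing montage channels: {missing}")
        order = [lower[n.lower()] for n in montage.names]
        data = data[order]
        names = list(montage.names)
    return data, float(raw.info["sfreq"]), names
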
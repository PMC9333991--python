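"""HDF5 and JSON persistence for stacks, movies, and ground truth."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .spectroscopy import HemoMovie, ReflectanceStack


def save_reflectance_h5(path, stack: ReflectanceStack, landmarks=None):
    """One dataset per wavelength; acquisition metadata as attributes."""
    with h5py.File(path, "w") as f:
        for i, wl in enumerate(stack.wavelengths):
            f.create_dataset(f"reflectance_{int(round(wl))}nm",
                             data=stack.data[i], compression="gzip")
        f.create_dataset("mask", data=stack.mask.astype(np.uint8))
        f.attrs["wavelengths_nm"] = np.asarray(stack.wavelengths)
        f.attrs["frame_rate_hz"] = stack.frame_rate
        if landmarks:
            f.attrs["landmarks"] = json.dumps(
                {k: list(v) for k, v in landmarks.items()})


def load_reflectance_h5(path) -> ReflectanceStack:
    with h5py.File(path, "r") as f:
        wavelengths = tuple(float(w) for w in f.attrs["wavelengths_nm"])
        data = np.stack([f[f"reflectance_{int(round(wl))}nm"][()]
                         for wl in wavelengths])
        return ReflectanceStack(data=data, wavelengths=wavelengths,
                                frame_rate=float(f.attrs["frame_rate_hz"]),
                                mask=f["mask"][()].astype(bool))


def save_hemo_h5(path, movie: HemoMovie):
    with h5py.File(path, "w") as f:
        for name in ("hbo", "hbr", "hbt"):
            f.create_dataset(name, data=getattr(movie, name),
                             compression="gzip")
        f.create_dataset("mask", data=movie.mask.astype(np.uint8))
        f.attrs["frame_rate_hz"] = movie.frame_rate
        f.attrs["space"] = movie.space


def load_hemo_h5(path) -> HemoMovie:
    with h5py.File(path, "r") as f:
        return HemoMovie(hbo=f["hbo"][()], hbr=f["hbr"][()], hbt=f["hbt"][()],
                         frame_rate=float(f.attrs["frame_rate_hz"]),
                         mask=f["mask"][()].astype(bool),
                         space=str(f.attrs["space"]))


def write_json(path, obj):
    """Deterministic JSON (sorted keys, fixed float repr)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default) + "\n")
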
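"""File formats and run manifests.

Sinograms travel as CSV (rows = angles, columns = sensors; a header comment
records the convention) or single-channel 32-bit float TIFF.  Images are
32-bit float TIFF or 16-bit PNG with the scale recorded in a sidecar text
file.  Configs and manifests are flat JSON objects; unknown config keys are
rejected so typos never pass silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

SINOGRAM_HEADER = "rows = angles (k), columns = sensors (j)"

CONFIG_KEYS = frozenset(
    {
        "sensors",
        "angles",
        "sensor_width",
        "angular_step",
        "image_side",
        "omega_radius",
        "n_subpixel",
        "sigma",
        "seed",
        "method",
        "filter",
        "window",
        "mask_mode",
        "epsilon",
        "omega",
        "lam",
        "iters",
        "ordering",
        "max_passes",
    }
)


def write_sinogram_csv(path, s: np.ndarray) -> None:
    np.savetxt(path, np.asarray(s, dtype=float), delimiter=",",
               header=SINOGRAM_HEADER)


def read_sinogram_csv(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=",", comments="#"))


def write_tiff(path, arr: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=float)


def write_png16(path, arr: np.ndarray) -> None:
    """16-bit PNG with the affine scale recorded in a `.scale.txt` sidecar."""
    import imageio.v3 as iio

    arr = np.asarray(arr, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    span = hi - lo if hi > lo else 1.0
    scaled = np.round((arr - lo) / span * 65535).astype(np.uint16)
    iio.imwrite(path, scaled)
    sidecar = Path(str(path) + ".scale.txt")
    sidecar.write_text(f"offset {lo!r}\nspan {span!r}\n")


def read_png16(path) -> np.ndarray:
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(path), dtype=float) / 65535.0
    sidecar = Path(str(path) + ".scale.txt")
    lo, span = 0.0, 1.0
    if sidecar.exists():
        for line in sidecar.read_text().splitlines():
            key, val = line.split()
            if key == "offset":
                lo = float(val)
            elif key == "span":
                span = float(val)
    return raw * span + lo


def read_array(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_sinogram_csv(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return read_tiff(path)
    if path.suffix.lower() == ".png":
        return read_png16(path)
    raise ValueError(f"unsupported file type: {path.suffix}")


def write_array(path, arr: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        write_sinogram_csv(path, arr)
    elif path.suffix.lower() in (".tif", ".tiff"):
        write_tiff(path, arr)
    elif path.suffix.lower() == ".png":
        write_png16(path, arr)
    else:
        raise ValueError(f"unsupported file type: {path.suffix}")


def read_config(path) -> dict:
    """Flat JSON config; unknown keys are rejected."""
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat JSON object")
    unknown = set(cfg) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def write_manifest(params: dict, path) -> None:
    """Record every parameter actually used, plus library versions."""
    manifest = dict(params)
    manifest["versions"] = {
        "tomoreduce": _package_version(),
        "numpy": np.__version__,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("tomoreduce")
    except Exception:
        return "unknown"
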
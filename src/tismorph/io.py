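"""Reading and writing of pipeline file formats.

* Multimodal NLO FOVs: multi-page TIFF, one page per channel, with a
  JSON description carrying channel names, pixel size and labels.
* RI tomograms: HDF5 with dataset ``"ri"`` and attributes
  ``voxel_size_um`` (dx, dy, dz), ``n_medium`` and labels.
* Ground truth: JSON sidecars; dataset manifests: CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .preprocess import CHANNELS, MultimodalImage
from .qpi import Tomogram


def write_multimodal_tiff(image: MultimodalImage, path: str | Path) -> Path:
    path = Path(path)
    names = [n for n in CHANNELS if n in image.channels] + [
        n for n in image.channels if n not in CHANNELS
    ]
    stack = np.stack([image.channels[n] for n in names]).astype(np.float32)
    desc = json.dumps(
        {
            "channels": names,
            "pixel_size_um": image.pixel_size_um,
            "fov_id": image.fov_id,
            "condition": image.condition,
            "time_point": image.time_point,
        }
    )
    tifffile.imwrite(path, stack, description=desc, metadata=None)
    return path


def read_multimodal_tiff(path: str | Path) -> MultimodalImage:
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            desc = tif.pages[0].description
    except Exception as exc:  # corrupt or non-TIFF input
        raise OSError(f"cannot read multimodal TIFF {path}: {exc}") from exc
    meta = json.loads(desc)
    names = meta["channels"]
    if stack.ndim == 2:
        stack = stack[None]
    if len(names) != stack.shape[0]:
        raise OSError(f"channel metadata of {path} does not match page count")
    return MultimodalImage(
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        pixel_size_um=float(meta["pixel_size_um"]),
        fov_id=meta.get("fov_id", ""),
        condition=meta.get("condition", ""),
        time_point=meta.get("time_point", ""),
    )


def write_tomogram_h5(tomo: Tomogram, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("ri", data=tomo.ri.astype(np.float32), compression="gzip")
        dset.attrs["voxel_size_um"] = tomo.voxel_size_um
        dset.attrs["n_medium"] = tomo.n_medium
        dset.attrs["tomo_id"] = tomo.tomo_id
        dset.attrs["condition"] = tomo.condition
        dset.attrs["time_point"] = tomo.time_point
    return path


def read_tomogram_h5(path: str | Path) -> Tomogram:
    with h5py.File(path, "r") as f:
        dset = f["ri"]
        return Tomogram(
            ri=dset[...].astype(float),
            voxel_size_um=tuple(dset.attrs["voxel_size_um"]),
            n_medium=float(dset.attrs["n_medium"]),
            tomo_id=str(dset.attrs.get("tomo_id", "")),
            condition=str(dset.attrs.get("condition", "")),
            time_point=str(dset.attrs.get("time_point", "")),
        )


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
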
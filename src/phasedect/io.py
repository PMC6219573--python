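"""HDF5 / TIFF interchange for the pipeline stages.

HDF5 is the canonical format (arrays + attributes in one file); TIFF export
is provided for viewing.  Geometry travels as JSON in an HDF5 attribute so
files are self-describing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .forward import AcquisitionGeometry, SteppingFrames
from .recon import SlicePair
from .stepping import ChannelSinograms

__all__ = [
    "write_stepping_frames", "read_stepping_frames",
    "write_channels", "read_channels",
    "write_slice_pair", "read_slice_pair",
    "export_tiff",
]


def _geometry_json(geometry: AcquisitionGeometry) -> str:
    return json.dumps(dataclasses.asdict(geometry))


def _geometry_from_json(blob: str) -> AcquisitionGeometry:
    return AcquisitionGeometry(**json.loads(blob))


def write_stepping_frames(path, frames: SteppingFrames) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("sample", data=frames.sample)
        fh.create_dataset("reference", data=frames.reference)
        fh.attrs["geometry"] = _geometry_json(frames.geometry)
        fh.attrs["seed"] = -1 if frames.seed is None else frames.seed


def read_stepping_frames(path) -> SteppingFrames:
    with h5py.File(path, "r") as fh:
        seed = int(fh.attrs["seed"])
        return SteppingFrames(
            sample=fh["sample"][()],
            reference=fh["reference"][()],
            geometry=_geometry_from_json(fh.attrs["geometry"]),
            seed=None if seed < 0 else seed,
        )


def write_channels(path, channels: ChannelSinograms,
                   geometry: AcquisitionGeometry | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("transmission", data=channels.transmission)
        fh.create_dataset("dphase", data=channels.dphase)
        fh.create_dataset("visibility", data=channels.visibility_ratio)
        fh.create_dataset("valid", data=channels.valid)
        if geometry is not None:
            fh.attrs["geometry"] = _geometry_json(geometry)


def read_channels(path):
    with h5py.File(path, "r") as fh:
        ch = ChannelSinograms(
            transmission=fh["transmission"][()],
            dphase=fh["dphase"][()],
            visibility_ratio=fh["visibility"][()],
            valid=fh["valid"][()].astype(bool),
        )
        geo = None
        if "geometry" in fh.attrs:
            geo = _geometry_from_json(fh.attrs["geometry"])
    return ch, geo


def write_slice_pair(path, pair: SlicePair) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("mu", data=pair.mu)
        fh.create_dataset("delta", data=pair.delta)
        fh.attrs["pixel_um"] = pair.pixel_um
        fh.attrs["provenance"] = json.dumps(pair.provenance or {})


def read_slice_pair(path) -> SlicePair:
    with h5py.File(path, "r") as fh:
        return SlicePair(
            mu=fh["mu"][()],
            delta=fh["delta"][()],
            pixel_um=float(fh.attrs["pixel_um"]),
            provenance=json.loads(fh.attrs.get("provenance", "{}")),
        )


def export_tiff(directory, maps: dict[str, np.ndarray]) -> list[Path]:
    """Write each named map as a 32-bit float TIFF; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, arr in maps.items():
        p = directory / f"{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        written.append(p)
    return written
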
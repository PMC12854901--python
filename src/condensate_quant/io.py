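"""TIFF + JSON-sidecar IO.

Stacks are multi-page TIFFs (one page per z-slice) with a ``<stem>.json``
sidecar carrying voxel dimensions in μm and the channel label. Synthetic
ground truth is written as a TIFF label volume plus a JSON file of scalars.
Intensities are float32 by default; 8- or 12-bit quantisation (rounding,
clipping at the bit-depth ceiling) is available at export.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile

from .core import VolumetricImage
from .synthetic import SyntheticGroundTruth

__all__ = [
    "save_volumetric",
    "load_volumetric",
    "save_scene",
    "save_two_channel_scene",
    "load_ground_truth",
]


def save_volumetric(
    img: VolumetricImage,
    path: Path | str,
    bit_depth: Optional[int] = None,
    extra_sidecar: Optional[dict] = None,
) -> Path:
    """Write a stack and its sidecar; returns the TIFF path."""
    path = Path(path).with_suffix(".tif")
    data = img.data
    if bit_depth is None:
        data = data.astype(np.float32)
    elif bit_depth in (8, 12):
        ceil = 2**bit_depth - 1
        data = np.clip(np.round(data), 0, ceil).astype(np.uint8 if bit_depth == 8 else np.uint16)
    else:
        raise ValueError(f"bit_depth must be None, 8 or 12, got {bit_depth}")
    tifffile.imwrite(path, data)
    sidecar = {
        "voxel_size_um": list(img.voxel_size),
        "channel": img.channel,
        "bit_depth": bit_depth,
    }
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_volumetric(
    path: Path | str,
    voxel_size: Optional[tuple[float, float, float]] = None,
    channel: Optional[str] = None,
) -> VolumetricImage:
    """Read a stack; voxel size and channel come from the sidecar unless
    overridden."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    if voxel_size is None:
        if "voxel_size_um" not in sidecar:
            raise ValueError(f"no voxel size: neither an override nor {sidecar_path} provides it")
        voxel_size = tuple(sidecar["voxel_size_um"])
    return VolumetricImage(
        data=np.asarray(data, dtype=float),
        voxel_size=voxel_size,
        channel=channel or sidecar.get("channel", "ch1"),
    )


def save_scene(
    img: VolumetricImage,
    gt: Optional[SyntheticGroundTruth],
    stem: Path | str,
    bit_depth: Optional[int] = None,
) -> Path:
    """Write a scene and, when present, its ground-truth labels and scalars."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    extra = {}
    if gt is not None:
        labels_path = stem.parent / f"{stem.name}_labels.tif"
        tifffile.imwrite(labels_path, gt.condensate_labels.astype(np.uint16))
        gt_path = stem.parent / f"{stem.name}_ground_truth.json"
        gt_path.write_text(
            json.dumps(
                {
                    "true_c_dil": gt.true_c_dil,
                    "true_c_den": gt.true_c_den,
                    "true_c_tot": gt.true_c_tot,
                    "true_volume_fraction": gt.true_volume_fraction,
                    "per_object_volumes_um3": gt.per_object_volumes,
                    "params": gt.params.model_dump(),
                },
                indent=2,
            )
        )
        extra["ground_truth_path"] = gt_path.name
    return save_volumetric(img, stem, bit_depth=bit_depth, extra_sidecar=extra)


def save_two_channel_scene(
    ch1: VolumetricImage,
    ch2: VolumetricImage,
    gt: Optional[SyntheticGroundTruth],
    stem: Path | str,
    bit_depth: Optional[int] = None,
) -> tuple[Path, Path]:
    """Write a two-channel scene as ``<stem>_ch1.tif`` / ``<stem>_ch2.tif``
    (ground truth attached to channel 1)."""
    stem = Path(stem)
    p1 = save_scene(ch1, gt, stem.parent / f"{stem.name}_ch1", bit_depth=bit_depth)
    p2 = save_volumetric(ch2, stem.parent / f"{stem.name}_ch2", bit_depth=bit_depth)
    return p1, p2


def load_ground_truth(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())
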
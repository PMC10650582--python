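"""NIfTI + JSON-sidecar I/O for CEST volumes and phantom maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .bm_simulator import CestVolume
from .phantom_geometry import LabelMap

__all__ = ["save_volume", "load_volume", "save_label_map", "load_label_map"]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[:-len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_volume(vol: CestVolume, path: str | Path) -> Path:
    """Write data as H x W x dyn NIfTI with offsets/m0/mask in a sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), np.eye(4)),
             str(path))
    sidecar = {
        "offsets_ppm": vol.offsets_ppm.tolist(),
        "m0": vol.m0.tolist(),
        "mask": vol.mask.astype(int).tolist(),
        "meta": _jsonable(vol.meta),
    }
    sidecar_path = _sidecar_path(path)
    sidecar_path.write_text(json.dumps(sidecar))
    return sidecar_path


def load_volume(path: str | Path) -> CestVolume:
    path = Path(path)
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    sidecar = json.loads(_sidecar_path(path).read_text())
    return CestVolume(
        data=data,
        offsets_ppm=np.array(sidecar["offsets_ppm"]),
        m0=np.array(sidecar["m0"]),
        mask=np.array(sidecar["mask"], dtype=bool),
        meta=sidecar.get("meta", {}),
    )


def save_label_map(lm: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(lm.labels.astype(np.int16), np.eye(4)),
             str(path))
    sidecar_path = _sidecar_path(path)
    sidecar_path.write_text(json.dumps(
        {"foreground": lm.foreground.astype(int).tolist()}))
    return sidecar_path


def load_label_map(path: str | Path) -> LabelMap:
    path = Path(path)
    labels = np.asarray(nib.load(str(path)).dataobj, dtype=np.int32)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        fg = np.array(json.loads(sidecar.read_text())["foreground"],
                      dtype=bool)
    else:  # arbitrary user label map: foreground = labelled area
        fg = labels > 0
    return LabelMap(labels=labels, foreground=fg)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
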
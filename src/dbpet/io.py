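"""NIfTI volume I/O and sidecar annotation files.

Volumes are written as .nii.gz with the isotropic voxel spacing in the
affine; acquisition duration and the image-set tag travel in the NIfTI
``descrip`` field.  Lesion annotations and phantom/experiment configs are
plain YAML.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import Lesion
from .volume import PETVolume

__all__ = ["save_volume", "load_volume", "save_lesions", "load_lesions"]


def save_volume(vol: PETVolume, path) -> None:
    affine = np.diag([vol.spacing, vol.spacing, vol.spacing, 1.0])
    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), affine)
    img.header["descrip"] = f"duration={vol.duration_min:g};meta={vol.meta}".encode()
    img.header.set_zooms((vol.spacing,) * 3)
    nib.save(img, str(path))


def load_volume(path) -> PETVolume:
    img = nib.load(str(path))
    spacing = float(img.header.get_zooms()[0])
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode()
    duration, meta = 1.0, ""
    for part in descrip.split(";"):
        if part.startswith("duration="):
            duration = float(part.split("=", 1)[1])
        elif part.startswith("meta="):
            meta = part.split("=", 1)[1]
    return PETVolume(values=np.asarray(img.dataobj, dtype=np.float64),
                     spacing=spacing, duration_min=duration, meta=meta)


def save_lesions(lesions: list[Lesion], path) -> None:
    payload = [
        {"kind": l.kind, "center": list(l.center), "diameter_mm": l.diameter_mm,
         "suv": l.suv, "edge_blur_mm": l.edge_blur_mm}
        for l in lesions
    ]
    Path(path).write_text(yaml.safe_dump({"lesions": payload}, sort_keys=False))


def load_lesions(path) -> list[Lesion]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        Lesion(kind=d["kind"], center=tuple(d["center"]),
               diameter_mm=d["diameter_mm"], suv=d["suv"],
               edge_blur_mm=d.get("edge_blur_mm", 0.0))
        for d in payload["lesions"]
    ]
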
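"""File formats: NIfTI fields, TCK/TRK tractograms, JSON landmarks, TSV.

Volume dialects (documented in a sidecar JSON next to each NIfTI):

* tensor: 4-D float volume, 6 components per voxel in lower-triangular
  order (xx, xy, xz, yy, yz, zz), mm^2/s;
* FOD: 4-D float volume of real even-order SH coefficients with the basis
  ordering identifier and maximum order in the sidecar — a mismatched
  ordering identifier is a hard error on read.

TCK is the canonical tractogram format (points in world/RAS+ mm, float32);
TRK is supported for interoperability with its voxel-space header
convention converted explicitly through the reference grid.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram as NibTractogram
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

from .phantom import Landmarks
from .shbasis import REAL_SYM_BASIS_ID
from .space import AffineGrid, FODField, TensorField
from .tracking import Streamline, Tractogram


def _sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suff in (".nii.gz", ".nii"):
        if name.endswith(suff):
            return p.with_name(name[: -len(suff)] + ".json")
    return p.with_suffix(".json")


def save_mask(path, mask: np.ndarray, grid: AffineGrid) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), grid.affine)
    nib.save(img, str(path))


def load_mask(path) -> tuple[np.ndarray, AffineGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return data.astype(bool), AffineGrid(data.shape[:3], img.affine)


def save_tensor_field(path, field: TensorField) -> None:
    img = nib.Nifti1Image(field.components.astype(np.float32), field.grid.affine)
    nib.save(img, str(path))
    meta = {
        "kind": "tensor",
        "component_order": ["xx", "xy", "xz", "yy", "yz", "zz"],
        "units": "mm^2/s",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def load_tensor_field(path, mask: np.ndarray | None = None) -> TensorField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError("tensor volume must be 4-D with 6 components")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("kind") not in (None, "tensor"):
            raise ValueError(f"{path}: sidecar declares kind {meta.get('kind')!r}")
    grid = AffineGrid(data.shape[:3], img.affine)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    return TensorField(grid, data, mask)


def save_fod_field(path, field: FODField) -> None:
    img = nib.Nifti1Image(field.sh_coeffs.astype(np.float32), field.grid.affine)
    nib.save(img, str(path))
    meta = {
        "kind": "fod",
        "sh_ordering": field.sh_ordering,
        "max_order": field.order,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def load_fod_field(path, mask: np.ndarray | None = None) -> FODField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError("FOD volume must be 4-D")
    sidecar = _sidecar_path(path)
    ordering = REAL_SYM_BASIS_ID
    order = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        ordering = meta.get("sh_ordering", ordering)
        order = meta.get("max_order", None)
    grid = AffineGrid(data.shape[:3], img.affine)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    return FODField(grid, data, mask, sh_ordering=ordering, order=order)


# ---------------------------------------------------------------------------
# tractograms


def save_tractogram(path, tractogram: Tractogram) -> None:
    """Write TCK (world mm) or TRK (voxel-order metadata from the grid)."""
    path = str(path)
    nt = NibTractogram(
        [s.points.astype(np.float32) for s in tractogram.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.endswith(".tck"):
        TckFile(nt).save(path)
    elif path.endswith(".trk"):
        grid = tractogram.grid_ref
        header = {
            "voxel_to_rasmm": grid.affine.astype(np.float32),
            "voxel_sizes": grid.voxel_size.astype(np.float32),
            "dimensions": np.asarray(grid.shape, dtype=np.int16),
            "voxel_order": "".join(nib.aff2axcodes(grid.affine)),
        }
        TrkFile(nt, header=header).save(path)
    else:
        raise ValueError("tractogram path must end in .tck or .trk")
    prov = dict(tractogram.provenance)
    if prov:
        Path(path).with_suffix(".json").write_text(
            json.dumps(prov, indent=2, default=str)
        )


def load_tractogram(path, grid: AffineGrid | None = None) -> Tractogram:
    path = str(path)
    try:
        f = nib.streamlines.load(path)
    except Exception as e:  # nibabel raises several header error types
        raise ValueError(f"cannot parse tractogram {path}: {e}") from e
    tg = f.tractogram.to_world()  # points in RAS+ mm for both TCK and TRK
    if grid is None:
        if path.endswith(".trk"):
            hdr = f.header
            grid = AffineGrid(
                tuple(int(d) for d in hdr["dimensions"]),
                np.asarray(hdr["voxel_to_rasmm"], dtype=float),
            )
        else:
            grid = AffineGrid((1, 1, 1), np.eye(4))
    streamlines = [
        Streamline(points=np.asarray(s, dtype=float), seed_index=0)
        for s in tg.streamlines
    ]
    prov = {}
    sidecar = Path(path).with_suffix(".json")
    if sidecar.exists():
        prov = json.loads(sidecar.read_text())
    return Tractogram(streamlines=streamlines, grid_ref=grid, provenance=prov)


# ---------------------------------------------------------------------------
# landmarks, tables, provenance


def save_landmarks(path, landmarks: Landmarks) -> None:
    doc = {
        "ac_apex": landmarks.ac_apex.tolist(),
        "pineal_apex": landmarks.pineal_apex.tolist(),
        "thalamus_mid": landmarks.thalamus_mid.tolist(),
        "has_ita": bool(landmarks.has_ita),
        "space": "RAS+ mm",
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_landmarks(path) -> Landmarks:
    doc = json.loads(Path(path).read_text())
    return Landmarks(
        ac_apex=np.asarray(doc["ac_apex"], dtype=float),
        pineal_apex=np.asarray(doc["pineal_apex"], dtype=float),
        thalamus_mid=np.asarray(doc["thalamus_mid"], dtype=float),
        has_ita=bool(doc.get("has_ita", True)),
    )


def save_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_hash(obj) -> str:
    """Stable short hash of any JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
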
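"""Reading and writing the neuroimaging formats the toolbox touches.

Volumes travel as NIfTI-1 (``.nii`` / ``.nii.gz``), surfaces as GIFTI
``.surf.gii``, per-vertex scalar maps as ``.func.gii`` and per-vertex label
maps as ``.label.gii`` with a color table.  All of it goes through nibabel;
this module only adds the thin domain types and validation the rest of the
package relies on.

Conventions
-----------
* Voxel indices are 0-based; the affine maps voxel *centers* to world mm
  (NIfTI sform semantics).
* 4D volumes are stacks of 3D frames sharing one affine.
* Probability thresholds are strict inequalities.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeImage", "VertexMap",
    "read_volume", "write_volume",
    "read_surface", "write_surface",
    "read_vertex_map", "write_vertex_map",
    "threshold_masks",
]

_VOLUME_KINDS = ("scalar", "label", "probability")


@dataclass
class VolumeImage:
    """A voxel grid with a voxel-to-world affine.

    Parameters
    ----------
    data : ndarray
        3D or 4D array of voxel values (arbitrary units).
    affine : ndarray
        4x4 invertible transform taking 0-based voxel indices to world mm.
    kind : {"scalar", "label", "probability"}
        Interpretation of the values; ``label`` requires non-negative
        integers, ``probability`` requires values in [0, 1].
    """

    data: np.ndarray
    affine: np.ndarray
    kind: str = "scalar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"volume must be 3D or 4D, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.kind not in _VOLUME_KINDS:
            raise ValueError(f"kind must be one of {_VOLUME_KINDS}")
        if self.kind == "probability":
            finite = self.data[np.isfinite(self.data)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("probability volume has values outside [0, 1]")
        if self.kind == "label":
            if not np.issubdtype(self.data.dtype, np.integer):
                if not np.all(np.mod(self.data[np.isfinite(self.data)], 1) == 0):
                    raise ValueError("label volume has non-integer values")
                self.data = self.data.astype(np.int32)
            if self.data.size and self.data.min() < 0:
                raise ValueError("label volume has negative labels")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[:3])

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the 3x3 block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "VolumeImage":
        return dataclasses.replace(self, data=data, kind=kind or self.kind)


@dataclass
class VertexMap:
    """Per-vertex scalar or integer-label annotation of a mesh."""

    values: np.ndarray
    kind: str = "scalar"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("vertex map must be 1D")
        if self.kind not in ("scalar", "label"):
            raise ValueError("kind must be 'scalar' or 'label'")
        if self.kind == "label" and not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.mod(self.values[np.isfinite(self.values)], 1) == 0):
                raise ValueError("label map has non-integer values")
            self.values = self.values.astype(np.int32)

    @property
    def n_vertices(self) -> int:
        return int(self.values.shape[0])


def read_volume(path: str | os.PathLike) -> VolumeImage:
    """Read a NIfTI volume; 4D inputs are preserved as 4D."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several format errors
        raise ValueError(f"not a readable NIfTI image: {path}") from exc
    data = np.asarray(img.get_fdata())
    if data.ndim > 4:
        raise ValueError(f"unsupported dimensionality {data.ndim} (max 4)")
    if data.ndim < 3:
        data = data.reshape(data.shape + (1,) * (3 - data.ndim))
    return VolumeImage(data=data, affine=np.asarray(img.affine))


def write_volume(vol: VolumeImage, path: str | os.PathLike) -> None:
    """Write a :class:`VolumeImage` as NIfTI-1."""
    data = vol.data
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int32)
    else:
        data = data.astype(np.float64)
    nib.save(nib.Nifti1Image(data, vol.affine), str(path))


def read_surface(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a GIFTI surface; returns (vertices world-mm, 0-based face triples)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    codes = nib.nifti1.intent_codes.code
    verts = faces = None
    for arr in img.darrays:
        if codes[arr.intent] == codes["NIFTI_INTENT_POINTSET"]:
            verts = np.asarray(arr.data, dtype=float)
        elif codes[arr.intent] == codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(arr.data, dtype=np.int64)
    if verts is None:
        raise ValueError(f"no coordinate (pointset) array in {path}")
    if faces is None:
        raise ValueError(f"no topology (triangle) array in {path}")
    if faces.size and (faces.min() < 0 or faces.max() >= len(verts)):
        raise ValueError("face index out of range for vertex array")
    return verts, faces


def write_surface(vertices: np.ndarray, faces: np.ndarray, path: str | os.PathLike) -> None:
    """Write vertices/faces as a GIFTI surface file."""
    vertices = np.asarray(vertices, dtype=np.float32)
    if vertices.shape[1] == 2:  # flat meshes are stored with z = 0
        vertices = np.column_stack([vertices, np.zeros(len(vertices), dtype=np.float32)])
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(vertices, intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(np.asarray(faces, dtype=np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


def write_vertex_map(vmap: VertexMap, path: str | os.PathLike,
                     labels: dict[int, tuple[str, tuple[float, float, float, float]]] | None = None,
                     ) -> None:
    """Write a vertex map: scalars as ``.func.gii``, labels as ``.label.gii``.

    Parameters
    ----------
    labels : dict, optional
        Required for label maps: ``{label: (name, (r, g, b, a))}`` with an
        entry for every label present in the data.
    """
    if vmap.kind == "label":
        present = set(int(v) for v in np.unique(vmap.values))
        if labels is None:
            raise ValueError("label map requires a label table")
        missing = present - set(int(k) for k in labels)
        if missing:
            raise ValueError(f"no table entry for labels: {sorted(missing)}")
        table = nib.gifti.GiftiLabelTable()
        for key, (name, rgba) in sorted(labels.items()):
            lab = nib.gifti.GiftiLabel(key=int(key), red=rgba[0], green=rgba[1],
                                       blue=rgba[2], alpha=rgba[3])
            lab.label = name
            table.labels.append(lab)
        img = nib.gifti.GiftiImage(labeltable=table, darrays=[
            nib.gifti.GiftiDataArray(vmap.values.astype(np.int32),
                                     intent="NIFTI_INTENT_LABEL",
                                     datatype="NIFTI_TYPE_INT32"),
        ])
    else:
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(vmap.values.astype(np.float32),
                                     intent="NIFTI_INTENT_NONE"),
        ])
    nib.save(img, str(path))


def read_vertex_map(path: str | os.PathLike) -> VertexMap:
    """Read a ``.func.gii`` / ``.label.gii`` vertex map."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if not img.darrays:
        raise ValueError(f"no data arrays in {path}")
    arr = img.darrays[0]
    codes = nib.nifti1.intent_codes.code
    kind = ("label" if codes[arr.intent] == codes["NIFTI_INTENT_LABEL"]
            else "scalar")
    return VertexMap(values=np.asarray(arr.data), kind=kind)


def threshold_masks(white_prob: VolumeImage, grey_prob: VolumeImage,
                    white_thresh: float = 0.4, grey_thresh: float = 0.5,
                    ) -> tuple[VolumeImage, VolumeImage]:
    """Build disjoint white- and grey-matter masks from probability volumes.

    The white-matter body is the set of voxels with white-matter probability
    strictly above ``white_thresh``; the remaining voxels are grey matter
    where the grey-matter probability strictly exceeds ``grey_thresh``.  The
    default thresholds (0.4, 0.5) follow the construction of the average
    cerebellar template.
    """
    if white_prob.shape3d != grey_prob.shape3d:
        raise ValueError("probability volumes are on different grids")
    if not np.allclose(white_prob.affine, grey_prob.affine):
        raise ValueError("probability volumes have different affines")
    for t in (white_thresh, grey_thresh):
        if not (0.0 < t < 1.0):
            raise ValueError("thresholds must be in (0, 1)")
    white = white_prob.data > white_thresh
    grey = (~white) & (grey_prob.data > grey_thresh)
    mk = lambda m: VolumeImage(m.astype(np.int32), white_prob.affine, kind="label")
    return mk(white), mk(grey)
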
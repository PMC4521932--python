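"""Area-to-volume distortion of the flatmap.

The flatmap is built so that each triangle's share of the total map area
approximates the share of total grey-matter volume it represents.  This
module quantifies the deviation from that ideal: for every triangle the
percentage of total map area it occupies and the percentage of total
grey-matter volume it represents are computed, and the log of their ratio
— ideally zero — is mapped back onto vertices for display.  Summary
statistics report what fraction of vertices fall within distortion bands
(ratio between 1:2 and 2:1, and between 1:1.5 and 1.5:1), and a
per-compartment table compares flatmap area against atlas volume across
lobular compartments.

Voxel-to-triangle assignment rule: each grey-matter voxel center is
assigned to the vertex whose correspondence segment passes nearest
(point-to-segment distance, ties to the lowest vertex index); each vertex's
voxel tally is then split equally among its incident faces.  The rule is
deterministic and partitions the grey mask exactly: summed per-triangle
volumes equal voxel count times voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correspondence import SurfacePair
from .io_formats import VolumeImage
from .mesh_core import FlatMesh, triangle_areas, vertex_areas

__all__ = [
    "DistortionReport", "CompartmentAssignment",
    "assign_voxels_to_vertices", "represented_volume",
    "distortion_map", "compartment_area_volume",
]

#: Distortion bands reported on the raw area:volume ratio.
BANDS: tuple[tuple[float, float], ...] = ((1 / 2, 2.0), (1 / 1.5, 1.5))


@dataclass
class DistortionReport:
    area_fraction: np.ndarray          # per-face share of total |flat area|
    volume_fraction: np.ndarray        # per-face share of represented volume
    log_ratio: np.ndarray              # per-face log2(area/volume share)
    vertex_log_ratio: np.ndarray       # area-weighted face average, for display
    band_summary: dict[str, float]     # fraction of vertices inside each band
    compartment_table: pd.DataFrame | None = None


@dataclass
class CompartmentAssignment:
    """Compartment labels on both sides of the comparison: per flat-mesh
    vertex (winner-take-all on the surface) and per voxel (argmax of the
    probability volumes)."""

    vertex_labels: np.ndarray
    voxel_labels: VolumeImage


def _grey_voxel_centers(grey_mask: VolumeImage) -> np.ndarray:
    idx = np.argwhere(grey_mask.data > 0)
    if idx.size == 0:
        raise ValueError("grey mask is empty")
    return idx @ grey_mask.affine[:3, :3].T + grey_mask.affine[:3, 3]


def assign_voxels_to_vertices(pair: SurfacePair, grey_mask: VolumeImage,
                              chunk: int = 2048) -> np.ndarray:
    """Assign each in-mask voxel center to the nearest correspondence
    segment's vertex.  Returns the vertex index per grey voxel (in
    ``np.argwhere`` order).  Ties break to the lowest vertex index."""
    points = _grey_voxel_centers(grey_mask)
    S = pair.outer.vertices
    D = pair.inner.vertices - S            # (V, 3)
    len2 = np.einsum("ij,ij->i", D, D)
    len2 = np.where(len2 == 0, 1.0, len2)  # zero-length segment -> point
    owner = np.empty(len(points), dtype=np.int64)
    for lo in range(0, len(points), chunk):
        P = points[lo:lo + chunk]                       # (n, 3)
        W = P[:, None, :] - S[None, :, :]               # (n, V, 3)
        t = np.clip(np.einsum("nvj,vj->nv", W, D) / len2[None, :], 0.0, 1.0)
        diff = W - t[:, :, None] * D[None, :, :]
        d2 = np.einsum("nvj,nvj->nv", diff, diff)
        owner[lo:lo + chunk] = np.argmin(d2, axis=1)
    return owner


def _vertex_to_face_volume(flat_faces: np.ndarray, n_vertices: int,
                           vertex_volume: np.ndarray) -> np.ndarray:
    """Distribute each vertex's volume equally among its incident faces
    (the dual of one-third vertex areas); exact partition is preserved."""
    deg = np.zeros(n_vertices)
    np.add.at(deg, flat_faces.ravel(), 1.0)
    share = np.divide(vertex_volume, deg, out=np.zeros_like(vertex_volume),
                      where=deg > 0)
    face_vol = np.zeros(len(flat_faces))
    for c in range(3):
        face_vol += share[flat_faces[:, c]]
    return face_vol


def represented_volume(pair: SurfacePair, grey_mask: VolumeImage,
                       flat: FlatMesh) -> np.ndarray:
    """Grey-matter volume (mm^3) represented by each flat-mesh triangle.

    Every in-mask voxel is assigned to exactly one vertex (nearest
    correspondence segment) and vertex volumes are then split equally among
    incident flat faces, so the per-triangle volumes sum exactly to
    ``n_grey_voxels * voxel_volume``.  The flat mesh may be a cut version of
    the projection surface; its ``cut_provenance`` carries vertex volumes
    across duplicated cut vertices (split equally among the copies).
    """
    owner = assign_voxels_to_vertices(pair, grey_mask)
    vv = grey_mask.voxel_volume
    vol_orig = np.zeros(pair.n_vertices)
    np.add.at(vol_orig, owner, vv)
    # carry to the (possibly cut) flat mesh: copies of a duplicated vertex
    # split its volume equally so the partition stays exact
    copies = np.zeros(pair.n_vertices)
    np.add.at(copies, flat.cut_provenance, 1.0)
    if np.any(copies == 0) and np.any(vol_orig[copies == 0] > 0):
        lost = float(np.sum(vol_orig[copies == 0]))
        raise ValueError(f"{lost} mm^3 assigned to vertices absent from the "
                         "flat mesh")
    vertex_volume = vol_orig[flat.cut_provenance] / copies[flat.cut_provenance]
    return _vertex_to_face_volume(flat.faces, flat.n_vertices, vertex_volume)


def distortion_map(flat: FlatMesh, volumes: np.ndarray,
                   assign: "CompartmentAssignment | None" = None,
                   grey_mask: VolumeImage | None = None) -> DistortionReport:
    """Per-face and per-vertex log2 area:volume distortion with band summary.

    ``volumes`` is the per-face represented grey volume (mm^3).  Fractions
    are shares of the totals; the per-face log2 ratio is averaged onto
    vertices weighted by face area for display, and the band summary counts
    vertices whose ratio lies within [1/2, 2] and [1/1.5, 1.5] (the narrow
    band is always a subset of the wide one).
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.shape != (flat.n_faces,):
        raise ValueError("need one volume per face")
    total_vol = volumes.sum()
    if total_vol <= 0:
        raise ValueError("total represented volume must be positive")
    areas = np.abs(triangle_areas(flat))
    area_fraction = areas / areas.sum()
    volume_fraction = volumes / total_vol
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = area_fraction / volume_fraction
        log_ratio = np.log2(ratio)

    # area-weighted average of face log-ratios around each vertex
    w = np.repeat(areas / 3.0, 3)
    lr = np.repeat(log_ratio, 3)
    ok = np.isfinite(lr)
    num = np.zeros(flat.n_vertices)
    den = np.zeros(flat.n_vertices)
    np.add.at(num, flat.faces.ravel()[ok], (w * lr)[ok])
    np.add.at(den, flat.faces.ravel()[ok], w[ok])
    vertex_log_ratio = np.divide(num, den, out=np.full(flat.n_vertices, np.nan),
                                 where=den > 0)

    vratio = np.exp2(vertex_log_ratio)
    valid = np.isfinite(vratio)
    band_summary = {}
    for lo, hi in BANDS:
        frac = float(np.mean((vratio[valid] >= lo) & (vratio[valid] <= hi))) \
            if valid.any() else 0.0
        band_summary[f"{lo:.4g}-{hi:.4g}"] = frac

    table = None
    if assign is not None:
        if grey_mask is None:
            raise ValueError("compartment table needs the grey mask")
        table, _ = compartment_area_volume(assign, flat, grey_mask)
    return DistortionReport(area_fraction=area_fraction,
                            volume_fraction=volume_fraction,
                            log_ratio=log_ratio,
                            vertex_log_ratio=vertex_log_ratio,
                            band_summary=band_summary,
                            compartment_table=table)


def compartment_area_volume(assign: CompartmentAssignment, flat: FlatMesh,
                            grey_mask: VolumeImage,
                            ) -> tuple[pd.DataFrame, float]:
    """Per-compartment flatmap area (%) versus atlas volume (%) and their
    Pearson correlation.

    Area share: sum of one-third-incidence vertex areas of the vertices
    labeled with each compartment, as a percent of total map area.  Volume
    share: in-mask voxel counts per compartment label, as a percent of all
    labeled in-mask voxels.  Compartment 0 (unassigned) is excluded.  With
    fewer than 2 compartments, or zero variance across compartments, the
    correlation is reported as 1.0 by convention for exact agreement and
    the table's ``degenerate`` attribute is set.
    """
    labels = np.asarray(assign.vertex_labels)
    if labels.shape != (flat.n_vertices,):
        raise ValueError("vertex labels must match the flat mesh")
    varea = vertex_areas(flat)
    surf_ids = sorted(int(k) for k in np.unique(labels) if k != 0)

    vox = assign.voxel_labels.data
    in_mask = grey_mask.data > 0
    vox_labels = np.where(in_mask, vox, 0)
    vol_ids = sorted(int(k) for k in np.unique(vox_labels) if k != 0)
    missing = sorted(set(vol_ids) - set(surf_ids))
    if missing:
        raise ValueError(f"compartments present in volume but absent on "
                         f"surface: {missing}")

    rows = []
    total_area = varea.sum()
    total_vox = int(np.sum(vox_labels > 0))
    if total_vox == 0:
        raise ValueError("no labeled in-mask voxels")
    for k in surf_ids:
        a = 100.0 * varea[labels == k].sum() / total_area
        v = 100.0 * int(np.sum(vox_labels == k)) / total_vox
        rows.append({"compartment": k, "area_pct": a, "volume_pct": v})
    table = pd.DataFrame(rows).set_index("compartment")

    a = table["area_pct"].to_numpy()
    v = table["volume_pct"].to_numpy()
    degenerate = len(a) < 2 or np.std(a) == 0 or np.std(v) == 0
    if degenerate:
        r = 1.0 if np.allclose(a, v) else np.nan
    else:
        r = float(stats.pearsonr(a, v).statistic)
    table.attrs["degenerate"] = bool(degenerate)
    table.attrs["pearson_r"] = r
    return table, r
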
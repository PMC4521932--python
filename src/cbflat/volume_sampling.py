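"""Sampling volumes along correspondence lines and integrating to vertices.

For each vertex the volume is sampled at a set of fractional depths along
the segment from the outer vertex (depth 0) to the inner vertex (depth 1).
The sampled profile is then integrated to one value per vertex with a
statistic suited to the data:

``mean``
    the typical choice for activation values;
``mode``
    for discrete labels such as network parcellations, where averaging
    would invent labels;
``absmax``
    the glass-brain projection for statistical maps — the minimum or
    maximum of the underlying voxels, whichever has the higher absolute
    value, so no significant cluster is hidden by averaging;
``min`` / ``max``
    one-sided extrema.

Samples falling outside the volume or outside an optional mask are NaN and
are ignored by the statistics; a vertex with no valid sample stays NaN
(scalar) or 0/unassigned (label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .correspondence import SurfacePair
from .io_formats import VertexMap, VolumeImage

__all__ = [
    "SampledProfile", "StatMap", "DEFAULT_DEPTHS",
    "sample_profile", "integrate", "winner_take_all",
    "composite_map", "one_sample_tmap",
]

#: Five evenly spaced depths, endpoints on the two surfaces included.
DEFAULT_DEPTHS: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class SampledProfile:
    """Values sampled along correspondence segments: (V vertices, D depths)."""

    values: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (V, D)")
        if self.depths.shape != (self.values.shape[1],):
            raise ValueError("depths length must match number of columns")
        if len(self.depths) < 1:
            raise ValueError("need at least one depth")
        if np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]


@dataclass
class StatMap:
    """A voxelwise t-statistic volume with its degrees of freedom."""

    t_values: VolumeImage
    df: int
    zero_variance: np.ndarray | None = None  # flags voxels where sd == 0


def _world_to_voxel(affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def sample_profile(vol: VolumeImage, pair: SurfacePair,
                   depths=DEFAULT_DEPTHS, interp: str = "trilinear",
                   mask: VolumeImage | None = None) -> SampledProfile:
    """Sample ``vol`` at each vertex and depth.

    The sample point at vertex ``v`` and depth ``d`` is
    ``(1 - d) * outer_v + d * inner_v`` in world mm, mapped through the
    inverse affine into voxel space.  ``interp`` is ``"trilinear"`` for
    continuous data or ``"nearest"`` for labels (labels must not blend).
    Out-of-volume and out-of-mask samples are NaN.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("empty depth list")
    if np.any((depths < 0) | (depths > 1)):
        raise ValueError("depths must lie in [0, 1]")
    if interp not in ("trilinear", "nearest"):
        raise ValueError("interp must be 'trilinear' or 'nearest'")
    if mask is not None:
        if mask.shape3d != vol.shape3d or not np.allclose(mask.affine, vol.affine):
            raise ValueError("mask must share the volume's grid and affine")
    if vol.data.ndim != 3:
        raise ValueError("sample_profile expects a 3D volume (pick a frame of 4D data)")

    starts, ends = pair.outer.vertices, pair.inner.vertices
    V, D = len(starts), len(depths)
    # (V, D, 3) world points along each segment
    pts = starts[:, None, :] * (1.0 - depths)[None, :, None] \
        + ends[:, None, :] * depths[None, :, None]
    vox = _world_to_voxel(vol.affine, pts.reshape(-1, 3)).T  # (3, V*D)

    order = 1 if interp == "trilinear" else 0
    vals = map_coordinates(vol.data.astype(float), vox, order=order,
                           mode="constant", cval=np.nan)
    inside = np.all((vox >= -0.5) & (vox <= np.array(vol.shape3d)[:, None] - 0.5),
                    axis=0)
    vals[~inside] = np.nan
    if mask is not None:
        # membership decided at the nearest voxel, never by blending the mask
        in_mask = map_coordinates(
            (mask.data > 0).astype(float), vox, order=0, mode="constant", cval=0.0)
        vals[in_mask < 0.5] = np.nan
    return SampledProfile(values=vals.reshape(V, D), depths=depths)


_SCALAR_STATS = ("mean", "absmax", "min", "max")


def integrate(profile: SampledProfile, stat: str = "mean") -> VertexMap:
    """Collapse a sampled profile to one value per vertex.

    NaN samples are ignored; a vertex whose samples are all NaN yields NaN
    for scalar statistics and 0 (unassigned) for ``mode``.  ``mode``
    requires integer label data and breaks ties toward the smallest label;
    ``absmax`` returns the signed value of largest magnitude.
    """
    v = profile.values
    with np.errstate(invalid="ignore"):
        if stat == "mean":
            out = np.full(v.shape[0], np.nan)
            has = ~np.all(np.isnan(v), axis=1)
            out[has] = np.nanmean(v[has], axis=1)
            return VertexMap(out, kind="scalar")
        if stat == "min":
            out = np.full(v.shape[0], np.nan)
            has = ~np.all(np.isnan(v), axis=1)
            out[has] = np.nanmin(v[has], axis=1)
            return VertexMap(out, kind="scalar")
        if stat == "max":
            out = np.full(v.shape[0], np.nan)
            has = ~np.all(np.isnan(v), axis=1)
            out[has] = np.nanmax(v[has], axis=1)
            return VertexMap(out, kind="scalar")
        if stat == "absmax":
            out = np.full(v.shape[0], np.nan)
            has = ~np.all(np.isnan(v), axis=1)
            if np.any(has):
                lo = np.nanmin(v[has], axis=1)
                hi = np.nanmax(v[has], axis=1)
                out[has] = np.where(np.abs(lo) > np.abs(hi), lo, hi)
            return VertexMap(out, kind="scalar")
    if stat == "mode":
        finite = v[np.isfinite(v)]
        # tolerate interpolation round-off on integer-valued data
        if finite.size and not np.allclose(finite, np.round(finite),
                                           atol=1e-6):
            raise ValueError("mode requires integer label data")
        out = np.zeros(v.shape[0], dtype=np.int32)
        for i, row in enumerate(v):
            row = np.round(row[np.isfinite(row)]).astype(np.int64)
            if row.size == 0:
                continue
            labels, counts = np.unique(row, return_counts=True)
            out[i] = labels[np.argmax(counts)]  # unique() sorts: smallest wins ties
        return VertexMap(out, kind="label")
    raise ValueError(f"unknown statistic {stat!r}; use one of "
                     f"{_SCALAR_STATS + ('mode',)}")


def winner_take_all(prob_vols: list[VolumeImage], pair: SurfacePair,
                    depths=DEFAULT_DEPTHS, mask: VolumeImage | None = None,
                    ) -> VertexMap:
    """Winner-take-all compartment labels from probability volumes.

    Each compartment's probabilities are sampled and averaged across depths;
    every vertex is assigned to the compartment (1..K) with the highest
    average.  Exact ties go to the lowest compartment index; a vertex where
    every average is zero or undefined stays 0 (unassigned).
    """
    if len(prob_vols) < 1:
        raise ValueError("need at least one probability volume")
    ref = prob_vols[0]
    for p in prob_vols[1:]:
        if p.shape3d != ref.shape3d or not np.allclose(p.affine, ref.affine):
            raise ValueError("probability volumes are on inconsistent grids")
    means = []
    for p in prob_vols:
        prof = sample_profile(p, pair, depths=depths, interp="trilinear", mask=mask)
        means.append(integrate(prof, "mean").values)
    avg = np.stack(means, axis=1)  # (V, K)
    avg = np.where(np.isnan(avg), 0.0, avg)
    labels = np.argmax(avg, axis=1) + 1  # argmax takes first max: lowest index
    labels[np.max(avg, axis=1) <= 0.0] = 0
    return VertexMap(labels.astype(np.int32), kind="label")


def composite_map(condition_maps: list[VertexMap], threshold: float) -> VertexMap:
    """Somatotopy-style composite: label of the condition with maximal
    activity wherever that maximum strictly exceeds ``threshold``, else 0.

    ``condition_maps`` are per-condition mean activity maps (e.g. one per
    body part); labels are 1-based in list order.  The threshold is in the
    input maps' units and is strict (a value exactly at threshold is
    sub-threshold).
    """
    if not condition_maps:
        raise ValueError("empty condition list")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    n = condition_maps[0].n_vertices
    for m in condition_maps:
        if m.n_vertices != n:
            raise ValueError("condition maps have different lengths")
    stack = np.stack([np.asarray(m.values, dtype=float) for m in condition_maps],
                     axis=1)
    stack = np.where(np.isnan(stack), -np.inf, stack)
    best = np.argmax(stack, axis=1) + 1
    peak = np.max(stack, axis=1)
    best[~(peak > threshold)] = 0
    return VertexMap(best.astype(np.int32), kind="label")


def one_sample_tmap(subject_vols: list[VolumeImage]) -> StatMap:
    """Voxelwise one-sample t-test across subjects (second-level analysis).

    Each input volume is one subject's contrast image on a common grid.
    ``t = mean / (sd / sqrt(n))`` with ``df = n - 1`` (sd uses ddof=1).
    Voxels with zero variance yield +/-inf (or 0 where the mean is also 0)
    and are flagged in ``zero_variance``.  Thresholding (e.g. at an
    FWE-corrected value computed elsewhere) is up to the caller.
    """
    n = len(subject_vols)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    ref = subject_vols[0]
    for v in subject_vols[1:]:
        if v.shape3d != ref.shape3d or not np.allclose(v.affine, ref.affine):
            raise ValueError("subject volumes are on inconsistent grids")
    stack = np.stack([v.data for v in subject_vols], axis=0)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero_var & (mean == 0)] = 0.0
    t[zero_var & (mean > 0)] = np.inf
    t[zero_var & (mean < 0)] = -np.inf
    return StatMap(t_values=VolumeImage(t, ref.affine, kind="scalar"),
                   df=n - 1, zero_variance=zero_var)
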
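"""Self-contained synthetic fixtures with known ground truth.

Real inputs to the toolbox — template-derived outer/inner cerebellar
surfaces and normalized functional volumes — are large external artifacts.
This module generates a geometrically transparent stand-in: a sinusoidally
folded open sheet (the outer surface), the same sheet offset inward along
its local normals (the inner surface), and the voxel band between them (the
grey-matter mask).  The folding reproduces the essential difficulty of the
real data — several layers of cortex stacked within a voxel column — while
every quantity of interest (flat layout, segment lengths, per-face volume
shares, blob peak vertices, compartment labels) has a closed-form or
brute-force ground truth.

The sheet folds along x only, so its exact flat layout is
``(arc-length(x), y)`` and curvature corrections are one-dimensional.  All
randomness is drawn from one stream seeded by ``SynthSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .correspondence import SurfacePair
from .io_formats import VolumeImage
from .mesh_core import FlatMesh, TriangleMesh

__all__ = [
    "SynthSpec", "make_folded_pair", "make_blob_volume",
    "make_label_and_prob_volumes", "inject_distortion",
    "analytic_sheet_volume",
]


@dataclass
class SynthSpec:
    """Parameters of the synthetic folded-sheet world.

    Defaults give a 72x48x40 voxel grid at 1 mm holding a 60x40 mm sheet
    with 3 sinusoidal folds of 6 mm peak-to-trough depth and a 2 mm
    grey-matter thickness — deep enough that a vertical voxel column crosses
    multiple grey layers, the regime the projection method is built for.
    """

    grid_shape: tuple[int, int, int] = (72, 48, 40)
    voxel_size: float = 1.0
    n_folds: int = 3
    fold_depth: float = 6.0          # peak-to-trough amplitude, mm
    sheet_extent: float = 60.0       # sheet length along x, mm (y extent = 2/3)
    thickness: float = 2.0           # grey-matter thickness (normal offset), mm
    blob_specs: tuple = ()           # (center_xyz_mm, sd_mm, amplitude)
    n_compartments: int = 4
    seed: int = 17
    mesh_shape: tuple[int, int] = (49, 25)  # surface vertices along x, y

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 4 or self.voxel_size <= 0:
            raise ValueError("grid must be at least 4 voxels per axis, voxel > 0")
        if self.fold_depth < 0 or self.thickness <= 0 or self.sheet_extent <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_folds < 0:
            raise ValueError("n_folds must be >= 0")

    # --- derived geometry -------------------------------------------------
    @property
    def _amp(self) -> float:
        return 0.5 * self.fold_depth

    @property
    def _k(self) -> float:
        return 2.0 * np.pi * self.n_folds / self.sheet_extent

    @property
    def _extent_y(self) -> float:
        return self.sheet_extent * 2.0 / 3.0

    @property
    def _world_size(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * self.voxel_size

    @property
    def _origin(self) -> np.ndarray:
        """World position of the sheet's (x=0, y=0) corner."""
        w = self._world_size
        return np.array([(w[0] - self.sheet_extent) / 2.0,
                         (w[1] - self._extent_y) / 2.0, 0.0])

    @property
    def _z_mid(self) -> float:
        return 0.55 * self._world_size[2]

    def outer_z(self, x: np.ndarray) -> np.ndarray:
        """Height of the outer surface over sheet coordinate x."""
        return self._z_mid + self._amp * np.sin(self._k * np.asarray(x, float))

    def outer_slope(self, x: np.ndarray) -> np.ndarray:
        return self._amp * self._k * np.cos(self._k * np.asarray(x, float))

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff

    def validate_geometry(self) -> None:
        max_curvature = self._amp * self._k ** 2
        if self.thickness * max_curvature >= 0.9:
            raise ValueError(
                "fold_depth too large for the grey-matter thickness: the "
                "inward offset surface would self-intersect "
                f"(thickness * max curvature = {self.thickness * max_curvature:.2f})")
        top = self._z_mid + self._amp
        bottom = self._z_mid - self._amp - self.thickness
        w = self._world_size
        if (top >= w[2] - 2 * self.voxel_size or bottom <= 2 * self.voxel_size
                or self.sheet_extent >= w[0] - 2 * self.voxel_size
                or self._extent_y >= w[1] - 2 * self.voxel_size):
            raise ValueError("sheet does not fit in the voxel grid")


def _arc_length_table(spec: SynthSpec, n: int = 4096,
                      ) -> tuple[np.ndarray, np.ndarray]:
    xs = np.linspace(0.0, spec.sheet_extent, n)
    speed = np.sqrt(1.0 + spec.outer_slope(xs) ** 2)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1])
                                         * np.diff(xs))])
    return xs, s


def analytic_sheet_volume(spec: SynthSpec) -> float:
    """First-order continuum volume of the grey band:
    arc length x sheet width x thickness (curvature corrections cancel to
    first order for a symmetric sinusoid)."""
    _, s = _arc_length_table(spec)
    return float(s[-1] * spec._extent_y * spec.thickness)


def _surface_vertices(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nu, nv = spec.mesh_shape
    xs = np.linspace(0.0, spec.sheet_extent, nu)
    ys = np.linspace(0.0, spec._extent_y, nv)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    origin = spec._origin
    outer = np.column_stack([
        origin[0] + X.ravel(), origin[1] + Y.ravel(),
        spec.outer_z(X.ravel()),
    ])
    slope = spec.outer_slope(X.ravel())
    norm = np.sqrt(1.0 + slope ** 2)
    normal = np.column_stack([-slope / norm, np.zeros(slope.size), 1.0 / norm])
    inner = outer - spec.thickness * normal
    return outer, inner, X

def _sheet_faces(nu: int, nv: int) -> np.ndarray:
    idx = np.arange(nu * nv).reshape(nu, nv)
    v00 = idx[:-1, :-1].ravel()
    v10 = idx[1:, :-1].ravel()
    v11 = idx[1:, 1:].ravel()
    v01 = idx[:-1, 1:].ravel()
    return np.concatenate([np.column_stack([v00, v10, v11]),
                           np.column_stack([v00, v11, v01])])


def _grey_flags_2d(spec: SynthSpec) -> np.ndarray:
    """In-plane (x-voxel, z-voxel) grey membership, shared by all y slices."""
    nx, _, nz = spec.grid_shape
    vs = spec.voxel_size
    xs_w = (np.arange(nx) + 0.0) * vs  # voxel centers (affine has no offset)
    zs_w = (np.arange(nz) + 0.0) * vs
    ox = spec._origin[0]

    dense_x = np.linspace(0.0, spec.sheet_extent, 6000)
    curve = np.column_stack([ox + dense_x, spec.outer_z(dense_x)])
    tree = cKDTree(curve)
    slope = spec.outer_slope(dense_x)
    norm = np.sqrt(1.0 + slope ** 2)
    normals = np.column_stack([-slope / norm, 1.0 / norm])

    Xw, Zw = np.meshgrid(xs_w, zs_w, indexing="ij")
    pts = np.column_stack([Xw.ravel(), Zw.ravel()])
    dist, nearest = tree.query(pts)
    signed = np.einsum("ij,ij->i", pts - curve[nearest], normals[nearest])
    in_x = (pts[:, 0] >= ox) & (pts[:, 0] <= ox + spec.sheet_extent)
    grey = in_x & (signed < 0) & (dist <= spec.thickness)
    return grey.reshape(len(xs_w), len(zs_w))


def make_grey_mask(spec: SynthSpec) -> VolumeImage:
    """Voxel mask of the band between the outer and inner sheets."""
    spec.validate_geometry()
    nx, ny, nz = spec.grid_shape
    flags2d = _grey_flags_2d(spec)
    ys_w = np.arange(ny) * spec.voxel_size
    oy = spec._origin[1]
    in_y = (ys_w >= oy) & (ys_w <= oy + spec._extent_y)
    mask = flags2d[:, None, :] & in_y[None, :, None]
    return VolumeImage(mask.astype(np.int32), spec.affine, kind="label")


def _point_to_segment_owner(points: np.ndarray, starts: np.ndarray,
                            ends: np.ndarray, chunk: int = 1024) -> np.ndarray:
    """Nearest correspondence segment per point (generator's own bookkeeping,
    kept separate from the distortion module's assignment code)."""
    D = ends - starts
    len2 = np.einsum("ij,ij->i", D, D)
    len2 = np.where(len2 == 0, 1.0, len2)
    owner = np.empty(len(points), dtype=np.int64)
    for lo in range(0, len(points), chunk):
        P = points[lo:lo + chunk]
        W = P[:, None, :] - starts[None, :, :]
        t = np.clip(np.einsum("nvj,vj->nv", W, D) / len2[None, :], 0.0, 1.0)
        diff = W - t[:, :, None] * D[None, :, :]
        d2 = np.einsum("nvj,nvj->nv", diff, diff)
        owner[lo:lo + chunk] = np.argmin(d2, axis=1)
    return owner


def _true_volume_shares(spec: SynthSpec, pair: SurfacePair,
                        grey_mask: VolumeImage, refine: int = 2) -> np.ndarray:
    """Per-face grey-volume shares from brute-force fine sub-voxel counting:
    every grey voxel is split into ``refine^3`` subpoints, each assigned to
    its nearest correspondence segment, and vertex tallies are split equally
    among incident faces."""
    idx = np.argwhere(grey_mask.data > 0).astype(float)
    offs = (np.arange(refine) + 0.5) / refine - 0.5
    sub = np.stack(np.meshgrid(offs, offs, offs, indexing="ij"), axis=-1
                   ).reshape(-1, 3)
    pts_vox = (idx[:, None, :] + sub[None, :, :]).reshape(-1, 3)
    pts = pts_vox @ grey_mask.affine[:3, :3].T + grey_mask.affine[:3, 3]
    owner = _point_to_segment_owner(pts, pair.outer.vertices, pair.inner.vertices)
    per_vertex = np.bincount(owner, minlength=pair.n_vertices).astype(float)
    faces = pair.outer.faces
    deg = np.zeros(pair.n_vertices)
    np.add.at(deg, faces.ravel(), 1.0)
    share = np.divide(per_vertex, deg, out=np.zeros_like(per_vertex),
                      where=deg > 0)
    face_counts = share[faces[:, 0]] + share[faces[:, 1]] + share[faces[:, 2]]
    total = face_counts.sum()
    if total == 0:
        raise ValueError("no grey voxels assigned to any face")
    return face_counts / total


def make_folded_pair(spec: SynthSpec,
                     ) -> tuple[SurfacePair, VolumeImage, FlatMesh, np.ndarray]:
    """Generate the folded surface pair and its ground truth.

    Returns ``(pair, grey_mask, flat_truth, true_shares)``: the outer/inner
    surface pair with shared topology, the voxel mask of the band between
    them, the analytic flat layout ``(arc length, y)``, and per-face true
    grey-volume shares from fine sub-voxel counting.  Deterministic given
    the spec (bit-identical for equal specs).
    """
    spec.validate_geometry()
    outer_v, inner_v, X = _surface_vertices(spec)
    faces = _sheet_faces(*spec.mesh_shape)
    pair = SurfacePair(outer=TriangleMesh(outer_v, faces),
                       inner=TriangleMesh(inner_v, faces.copy()))
    grey_mask = make_grey_mask(spec)

    xs_tab, s_tab = _arc_length_table(spec)
    flat_x = np.interp(X.ravel(), xs_tab, s_tab)
    flat_y = outer_v[:, 1] - spec._origin[1]
    flat_truth = FlatMesh(np.column_stack([flat_x, flat_y]), faces.copy())

    true_shares = _true_volume_shares(spec, pair, grey_mask)
    return pair, grey_mask, flat_truth, true_shares


def make_blob_volume(spec: SynthSpec, grey_mask: VolumeImage,
                     pair: SurfacePair) -> tuple[VolumeImage, list[int]]:
    """Sum-of-Gaussians activation volume restricted to the grey mask.

    ``spec.blob_specs`` holds ``(center_world_mm, sd_mm, amplitude)``
    triples.  Returns the volume and, per blob, the ground-truth peak
    vertex: the vertex whose correspondence segment passes closest to the
    blob center.
    """
    if not spec.blob_specs:
        raise ValueError("no blobs specified")
    nx, ny, nz = grey_mask.shape3d
    ii = np.indices((nx, ny, nz), dtype=float).reshape(3, -1).T
    pts = ii @ grey_mask.affine[:3, :3].T + grey_mask.affine[:3, 3]
    data = np.zeros(nx * ny * nz)
    peaks: list[int] = []
    for center, sd, amp in spec.blob_specs:
        center = np.asarray(center, dtype=float)
        sd = max(float(sd), 1e-6)  # sd -> 0 degenerates to an impulse
        d2 = np.sum((pts - center) ** 2, axis=1)
        data += amp * np.exp(-0.5 * d2 / sd ** 2)
        owner = _point_to_segment_owner(center[None, :], pair.outer.vertices,
                                        pair.inner.vertices)
        peaks.append(int(owner[0]))
    data = data.reshape(nx, ny, nz) * (grey_mask.data > 0)
    return VolumeImage(data, grey_mask.affine, kind="scalar"), peaks


def make_label_and_prob_volumes(spec: SynthSpec, grey_mask: VolumeImage,
                                pair: SurfacePair, smooth_sigma: float = 1.0,
                                slab_widths: np.ndarray | None = None,
                                ) -> tuple[VolumeImage, list[VolumeImage], np.ndarray]:
    """Partition the grey band into K contiguous slabs along x.

    Slab widths default to the proportions 1:2:...:K — compartments of
    deliberately different sizes, like the real lobular compartments, so
    that area-versus-volume comparisons across compartments have dynamic
    range.  Pass ``slab_widths`` (any positive weights) to override.

    Returns the discrete label volume (labels 1..K inside the mask, 0
    outside), K probability volumes (Gaussian-smoothed slab indicators,
    renormalized so the per-voxel sum never exceeds 1; ``smooth_sigma=0``
    gives the raw indicators), and ground-truth per-vertex labels from slab
    membership of the correspondence-segment midpoints.
    """
    K = int(spec.n_compartments)
    if K < 2:
        raise ValueError("need at least 2 compartments")
    nu = spec.mesh_shape[0]
    if K > nu - 1:
        raise ValueError("more compartments than available slabs")
    if slab_widths is None:
        slab_widths = np.arange(1, K + 1, dtype=float)
    slab_widths = np.asarray(slab_widths, dtype=float)
    if slab_widths.shape != (K,) or np.any(slab_widths <= 0):
        raise ValueError("slab_widths must be K positive weights")
    ox = spec._origin[0]
    edges = ox + spec.sheet_extent * np.concatenate(
        [[0.0], np.cumsum(slab_widths) / slab_widths.sum()])

    nx, ny, nz = grey_mask.shape3d
    xs_w = np.arange(nx) * spec.voxel_size
    slab_of_x = np.clip(np.searchsorted(edges, xs_w, side="right") - 1, 0, K - 1)
    labels = np.where(grey_mask.data > 0,
                      (slab_of_x + 1)[:, None, None], 0).astype(np.int32)
    label_vol = VolumeImage(labels, grey_mask.affine, kind="label")

    probs = []
    raw = [(labels == k + 1).astype(float) for k in range(K)]
    if smooth_sigma > 0:
        sm = [gaussian_filter(r, sigma=smooth_sigma / spec.voxel_size)
              for r in raw]
    else:
        sm = raw
    total = np.sum(sm, axis=0)
    scale = np.where(total > 1.0, total, 1.0)
    for r in sm:
        probs.append(VolumeImage(np.clip(r / scale, 0.0, 1.0),
                                 grey_mask.affine, kind="probability"))

    mid = 0.5 * (pair.outer.vertices + pair.inner.vertices)
    vert_slab = np.clip(np.searchsorted(edges, mid[:, 0], side="right") - 1,
                        0, K - 1)
    true_vertex_labels = (vert_slab + 1).astype(np.int32)
    return label_vol, probs, true_vertex_labels


def inject_distortion(true_shares: np.ndarray, factor: float = 3.0,
                      fraction: float = 0.1, seed: int | None = None,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt a known fraction of per-face volume shares by ``factor``.

    Divides the volume share of a random ``fraction`` of faces by
    ``factor`` (making those faces over-represented by about that factor
    once shares are renormalized), for distortion-band bookkeeping tests.
    Returns ``(distorted_shares, chosen_face_indices)``.
    """
    true_shares = np.asarray(true_shares, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(true_shares)
    n_pick = max(1, int(round(fraction * n)))
    chosen = rng.choice(n, size=n_pick, replace=False)
    out = true_shares.copy()
    out[chosen] /= factor
    return out / out.sum(), np.sort(chosen)
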
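"""Flatmap rendering, label-boundary extraction, and focus plotting."""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import LineCollection
from matplotlib.colors import ListedColormap
from matplotlib.tri import Triangulation

from .correspondence import SurfacePair
from .io_formats import VertexMap
from .mesh_core import FlatMesh, edges_of_faces

__all__ = ["RenderSpec", "extract_label_boundaries", "render_flatmap", "plot_foci"]


@dataclass
class RenderSpec:
    """How to draw a flatmap panel."""

    colormap: str = "viridis"
    vmin: float | None = None
    vmax: float | None = None
    label_colors: dict[int, tuple[float, float, float, float]] | None = None
    boundary_style: dict = field(default_factory=lambda: {
        "colors": "k", "linestyles": ":", "linewidths": 0.8})
    figsize: tuple[float, float] = (6.0, 5.0)
    dpi: int = 150

    def __post_init__(self) -> None:
        for v in (self.vmin, self.vmax):
            if v is not None and not np.isfinite(v):
                raise ValueError("value range must be finite")


def extract_label_boundaries(flat: FlatMesh, labels: VertexMap,
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Edges of the flat mesh whose two vertices carry different labels.

    Used to overlay compartment borders as dotted lines on functional maps.
    Returns ``(edges, segments)``: unique undirected vertex-index pairs and
    the matching (E, 2, 2) array of 2D endpoints.
    """
    vals = np.asarray(labels.values)
    if len(vals) != flat.n_vertices:
        raise ValueError("label map length does not match the flat mesh")
    e = edges_of_faces(flat.faces)
    e = np.sort(e, axis=1)
    e = np.unique(e, axis=0)
    diff = vals[e[:, 0]] != vals[e[:, 1]]
    edges = e[diff]
    segments = flat.coords2d[edges]
    return edges, segments


def render_flatmap(flat: FlatMesh, data: VertexMap, spec: RenderSpec,
                   path: str, boundaries: np.ndarray | None = None) -> str:
    """Render per-vertex data on the flat mesh and write an image file.

    Scalars are Gouraud-shaded per triangle (NaN vertices left as
    background); labels are flat-colored from ``spec.label_colors``.
    ``boundaries`` is the (E, 2, 2) segment array from
    :func:`extract_label_boundaries`, drawn dotted on top.
    """
    vals = np.asarray(data.values, dtype=float)
    if len(vals) != flat.n_vertices:
        raise ValueError("data length does not match the flat mesh")
    tri = Triangulation(flat.coords2d[:, 0], flat.coords2d[:, 1], flat.faces)
    fig, ax = plt.subplots(figsize=spec.figsize)
    ax.set_aspect("equal")
    ax.axis("off")
    if data.kind == "label":
        if spec.label_colors is None:
            raise ValueError("label rendering needs label_colors")
        present = set(int(v) for v in np.unique(vals))
        missing = present - set(spec.label_colors)
        if missing:
            raise ValueError(f"missing colors for labels {sorted(missing)}")
        keys = sorted(spec.label_colors)
        lut = {k: i for i, k in enumerate(keys)}
        cmap = ListedColormap([spec.label_colors[k] for k in keys])
        face_lab = vals[flat.faces].astype(int)
        # a face takes its majority vertex label (ties: smallest)
        from scipy import stats as _st
        face_val = _st.mode(face_lab, axis=1, keepdims=False).mode
        mapped = np.vectorize(lut.get)(face_val)
        ax.tripcolor(tri, facecolors=mapped, cmap=cmap,
                     vmin=-0.5, vmax=len(keys) - 0.5)
    else:
        mask = np.any(np.isnan(vals[flat.faces]), axis=1)
        tri.set_mask(mask)  # NaN-touching faces render as background
        plot_vals = np.where(np.isnan(vals), 0.0, vals)
        ax.tripcolor(tri, plot_vals, shading="gouraud", cmap=spec.colormap,
                     vmin=spec.vmin, vmax=spec.vmax)
    if boundaries is not None and len(boundaries):
        ax.add_collection(LineCollection(boundaries, **spec.boundary_style))
    fig.savefig(path, dpi=spec.dpi, metadata=_deterministic_metadata(path))
    plt.close(fig)
    return path


def _deterministic_metadata(path: str) -> dict | None:
    # strip timestamps so identical inputs give byte-identical rasters
    if path.endswith(".png"):
        return {"Software": None}
    if path.endswith(".svg"):
        return {"Date": None}
    return None


def plot_foci(flat: FlatMesh, pair: SurfacePair, foci: np.ndarray,
              flag_distance: float = 5.0,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map 3D activation foci (world mm) to flatmap coordinates.

    Each focus lands at the flat position of the vertex whose
    correspondence segment passes nearest (point-to-segment distance).
    Returns ``(coords2d, distances, flagged)``; foci farther than
    ``flag_distance`` mm from every segment are flagged rather than
    dropped, so off-structure coordinates remain visible to the caller.
    """
    foci = np.atleast_2d(np.asarray(foci, dtype=float))
    if not np.all(np.isfinite(foci)):
        raise ValueError("foci must be finite")
    S = pair.outer.vertices[flat.cut_provenance]
    E = pair.inner.vertices[flat.cut_provenance]
    D = E - S
    len2 = np.einsum("ij,ij->i", D, D)
    len2 = np.where(len2 == 0, 1.0, len2)
    coords = np.empty((len(foci), 2))
    dists = np.empty(len(foci))
    for i, p in enumerate(foci):
        W = p[None, :] - S
        t = np.clip(np.einsum("vj,vj->v", W, D) / len2, 0.0, 1.0)
        diff = W - t[:, None] * D
        d = np.sqrt(np.einsum("vj,vj->v", diff, diff))
        v = int(np.argmin(d))
        coords[i] = flat.coords2d[v]
        dists[i] = d[v]
    return coords, dists, dists > flag_distance
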
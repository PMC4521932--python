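"""Area-proportional relaxation of the flatmap.

With the hand-adjusted outline held fixed, interior vertices of the 2D
layout are moved so that each triangle's share of total map area matches
the share of grey-matter volume it represents.  The objective is a
weighted squared-log measure of disproportion,

    E(x) = sum_f  t_f * [ log( a_f(x) / (A * t_f) ) ]^2 ,

where ``a_f`` is the signed area of face ``f``, ``A`` the total map area
and ``t_f`` the face's target share (non-negative, summing to 1).  The log
makes over- and under-representation symmetric — a face at twice its
target costs the same as one at half — and matches the log-ratio used to
display distortion.  E is zero exactly when every share matches.  Any
inverted face (negative signed area) makes the objective infinite, acting
as a barrier that keeps the layout fold-over free.

Optimization is plain gradient descent on the free (interior) vertices
with an analytic gradient and backtracking line search; steps that would
invert a face are rejected and halved.  The trace of objective values is
strictly non-increasing by construction.  With the outline fixed, the
total signed area A of the triangulated disk is constant (it equals the
area of the boundary polygon), which the gradient exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import FlatMesh, triangle_areas

__all__ = ["FlattenProblem", "FlattenResult", "flatten_objective",
           "flatten_gradient", "optimize"]

_EPS_AREA = 1e-300  # signed areas at or below this count as inverted


@dataclass
class FlattenProblem:
    """An area-proportional relaxation problem.

    ``flat0`` is the initial layout (no inverted faces), ``target_fraction``
    the desired per-face area shares (sum to 1; zero-target faces are
    tolerated only with zero weight), and ``fixed_mask`` flags vertices held
    fixed (at minimum the outline; at least 3).
    """

    flat0: FlatMesh
    target_fraction: np.ndarray
    fixed_mask: np.ndarray

    def __post_init__(self) -> None:
        self.target_fraction = np.asarray(self.target_fraction, dtype=float)
        self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
        if self.target_fraction.shape != (self.flat0.n_faces,):
            raise ValueError("one target fraction per face required")
        if np.any(self.target_fraction < 0):
            raise ValueError("target fractions must be non-negative")
        if not np.isclose(self.target_fraction.sum(), 1.0, atol=1e-8):
            raise ValueError("target fractions must sum to 1")
        if self.fixed_mask.shape != (self.flat0.n_vertices,):
            raise ValueError("fixed mask must be per-vertex")
        if np.sum(self.fixed_mask) < 3:
            raise ValueError("need at least 3 fixed vertices")
        if np.any(triangle_areas(self.flat0) <= 0):
            raise ValueError("initial layout has inverted or degenerate faces")


@dataclass
class FlattenResult:
    flat: FlatMesh
    objective_trace: np.ndarray
    iterations: int
    converged: bool


def _objective_from_areas(areas: np.ndarray, targets: np.ndarray) -> float:
    if np.any(areas <= _EPS_AREA):
        return np.inf  # inverted/collapsed face: barrier
    active = targets > 0
    A = areas.sum()
    r = np.log(areas[active] / (A * targets[active]))
    return float(np.sum(targets[active] * r * r))


def flatten_objective(flat: FlatMesh, target_fraction: np.ndarray) -> float:
    """E = sum_f t_f log^2(a_f / (A t_f)); +inf if any face is inverted.

    Faces with zero target carry zero weight and contribute nothing while
    positively oriented, but still trigger the barrier if inverted."""
    return _objective_from_areas(triangle_areas(flat),
                                 np.asarray(target_fraction, dtype=float))


def flatten_gradient(coords: np.ndarray, faces: np.ndarray,
                     targets: np.ndarray) -> np.ndarray:
    """Analytic gradient of the objective w.r.t. all vertex coordinates.

    For face (i, j, k): da/dv_i = 0.5 * perp(v_k - v_j) with
    perp(x, y) = (y, -x) ... applied cyclically; the dA/dx term vanishes
    for interior vertices of a fixed-boundary disk and is included anyway
    for correctness on general meshes.
    """
    a, b, c = (coords[faces[:, i]] for i in range(3))
    areas = 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                   - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    A = areas.sum()
    active = targets > 0
    coef = np.zeros(len(faces))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log(np.where(active, areas, 1.0) / (A * np.where(active, targets, 1.0)))
    coef[active] = 2.0 * targets[active] * r[active] / areas[active]
    sum_coef_over_A = float(np.sum(2.0 * targets[active] * r[active])) / A

    grad = np.zeros_like(coords)

    def perp(v):  # d(signed area)/d(vertex): rotate opposite edge by +90 deg
        return 0.5 * np.column_stack([-v[:, 1], v[:, 0]])

    d_i, d_j, d_k = perp(c - b), perp(a - c), perp(b - a)
    for corner, d in ((0, d_i), (1, d_j), (2, d_k)):
        np.add.at(grad, faces[:, corner], coef[:, None] * d)
        np.add.at(grad, faces[:, corner], -sum_coef_over_A * d)
    return grad


def optimize(problem: FlattenProblem, max_iter: int = 2000,
             tol: float = 1e-6, initial_step: float | None = None,
             ) -> FlattenResult:
    """Gradient descent with backtracking; rejects inverting steps.

    Terminates when the relative objective change over an accepted step
    falls below ``tol``, the gradient step underflows, or ``max_iter`` is
    reached.  Fixed vertices never move; the objective trace is
    non-increasing; the output has no inverted faces.  Deterministic: the
    optimizer itself uses no randomness.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    flat0 = problem.flat0
    coords = flat0.coords2d.copy()
    faces = flat0.faces
    targets = problem.target_fraction
    free = ~problem.fixed_mask

    def fval(x):
        a, b, c = (x[faces[:, i]] for i in range(3))
        areas = 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                       - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
        return _objective_from_areas(areas, targets)

    trace = [fval(coords)]
    if not np.isfinite(trace[0]):
        raise ValueError("initial layout has inverted faces")

    # characteristic length for the first trial step
    span = np.ptp(coords, axis=0).max()
    step = initial_step if initial_step is not None else 0.1 * span
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = flatten_gradient(coords, faces, targets)
        g[~free] = 0.0
        gnorm = np.linalg.norm(g)
        if gnorm == 0:
            converged = True
            break
        direction = -g / gnorm
        f0 = trace[-1]
        accepted = False
        s = step
        for _ in range(60):
            trial = coords + s * direction
            f1 = fval(trial)
            # simple decrease; infinite f1 means an inverted face: halve
            if np.isfinite(f1) and f1 < f0:
                coords = trial
                trace.append(f1)
                accepted = True
                step = s * 2.0  # allow growth again next iteration
                break
            s *= 0.5
        if not accepted:
            converged = True  # no descent step found at any scale
            break
        if f0 > 0 and (f0 - trace[-1]) / f0 < tol:
            converged = True
            break
        if trace[-1] == 0.0:
            converged = True
            break

    out = FlatMesh(coords, faces.copy(),
                   boundary_vertex=flat0.boundary_vertex.copy(),
                   cut_provenance=flat0.cut_provenance.copy())
    return FlattenResult(flat=out, objective_trace=np.asarray(trace),
                         iterations=it, converged=converged)
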
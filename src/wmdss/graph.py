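"""White-matter voxel graphs with diffusion-ODF edge weights.

Vertices are white-matter voxels; edges connect lattice neighbors under
either the 3-conn (3x3x3, 26 neighbors) or the pruned 5-conn (5x5x5, 98
neighbors) definition. Each directed neighbor relation (i -> j) is scored
by the mean of voxel i's ODF over the spherical cone of solid angle
``4*pi/n_neighbors`` around the neighbor direction; per-voxel
normalization maps the cone means to q in [0, 0.5] (the argmax neighbor
gets exactly 0.5), the symmetrized sum w = q_ij + q_ji lands in [0, 1],
and a tunable sigmoid h(w; alpha, beta) sharpens the contrast between
strong- and weak-diffusion directions while keeping every nonzero weight
nonzero (which preserves graph connectivity).

The spectral domain is provided by the normalized graph Laplacian
``L = I - D^{-1/2} A D^{-1/2}``, whose spectrum lies in [0, 2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.special import expit

from .odf import AnalyticODFField, DirectionSet, ODFField

__all__ = [
    "NeighborhoodDef",
    "EdgeWeightParams",
    "WMGraph",
    "DegenerateVoxelError",
    "neighborhood_offsets",
    "cone_half_angle",
    "cone_directions",
    "odf_cone_measure",
    "normalize_q",
    "symmetric_weight",
    "sigmoid_threshold",
    "build_wm_graph",
    "normalized_laplacian",
]


class DegenerateVoxelError(ValueError):
    """Raised for voxels whose ODF cone means are all zero."""


@dataclass(frozen=True)
class NeighborhoodDef:
    """Voxel neighborhood on the cubic lattice.

    ``solid_angle_sr`` is the solid angle 4*pi/|offsets| assigned to each
    neighbor direction when discretizing the ODF.
    """

    kind: str
    offsets: np.ndarray  # (n, 3) int
    solid_angle_sr: float

    def __len__(self) -> int:
        return self.offsets.shape[0]

    @property
    def directions(self) -> np.ndarray:
        """Unit vectors toward each neighbor."""
        o = self.offsets.astype(float)
        return o / np.linalg.norm(o, axis=1, keepdims=True)


@dataclass(frozen=True)
class EdgeWeightParams:
    """Sigmoid-thresholding parameters for edge weights.

    alpha in (0, 1) sets the threshold level (h(alpha) = 0.5); beta > 0
    the steepness of the 0 -> 1 transition. The reference settings are
    alpha in {0.85, 0.9, 0.95} with beta = 50.
    """

    alpha: float = 0.9
    beta: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


def neighborhood_offsets(kind) -> NeighborhoodDef:
    """Return the 3-conn (26 offsets) or 5-conn (98 offsets) neighborhood.

    The 5-conn set keeps all 3-conn offsets and adds the 5x5x5 outer-layer
    offsets that are not collinear with an inner offset (those parallel
    directions would duplicate an already-represented orientation).
    """
    kind = str(kind)
    if kind in ("3", "3-conn"):
        rng = [-1, 0, 1]
        offsets = np.array([(i, j, k) for i in rng for j in rng for k in rng
                            if (i, j, k) != (0, 0, 0)], dtype=int)
        kind = "3-conn"
    elif kind in ("5", "5-conn"):
        inner = neighborhood_offsets("3").offsets
        inner_set = {tuple(o) for o in inner}
        outer = []
        rng = range(-2, 3)
        for i in rng:
            for j in rng:
                for k in rng:
                    o = (i, j, k)
                    if max(abs(i), abs(j), abs(k)) != 2:
                        continue
                    # exclude offsets collinear with an inner offset
                    g = np.gcd.reduce([abs(i), abs(j), abs(k)])
                    if tuple(np.array(o) // g) in inner_set:
                        continue
                    outer.append(o)
        offsets = np.vstack([inner, np.array(outer, dtype=int)])
        kind = "5-conn"
    else:
        raise ValueError(f"unknown neighborhood kind {kind!r}; use '3-conn' or '5-conn'")
    return NeighborhoodDef(kind=kind, offsets=offsets,
                           solid_angle_sr=4.0 * np.pi / len(offsets))


def cone_half_angle(solid_angle_sr: float) -> float:
    """Half-angle of the spherical cap with the given solid angle.

    Inverts the cap-area formula Omega = 2*pi*(1 - cos(theta)).
    """
    return float(np.arccos(1.0 - solid_angle_sr / (2.0 * np.pi)))


def cone_directions(center: np.ndarray, solid_angle_sr: float,
                    dense_set: DirectionSet) -> np.ndarray:
    """Dense-set directions within the cone around ``center``.

    Returns all members of ``dense_set`` within angular radius
    ``arccos(1 - Omega/2pi)`` of the (unit) center direction; if the cone
    captures no dense sample, the center itself is returned so that at
    least one sample is always available.
    """
    if len(dense_set) == 0:
        raise ValueError("dense direction set must be nonempty")
    center = np.asarray(center, dtype=float)
    center = center / np.linalg.norm(center)
    cos_cap = 1.0 - solid_angle_sr / (2.0 * np.pi)
    dots = dense_set.directions @ center
    members = dense_set.directions[dots >= cos_cap - 1e-12]
    if members.shape[0] == 0:
        members = center[None, :]
    return members


def _cone_sample_table(ndef: NeighborhoodDef, dense_set: DirectionSet) -> list[np.ndarray]:
    """Per-offset cone sample directions (the N_t samples of each cone)."""
    return [cone_directions(d, ndef.solid_angle_sr, dense_set)
            for d in ndef.directions]


def odf_cone_measure(field: ODFField, i, j, ndef: NeighborhoodDef,
                     dense_set: DirectionSet) -> float:
    """Sampled cone mean ``p~(i, r_ij)`` of voxel i's ODF toward neighbor j.

    The exact measure is the mean of O_i over the spherical cap of solid
    angle 4*pi/|neighborhood| around the direction from i to j; it is
    approximated by averaging O_i over the dense-set samples that fall
    inside the cap.
    """
    i = np.asarray(i, dtype=int)
    j = np.asarray(j, dtype=int)
    off = j - i
    match = np.all(ndef.offsets == off, axis=1)
    if not match.any():
        raise ValueError(f"voxel {tuple(j)} is not a {ndef.kind} neighbor of {tuple(i)}")
    samples = cone_directions(off.astype(float) / np.linalg.norm(off),
                              ndef.solid_angle_sr, dense_set)
    return float(field.evaluate(i[None, :], samples).mean())


def normalize_q(p_tilde: np.ndarray, degenerate: str = "raise") -> np.ndarray:
    """Normalize cone means to ``q = p~ / (2 max_j p~)`` in [0, 0.5].

    The neighbor along which the ODF attains its maximal cone mean gets
    exactly 0.5. All-zero input is degenerate: with ``degenerate="raise"``
    a :class:`DegenerateVoxelError` is raised; with ``"isotropic"`` the
    voxel is treated as an isotropic ODF of infinitesimal magnitude and
    every neighbor gets 0.5.
    """
    p = np.asarray(p_tilde, dtype=float)
    if np.any(p < 0):
        raise ValueError("cone means must be nonnegative")
    m = p.max() if p.size else 0.0
    if m <= 0.0:
        if degenerate == "isotropic":
            return np.full_like(p, 0.5)
        raise DegenerateVoxelError("all cone means are zero")
    return p / (2.0 * m)


def symmetric_weight(q_ij, q_ji):
    """Symmetric bidirectional diffusion weight ``w = q_ij + q_ji`` in [0, 1]."""
    return np.asarray(q_ij, dtype=float) + np.asarray(q_ji, dtype=float)


def sigmoid_threshold(x, alpha: float, beta: float):
    """Tunable sigmoid h mapping [0, 1] onto [0, 1].

    h(x) = ((1-alpha) x)^beta / (((1-alpha) x)^beta + ((1-x) alpha)^beta),
    evaluated in log space for numerical stability at large beta. h is
    nondecreasing with h(0) = 0, h(alpha) = 0.5, h(1) = 1, and maps every
    nonzero x to a nonzero value (up to floating-point underflow).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if beta <= 0:
        raise ValueError("beta must be positive")
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1.0 + 1e-12):
        raise ValueError("sigmoid argument must lie in [0, 1]")
    x = np.clip(x, 0.0, 1.0)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    zero = x == 0.0
    one = x == 1.0
    mid = ~(zero | one)
    out[zero] = 0.0
    out[one] = 1.0
    with np.errstate(divide="ignore"):
        t = beta * (np.log((1.0 - alpha) * x[mid]) - np.log(alpha * (1.0 - x[mid])))
    out[mid] = expit(t)
    return float(out[0]) if scalar else out


@dataclass
class WMGraph:
    """Weighted voxel graph of a white-matter mask.

    ``vertex_to_voxel`` maps vertex index -> integer voxel triple;
    ``voxel_to_vertex`` is the inverse 3D lookup (-1 outside the graph).
    ``adjacency`` is the symmetric sparse weight matrix with entries
    a_ij = h(w_ij) in [0, 1] and zero diagonal.
    """

    mask_shape: tuple
    vertex_to_voxel: np.ndarray  # (N, 3) int
    adjacency: sp.csr_matrix
    neighborhood: str
    params: EdgeWeightParams
    voxel_size_mm: float = 1.25
    n_dropped_voxels: int = 0

    @cached_property
    def voxel_to_vertex(self) -> np.ndarray:
        lut = np.full(self.mask_shape, -1, dtype=np.int64)
        v = self.vertex_to_voxel
        lut[v[:, 0], v[:, 1], v[:, 2]] = np.arange(v.shape[0])
        return lut

    @property
    def n_vertices(self) -> int:
        return self.vertex_to_voxel.shape[0]

    @cached_property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @cached_property
    def laplacian(self) -> sp.csr_matrix:
        return normalized_laplacian(self)

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.mask_shape, dtype=bool)
        v = self.vertex_to_voxel
        m[v[:, 0], v[:, 1], v[:, 2]] = True
        return m

    def signal_from_volume(self, volume: np.ndarray) -> np.ndarray:
        """Extract the graph signal (vertex-ordered vector) from a volume."""
        volume = np.asarray(volume)
        if volume.shape[:3] != self.mask_shape:
            raise ValueError(
                f"volume grid {volume.shape[:3]} does not match graph grid {self.mask_shape}"
            )
        v = self.vertex_to_voxel
        return volume[v[:, 0], v[:, 1], v[:, 2]]

    def volume_from_signal(self, signal: np.ndarray, fill=0.0,
                           out: np.ndarray | None = None) -> np.ndarray:
        """Scatter a graph signal back into a volume (``fill`` outside)."""
        signal = np.asarray(signal)
        if signal.shape[0] != self.n_vertices:
            raise ValueError("signal length does not match graph size")
        shape = self.mask_shape + signal.shape[1:]
        if out is None:
            out = np.full(shape, fill, dtype=float)
        v = self.vertex_to_voxel
        out[v[:, 0], v[:, 1], v[:, 2]] = signal
        return out


def _default_dense_set() -> DirectionSet:
    from .phantoms import icosphere  # local import to avoid cycle

    return icosphere(4)  # 2562 near-uniform directions


def _cone_mean_matrix(field: ODFField, voxels: np.ndarray,
                      ndef: NeighborhoodDef, dense_set: DirectionSet,
                      chunk: int = 65536) -> np.ndarray:
    """Cone means p~ for every (in-mask voxel, neighbor offset) pair."""
    tables = _cone_sample_table(ndef, dense_set)
    n = voxels.shape[0]
    P = np.empty((n, len(ndef)), dtype=float)
    for oi, samples in enumerate(tables):
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            P[sl, oi] = field.evaluate(voxels[sl], samples).mean(axis=1)
    return P


def build_wm_graph(
    field: ODFField,
    mask: np.ndarray | None = None,
    ndef: NeighborhoodDef | str = "5-conn",
    params: EdgeWeightParams | None = None,
    dense_set: DirectionSet | None = None,
) -> WMGraph:
    """Build the ODF-weighted voxel graph over a white-matter mask.

    One vertex per mask voxel; an edge joins voxels i, j whenever both
    are in the mask and j - i is a neighborhood offset, with weight
    a_ij = h(q_ij + q_ji). If the resulting graph is disconnected it is
    restricted to its largest connected component (with a warning), so
    that the normalized Laplacian is well defined on every vertex.
    """
    if isinstance(ndef, str):
        ndef = neighborhood_offsets(ndef)
    if params is None:
        params = EdgeWeightParams()
    if dense_set is None:
        dense_set = _default_dense_set()
    if mask is None:
        mask = field.mask
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3 or not mask.any():
        raise ValueError("mask must be a nonempty 3D boolean volume")

    voxels = np.argwhere(mask)
    n = voxels.shape[0]
    lut = np.full(mask.shape, -1, dtype=np.int64)
    lut[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = np.arange(n)

    # neighbor vertex index per (voxel, offset); -1 where absent
    shape = np.asarray(mask.shape)
    nbr = np.full((n, len(ndef)), -1, dtype=np.int64)
    for oi, off in enumerate(ndef.offsets):
        tgt = voxels + off
        ok = np.all((tgt >= 0) & (tgt < shape), axis=1)
        idx = lut[tgt[ok, 0], tgt[ok, 1], tgt[ok, 2]]
        rows = np.flatnonzero(ok)
        nbr[rows, oi] = idx  # -1 entries from lut mark out-of-mask targets

    valid = nbr >= 0
    P = _cone_mean_matrix(field, voxels, ndef, dense_set)
    if np.any(P < -1e-12):
        raise ValueError("ODF produced negative cone means")
    P = np.clip(P, 0.0, None)

    # per-voxel normalization over existing neighbors (Eq. 7), q in [0, 0.5]
    Pm = np.where(valid, P, 0.0)
    row_max = Pm.max(axis=1)
    q = np.zeros_like(P)
    pos = row_max > 0
    q[pos] = Pm[pos] / (2.0 * row_max[pos, None])
    # degenerate all-zero voxels: isotropic-in-the-limit convention
    q[~pos] = 0.5
    q[~valid] = 0.0

    # pair q_ij with q_ji through the negated-offset column
    neg_col = np.empty(len(ndef), dtype=int)
    for oi, off in enumerate(ndef.offsets):
        neg_col[oi] = int(np.flatnonzero(np.all(ndef.offsets == -off, axis=1))[0])

    rows_all, cols_all, w_all = [], [], []
    for oi in range(len(ndef)):
        if oi > neg_col[oi]:
            continue  # each undirected pair once
        i_idx = np.flatnonzero(valid[:, oi])
        j_idx = nbr[i_idx, oi]
        w = q[i_idx, oi] + q[j_idx, neg_col[oi]]
        rows_all.append(i_idx)
        cols_all.append(j_idx)
        w_all.append(w)
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    w = np.concatenate(w_all)
    a = sigmoid_threshold(w, params.alpha, params.beta)

    A = sp.coo_matrix((np.concatenate([a, a]),
                       (np.concatenate([rows, cols]),
                        np.concatenate([cols, rows]))), shape=(n, n)).tocsr()

    # restrict to the largest connected component if needed
    n_comp, labels = connected_components(A, directed=False)
    dropped = 0
    vertex_to_voxel = voxels
    if n_comp > 1:
        largest = np.argmax(np.bincount(labels))
        keep = labels == largest
        dropped = int(n - keep.sum())
        warnings.warn(
            f"graph is disconnected ({n_comp} components); restricting to the "
            f"largest component and dropping {dropped} voxels",
            stacklevel=2,
        )
        A = A[keep][:, keep].tocsr()
        vertex_to_voxel = voxels[keep]

    return WMGraph(
        mask_shape=mask.shape,
        vertex_to_voxel=np.ascontiguousarray(vertex_to_voxel),
        adjacency=A,
        neighborhood=ndef.kind,
        params=params,
        voxel_size_mm=float(getattr(field, "voxel_size_mm", 1.25)),
        n_dropped_voxels=dropped,
    )


def normalized_laplacian(graph) -> sp.csr_matrix:
    """Normalized Laplacian ``L = I - D^{-1/2} A D^{-1/2}`` (sparse, symmetric).

    Requires strictly positive degrees, which holds after largest-component
    restriction on any graph with at least two vertices.
    """
    A = graph.adjacency if isinstance(graph, WMGraph) else sp.csr_matrix(graph)
    d = np.asarray(A.sum(axis=1)).ravel()
    if np.any(d <= 0):
        raise DegenerateVoxelError("graph has zero-degree vertices")
    dinv = 1.0 / np.sqrt(d)
    L = sp.eye(A.shape[0], format="csr") - sp.diags(dinv) @ A @ sp.diags(dinv)
    return (L + L.T) / 2.0  # enforce exact symmetry
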
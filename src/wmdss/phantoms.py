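"""Synthetic validation phantoms for white-matter smoothing experiments.

Three phantom families are provided, each bundling a ground-truth
activation volume with an ODF field consistent with its geometry:

* circular phantoms -- a 1-voxel-thick circular "streamline" of a given
  radius and plane orientation, with high-concentration single-lobe ODFs
  along the local tangent and an isotropic background. Orientations are
  drawn near-uniformly from the 93 vertices of a 3x-subdivided
  icosahedron that fall in the nonnegative octant.
* streamline phantoms -- smooth random polylines (a synthetic stand-in
  for deterministic tractography) carrying diffuse, non-binary
  activations that decay anisotropically with arclength from a random
  focal point and with perpendicular distance from the curve.
* time-series phantoms -- a 100-frame block design (five 20-frame
  blocks, off-on-off-on-off) whose active frames carry the phantom
  truth, to be corrupted with white Gaussian noise and analyzed with a
  GLM.

All randomness is driven by explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .odf import AnalyticODFField, DirectionSet

__all__ = [
    "OrientationSet",
    "Phantom",
    "TimeSeriesPhantom",
    "Tractogram",
    "icosphere",
    "phantom_orientations",
    "make_circular_phantom",
    "synth_tractogram",
    "make_streamline_phantom",
    "make_timeseries",
    "add_noise",
    "DEFAULT_VOXEL_SIZE_MM",
]

DEFAULT_VOXEL_SIZE_MM = 1.25
# Watson-lobe concentration giving ~45 deg angular FWHM, the sharpness of a
# typical single-fiber diffusion ODF (much broader than a fiber FOD).
_DEFAULT_KAPPA = 5.0
_DEFAULT_FLOOR = 0.1    # isotropic floor under a fiber lobe


def icosphere(levels: int) -> DirectionSet:
    """Unit-sphere tessellation by recursive icosahedron subdivision.

    Starts from the canonical icosahedron (cyclic permutations of
    (0, +-1, +-phi), normalized) and performs ``levels`` rounds of
    edge-midpoint subdivision with reprojection onto the sphere. Level L
    has 10 * 4**L + 2 vertices; the vertex set is antipodally symmetric.
    """
    if levels < 0:
        raise ValueError("levels must be >= 0")
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    base = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            base += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
    verts = np.asarray(base)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = ConvexHull(verts).simplices
    for _ in range(levels):
        new_verts = [tuple(v) for v in verts]
        midpoint_cache: dict = {}

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in midpoint_cache:
                m = verts[i] + verts[j]
                m = m / np.linalg.norm(m)
                midpoint_cache[key] = len(new_verts)
                new_verts.append(tuple(m))
            return midpoint_cache[key]

        new_faces = []
        for i, j, k in faces:
            a, b, c = midpoint(i, j), midpoint(j, k), midpoint(k, i)
            new_faces += [(i, a, c), (a, j, b), (c, b, k), (a, b, c)]
        verts = np.asarray(new_verts)
        faces = np.asarray(new_faces)
    return DirectionSet(directions=verts, antipodal_symmetric=True)


@dataclass(frozen=True)
class OrientationSet:
    """Near-uniform 3D orientations for phantom construction.

    The 93 vertices of the level-3 icosphere (642 vertices) that fall in
    the closed spherical sector 0 <= theta, phi <= pi/2 (polar angle
    from +z, azimuth from +x toward +y), i.e. the nonnegative octant.
    """

    vectors: np.ndarray

    def __len__(self) -> int:
        return self.vectors.shape[0]


def phantom_orientations(tol: float = 1e-9) -> OrientationSet:
    """Select the octant subset of the level-3 icosphere (93 orientations)."""
    v = icosphere(3).directions
    keep = np.all(v >= -tol, axis=1)  # closed sector: boundary inclusive
    return OrientationSet(vectors=v[keep])


@dataclass
class Phantom:
    """Ground-truth activation plus a geometry-consistent ODF field."""

    truth: np.ndarray          # 3D; binary (circular) or diffuse in [0, 1]
    odf_field: AnalyticODFField
    mask: np.ndarray           # 3D boolean
    meta: dict = field(default_factory=dict)


@dataclass
class TimeSeriesPhantom:
    """Block-design 4D series built on a spatial phantom."""

    series: np.ndarray   # (x, y, z, t)
    design: np.ndarray   # (t,) activity indicator
    phantom: Phantom
    amplitude: float = 1.0


def _tangent_lobe_field(mask_shape, on_voxels: np.ndarray, tangents: np.ndarray,
                        background: str, kappa: float, floor_on: float,
                        voxel_size_mm: float, max_lobes: int = 1,
                        extra: list | None = None) -> AnalyticODFField:
    """Analytic field: tangent-aligned lobes on given voxels, isotropic elsewhere."""
    shape = tuple(mask_shape)
    axes = np.zeros(shape + (max_lobes, 3))
    axes[..., 2] = 1.0
    kappas = np.full(shape + (max_lobes,), kappa)
    weights = np.zeros(shape + (max_lobes,))
    bg = 1.0 if background == "isotropic" else 0.0
    floor = np.full(shape, bg)
    i, j, k = on_voxels[:, 0], on_voxels[:, 1], on_voxels[:, 2]
    axes[i, j, k, 0] = tangents
    weights[i, j, k, 0] = 1.0
    floor[i, j, k] = floor_on
    if extra:  # second-lobe assignments: list of (voxel, axis)
        for (vi, vj, vk), ax in extra:
            axes[vi, vj, vk, 1] = ax
            weights[vi, vj, vk, 1] = 1.0
    mask = np.ones(shape, dtype=bool)
    return AnalyticODFField(mask, axes, kappas, weights, floor, voxel_size_mm)


def make_circular_phantom(
    normal,
    radius_vox: float,
    shape=(64, 64, 64),
    background: str = "tangent",
    tube_radius_vox: float = 1.0 / np.sqrt(np.pi),
    kappa: float = _DEFAULT_KAPPA,
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM,
) -> Phantom:
    """Circular-streamline phantom with tangent-aligned ODFs.

    The activation is the binary rasterization of a circle of
    ``radius_vox`` voxels lying in the plane through the volume center
    with the given normal, as a thin tube of cross-sectional area ~1
    voxel^2 (``tube_radius_vox = 1/sqrt(pi)``), so the voxel count
    tracks the circumference 2*pi*radius. The mask covers the full
    volume.

    The ODF map represents strong diffusion along the circle. With the
    default ``background="tangent"`` every voxel carries a single-lobe
    ODF along the tangent of the concentric circle through it (the
    activation circle lies inside a volume-filling field of coaxial
    circular fibers; only voxels within 1 voxel of the axis, where the
    tangent is ill-defined, are isotropic). ``background="isotropic"``
    restricts tangent lobes to activation voxels with an isotropic
    background, and ``background="none"`` additionally zeroes the
    background ODF amplitude.
    """
    if background not in ("tangent", "isotropic", "none"):
        raise ValueError("background must be 'tangent', 'isotropic' or 'none'")
    normal = np.asarray(normal, dtype=float)
    nn = np.linalg.norm(normal)
    if nn == 0:
        raise ValueError("normal must be nonzero")
    normal = normal / nn
    shape = tuple(int(s) for s in shape)
    if radius_vox + tube_radius_vox + 2.0 > min(shape) / 2.0:
        raise ValueError(
            f"circle of radius {radius_vox} does not fit in shape {shape} "
            "with a 2-voxel margin"
        )
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0

    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"), axis=-1)
    rel = grid - center
    axial = rel @ normal                      # signed distance to the plane
    in_plane = rel - axial[..., None] * normal
    rho = np.linalg.norm(in_plane, axis=-1)
    dist = np.sqrt((rho - radius_vox) ** 2 + axial**2)  # distance to the circle
    truth = (dist <= tube_radius_vox).astype(float)

    if background == "tangent":
        # tangent field of the concentric circles through every voxel
        on = np.argwhere(rho >= 1.0)
    else:
        on = np.argwhere(truth > 0)
    radial = in_plane[on[:, 0], on[:, 1], on[:, 2]]
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    tangents = np.cross(np.broadcast_to(normal, radial.shape), radial)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    bg = "isotropic" if background == "tangent" else background
    fld = _tangent_lobe_field(shape, on, tangents, bg, kappa,
                              _DEFAULT_FLOOR, voxel_size_mm)
    return Phantom(truth=truth, odf_field=fld, mask=np.ones(shape, dtype=bool),
                   meta={"type": "circular", "normal": normal,
                         "radius_vox": float(radius_vox), "shape": shape})


@dataclass
class Tractogram:
    """Synthetic streamline bundle plus the ODF field it induces."""

    streamlines: list            # list of (L_i, 3) float arrays, voxel coords
    odf_field: AnalyticODFField
    shape: tuple

    @property
    def lengths(self) -> np.ndarray:
        return np.array([np.linalg.norm(np.diff(s, axis=0), axis=1).sum()
                         for s in self.streamlines])


def synth_tractogram(
    n_streamlines: int,
    shape=(64, 64, 64),
    length_range=(30.0, 120.0),
    curvature_std: float = 0.08,
    step: float = 0.5,
    margin: float = 2.0,
    kappa: float = _DEFAULT_KAPPA,
    voxel_size_mm: float = DEFAULT_VOXEL_SIZE_MM,
    seed: int = 0,
) -> Tractogram:
    """Generate smooth random polylines and a consistent ODF field.

    Streamlines are grown by a direction random walk with per-step
    angular perturbation of magnitude ``curvature_std`` (radians per
    step), which yields slowly curving, spline-like arcs. Growth stops
    when the target length is reached or the margin is hit, so every
    polyline lies strictly inside the volume. Voxels traversed by a
    streamline receive a sharp lobe along the local tangent (a second
    lobe is added where two streamlines cross at a wide angle); all
    other voxels are isotropic. Deterministic given ``seed``.
    """
    if n_streamlines < 1:
        raise ValueError("n_streamlines must be >= 1")
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    lo = np.full(3, margin)
    hi = np.asarray(shape, dtype=float) - 1.0 - margin

    streamlines = []
    for _ in range(n_streamlines):
        target_len = rng.uniform(*length_range)
        p = rng.uniform(lo + 2, hi - 2)
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        pts = [p.copy()]
        travelled = 0.0
        while travelled < target_len:
            d = d + curvature_std * rng.normal(size=3)
            d /= np.linalg.norm(d)
            p = p + step * d
            if np.any(p < lo) or np.any(p > hi):
                break
            pts.append(p.copy())
            travelled += step
        if len(pts) >= 2:
            streamlines.append(np.asarray(pts))

    # voxelize tangents; allow a crossing second lobe
    tangent_of: dict = {}
    extra = []
    for s in streamlines:
        tans = np.gradient(s, axis=0)
        tans /= np.linalg.norm(tans, axis=1, keepdims=True)
        vox = np.round(s).astype(int)
        for v, t in zip(map(tuple, vox), tans):
            if v not in tangent_of:
                tangent_of[v] = t
            elif abs(float(tangent_of[v] @ t)) < np.cos(np.deg2rad(30.0)):
                extra.append((v, t))
    on = np.array(sorted(tangent_of), dtype=int).reshape(-1, 3)
    tangents = np.array([tangent_of[tuple(v)] for v in on])

    fld = _tangent_lobe_field(shape, on, tangents, "isotropic", kappa,
                              _DEFAULT_FLOOR, voxel_size_mm,
                              max_lobes=2, extra=extra)
    return Tractogram(streamlines=streamlines, odf_field=fld, shape=shape)


def make_streamline_phantom(
    tractogram: Tractogram,
    n_active: int,
    sigma_par: float = 6.0,
    sigma_perp: float = 1.5,
    seed: int = 0,
) -> Phantom:
    """Diffuse streamline-shaped activations on a synthetic tractogram.

    ``n_active`` streamlines are selected without replacement with
    probability proportional to their length (a non-uniform spread that
    favors long bundles). On each, a focal point is drawn uniformly and
    the activation decays as ``exp(-s^2 / 2 sigma_par^2) *
    exp(-d^2 / 2 sigma_perp^2)`` with s the arclength from the focus
    along the streamline and d the distance from the curve; the truth
    volume is the voxel-wise maximum over activations, in [0, 1], with
    value 1 at each focal voxel.
    """
    n_avail = len(tractogram.streamlines)
    if n_active > n_avail:
        raise ValueError(f"n_active ({n_active}) exceeds available streamlines ({n_avail})")
    rng = np.random.default_rng(seed)
    lengths = tractogram.lengths
    prob = lengths / lengths.sum()
    chosen = rng.choice(n_avail, size=n_active, replace=False, p=prob)

    shape = tractogram.shape
    truth = np.zeros(shape)
    reach = int(np.ceil(3.0 * sigma_perp))
    for si in chosen:
        s = tractogram.streamlines[si]
        seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        focus = rng.integers(0, s.shape[0])
        rel_arc = arc - arc[focus]
        amp = np.exp(-(rel_arc**2) / (2.0 * sigma_par**2))
        pts = s.copy()
        pts[focus] = np.round(s[focus])  # focal voxel carries truth exactly 1
        for p, a in zip(pts, amp):
            if a < 1e-4:
                continue
            c = np.round(p).astype(int)
            sl = tuple(slice(max(c[ax] - reach, 0), min(c[ax] + reach + 1, shape[ax]))
                       for ax in range(3))
            sub = np.stack(np.meshgrid(*[np.arange(sl[ax].start, sl[ax].stop)
                                         for ax in range(3)], indexing="ij"), axis=-1)
            d2 = np.sum((sub - p) ** 2, axis=-1)
            val = a * np.exp(-d2 / (2.0 * sigma_perp**2))
            np.maximum(truth[sl], val, out=truth[sl])

    return Phantom(truth=truth, odf_field=tractogram.odf_field,
                   mask=np.ones(shape, dtype=bool),
                   meta={"type": "streamline", "n_active": int(n_active),
                         "sigma_par": sigma_par, "sigma_perp": sigma_perp})


def make_timeseries(phantom: Phantom, n_vol: int = 100, block: int = 20,
                    amplitude: float = 1.0) -> TimeSeriesPhantom:
    """Block-design series: rest/activity in an off-on-off-on-off paradigm.

    Frame t equals ``amplitude * truth * design[t]`` (noise is added
    separately with :func:`add_noise`); the design is five consecutive
    ``block``-frame stretches alternating rest and activity, starting
    and ending with rest.
    """
    if n_vol != 5 * block:
        raise ValueError("n_vol must equal 5 equal blocks (off-on-off-on-off)")
    design = np.concatenate([np.zeros(block), np.ones(block), np.zeros(block),
                             np.ones(block), np.zeros(block)])
    series = amplitude * phantom.truth[..., None] * design[None, None, None, :]
    return TimeSeriesPhantom(series=series, design=design, phantom=phantom,
                             amplitude=float(amplitude))


def add_noise(data: np.ndarray, sigma: float = 1.0, n_realizations: int = 10,
              seed: int = 0) -> np.ndarray:
    """Seeded additive white Gaussian noise realizations.

    Returns an array of ``n_realizations`` independent noisy copies
    (stacked on a new leading axis). Realization i is generated from the
    i-th child of ``SeedSequence(seed)``, so the same (seed, index) pair
    always yields the same copy and adding realizations never perturbs
    earlier ones.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    data = np.asarray(data, dtype=float)
    children = np.random.SeedSequence(seed).spawn(n_realizations)
    out = np.empty((n_realizations,) + data.shape)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        out[i] = data if sigma == 0 else data + sigma * rng.standard_normal(data.shape)
    return out
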
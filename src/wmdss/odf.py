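"""Diffusion orientation distribution function (ODF) fields.

An ODF is an antipodally symmetric, nonnegative function on the unit
sphere attached to each voxel, summarizing the magnitude of water
diffusion along each direction. This module provides the two concrete
representations used throughout the package:

* :class:`AnalyticODFField` -- a parametric field built from
  Watson-like lobes ``exp(kappa * ((axis . r)^2 - 1))`` plus an
  isotropic floor.  Used by the phantom simulators, where the fiber
  geometry is known analytically.
* :class:`TabulatedODFField` -- per-voxel sample values over a fixed
  direction set (the generic 4D-samples + direction-file convention),
  evaluated by nearest-direction or inverse-angular-distance
  interpolation.

Both expose the same evaluation interface consumed by the graph
builder: values at arbitrary unit directions, for single voxels or
vectorized over many voxels at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DirectionSet",
    "AnalyticODF",
    "ODFField",
    "AnalyticODFField",
    "TabulatedODFField",
    "evaluate_odf",
    "tabulated_odf_from_samples",
    "OutsideMaskError",
]

_UNIT_TOL = 1e-9


class OutsideMaskError(ValueError):
    """Raised when an ODF is evaluated at a voxel outside the mask."""


def _as_unit_rows(directions: np.ndarray, tol: float = _UNIT_TOL) -> np.ndarray:
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.shape[-1] != 3:
        raise ValueError(f"directions must be 3-vectors, got shape {directions.shape}")
    norms = np.linalg.norm(directions, axis=-1)
    if np.any(np.abs(norms - 1.0) > tol):
        raise ValueError("directions must have unit norm (tol %.0e)" % tol)
    return directions


@dataclass(frozen=True)
class DirectionSet:
    """A fixed set of unit direction vectors on the sphere.

    Parameters
    ----------
    directions : (n, 3) ndarray
        Unit vectors (validated at construction, tolerance 1e-9).
    antipodal_symmetric : bool
        If True, the set either contains -v for every v, or is
        interpreted over the projective sphere (directions identified
        with their antipodes).
    """

    directions: np.ndarray
    antipodal_symmetric: bool = True

    def __post_init__(self) -> None:
        d = _as_unit_rows(self.directions)
        object.__setattr__(self, "directions", d)

    def __len__(self) -> int:
        return self.directions.shape[0]

    def contains_antipodes(self, tol: float = 1e-8) -> bool:
        """Check that -v is a member for every member v."""
        d = self.directions
        dots = d @ d.T
        return bool(np.all(dots.min(axis=1) <= -1.0 + tol))


@dataclass(frozen=True)
class AnalyticODF:
    """Single-voxel analytic ODF: isotropic floor plus Watson-like lobes.

    Each lobe contributes ``weight * exp(kappa * ((axis . r)^2 - 1))``,
    i.e. a symmetric bell around +-axis normalized to peak value
    ``weight``.  The sum is antipodally symmetric by construction.
    """

    lobes: tuple = ()  # sequence of (axis, kappa, weight)
    isotropic_floor: float = 0.0

    def __post_init__(self) -> None:
        lobes = []
        for axis, kappa, weight in self.lobes:
            axis = np.asarray(axis, dtype=float)
            axis = axis / np.linalg.norm(axis)
            if kappa < 0 or weight < 0:
                raise ValueError("lobe concentration and weight must be nonnegative")
            lobes.append((axis, float(kappa), float(weight)))
        object.__setattr__(self, "lobes", tuple(lobes))
        if self.isotropic_floor < 0:
            raise ValueError("isotropic_floor must be nonnegative")

    def __call__(self, directions: np.ndarray) -> np.ndarray:
        d = _as_unit_rows(directions)
        out = np.full(d.shape[0], self.isotropic_floor, dtype=float)
        for axis, kappa, weight in self.lobes:
            c2 = (d @ axis) ** 2
            out += weight * np.exp(kappa * (c2 - 1.0))
        return out


class ODFField:
    """Base class for per-voxel ODF fields over a 3D mask."""

    mask: np.ndarray
    voxel_size_mm: float

    def _check_voxels(self, voxels: np.ndarray) -> np.ndarray:
        voxels = np.atleast_2d(np.asarray(voxels, dtype=int))
        if voxels.shape[-1] != 3:
            raise ValueError("voxel indices must be integer triples")
        shape = np.asarray(self.mask.shape)
        if np.any(voxels < 0) or np.any(voxels >= shape):
            raise OutsideMaskError("voxel index outside the volume")
        inside = self.mask[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        if not np.all(inside):
            raise OutsideMaskError("ODF evaluation requested outside the mask")
        return voxels

    def evaluate(self, voxels: np.ndarray, directions: np.ndarray) -> np.ndarray:
        """Evaluate the field at voxel/direction pairs.

        Parameters
        ----------
        voxels : (n, 3) int array (or a single triple)
        directions : (m, 3) float array of unit vectors

        Returns
        -------
        (n, m) ndarray of nonnegative ODF values.
        """
        raise NotImplementedError


class AnalyticODFField(ODFField):
    """Field of analytic ODFs with per-voxel lobe parameters.

    Lobe parameters are stored as dense grid arrays so that evaluation
    over many voxels and directions is a single vectorized expression;
    voxels with all lobe weights zero are purely isotropic.
    """

    def __init__(
        self,
        mask: np.ndarray,
        lobe_axes: np.ndarray,
        lobe_kappas: np.ndarray,
        lobe_weights: np.ndarray,
        isotropic_floor: np.ndarray | float,
        voxel_size_mm: float = 1.25,
    ) -> None:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim != 3:
            raise ValueError("mask must be a 3D boolean volume")
        shape = mask.shape
        lobe_axes = np.asarray(lobe_axes, dtype=float)
        if lobe_axes.shape[:3] != shape or lobe_axes.shape[-1] != 3:
            raise ValueError("lobe_axes must have shape (X, Y, Z, n_lobes, 3)")
        self.mask = mask
        self.lobe_axes = lobe_axes
        self.lobe_kappas = np.asarray(lobe_kappas, dtype=float)
        self.lobe_weights = np.asarray(lobe_weights, dtype=float)
        floor = np.asarray(isotropic_floor, dtype=float)
        if floor.ndim == 0:
            floor = np.full(shape, float(floor))
        self.isotropic_floor = floor
        if voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        self.voxel_size_mm = float(voxel_size_mm)

    @classmethod
    def isotropic(cls, mask: np.ndarray, value: float = 1.0, n_lobes: int = 1,
                  voxel_size_mm: float = 1.25) -> "AnalyticODFField":
        shape = np.asarray(mask, dtype=bool).shape
        axes = np.zeros(shape + (n_lobes, 3))
        axes[..., 2] = 1.0  # dummy axis; weight 0 makes it inert
        return cls(mask, axes, np.ones(shape + (n_lobes,)),
                   np.zeros(shape + (n_lobes,)), value, voxel_size_mm)

    def evaluate(self, voxels: np.ndarray, directions: np.ndarray) -> np.ndarray:
        voxels = self._check_voxels(voxels)
        d = _as_unit_rows(directions)
        i, j, k = voxels[:, 0], voxels[:, 1], voxels[:, 2]
        axes = self.lobe_axes[i, j, k]          # (n, K, 3)
        kappas = self.lobe_kappas[i, j, k]      # (n, K)
        weights = self.lobe_weights[i, j, k]    # (n, K)
        dots = np.einsum("nkc,mc->nkm", axes, d)
        vals = weights[..., None] * np.exp(kappas[..., None] * (dots**2 - 1.0))
        return self.isotropic_floor[i, j, k][:, None] + vals.sum(axis=1)


class TabulatedODFField(ODFField):
    """ODF field given by per-voxel samples over a direction set.

    Evaluation at an arbitrary direction uses the projective angular
    distance (so antipodal symmetry holds by construction) with either
    nearest-direction lookup or Shepard inverse-angular-distance
    interpolation over the ``k_neighbors`` closest tabulated
    directions. An exact hit on a tabulated direction returns the
    stored sample under both schemes.
    """

    def __init__(
        self,
        samples: np.ndarray,
        mask: np.ndarray,
        direction_set: DirectionSet,
        interpolation: str = "nearest",
        k_neighbors: int = 3,
        voxel_size_mm: float = 1.25,
    ) -> None:
        mask = np.asarray(mask, dtype=bool)
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 4 or samples.shape[:3] != mask.shape:
            raise ValueError("samples must be 4D (x, y, z, n_directions) over the mask grid")
        if samples.shape[3] != len(direction_set):
            raise ValueError(
                f"sample count per voxel ({samples.shape[3]}) must equal "
                f"|DirectionSet| ({len(direction_set)})"
            )
        if np.any(samples[mask] < 0):
            raise ValueError("ODF samples must be nonnegative")
        if interpolation not in ("nearest", "inverse-distance"):
            raise ValueError(f"unknown interpolation {interpolation!r}")
        self.samples = samples
        self.mask = mask
        self.direction_set = direction_set
        self.interpolation = interpolation
        self.k_neighbors = int(k_neighbors)
        self.voxel_size_mm = float(voxel_size_mm)

    def evaluate(self, voxels: np.ndarray, directions: np.ndarray) -> np.ndarray:
        voxels = self._check_voxels(voxels)
        d = _as_unit_rows(directions)
        table = self.direction_set.directions
        # projective angle: arccos(|d . t|)
        absdot = np.clip(np.abs(d @ table.T), 0.0, 1.0)  # (m, n_table)
        vox_samples = self.samples[voxels[:, 0], voxels[:, 1], voxels[:, 2]]  # (n, S)
        if self.interpolation == "nearest":
            idx = np.argmax(absdot, axis=1)  # (m,)
            return vox_samples[:, idx]
        ang = np.arccos(absdot)  # (m, S)
        k = min(self.k_neighbors, ang.shape[1])
        nn = np.argpartition(ang, k - 1, axis=1)[:, :k]  # (m, k)
        ang_nn = np.take_along_axis(ang, nn, axis=1)
        out = np.empty((vox_samples.shape[0], d.shape[0]))
        for m in range(d.shape[0]):
            a = ang_nn[m]
            if a.min() < 1e-12:  # exact tabulated direction
                out[:, m] = vox_samples[:, nn[m][np.argmin(a)]]
            else:
                w = 1.0 / a
                w = w / w.sum()
                out[:, m] = vox_samples[:, nn[m]] @ w
        return out


def evaluate_odf(field: ODFField, voxel, direction) -> float:
    """Evaluate ``O_i(r)`` for a single voxel and unit direction.

    Raises
    ------
    OutsideMaskError
        If the voxel lies outside the field's mask.
    ValueError
        If the direction is not unit-norm (tolerance 1e-9).
    """
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > _UNIT_TOL:
        raise ValueError("direction must be unit-norm")
    return float(field.evaluate(np.asarray(voxel)[None, :], direction[None, :])[0, 0])


def tabulated_odf_from_samples(
    samples: np.ndarray,
    mask: np.ndarray,
    direction_set: DirectionSet,
    interpolation: str = "nearest",
    voxel_size_mm: float = 1.25,
) -> TabulatedODFField:
    """Build a :class:`TabulatedODFField` from a 4D sample array."""
    return TabulatedODFField(samples, mask, direction_set,
                             interpolation=interpolation,
                             voxel_size_mm=voxel_size_mm)
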
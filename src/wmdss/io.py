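"""File I/O: NIfTI volumes, direction files, graph exports.

Conventions: volumes and masks are NIfTI-1 (nonzero = in-mask); ODF
sample sets are 4D NIfTI (x, y, z, n_directions) plus a plain-text
direction file with one whitespace-separated unit vector per line;
graphs are exported as TSV edge lists and Matrix Market Laplacians, and
round-tripped internally through a compressed ``.npz`` container. All
voxel indices in files are 0-based; world coordinates live only in the
NIfTI affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite

from .graph import EdgeWeightParams, WMGraph
from .odf import DirectionSet

__all__ = [
    "read_volume",
    "write_volume",
    "read_directions",
    "write_directions",
    "check_same_grid",
    "write_edge_list",
    "write_laplacian_mtx",
    "save_graph",
    "load_graph",
]


def read_volume(path):
    """Load a 3D/4D NIfTI volume; returns ``(data, img)``."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected a 3D or 4D volume, got ndim={data.ndim}")
    return data, img


def write_volume(data: np.ndarray, path, ref_img=None, affine=None) -> None:
    """Write a volume as NIfTI-1, copying affine/header from ``ref_img``."""
    data = np.asarray(data)
    if ref_img is not None:
        img = nib.Nifti1Image(data, ref_img.affine, header=ref_img.header)
    else:
        img = nib.Nifti1Image(data, np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def read_directions(path) -> DirectionSet:
    """Read a plain-text direction file (one unit vector per line)."""
    arr = np.loadtxt(str(path), ndmin=2)
    if arr.shape[1] != 3:
        raise ValueError(f"{path}: direction file must have 3 columns")
    return DirectionSet(directions=arr)


def write_directions(dirset: DirectionSet, path) -> None:
    np.savetxt(str(path), dirset.directions, fmt="%.12f")


def check_same_grid(img_a, img_b, atol: float = 1e-4) -> None:
    """Hard error if two NIfTI images disagree on grid or affine."""
    if img_a.shape[:3] != img_b.shape[:3]:
        raise ValueError(f"grid mismatch: {img_a.shape[:3]} vs {img_b.shape[:3]}")
    if not np.allclose(img_a.affine, img_b.affine, atol=atol):
        raise ValueError(
            "affine mismatch between volumes:\n"
            f"{img_a.affine}\nvs\n{img_b.affine}"
        )


def write_edge_list(graph: WMGraph, path) -> None:
    """Export graph edges as TSV: vertex_i, vertex_j, weight (i < j)."""
    A = sp.triu(graph.adjacency, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in zip(A.row, A.col, A.data):
            fh.write(f"{i}\t{j}\t{w:.12g}\n")


def write_laplacian_mtx(graph: WMGraph, path) -> None:
    """Export the normalized Laplacian in Matrix Market format."""
    mmwrite(str(path), sp.coo_matrix(graph.laplacian))


def save_graph(graph: WMGraph, path) -> None:
    """Serialize a graph (adjacency + vertex map + parameters) to .npz."""
    A = graph.adjacency.tocoo()
    meta = dict(
        mask_shape=list(graph.mask_shape),
        neighborhood=graph.neighborhood,
        alpha=graph.params.alpha,
        beta=graph.params.beta,
        voxel_size_mm=graph.voxel_size_mm,
        n_dropped_voxels=graph.n_dropped_voxels,
    )
    np.savez_compressed(
        str(path),
        vertex_to_voxel=graph.vertex_to_voxel,
        row=A.row, col=A.col, weight=A.data,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_graph(path) -> WMGraph:
    with np.load(str(path)) as z:
        meta = json.loads(bytes(z["meta"].tobytes()).decode())
        v2v = z["vertex_to_voxel"]
        n = v2v.shape[0]
        A = sp.coo_matrix((z["weight"], (z["row"], z["col"])), shape=(n, n)).tocsr()
    return WMGraph(
        mask_shape=tuple(meta["mask_shape"]),
        vertex_to_voxel=v2v,
        adjacency=A,
        neighborhood=meta["neighborhood"],
        params=EdgeWeightParams(alpha=meta["alpha"], beta=meta["beta"]),
        voxel_size_mm=meta["voxel_size_mm"],
        n_dropped_voxels=meta["n_dropped_voxels"],
    )
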
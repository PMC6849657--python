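"""Single-subject gray-matter covariance network construction.

The subject's volume is tiled into non-overlapping 3x3x3-voxel cubes (the
network nodes), every pair of cubes is scored by the Pearson correlation r
between their 27 voxel values, and the resulting similarity matrix is
thresholded into a binary adjacency matrix.  Thresholding either uses a
fixed correlation cut or calibrates the cut from within-vector permutations
so that the expected false-positive edge rate equals a requested level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from nibabel.affines import apply_affine

from .volume import GrayMatterVolume

__all__ = [
    "CubeNodeSet",
    "SimilarityMatrix",
    "BinaryNetwork",
    "DegenerateSubjectError",
    "ContractViolation",
    "parcellate_cubes",
    "compute_similarity",
    "threshold_network",
]

_SYMMETRY_TOL = 1e-12
_VAR_TOL = 1e-12  # std below this is numerically zero (constant cube)


class DegenerateSubjectError(ValueError):
    """No cube of the subject's volume qualifies as a network node."""


class ContractViolation(ValueError):
    """An internal data contract (symmetry, variance, shape) was broken."""


@dataclass
class CubeNodeSet:
    """Nodes of one subject's network: per-cube voxel-value vectors.

    ``node_values[i]`` holds cube i's voxel values in fixed C order (x, y, z
    fastest-last within the cube); ``centroids[i]`` is the cube center in
    world mm; ``cube_origins[i]`` the cube's corner voxel index.
    """

    node_values: np.ndarray  # (n_nodes, cube_edge**3)
    centroids: np.ndarray  # (n_nodes, 3) world mm
    node_ids: np.ndarray  # (n_nodes,) stable integer ids
    cube_origins: np.ndarray  # (n_nodes, 3) voxel indices
    cube_edge: int = 3

    @property
    def n_nodes(self) -> int:
        return int(self.node_values.shape[0])


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise Pearson correlations, unit diagonal."""

    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ContractViolation("similarity matrix must be square")
        self.r = r

    @property
    def n_nodes(self) -> int:
        return int(self.r.shape[0])


@dataclass
class BinaryNetwork:
    """Thresholded network: symmetric 0/1 adjacency with zero diagonal."""

    adjacency: np.ndarray
    threshold_used: float
    method: str = "fixed_r"

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ContractViolation("adjacency must be square")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return int(self.adjacency.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def parcellate_cubes(
    volume: GrayMatterVolume,
    min_gm: float = 0.1,
    cube_edge: int = 3,
) -> CubeNodeSet:
    """Tile the volume into cube nodes and retain gray-matter-bearing cubes.

    Cubes are tiled from the volume origin; partial cubes at the far
    boundaries are dropped.  A cube becomes a node iff its mean voxel value
    exceeds ``min_gm`` (a gray-matter floor, the standard VBM masking
    convention) *and* its values have nonzero variance (a constant cube has
    no defined correlation with anything).
    """
    if cube_edge < 1:
        raise ValueError("cube_edge must be >= 1")
    v = volume.values
    if any(s < cube_edge for s in v.shape):
        raise ValueError(
            f"volume shape {v.shape} smaller than cube_edge={cube_edge}"
        )
    grid = tuple(s // cube_edge for s in v.shape)
    trimmed = v[: grid[0] * cube_edge, : grid[1] * cube_edge, : grid[2] * cube_edge]
    cubes = (
        trimmed.reshape(grid[0], cube_edge, grid[1], cube_edge, grid[2], cube_edge)
        .transpose(0, 2, 4, 1, 3, 5)
        .reshape(-1, cube_edge**3)
    )
    origins = (
        np.stack(np.meshgrid(*[np.arange(g) for g in grid], indexing="ij"), axis=-1)
        .reshape(-1, 3)
        * cube_edge
    )
    keep = (cubes.mean(axis=1) > min_gm) & (cubes.std(axis=1) > _VAR_TOL)
    if not keep.any():
        raise DegenerateSubjectError(
            f"degenerate subject {volume.subject_id!r}: no cube exceeds "
            f"min_gm={min_gm} with nonzero variance"
        )
    kept = np.flatnonzero(keep)
    center_vox = origins[kept] + (cube_edge - 1) / 2.0
    centroids = apply_affine(volume.affine, center_vox)
    return CubeNodeSet(
        node_values=cubes[kept].astype(float),
        centroids=np.asarray(centroids, dtype=float),
        node_ids=np.arange(kept.size),
        cube_origins=origins[kept],
        cube_edge=cube_edge,
    )


def _cube_symmetries(edge: int) -> np.ndarray:
    """Index permutations of an edge^3 cube under the full octahedral group
    (24 rotations + 24 roto-reflections = 48 orientations)."""
    base = np.arange(edge**3).reshape(edge, edge, edge)
    perms = []
    for axes in itertools.permutations(range(3)):
        for flips in itertools.product([False, True], repeat=3):
            arr = np.transpose(base, axes)
            for ax, f in enumerate(flips):
                if f:
                    arr = np.flip(arr, axis=ax)
            perms.append(arr.reshape(-1))
    return np.unique(np.stack(perms), axis=0)


def compute_similarity(
    nodes: CubeNodeSet, rotation_invariant: bool = False
) -> SimilarityMatrix:
    """Pairwise Pearson correlation between node vectors.

    With ``rotation_invariant`` the correlation of a pair is the maximum
    plain Pearson r over the 48 cube rotations/reflections applied to one
    member, matching similarity-based extraction schemes that align cube
    orientation; the default is the plain aligned-voxel correlation.
    """
    X = np.asarray(nodes.node_values, dtype=float)
    sd = X.std(axis=1)
    if np.any(sd <= _VAR_TOL):
        bad = np.flatnonzero(sd <= _VAR_TOL)[:5]
        raise ContractViolation(f"zero-variance node vectors at indices {bad.tolist()}")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    m = X.shape[1]
    if not rotation_invariant:
        r = (Z @ Z.T) / m
    else:
        r = np.full((X.shape[0], X.shape[0]), -np.inf)
        for perm in _cube_symmetries(nodes.cube_edge):
            np.maximum(r, (Z @ Z[:, perm].T) / m, out=r)
        r = np.maximum(r, r.T)  # group closure makes this a no-op; keep exact
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0
    return SimilarityMatrix(r=r)


def _check_symmetric(r: np.ndarray) -> None:
    if not np.allclose(r, r.T, atol=_SYMMETRY_TOL, rtol=0.0):
        raise ContractViolation("similarity matrix is not symmetric")


def permutation_null_threshold(
    nodes: CubeNodeSet,
    fpr: float,
    n_permutations: int = 20,
    seed: int | None = None,
) -> float:
    """Correlation cut calibrated so that edges among permuted (structure-
    free) node vectors appear at rate ``fpr``: the (1 - fpr) quantile of
    correlations between within-vector-permuted copies of the nodes."""
    if not 0.0 < fpr < 1.0:
        raise ValueError("false-positive rate must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    X = np.asarray(nodes.node_values, dtype=float)
    n = X.shape[0]
    iu = np.triu_indices(n, k=1)
    null_rs = []
    for _ in range(n_permutations):
        Xp = rng.permuted(X, axis=1)
        sd = Xp.std(axis=1)
        Zp = (Xp - Xp.mean(axis=1, keepdims=True)) / sd[:, None]
        null_rs.append(((Zp @ Zp.T) / X.shape[1])[iu])
    return float(np.quantile(np.concatenate(null_rs), 1.0 - fpr))


def threshold_network(
    sim: SimilarityMatrix,
    method: str = "permutation_fpr",
    param: float = 0.05,
    *,
    nodes: CubeNodeSet | None = None,
    n_permutations: int = 20,
    seed: int | None = None,
) -> BinaryNetwork:
    """Binarize the similarity matrix.

    ``fixed_r``: edge iff r > param (param in [-1, 1]).
    ``permutation_fpr``: edge iff r exceeds the permutation-calibrated null
    quantile at false-positive rate ``param`` (param in (0, 1)); requires
    ``nodes`` to supply the vectors being permuted.
    """
    _check_symmetric(sim.r)
    if method == "fixed_r":
        if not -1.0 <= param <= 1.0:
            raise ValueError("fixed_r threshold must lie in [-1, 1]")
        thr = float(param)
    elif method == "permutation_fpr":
        if nodes is None:
            raise ValueError("permutation_fpr thresholding requires the node set")
        thr = permutation_null_threshold(nodes, param, n_permutations, seed)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    adj = (sim.r > thr).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return BinaryNetwork(adjacency=adj, threshold_used=thr, method=method)
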
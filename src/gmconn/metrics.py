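"""Graph-theoretic metrics of a binary cube network.

Nodal efficiency of node i is the mean inverse shortest-path length from i
to every other node,

    E(i) = 1/(n-1) * sum_{j != i} 1 / d(i, j),

with 1/d = 0 for unreachable pairs; it is 1 on a complete graph and 0 for an
isolated node.  Path lengths are unweighted hop counts from breadth-first
search.  Alongside the 90 regional efficiencies the prediction models use
three global quantities that confound connectome measurements: total brain
volume, network size (node count) and mean nodal degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .network import BinaryNetwork, ContractViolation, CubeNodeSet
from .volume import GrayMatterVolume

__all__ = ["GlobalMetrics", "nodal_efficiency", "global_metrics"]


@dataclass
class GlobalMetrics:
    network_size: int
    mean_degree: float
    brain_volume: float


def nodal_efficiency(net: BinaryNetwork) -> np.ndarray:
    """Per-node efficiency in [0, 1] via all-pairs BFS."""
    n = net.n_nodes
    if n < 2:
        raise ValueError(f"nodal efficiency undefined for n={n} (< 2) nodes")
    adj = net.adjacency
    if np.any(adj != adj.T):
        raise ContractViolation("adjacency must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ContractViolation("adjacency must have zero diagonal")
    d = shortest_path(csr_matrix(adj), method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0  # self (d=0) and unreachable (d=inf)
    return inv.sum(axis=1) / (n - 1)


def global_metrics(
    net: BinaryNetwork, nodes: CubeNodeSet, volume: GrayMatterVolume
) -> GlobalMetrics:
    """Network size, mean degree, and brain volume over the retained cubes."""
    if net.n_nodes != nodes.n_nodes:
        raise ContractViolation(
            f"node-count mismatch: network has {net.n_nodes}, node set {nodes.n_nodes}"
        )
    mean_degree = 2.0 * net.n_edges / net.n_nodes if net.n_nodes else 0.0
    brain_volume = float(nodes.node_values.sum() * volume.voxel_volume)
    return GlobalMetrics(
        network_size=net.n_nodes, mean_degree=mean_degree, brain_volume=brain_volume
    )
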
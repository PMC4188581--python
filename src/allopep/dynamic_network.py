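"""Dynamical-network analysis of residue motion: contact edges, masked
displacement correlations, and interface-stability scoring.

Nodes are residues.  Two nodes form an edge when their minimum inter-atom
distance is below 4.5 Å (strict) in at least 75% of trajectory frames
(inclusive); sequence-adjacent residues within a chain never form an edge.
Edge-connected pairs carry the normalized displacement cross-correlation

    C_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>),   Δr_i(t) = r_i(t) − <r_i>,

averaged over frames, with one representative point per residue; C is set
to zero on non-edges.  The interface-stability score of a two-chain
complex is the mean *signed* C_ij over cross-chain edges: larger values
mean more strongly coupled, hence more stable, interface motion, while
anti-correlation is a distinct signature and is not folded into the mean
by absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial.distance import cdist

from .trajectory_io import Trajectory

__all__ = [
    "ContactNetwork",
    "InterfaceScore",
    "NoInterfaceError",
    "ZeroVarianceError",
    "compute_occupancies",
    "build_edges",
    "compute_correlation",
    "masked_correlation",
    "interface_mean_correlation",
    "rank_interface_stability",
]

DEFAULT_CONTACT_CUTOFF = 4.5      # Å, strict less-than
DEFAULT_OCCUPANCY_THRESHOLD = 0.75  # inclusive


class NoInterfaceError(ValueError):
    """No cross-chain contact edges between the requested chains."""


class ZeroVarianceError(ValueError):
    """A node never moves; its correlation is undefined."""


@dataclass
class ContactNetwork:
    """Occupancy-filtered residue graph with masked correlations.

    ``correlation`` is symmetric with C_ii = 1 (pre-mask) and C_ij = 0 for
    every non-edge pair.
    """

    nodes: pd.DataFrame                  # chain, resid, resname
    edges: set[tuple[int, int]]          # node-index pairs, i < j
    occupancy: np.ndarray                # (n, n) symmetric
    correlation: np.ndarray              # (n, n) masked C

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for i, j in sorted(self.edges):
            rows.append(
                {
                    "node_i": i,
                    "node_j": j,
                    "chain_i": self.nodes.at[i, "chain"],
                    "resid_i": self.nodes.at[i, "resid"],
                    "chain_j": self.nodes.at[j, "chain"],
                    "resid_j": self.nodes.at[j, "resid"],
                    "occupancy": self.occupancy[i, j],
                    "correlation": self.correlation[i, j],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "node_i", "node_j", "chain_i", "resid_i",
                "chain_j", "resid_j", "occupancy", "correlation",
            ],
        )

    def write_edge_list(self, path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    def write_matrix(self, path) -> None:
        labels = [f"{c}{r}" for c, r in zip(self.nodes["chain"], self.nodes["resid"])]
        pd.DataFrame(self.correlation, index=labels, columns=labels).to_csv(path)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, row in self.nodes.iterrows():
            g.add_node(int(i), chain=str(row["chain"]), resid=int(row["resid"]),
                       resname=str(row["resname"]))
        for i, j in sorted(self.edges):
            g.add_edge(int(i), int(j), occupancy=float(self.occupancy[i, j]),
                       correlation=float(self.correlation[i, j]))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclass
class InterfaceScore:
    """Mean signed correlation over cross-chain contact edges."""

    mean_correlation: float
    n_pairs: int
    pairs: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("interface score needs at least one pair")
        if not -1.0 - 1e-9 <= self.mean_correlation <= 1.0 + 1e-9:
            raise ValueError("mean correlation outside [-1, 1]")


# ---------------------------------------------------------------------------
# occupancies and edges
# ---------------------------------------------------------------------------

def compute_occupancies(
    traj: Trajectory,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    heavy_atom: bool = True,
) -> np.ndarray:
    """Fraction of frames in which each node pair is in contact.

    Contact in a frame means the minimum distance between any two atoms of
    the two nodes (``heavy_atom=True``) or between their representative
    points is strictly below ``cutoff``.  Diagonal entries are set to 1
    but carry no meaning.
    """
    if traj.n_frames < 2:
        raise ValueError("occupancy needs at least 2 frames")
    n = traj.n_nodes
    if heavy_atom:
        node_idx = traj.node_of_atom
        coords = traj.coords
        ii = node_idx[:, None] * np.ones_like(node_idx)[None, :]
        jj = ii.T
    else:
        coords = traj.representative_coords()
        node_idx = np.arange(n)
        ii = node_idx[:, None] * np.ones(n, dtype=int)[None, :]
        jj = ii.T
    counts = np.zeros((n, n))
    for f in range(traj.n_frames):
        d = cdist(coords[f], coords[f])
        minmat = np.full((n, n), np.inf)
        np.minimum.at(minmat, (ii, jj), d)
        counts += minmat < cutoff
    occ = counts / traj.n_frames
    np.fill_diagonal(occ, 1.0)
    return occ


def build_edges(
    occupancies: np.ndarray,
    nodes: pd.DataFrame,
    threshold: float = DEFAULT_OCCUPANCY_THRESHOLD,
) -> set[tuple[int, int]]:
    """Edges: occupancy >= threshold, excluding self and same-chain
    sequence neighbours (|Δresid| == 1)."""
    n = occupancies.shape[0]
    if occupancies.shape != (n, n) or len(nodes) != n:
        raise ValueError("occupancy matrix and node table sizes disagree")
    chains = nodes["chain"].to_numpy()
    resids = nodes["resid"].to_numpy()
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if chains[i] == chains[j] and abs(int(resids[i]) - int(resids[j])) == 1:
                continue
            if occupancies[i, j] >= threshold:
                edges.add((i, j))
    return edges


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def compute_correlation(
    traj: Trajectory,
    representative: str = "CA",
    strict: bool = True,
) -> np.ndarray:
    """Full normalized displacement cross-correlation matrix.

    A node with zero displacement variance has undefined correlations: in
    strict mode this raises :class:`ZeroVarianceError`; otherwise its rows
    and columns are NaN (diagonal kept at 1).
    """
    if traj.n_frames < 2:
        raise ValueError("correlation needs at least 2 frames")
    x = traj.representative_coords(representative)        # (F, N, 3)
    dx = x - x.mean(axis=0, keepdims=True)
    cov = np.einsum("fni,fmi->nm", dx, dx) / traj.n_frames
    var = np.diag(cov).copy()
    zero = var <= 0
    if zero.any():
        if strict:
            bad = traj.nodes.loc[np.nonzero(zero)[0]]
            ids = [f"{r.chain}{r.resid}" for r in bad.itertuples()]
            raise ZeroVarianceError(f"zero-variance nodes: {ids}")
        var[zero] = np.nan
    c = cov / np.sqrt(np.outer(var, var))
    c = np.clip(c, -1.0, 1.0, out=c) if not np.isnan(c).any() else c
    np.fill_diagonal(c, 1.0)
    return c


def masked_correlation(c: np.ndarray, edges: set[tuple[int, int]]) -> np.ndarray:
    """Zero the correlation matrix off the contact edges (diagonal kept)."""
    n = c.shape[0]
    mask = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        mask[i, j] = mask[j, i] = True
    out = np.where(mask, c, 0.0)
    np.fill_diagonal(out, np.diag(c))
    return out


def build_contact_network(
    traj: Trajectory,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    occupancy_threshold: float = DEFAULT_OCCUPANCY_THRESHOLD,
    heavy_atom: bool = True,
    representative: str = "CA",
) -> ContactNetwork:
    """Occupancies, edge rule, correlations and mask in one pass."""
    occ = compute_occupancies(traj, cutoff=cutoff, heavy_atom=heavy_atom)
    nodes = traj.nodes
    edges = build_edges(occ, nodes, threshold=occupancy_threshold)
    c = compute_correlation(traj, representative=representative)
    return ContactNetwork(nodes=nodes, edges=edges, occupancy=occ,
                          correlation=masked_correlation(c, edges))


# ---------------------------------------------------------------------------
# interface scoring
# ---------------------------------------------------------------------------

def interface_mean_correlation(
    net: ContactNetwork, chain_a: str, chain_b: str
) -> InterfaceScore:
    """Mean signed C_ij over contact edges joining ``chain_a`` and ``chain_b``."""
    chains = net.nodes["chain"].to_numpy()
    rows = []
    for i, j in sorted(net.edges):
        pair = {chains[i], chains[j]}
        if pair == {chain_a, chain_b}:
            rows.append((i, j, net.occupancy[i, j], net.correlation[i, j]))
    if not rows:
        raise NoInterfaceError(
            f"no contact edges between chains {chain_a!r} and {chain_b!r}"
        )
    table = pd.DataFrame(rows, columns=["node_i", "node_j", "occupancy", "correlation"])
    return InterfaceScore(
        mean_correlation=float(table["correlation"].mean()),
        n_pairs=len(table),
        pairs=table,
    )


def rank_interface_stability(
    scores: Mapping[str, "InterfaceScore | float"],
) -> list[str]:
    """Order conditions by ascending interface score (least stable first).

    Accepts plain floats or :class:`InterfaceScore` values; ties break
    lexicographically on the condition label.
    """
    if not scores:
        raise ValueError("need at least one condition")
    def mean(v) -> float:
        return v.mean_correlation if isinstance(v, InterfaceScore) else float(v)
    return sorted(scores, key=lambda k: (mean(scores[k]), k))
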
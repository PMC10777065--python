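"""Structural embedding of the bipartite interaction network (HOPE).

The circRNA-miRNA graph is undirected and bipartite; its high-order
proximity is summarized by the Katz index S = sum_{l>=1} beta^l A^l =
(I - beta A)^{-1} beta A, convergent when beta * rho(A) < 1. Factorizing
S ~= Us Ut^T with the top-d singular triplets (Us = U_d sqrt(Sigma_d),
Ut = V_d sqrt(Sigma_d)) minimizes the Frobenius reconstruction error among
all rank-d factorizations, and the per-node structural feature is the
concatenation [Us_row | Ut_row].

Graphs here are small (thousands of nodes), so the proximity matrix is
built densely and factorized with a full SVD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

DEFAULT_DIM = 32  # per side; concatenated feature is 2d = 64
DEFAULT_BETA_FRACTION = 0.5  # beta = fraction / spectral_radius(A)


@dataclass
class BioGraph:
    """Undirected bipartite graph over circRNA and miRNA nodes.

    Node order (circRNAs first, then miRNAs) is fixed by construction so
    that adjacency rows, embeddings and id lookups stay aligned. Isolated
    nodes are retained: every molecule needs a structural feature.
    """

    circ_ids: list[str]
    mir_ids: list[str]
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return self.circ_ids + self.mir_ids

    @property
    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, dtype=np.float64)


@dataclass
class ProximityFactorization:
    """Low-rank factorization S ~= Us Ut^T of a proximity matrix."""

    S: np.ndarray
    Us: np.ndarray
    Ut: np.ndarray
    d: int
    beta: float | None = None
    singular_values: np.ndarray | None = None

    def reconstruction_error(self) -> float:
        return float(np.linalg.norm(self.S - self.Us @ self.Ut.T, ord="fro"))


def build_graph(
    train_pairs: Sequence[tuple[str, str]],
    circ_ids: Sequence[str],
    mir_ids: Sequence[str],
) -> BioGraph:
    """Build the undirected interaction graph from positive pairs only.

    All known ids become nodes (isolated ones included); any pair that does
    not connect a circRNA to a miRNA violates bipartiteness and is an error.
    """
    circ_set, mir_set = set(circ_ids), set(mir_ids)
    if circ_set & mir_set:
        raise ValueError("circRNA and miRNA id sets overlap")
    g = nx.Graph()
    g.add_nodes_from(circ_ids, side="circ")
    g.add_nodes_from(mir_ids, side="mir")
    for c, m in train_pairs:
        if c not in circ_set or m not in mir_set:
            if c in mir_set or m in circ_set:
                raise ValueError(f"pair ({c!r}, {m!r}) violates bipartiteness")
            raise KeyError(f"pair ({c!r}, {m!r}) references an unknown id")
        g.add_edge(c, m)
    return BioGraph(circ_ids=list(circ_ids), mir_ids=list(mir_ids), graph=g)


def spectral_radius(A: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvalsh(A)))) if A.size else 0.0


def katz_proximity(A: np.ndarray, beta: float) -> np.ndarray:
    """Katz index S = sum_{l>=1} beta^l A^l = (I - beta A)^{-1} beta A.

    Requires beta * rho(A) < 1 for the series to converge. Symmetric and
    entrywise non-negative for symmetric non-negative A.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if beta == 0.0:
        return np.zeros_like(A)
    rho = spectral_radius(A)
    if beta * rho >= 1.0:
        raise ValueError(
            f"Katz series diverges: beta*rho(A) = {beta * rho:.6g} >= 1 (rho={rho:.6g})"
        )
    n = A.shape[0]
    return np.linalg.solve(np.eye(n) - beta * A, beta * A)


def common_neighbor_proximity(A: np.ndarray) -> np.ndarray:
    """Second-order proximity A^T A (shared-neighbor counts)."""
    A = np.asarray(A, dtype=np.float64)
    return A.T @ A


def katz_beta(A: np.ndarray, fraction: float = DEFAULT_BETA_FRACTION) -> float:
    """Decay beta = fraction / rho(A); 0 for an empty graph."""
    rho = spectral_radius(A)
    return 0.0 if rho == 0.0 else fraction / rho


def factorize(S: np.ndarray, d: int) -> ProximityFactorization:
    """Best rank-d factorization of S via truncated SVD (Eckart-Young).

    Us = U_d sqrt(Sigma_d), Ut = V_d sqrt(Sigma_d); the sign of each
    singular pair is fixed by making the largest-magnitude entry of the
    left vector positive, for reproducibility across backends.
    """
    S = np.asarray(S, dtype=np.float64)
    if S.ndim != 2:
        raise ValueError("S must be a matrix")
    if d < 1 or d > min(S.shape):
        raise ValueError(f"d={d} out of range for a {S.shape} matrix")
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)
    U, sig, Vt = U[:, :d], sig[:d], Vt[:d]
    for j in range(d):
        i_max = int(np.argmax(np.abs(U[:, j])))
        if U[i_max, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    root = np.sqrt(sig)
    return ProximityFactorization(
        S=S, Us=U * root, Ut=Vt.T * root, d=d,
        singular_values=np.linalg.svd(S, compute_uv=False),
    )


def node_struct_feature(fac: ProximityFactorization, index: int) -> np.ndarray:
    """Structural feature of one node: [Us_row | Ut_row], length 2d."""
    if not 0 <= index < fac.Us.shape[0]:
        raise KeyError(f"node index {index} out of range")
    return np.concatenate([fac.Us[index], fac.Ut[index]])


def embed_graph(
    graph: BioGraph,
    d: int = DEFAULT_DIM,
    beta_fraction: float = DEFAULT_BETA_FRACTION,
    proximity: str = "katz",
) -> tuple[dict[str, np.ndarray], ProximityFactorization]:
    """Full structural embedding: proximity matrix, factorization, features.

    Returns a node-id -> 2d-vector map. Nodes whose proximity row is all
    zero (isolated in the training graph) get an exactly zero vector.
    """
    A = graph.adjacency()
    if proximity == "katz":
        S = katz_proximity(A, katz_beta(A, beta_fraction))
    elif proximity == "common-neighbors":
        S = common_neighbor_proximity(A)
    else:
        raise ValueError(f"unknown proximity measure {proximity!r}")
    fac = factorize(S, d)
    feats: dict[str, np.ndarray] = {}
    for i, node in enumerate(graph.nodes):
        if not S[i].any() and not S[:, i].any():
            feats[node] = np.zeros(2 * d)
        else:
            feats[node] = node_struct_feature(fac, i)
    return feats, fac
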
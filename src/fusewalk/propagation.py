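"""Random walk with restart over the compiled gene network.

The walker moves along edges of the column-normalized adjacency with
probability ``1 - gamma`` and teleports back to the seed distribution with
probability ``gamma``:

    p[t+1] = (1 - gamma) * T @ p[t] + gamma * p0

Iteration stops when the L1 change between successive iterates drops below
the tolerance.  The stationary vector scores every gene's proximity to the
seeds (the fusion's predicted interaction partners).

Dangling (degree-0) nodes get restart-only handling: probability mass
sitting on a zero column is redistributed to the seed distribution, which
preserves conservation (sum(p) == 1 throughout).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import scipy.sparse as sp

from fusewalk.errors import EmptySeedError, InvalidInputError

__all__ = [
    "GeneNetwork",
    "TransitionMatrix",
    "PropagationConfig",
    "ScoreVector",
    "build_transition_matrix",
    "random_walk_restart",
    "solve_stationary_oracle",
]


class GeneNetwork:
    """Undirected weighted gene network with a fixed node order.

    Parameters
    ----------
    nodes
        Gene identifiers; duplicates are an error.  Order defines vector
        indices for the propagation.
    edges
        ``(u, v)`` or ``(u, v, weight)`` tuples; both endpoints must be
        nodes.  Weights must be non-negative (default 1.0); parallel
        edges accumulate.
    """

    def __init__(
        self,
        nodes: Sequence[str],
        edges: Iterable[Tuple] = (),
    ):
        self.nodes: List[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise InvalidInputError("duplicate node identifiers in network")
        self.index: Dict[str, int] = {g: i for i, g in enumerate(self.nodes)}
        self._adj = sp.lil_matrix((len(self.nodes), len(self.nodes)))
        for edge in edges:
            if len(edge) == 2:
                u, v = edge
                w = 1.0
            else:
                u, v, w = edge
            if w < 0:
                raise InvalidInputError(f"negative edge weight on ({u}, {v}): {w}")
            try:
                i, j = self.index[u], self.index[v]
            except KeyError as exc:
                raise InvalidInputError(f"edge endpoint {exc.args[0]!r} is not a node") from None
            self._adj[i, j] += w
            if i != j:
                self._adj[j, i] += w

    @property
    def n(self) -> int:
        return len(self.nodes)

    def adjacency(self) -> sp.csr_matrix:
        return self._adj.tocsr()

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=0)).ravel()

    @classmethod
    def from_edges(cls, edges: Iterable[Tuple]) -> "GeneNetwork":
        """Build with node order = sorted set of edge endpoints."""
        edges = list(edges)
        nodes = sorted({e[0] for e in edges} | {e[1] for e in edges})
        return cls(nodes, edges)


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix plus the dangling-column mask."""

    T: sp.csr_matrix
    nodes: List[str]
    dangling: np.ndarray  # boolean mask of zero-degree columns

    def __post_init__(self) -> None:
        colsums = np.asarray(self.T.sum(axis=0)).ravel()
        live = ~self.dangling
        if live.any() and not np.allclose(colsums[live], 1.0, atol=1e-12):
            raise InvalidInputError("non-dangling columns must sum to 1")


@dataclass
class PropagationConfig:
    """Knobs for the restart walk.

    ``gamma`` is the restart probability (default 0.7, the customary
    value for network-based gene prioritization).  ``tolerance`` is the
    L1 change between successive iterates at which iteration stops;
    float64 cannot always reach the 1e-30 default, so ``max_iter`` caps
    the loop and non-convergence is a warning, not an error.
    """

    gamma: float = 0.7
    tolerance: float = 1e-30
    max_iter: int = 10_000
    norm: str = "l1"  # "l1" | "l2" | "max"

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise InvalidInputError(f"gamma must be in (0, 1], got {self.gamma}")
        if self.tolerance <= 0:
            raise InvalidInputError("tolerance must be positive")
        if self.max_iter < 1:
            raise InvalidInputError("max_iter must be >= 1")
        if self.norm not in ("l1", "l2", "max"):
            raise InvalidInputError(f"unknown norm {self.norm!r}")

    def change(self, a: np.ndarray, b: np.ndarray) -> float:
        d = a - b
        if self.norm == "l1":
            return float(np.abs(d).sum())
        if self.norm == "l2":
            return float(np.sqrt((d * d).sum()))
        return float(np.abs(d).max())


@dataclass
class ScoreVector:
    """Per-gene stationary scores plus the seed set that produced them."""

    scores: Dict[str, float]
    seed_set: Set[str]
    converged: bool = True
    n_iter: int = 0
    off_network_seeds: Set[str] = field(default_factory=set)

    def as_array(self, nodes: Sequence[str]) -> np.ndarray:
        return np.array([self.scores[g] for g in nodes])

    def __getitem__(self, gene: str) -> float:
        return self.scores[gene]


def build_transition_matrix(network: GeneNetwork) -> TransitionMatrix:
    """Column-normalize the adjacency: T[i, j] = w(i, j) / sum_k w(k, j)."""
    if network.n == 0:
        raise InvalidInputError("empty network")
    A = network.adjacency()
    colsums = np.asarray(A.sum(axis=0)).ravel()
    dangling = colsums == 0
    inv = np.zeros_like(colsums)
    inv[~dangling] = 1.0 / colsums[~dangling]
    T = (A @ sp.diags(inv)).tocsr()
    return TransitionMatrix(T=T, nodes=list(network.nodes), dangling=dangling)


def _seed_vector(seeds: Set[str], network: GeneNetwork) -> Tuple[np.ndarray, Set[str], Set[str]]:
    in_net = {s for s in seeds if s in network.index}
    off = set(seeds) - in_net
    if not in_net:
        raise EmptySeedError(f"no seed is in the network; off-network seeds: {sorted(off)}")
    p0 = np.zeros(network.n)
    for s in in_net:
        p0[network.index[s]] = 1.0 / len(in_net)
    return p0, in_net, off


def random_walk_restart(
    seeds: Set[str],
    network: GeneNetwork,
    config: Optional[PropagationConfig] = None,
) -> ScoreVector:
    """Iterate the restart walk to its stationary distribution.

    Deterministic despite the name: the walk is a power iteration on the
    linear map, not a sampled trajectory.  Seeds outside the network are
    dropped (reported in ``off_network_seeds``); having none in-network is
    fatal.
    """
    config = config or PropagationConfig()
    p0, in_net, off = _seed_vector(seeds, network)
    tm = build_transition_matrix(network)
    gamma = config.gamma
    p = p0.copy()
    n_iter = 0
    converged = False
    if gamma == 1.0:
        converged = True
    else:
        for n_iter in range(1, config.max_iter + 1):
            dangling_mass = p[tm.dangling].sum() if tm.dangling.any() else 0.0
            p_next = (1.0 - gamma) * (tm.T @ p + dangling_mass * p0) + gamma * p0
            delta = config.change(p_next, p)
            p = p_next
            if delta < config.tolerance:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"propagation did not reach tolerance {config.tolerance:g} in "
                f"{config.max_iter} iterations (last change {delta:g})",
                stacklevel=2,
            )
    return ScoreVector(
        scores={g: float(p[i]) for i, g in enumerate(network.nodes)},
        seed_set=in_net,
        converged=converged,
        n_iter=n_iter,
        off_network_seeds=off,
    )


def solve_stationary_oracle(
    seeds: Set[str],
    network: GeneNetwork,
    gamma: float = 0.7,
) -> ScoreVector:
    """Exact fixed point by dense linear solve; test oracle for small n.

    Solves ``(I - (1-gamma) * (T + p0 @ d^T)) p = gamma * p0`` where ``d``
    is the dangling-column indicator, matching the iterative scheme's
    restart-only dangling handling.
    """
    PropagationConfig(gamma=gamma)  # validate range
    p0, in_net, off = _seed_vector(seeds, network)
    tm = build_transition_matrix(network)
    n = network.n
    if gamma == 1.0:
        p = p0
    else:
        M = np.eye(n) - (1.0 - gamma) * tm.T.toarray()
        if tm.dangling.any():
            d = tm.dangling.astype(float)
            M -= (1.0 - gamma) * np.outer(p0, d)
        p = np.linalg.solve(M, gamma * p0)
    return ScoreVector(
        scores={g: float(p[i]) for i, g in enumerate(network.nodes)},
        seed_set=in_net,
        converged=True,
        n_iter=0,
        off_network_seeds=off,
    )
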
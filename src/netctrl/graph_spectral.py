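"""Graph Laplacian spectra, stabilized dynamics and eigenmap output projectors.

The state of an undirected network can be viewed as a signal on a graph.  The
graph Laplacian ``L = D - A`` provides an orthonormal basis of eigenvectors
(*eigenmaps*) ordered by eigenvalue: low-eigenvalue maps encode coarse modular
structure, high-eigenvalue maps fine-grained detail.  Projecting a state onto a
few eigenmaps -- the graph Fourier transform (GFT) restricted to ``r``
components -- turns a full-state control problem into a low-dimensional output
control problem.  This module builds the pieces: validated network containers,
the stabilized state matrix ``A = G - cI``, the spectral basis, GFT/iGFT, the
row-selection output projector ``C = H_r V^T``, and betweenness driver ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "WeightedNetwork",
    "StabilizedSystem",
    "SpectralBasis",
    "OutputProjector",
    "laplacian",
    "stabilize",
    "eigendecompose",
    "gft",
    "igft",
    "build_projector",
    "betweenness_ranking",
]

#: absolute tolerance for symmetry / orthonormality checks
SYM_ATOL = 1e-8

#: machine-epsilon stabilization margin: makes the spectrum of A = G - cI
#: strictly negative while leaving the Laplacian untouched
DEFAULT_EPSILON = 2e-16


class NetworkValidationError(ValueError):
    """Raised when an adjacency matrix violates the undirected-network contract."""


@dataclass(frozen=True)
class WeightedNetwork:
    """Symmetric, nonnegative, zero-diagonal adjacency with node labels.

    Parameters
    ----------
    adjacency
        ``(n, n)`` symmetric matrix of nonnegative link weights (fiber counts
        or 0/1).  The diagonal must be zero: self-loops enter the dynamics
        only through stabilization, never through the network itself.
    node_labels
        Unique string label per node.  Defaults to ``"0", "1", ...``.
    """

    adjacency: np.ndarray
    node_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=float)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise NetworkValidationError(f"adjacency must be square, got shape {adj.shape}")
        if not np.allclose(adj, adj.T, atol=SYM_ATOL):
            raise NetworkValidationError("adjacency must be symmetric (undirected network)")
        if np.any(adj < 0):
            raise NetworkValidationError("link weights must be nonnegative")
        if np.any(np.diagonal(adj) != 0):
            raise NetworkValidationError("adjacency diagonal must be zero (no self-loops)")
        adj = 0.5 * (adj + adj.T)  # exact symmetry for downstream eigh calls
        adj.flags.writeable = False
        object.__setattr__(self, "adjacency", adj)
        labels = tuple(self.node_labels) or tuple(str(i) for i in range(adj.shape[0]))
        if len(labels) != adj.shape[0]:
            raise NetworkValidationError(
                f"{len(labels)} labels for {adj.shape[0]} nodes"
            )
        if len(set(labels)) != len(labels):
            raise NetworkValidationError("node labels must be unique")
        object.__setattr__(self, "node_labels", labels)

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def degree(self) -> np.ndarray:
        """Weighted degree (node strength): row sums of the adjacency."""
        return self.adjacency.sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        nx.relabel_nodes(g, dict(enumerate(self.node_labels)), copy=False)
        return g


@dataclass(frozen=True)
class StabilizedSystem:
    """State matrix ``A = G - cI`` with ``c = lambda_max(G) + epsilon``.

    Shifting the adjacency by slightly more than its spectral radius makes
    every eigenvalue of ``A`` strictly negative, so the infinite-horizon
    controllability Gramian exists.  The shift only touches the diagonal and
    therefore leaves the graph Laplacian unchanged.
    """

    state_matrix: np.ndarray
    shift: float
    epsilon: float

    @property
    def n(self) -> int:
        return self.state_matrix.shape[0]


@dataclass(frozen=True)
class SpectralBasis:
    """Laplacian eigenvalues (ascending) and orthonormal eigenvectors.

    ``eigenvectors[:, i]`` is the eigenmap for ``eigenvalues[i]``.  For a
    connected graph the first eigenvalue is 0 with a constant eigenvector.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass(frozen=True)
class OutputProjector:
    """Selection/reordering of ``r`` eigenmaps: output matrix ``C = H_r V^T``.

    ``filter_matrix`` (``H_r``) has one unit entry per row in distinct
    columns, so the rows of ``C`` are transposed eigenmaps and ``C C^T = I_r``.
    """

    r: int
    selected_indices: tuple[int, ...]
    filter_matrix: np.ndarray
    output_matrix: np.ndarray


def laplacian(network: WeightedNetwork) -> np.ndarray:
    """Graph Laplacian ``L = D - A`` with ``D`` the diagonal degree matrix.

    Every row of ``L`` sums to zero and ``L`` is positive semidefinite.
    """
    adj = network.adjacency
    lap = np.diag(adj.sum(axis=1)) - adj
    return lap


def stabilize(network: WeightedNetwork, epsilon: float = DEFAULT_EPSILON) -> StabilizedSystem:
    """Add uniform negative self-loops: ``A = G - cI``, ``c = lambda_max(G) + epsilon``.

    Parameters
    ----------
    epsilon
        Strictly positive margin pushing the spectrum of ``A`` below zero.
        The default (2e-16, on the order of machine epsilon) perturbs the
        dynamics as little as possible while guaranteeing the Gramian exists.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be strictly positive")
    adj = network.adjacency
    lam_max = float(np.linalg.eigvalsh(adj)[-1]) if network.n > 0 else 0.0
    c = lam_max + epsilon
    a = adj - c * np.eye(network.n)
    return StabilizedSystem(state_matrix=a, shift=c, epsilon=epsilon)


def eigendecompose(lap: np.ndarray) -> SpectralBasis:
    """Symmetric eigendecomposition ``L = V Lambda V^T`` with ascending eigenvalues.

    A deterministic sign convention is applied: each eigenvector is flipped so
    that its largest-magnitude entry (ties broken by first index) is positive.
    This makes magnitude-based eigenmap selection reproducible across linear
    algebra backends.
    """
    lap = np.asarray(lap, dtype=float)
    if not np.allclose(lap, lap.T, atol=SYM_ATOL):
        raise ValueError("Laplacian must be symmetric")
    eigenvalues, eigenvectors = np.linalg.eigh(0.5 * (lap + lap.T))
    # sign convention: largest-|entry| of each column made positive
    pivot = np.argmax(np.abs(eigenvectors), axis=0)
    signs = np.sign(eigenvectors[pivot, np.arange(eigenvectors.shape[1])])
    signs[signs == 0] = 1.0
    eigenvectors = eigenvectors * signs
    return SpectralBasis(eigenvalues=eigenvalues, eigenvectors=eigenvectors)


def gft(x: np.ndarray, basis: SpectralBasis) -> np.ndarray:
    """Graph Fourier transform: eigenstate ``x~ = V^T x``."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != basis.n:
        raise ValueError(f"state length {x.shape[0]} != basis size {basis.n}")
    return basis.eigenvectors.T @ x


def igft(xt: np.ndarray, basis: SpectralBasis) -> np.ndarray:
    """Inverse graph Fourier transform: ``x = V x~``."""
    xt = np.asarray(xt, dtype=float)
    if xt.shape[0] != basis.n:
        raise ValueError(f"eigenstate length {xt.shape[0]} != basis size {basis.n}")
    return basis.eigenvectors @ xt


def build_projector(
    basis: SpectralBasis,
    r: int,
    mode: str = "magnitude",
    reference_state: np.ndarray | None = None,
) -> OutputProjector:
    """Select and order ``r`` eigenmaps into the output matrix ``C = H_r V^T``.

    Parameters
    ----------
    r
        Number of retained eigenmaps, ``1 <= r <= n``.
    mode
        ``"magnitude"`` ranks eigenmaps by the absolute eigenstate of
        ``reference_state`` (most informative components of the desired final
        state first); ``"lambda"`` takes the first ``r`` eigenmaps in
        eigenvalue order (coarsest topological scales first).
    reference_state
        Length-``n`` state whose eigenstate magnitudes rank the maps
        (required in magnitude mode).
    """
    n = basis.n
    if not 1 <= r <= n:
        raise ValueError(f"r must be in [1, {n}], got {r}")
    if mode == "magnitude":
        if reference_state is None:
            raise ValueError("magnitude mode requires a reference_state")
        magnitudes = np.abs(gft(reference_state, basis))
        # stable sort on (-|x~|, index): descending magnitude, index tie-break
        order = np.lexsort((np.arange(n), -magnitudes))
        selected = tuple(int(i) for i in order[:r])
    elif mode == "lambda":
        selected = tuple(range(r))
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'magnitude' or 'lambda'")
    filter_matrix = np.zeros((r, n))
    filter_matrix[np.arange(r), list(selected)] = 1.0
    output_matrix = basis.eigenvectors[:, list(selected)].T
    return OutputProjector(
        r=r,
        selected_indices=selected,
        filter_matrix=filter_matrix,
        output_matrix=output_matrix,
    )


def betweenness_ranking(network: WeightedNetwork) -> np.ndarray:
    """Node indices sorted by descending shortest-path betweenness centrality.

    High-betweenness nodes sit on many shortest paths and make homogeneous
    driver candidates.  Weighted links are converted to path lengths via the
    reciprocal weight (stronger links are shorter); binary networks reduce to
    ordinary unweighted betweenness.  Ties break by node index.
    """
    g = nx.from_numpy_array(network.adjacency)
    if network.n > 0 and not nx.is_connected(g):
        warnings.warn("network is disconnected; betweenness computed per component")
    weights = network.adjacency[network.adjacency > 0]
    if weights.size and not np.all(weights == 1.0):
        for _, _, d in g.edges(data=True):
            d["length"] = 1.0 / d["weight"]
        bc = nx.betweenness_centrality(g, weight="length", normalized=True)
    else:
        bc = nx.betweenness_centrality(g, normalized=True)
    scores = np.array([bc[i] for i in range(network.n)])
    return np.lexsort((np.arange(network.n), -scores))
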
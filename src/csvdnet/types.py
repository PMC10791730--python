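"""Shared containers for probability-weighted structural networks.

The pipeline's central object is a symmetric, hollow (zero-diagonal),
nonnegative N x N matrix of connectivity probabilities ``P_ij`` — the
fraction of probabilistic streamline samples seeded in region *i* that
reach region *j*.  ``ConnectivityMatrix`` enforces those invariants once,
at the boundary; downstream numerical code then works on plain arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MatrixValidationError

#: tolerance for symmetry / zero-diagonal checks on matrices read from text
SYMMETRY_ATOL = 1e-9


def validate_weights(
    weights: np.ndarray,
    *,
    unit_interval: bool = True,
    atol: float = SYMMETRY_ATOL,
) -> np.ndarray:
    """Validate a square symmetric nonnegative weight matrix.

    Returns the validated ``float64`` array.  Raises
    :class:`~csvdnet.errors.MatrixValidationError` with the offending
    coordinates for NaN entries and with the maximum-asymmetry entry for
    asymmetric input.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise MatrixValidationError(f"expected a square matrix, got shape {w.shape}")
    nan_idx = np.argwhere(np.isnan(w))
    if nan_idx.size:
        i, j = nan_idx[0]
        raise MatrixValidationError(f"NaN entry at (row={i}, col={j})")
    if not np.all(np.isfinite(w)):
        raise MatrixValidationError("matrix contains non-finite entries")
    asym = np.abs(w - w.T)
    if asym.max(initial=0.0) > atol:
        i, j = np.unravel_index(int(np.argmax(asym)), asym.shape)
        raise MatrixValidationError(
            f"matrix is asymmetric: |w[{i},{j}] - w[{j},{i}]| = {asym[i, j]:.3g}"
        )
    if np.abs(np.diagonal(w)).max(initial=0.0) > atol:
        raise MatrixValidationError("matrix diagonal must be zero")
    if w.min(initial=0.0) < 0:
        raise MatrixValidationError("matrix has negative entries")
    if unit_interval and w.max(initial=0.0) > 1.0 + atol:
        raise MatrixValidationError("connection probabilities must lie in [0, 1]")
    out = 0.5 * (w + w.T)  # exact symmetry after tolerance check
    np.fill_diagonal(out, 0.0)
    return out


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric probability-weighted network over N brain regions."""

    weights: np.ndarray
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        w = validate_weights(self.weights, unit_interval=True)
        object.__setattr__(self, "weights", w)
        if self.node_labels is not None:
            labels = tuple(self.node_labels)
            if len(labels) != w.shape[0]:
                raise MatrixValidationError(
                    f"{len(labels)} node labels for a {w.shape[0]}-node matrix"
                )
            if len(set(labels)) != len(labels):
                raise MatrixValidationError("node labels must be unique")
            object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class ThresholdedNetwork:
    """A network surviving one sparsity level of the threshold sweep.

    ``sparsity`` is the fraction of the N(N-1)/2 possible undirected edges
    retained; ``retained_edges`` the realized count (it can fall short of
    ``floor(sparsity * N(N-1)/2)`` only when the raw matrix had fewer
    nonzero connections than requested).
    """

    weights: np.ndarray
    sparsity: float
    retained_edges: int = field(default=-1)

    def __post_init__(self) -> None:
        if not (0.0 < self.sparsity <= 1.0):
            raise MatrixValidationError(f"sparsity {self.sparsity} outside (0, 1]")
        w = validate_weights(self.weights, unit_interval=False)
        object.__setattr__(self, "weights", w)
        if self.retained_edges < 0:
            n_edges = int(np.count_nonzero(np.triu(w, 1)))
            object.__setattr__(self, "retained_edges", n_edges)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


def as_weights(network) -> np.ndarray:
    """Extract the weight array from any supported network representation."""
    if isinstance(network, (ConnectivityMatrix, ThresholdedNetwork)):
        return network.weights
    return np.asarray(network, dtype=float)
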
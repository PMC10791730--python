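"""Sparsity thresholding of probability-weighted connectivity matrices.

Spurious connections are removed by keeping only the strongest fraction
(*sparsity*) of all possible undirected edges, and the analysis is swept
over a sparsity grid (6–24% in 1% steps by default) so that no result
hinges on a single arbitrary cutoff.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import DegenerateThresholdError, MatrixValidationError, ParameterError, ThresholdWarning
from .types import ThresholdedNetwork, as_weights, validate_weights

DEFAULT_SMIN = 0.06
DEFAULT_SMAX = 0.24
DEFAULT_STEP = 0.01


def _validated(network, symmetrize: str | None) -> np.ndarray:
    w = np.asarray(as_weights(network), dtype=float)
    if symmetrize == "mean" and w.ndim == 2 and w.shape[0] == w.shape[1]:
        w = 0.5 * (w + w.T)
        np.fill_diagonal(w, 0.0)
    elif symmetrize not in (None, "mean"):
        raise ParameterError(f"unknown symmetrize option {symmetrize!r}")
    return validate_weights(w, unit_interval=False)


def apply_sparsity_threshold(
    network,
    sparsity: float,
    *,
    symmetrize: str | None = None,
) -> ThresholdedNetwork:
    """Keep the ``floor(sparsity * N(N-1)/2)`` strongest undirected edges.

    Retained edges keep their original weights; everything else is zeroed.
    Ties at the cutoff weight are broken deterministically by ascending
    (row, column) index so results are reproducible across platforms.

    Raises
    ------
    DegenerateThresholdError
        If the requested sparsity retains zero edges.
    ParameterError
        If ``sparsity`` lies outside (0, 1].
    """
    if not (0.0 < sparsity <= 1.0):
        raise ParameterError(f"sparsity must lie in (0, 1], got {sparsity}")
    w = _validated(network, symmetrize)
    n = w.shape[0]
    n_pairs = n * (n - 1) // 2
    m = int(np.floor(sparsity * n_pairs))
    if m == 0:
        raise DegenerateThresholdError(
            f"sparsity {sparsity} retains 0 of {n_pairs} possible edges"
        )
    rows, cols = np.triu_indices(n, 1)
    vals = w[rows, cols]
    nonzero = vals > 0
    available = int(nonzero.sum())
    if m > available:
        warnings.warn(
            f"sparsity {sparsity} requests {m} edges but only {available} "
            "nonzero connections exist; keeping all of them",
            ThresholdWarning,
            stacklevel=2,
        )
        m = available
    # primary key: descending weight; ties by ascending (row, col)
    order = np.lexsort((cols, rows, -vals))
    order = order[nonzero[order]][:m]
    out = np.zeros_like(w)
    out[rows[order], cols[order]] = vals[order]
    out += out.T
    return ThresholdedNetwork(weights=out, sparsity=float(sparsity), retained_edges=m)


def sparsity_grid(
    s_min: float = DEFAULT_SMIN,
    s_max: float = DEFAULT_SMAX,
    step: float = DEFAULT_STEP,
) -> np.ndarray:
    """Inclusive sparsity grid ``s_min, s_min+step, ..., s_max``."""
    if step <= 0:
        raise ParameterError("step must be positive")
    if s_min > s_max:
        raise ParameterError(f"s_min {s_min} > s_max {s_max}")
    n_steps = int(np.floor((s_max - s_min) / step + 0.5)) + 1
    grid = s_min + step * np.arange(n_steps)
    grid = grid[grid <= s_max + 0.5 * step]
    if grid.size == 0:
        raise ParameterError("empty sparsity grid")
    return np.round(grid, 12)


def threshold_sweep(
    network,
    s_min: float = DEFAULT_SMIN,
    s_max: float = DEFAULT_SMAX,
    step: float = DEFAULT_STEP,
    *,
    symmetrize: str | None = None,
) -> list[ThresholdedNetwork]:
    """Threshold one matrix at every sparsity level of the grid.

    The returned list is ordered by increasing sparsity, so retained edge
    counts are non-decreasing and (for tie-free weights) the edge sets are
    nested.
    """
    grid = sparsity_grid(s_min, s_max, step)
    w = _validated(network, symmetrize)
    n = w.shape[0]
    n_pairs = n * (n - 1) // 2
    rows, cols = np.triu_indices(n, 1)
    vals = w[rows, cols]
    nonzero = vals > 0
    available = int(nonzero.sum())
    # sort once; every threshold is a prefix of the same ranking
    order = np.lexsort((cols, rows, -vals))
    order = order[nonzero[order]]
    out = []
    for s in grid:
        m = int(np.floor(float(s) * n_pairs))
        if m == 0:
            raise DegenerateThresholdError(
                f"sparsity {s} retains 0 of {n_pairs} possible edges"
            )
        if m > available:
            warnings.warn(
                f"sparsity {s} requests {m} edges but only {available} "
                "nonzero connections exist; keeping all of them",
                ThresholdWarning,
                stacklevel=2,
            )
            m = available
        keep = order[:m]
        tw = np.zeros_like(w)
        tw[rows[keep], cols[keep]] = vals[keep]
        tw += tw.T
        out.append(ThresholdedNetwork(weights=tw, sparsity=float(s), retained_edges=m))
    return out
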
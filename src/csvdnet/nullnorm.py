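"""Matched random networks and normalized small-world indices.

A network is called small-world when its clustering greatly exceeds that
of a degree-matched random network while its characteristic path length
stays comparable: gamma = Cp_real / Cp_rand > 1 with
lambda = Lp_real / Lp_rand ~ 1, summarized by sigma = gamma / lambda > 1.

The matched null model preserves the degree sequence exactly
(Maslov–Sneppen double-edge swaps) and the weight multiset exactly (the
original weights are randomly permuted onto the rewired edge set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateEnsembleError, NullModelWarning, ParameterError
from .metrics import characteristic_path_length, clustering, scale_weights, shortest_paths
from .errors import DisconnectedNetworkWarning
from .types import ThresholdedNetwork, as_weights

DEFAULT_N_RANDOM = 100
#: successful swaps per edge targeted by the rewiring (conventional mixing heuristic)
DEFAULT_SWAP_FACTOR = 10


@dataclass(frozen=True)
class RandomEnsemble:
    n_random: int
    mean_Cp_rand: float
    mean_Lp_rand: float


@dataclass(frozen=True)
class SmallWorldRecord:
    gamma: float
    lam: float
    sigma: float
    subject_id: str | None = None
    sparsity: float | None = None


def rewire_matched_random(
    network,
    rng: np.random.Generator,
    *,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    max_attempt_factor: int = 100,
) -> ThresholdedNetwork:
    """Degree- and weight-multiset-preserving randomization of one network.

    Performs ``swap_factor * n_edges`` successful double-edge swaps
    ((u,v),(x,y) -> (u,x),(v,y), rejecting self-loops and multi-edges), then
    permutes the original weight multiset onto the rewired edge set.  If the
    swap target cannot be reached within the attempt budget (e.g. a star
    graph admits no swap at all) a :class:`NullModelWarning` reports the
    achieved count and the partially rewired network is returned.
    """
    w = as_weights(network)
    n = w.shape[0]
    rows, cols = np.triu_indices(n, 1)
    mask = w[rows, cols] > 0
    edges = list(zip(rows[mask].tolist(), cols[mask].tolist()))
    weight_pool = w[rows[mask], cols[mask]]
    n_edges = len(edges)
    if n_edges < 4:
        raise ParameterError(f"rewiring requires >= 4 edges, got {n_edges}")

    edge_set = set(edges)
    target = swap_factor * n_edges
    max_attempts = max_attempt_factor * max(target, 1)
    swaps = attempts = 0
    randint = rng.integers
    while swaps < target and attempts < max_attempts:
        attempts += 1
        a = int(randint(n_edges))
        b = int(randint(n_edges))
        if a == b:
            continue
        u, v = edges[a]
        x, y = edges[b]
        if randint(2):
            u, v = v, u
        if randint(2):
            x, y = y, x
        if u == x or v == y or u == y or v == x:
            continue
        e1 = (u, x) if u < x else (x, u)
        e2 = (v, y) if v < y else (y, v)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[a])
        edge_set.discard(edges[b])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[a] = e1
        edges[b] = e2
        swaps += 1
    if swaps < target:
        warnings.warn(
            f"double-edge swap target {target} not reached: {swaps} successful "
            f"swaps in {attempts} attempts",
            NullModelWarning,
            stacklevel=2,
        )

    perm = rng.permutation(n_edges)
    out = np.zeros_like(w)
    idx = np.array(edges)
    out[idx[:, 0], idx[:, 1]] = weight_pool[perm]
    out += out.T
    sparsity = getattr(network, "sparsity", n_edges / (n * (n - 1) / 2))
    return ThresholdedNetwork(weights=out, sparsity=float(sparsity), retained_edges=n_edges)


def _cp_lp(weights) -> tuple[float, float]:
    scaled = scale_weights(weights)
    _, cp = clustering(scaled)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DisconnectedNetworkWarning)
        lp, _ = characteristic_path_length(shortest_paths(scaled))
    return cp, lp


def ensemble_reference(
    network,
    n_random: int,
    rng: np.random.Generator,
    *,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    surrogates=None,
) -> RandomEnsemble:
    """Mean Cp and Lp over ``n_random`` matched random surrogates.

    ``surrogates`` lets callers supply a pre-built ensemble (used by tests,
    e.g. the self-ensemble for which gamma = lambda = sigma = 1).
    """
    if surrogates is None:
        if n_random < 1:
            raise ParameterError("n_random must be >= 1")
        surrogates = (
            rewire_matched_random(network, rng, swap_factor=swap_factor)
            for _ in range(n_random)
        )
        count = n_random
    else:
        surrogates = list(surrogates)
        count = len(surrogates)
    cps, lps = [], []
    for s in surrogates:
        cp, lp = _cp_lp(s)
        cps.append(cp)
        lps.append(lp)
    return RandomEnsemble(
        n_random=count,
        mean_Cp_rand=float(np.mean(cps)),
        mean_Lp_rand=float(np.mean(lps)),
    )


def normalized_small_world(
    network,
    n_random: int = DEFAULT_N_RANDOM,
    rng: np.random.Generator | None = None,
    *,
    swap_factor: int = DEFAULT_SWAP_FACTOR,
    surrogates=None,
    subject_id: str | None = None,
) -> SmallWorldRecord:
    """gamma, lambda and sigma of one network against its matched ensemble.

    gamma = Cp_real / Cp_rand, lambda = Lp_real / Lp_rand,
    sigma = gamma / lambda.
    """
    if rng is None:
        rng = np.random.default_rng()
    cp_real, lp_real = _cp_lp(network)
    ens = ensemble_reference(
        network, n_random, rng, swap_factor=swap_factor, surrogates=surrogates
    )
    if ens.mean_Cp_rand <= 0 or not np.isfinite(ens.mean_Cp_rand):
        raise DegenerateEnsembleError(
            f"ensemble mean clustering {ens.mean_Cp_rand} unusable for normalization"
        )
    if ens.mean_Lp_rand <= 0 or not np.isfinite(ens.mean_Lp_rand):
        raise DegenerateEnsembleError(
            f"ensemble mean path length {ens.mean_Lp_rand} unusable for normalization"
        )
    gamma = cp_real / ens.mean_Cp_rand
    lam = lp_real / ens.mean_Lp_rand
    return SmallWorldRecord(
        gamma=float(gamma),
        lam=float(lam),
        sigma=float(gamma / lam),
        subject_id=subject_id,
        sparsity=getattr(network, "sparsity", None),
    )
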
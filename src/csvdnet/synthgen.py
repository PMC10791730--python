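"""Synthetic cohort generator emulating probabilistic-tractography output.

Real inputs to this pipeline are per-subject 90 x 90 matrices of
connectivity probabilities from diffusion tractography, together with
demographics and cognitive scores for three groups: severe cerebral
small vessel disease (CSVD-s), mild disease (CSVD-m) and healthy
controls (HC).  The generator emulates that data at the statistical
level the analysis needs:

* a Watts–Strogatz small-world backbone (N=90, lattice degree 10,
  rewiring probability 0.1) carrying clipped log-normal edge weights in
  (0, 1] — yields gamma > 1 and lambda ~ 1 like empirical connectomes;
* a group-graded *local* deficit: a fraction of triangle-closing edges is
  attenuated by a per-group factor delta (CSVD-s strongest), lowering
  local efficiency while barely touching global metrics;
* cognitive scores tied to the per-subject latent damage score and
  calibrated to published group means/SDs, with the expected sign
  pattern (more damage: lower MoCA/AVLT/SDMT, higher SCWT/TMT).

Everything is reproducible from a single seed; per-subject RNG streams
are spawned from it so cohorts are stable under any iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, GenerationError, ParameterError
from .types import ConnectivityMatrix

GROUPS = ("CSVD-s", "CSVD-m", "HC")
COGNITIVE_TESTS = ("MoCA", "AVLT", "SDMT", "SCWT", "TMT_BA")
#: -1: damage lowers the score; +1: damage raises it (timed / error scores)
SCORE_DIRECTION = {"MoCA": -1.0, "AVLT": -1.0, "SDMT": -1.0, "SCWT": 1.0, "TMT_BA": 1.0}

DEFAULT_GROUP_SIZES = {"CSVD-s": 67, "CSVD-m": 133, "HC": 89}
DEFAULT_ATTENUATION = {"CSVD-s": 0.5, "CSVD-m": 0.9, "HC": 1.0}

#: per-group (mean, SD) cognitive calibration
DEFAULT_COGNITION = {
    "CSVD-s": {"MoCA": (24.03, 2.97), "AVLT": (54.76, 12.82), "SDMT": (26.39, 11.24),
               "SCWT": (175.44, 55.79), "TMT_BA": (172.86, 94.78)},
    "CSVD-m": {"MoCA": (25.26, 3.58), "AVLT": (60.16, 13.14), "SDMT": (31.55, 12.53),
               "SCWT": (147.36, 43.95), "TMT_BA": (127.47, 100.03)},
    "HC": {"MoCA": (26.04, 3.79), "AVLT": (63.11, 12.44), "SDMT": (39.32, 14.05),
           "SCWT": (137.12, 50.35), "TMT_BA": (111.37, 93.14)},
}

#: per-group age/education (mean, SD) and male fraction
DEFAULT_COVARIATES = {
    "CSVD-s": {"age": (64.16, 5.48), "education": (11.13, 3.15), "male_fraction": 43 / 67},
    "CSVD-m": {"age": (62.11, 6.88), "education": (12.10, 3.29), "male_fraction": 70 / 133},
    "HC": {"age": (61.43, 9.54), "education": (12.38, 3.88), "male_fraction": 40 / 89},
}


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    age: float
    sex: str
    education: float
    scores: dict[str, float]
    damage_score: float = 0.0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """All knobs of the generator; defaults are the study conditions."""

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_nodes: int = 90
    ws_neighbors: int = 10
    ws_rewire_prob: float = 0.1
    weight_log_mean: float = -4.0
    weight_log_sd: float = 0.7
    attenuation: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ATTENUATION))
    attenuated_fraction: float = 0.5
    severity_jitter: float = 0.5
    cognition_calibration: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_COGNITION.items()
    })
    covariate_calibration: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_COVARIATES.items()
    })
    noise_share: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if set(self.group_sizes) != set(GROUPS):
            raise ConfigError(f"group_sizes must cover exactly {GROUPS}")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ParameterError("every group needs >= 2 subjects")
        if not (0 < self.attenuated_fraction <= 1):
            raise ParameterError("attenuated_fraction must lie in (0, 1]")
        if not (0 <= self.severity_jitter < 1):
            raise ParameterError("severity_jitter must lie in [0, 1)")
        for g, d in self.attenuation.items():
            if not (0 < d <= 1):
                raise ParameterError(f"attenuation for {g} must lie in (0, 1], got {d}")
        if self.ws_neighbors % 2 or not (2 <= self.ws_neighbors < self.n_nodes):
            raise ParameterError("ws_neighbors must be even and in [2, n_nodes)")
        if not (0 <= self.ws_rewire_prob <= 1):
            raise ParameterError("ws_rewire_prob must lie in [0, 1]")
        if not (0 <= self.noise_share <= 1):
            raise ParameterError("noise_share must lie in [0, 1]")
        for g in GROUPS:
            cal = self.cognition_calibration.get(g, {})
            missing = set(COGNITIVE_TESTS) - set(cal)
            if missing:
                raise ConfigError(f"cognition calibration for {g} missing {sorted(missing)}")
            unknown = set(cal) - set(COGNITIVE_TESTS)
            if unknown:
                raise ConfigError(f"unknown test name(s) in calibration: {sorted(unknown)}")

    def with_(self, **kwargs) -> "SyntheticCohortConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# per-subject building blocks

def generate_base_topology(
    n_nodes: int,
    ws_neighbors: int,
    ws_rewire_prob: float,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> np.ndarray:
    """Connected Watts–Strogatz backbone as a binary adjacency matrix.

    Rewiring preserves the edge count (n * k0 / 2); disconnected draws are
    resampled up to ``max_retries`` times.
    """
    if ws_neighbors % 2:
        raise ParameterError(f"ws_neighbors must be even, got {ws_neighbors}")
    if not (2 <= ws_neighbors < n_nodes):
        raise ParameterError("need 2 <= ws_neighbors < n_nodes")
    try:
        g = nx.connected_watts_strogatz_graph(
            n_nodes, ws_neighbors, ws_rewire_prob,
            tries=max_retries, seed=int(rng.integers(2**31)),
        )
    except nx.NetworkXError as exc:
        raise GenerationError(
            f"no connected Watts-Strogatz graph in {max_retries} tries"
        ) from exc
    adj = nx.to_numpy_array(g, nodelist=range(n_nodes), dtype=float)
    adj[adj > 0] = 1.0
    return adj


def assign_weights(
    adjacency: np.ndarray,
    weight_log_mean: float,
    weight_log_sd: float,
    rng: np.random.Generator,
    node_labels=None,
) -> ConnectivityMatrix:
    """Independent log-normal weight per edge, clipped to (0, 1]."""
    a = np.asarray(adjacency, dtype=float)
    n = a.shape[0]
    rows, cols = np.triu_indices(n, 1)
    mask = a[rows, cols] > 0
    draws = rng.lognormal(mean=weight_log_mean, sigma=weight_log_sd, size=int(mask.sum()))
    draws = np.minimum(draws, 1.0)
    w = np.zeros_like(a)
    w[rows[mask], cols[mask]] = draws
    w += w.T
    return ConnectivityMatrix(weights=w, node_labels=node_labels)


def apply_group_effect(
    matrix: ConnectivityMatrix,
    group: str,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> tuple[ConnectivityMatrix, float]:
    """Attenuate a random set of preferentially triangle-closing edges.

    A per-subject severity multiplier (uniform in 1 +/- severity_jitter)
    scales the attenuated fraction, modelling inter-patient heterogeneity
    of lesion burden.  Returns the modified matrix and the latent damage
    score: the mean per-edge attenuation applied, i.e.
    ``n_attenuated * (1 - delta) / n_edges`` (0 for HC where delta = 1).
    """
    if group not in GROUPS:
        raise ParameterError(f"unknown group {group!r}")
    delta = config.attenuation[group]
    if not (0 < delta <= 1):
        raise ParameterError(f"attenuation must lie in (0, 1], got {delta}")
    w = matrix.weights
    n = w.shape[0]
    rows, cols = np.triu_indices(n, 1)
    mask = w[rows, cols] > 0
    n_edges = int(mask.sum())
    if delta == 1.0 or n_edges == 0:
        return matrix, 0.0

    severity = 1.0 + config.severity_jitter * (2.0 * rng.random() - 1.0)
    frac = min(max(config.attenuated_fraction * severity, 0.0), 1.0)
    n_sel = min(int(round(frac * n_edges)), n_edges)
    if n_sel == 0:
        return matrix, 0.0

    adj = (w > 0).astype(float)
    common = adj @ adj  # common-neighbor count = triangles each edge closes
    er, ec = rows[mask], cols[mask]
    # selection probability ~ (triangle count)^2: the insult concentrates in
    # densely clustered neighborhoods, so the deficit is specifically local
    score = common[er, ec].astype(float) ** 2
    tri_idx = np.flatnonzero(score > 0)
    other_idx = np.flatnonzero(score == 0)
    if tri_idx.size >= n_sel:
        p = score[tri_idx] / score[tri_idx].sum()
        picked = rng.choice(tri_idx, size=n_sel, replace=False, p=p)
    else:
        extra = rng.permutation(other_idx)[: n_sel - tri_idx.size]
        picked = np.concatenate([tri_idx, extra])

    out = w.copy()
    out[er[picked], ec[picked]] *= delta
    out[ec[picked], er[picked]] *= delta
    damage = picked.size * (1.0 - delta) / n_edges
    return ConnectivityMatrix(weights=out, node_labels=matrix.node_labels), float(damage)


def expected_damage(group: str, config: SyntheticCohortConfig) -> float:
    """Analytic group-mean latent damage under the configured attenuation."""
    return config.attenuated_fraction * (1.0 - config.attenuation[group])


def _damage_sd(group: str, config: SyntheticCohortConfig) -> float:
    # SD of frac*(1-delta) with the uniform severity multiplier
    return (
        config.attenuated_fraction
        * (1.0 - config.attenuation[group])
        * config.severity_jitter
        / np.sqrt(3.0)
    )


def generate_cognition(
    damage_score: float,
    group: str,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Cognitive scores linked to the latent damage score.

    Each score is the calibrated group mean plus a damage-linked shift plus
    Gaussian noise.  The slope is set so the damage signal carries a
    ``1 - noise_share`` share of the calibrated variance (sign per test:
    damage lowers MoCA/AVLT/SDMT, raises SCWT/TMT).  Groups without damage
    variance (delta = 1) get pure noise at the full calibrated SD.
    """
    if damage_score < 0:
        raise ParameterError("damage_score must be >= 0")
    cal = config.cognition_calibration[group]
    unknown = set(cal) - set(COGNITIVE_TESTS)
    if unknown:
        raise ConfigError(f"unknown test name(s) in calibration: {sorted(unknown)}")
    dmean = expected_damage(group, config)
    dsd = _damage_sd(group, config)
    scores = {}
    for test in COGNITIVE_TESTS:
        mean, sd = cal[test]
        if dsd > 0:
            slope = SCORE_DIRECTION[test] * np.sqrt(1.0 - config.noise_share) * sd / dsd
            noise_sd = sd * np.sqrt(config.noise_share)
        else:
            slope = 0.0
            noise_sd = sd
        scores[test] = float(mean + slope * (damage_score - dmean) + rng.normal(0.0, noise_sd))
    return scores


# ---------------------------------------------------------------------------
# cohort assembly

def generate_subject(
    subject_id: str,
    group: str,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
    node_labels=None,
) -> tuple[ConnectivityMatrix, SubjectRecord]:
    adjacency = generate_base_topology(
        config.n_nodes, config.ws_neighbors, config.ws_rewire_prob, rng
    )
    matrix = assign_weights(
        adjacency, config.weight_log_mean, config.weight_log_sd, rng, node_labels
    )
    matrix, damage = apply_group_effect(matrix, group, config, rng)
    scores = generate_cognition(damage, group, config, rng)
    cov = config.covariate_calibration[group]
    age = float(rng.normal(*cov["age"]))
    education = float(max(0.0, rng.normal(*cov["education"])))
    sex = "M" if rng.random() < cov["male_fraction"] else "F"
    record = SubjectRecord(
        subject_id=subject_id, group=group, age=age, sex=sex,
        education=education, scores=scores, damage_score=damage,
    )
    return matrix, record


def generate_backbone_matrices(
    n_subjects: int,
    config: SyntheticCohortConfig | None = None,
    seed: int | None = None,
) -> list[ConnectivityMatrix]:
    """Undamaged small-world subjects (backbone + weights only, no group effect).

    The healthy-control condition of the generator; used for small-world
    characterization where no deficit is injected.
    """
    config = config or SyntheticCohortConfig()
    children = np.random.SeedSequence(config.seed if seed is None else seed).spawn(n_subjects)
    out = []
    for child in children:
        rng = np.random.default_rng(child)
        adj = generate_base_topology(
            config.n_nodes, config.ws_neighbors, config.ws_rewire_prob, rng
        )
        out.append(assign_weights(adj, config.weight_log_mean, config.weight_log_sd, rng))
    return out


def generate_cohort(
    config: SyntheticCohortConfig | None = None,
) -> tuple[list[ConnectivityMatrix], pd.DataFrame]:
    """Full synthetic cohort: one matrix plus one metadata row per subject.

    Reproducible bit-for-bit from ``config.seed`` (per-subject RNG streams
    are spawned from one seed sequence).
    """
    config = config or SyntheticCohortConfig()
    config.validate()
    total = sum(config.group_sizes[g] for g in GROUPS)
    children = np.random.SeedSequence(config.seed).spawn(total)
    labels = None
    if config.n_nodes == 90:
        from .io import load_node_labels

        labels = tuple(load_node_labels())

    matrices: list[ConnectivityMatrix] = []
    rows = []
    i = 0
    for group in GROUPS:
        for _ in range(config.group_sizes[group]):
            rng = np.random.default_rng(children[i])
            sid = f"sub-{i + 1:03d}"
            matrix, rec = generate_subject(sid, group, config, rng, node_labels=labels)
            matrices.append(matrix)
            rows.append({
                "subject_id": rec.subject_id, "group": rec.group, "age": rec.age,
                "sex": rec.sex, "education": rec.education, **rec.scores,
                "damage_score": rec.damage_score,
            })
            i += 1
    return matrices, pd.DataFrame(rows)
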
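"""Threshold-curve aggregation (AUC) and hub identification.

Each metric is computed at every sparsity of the sweep; the area under
that curve (trapezoid rule over the sparsity axis) summarizes the metric
in a single scalar independent of any one threshold.  Hubs are nodes whose
group-mean nodal-efficiency AUC exceeds the network mean by more than one
standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class MetricCurve:
    thresholds: np.ndarray
    values: np.ndarray
    metric_name: str = ""
    subject_id: str | None = None

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ParameterError("thresholds and values must be 1-D and equal length")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ParameterError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class HubSet:
    hubs: tuple[str, ...]
    cutoff: float
    group_label: str | None = None


def compute_auc(curve: MetricCurve | None = None, *, thresholds=None, values=None) -> float:
    """Trapezoidal area under a metric-vs-sparsity curve (>= 2 points)."""
    if curve is None:
        curve = MetricCurve(thresholds=thresholds, values=values)
    if curve.thresholds.size < 2:
        raise ParameterError("AUC requires at least 2 curve points")
    return float(np.trapezoid(curve.values, curve.thresholds))


def identify_hubs(
    values,
    labels,
    *,
    group_label: str | None = None,
    ddof: int = 1,
) -> HubSet:
    """Nodes whose value strictly exceeds mean + SD of the vector.

    ``ddof=1`` (sample SD) by default; population SD available via
    ``ddof=0``.  A zero-variance vector yields an empty hub set.
    """
    v = np.asarray(values, dtype=float)
    labels = list(labels)
    if v.ndim != 1 or v.size < 2:
        raise ParameterError("hub identification requires a vector of >= 2 nodes")
    if len(labels) != v.size:
        raise ParameterError(f"{len(labels)} labels for {v.size} values")
    cutoff = float(v.mean() + v.std(ddof=ddof))
    hubs = tuple(lab for lab, val in zip(labels, v) if val > cutoff)
    return HubSet(hubs=hubs, cutoff=cutoff, group_label=group_label)
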
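"""Weighted node-level network metrics.

The five metrics analyzed by the protocol are weighted outdegree,
indegree and total degree (strengths), eigenvector centrality, and a
weighted local clustering coefficient.

Directionality conventions
--------------------------
Strengths are computed on the raw directed matrix: outdegree of *i* is
the total weight of behavior *i* gives, indegree the total it receives,
and degree their sum ("activity").  Eigenvector centrality and the
clustering coefficient are defined on the symmetrized weight matrix
``W = M + M.T`` — the default of the classic desktop SNA tools these
analyses mirror — because both metrics measure undirected cohesion.

Clustering follows the Barrat et al. weighted formulation

.. math::

    C_i = \\frac{1}{s_i (k_i - 1)} \\sum_{j,h} \\frac{w_{ij} + w_{ih}}{2}
          a_{ij} a_{ih} a_{jh}

which credits each closed triangle around *i* in proportion to the
strength of the two ties anchored at *i*.  Nodes with fewer than two
neighbors get 0 (not NaN) so regressions over all individuals keep every
row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateNetworkError
from .io_core import InteractionMatrix

METRIC_NAMES = ("outdegree", "indegree", "degree", "eigenvector", "clustering")

_POWER_TOL = 1e-10
_POWER_MAXITER = 100_000


@dataclass
class MetricVector:
    """One real value per individual for a single named metric."""

    metric: str
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("metric vector length must match ids")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.ids, name=self.metric)


def strength(m: InteractionMatrix, mode: str = "total") -> MetricVector:
    """Weighted degree: ``out`` (row sums), ``in`` (column sums) or ``total``."""
    w = m.counts.astype(float)
    if mode == "out":
        vals, name = w.sum(axis=1), "outdegree"
    elif mode == "in":
        vals, name = w.sum(axis=0), "indegree"
    elif mode == "total":
        vals, name = w.sum(axis=1) + w.sum(axis=0), "degree"
    else:
        raise ValueError(f"unknown strength mode {mode!r}")
    return MetricVector(name, list(m.ids), vals)


def eigenvector_centrality(m: InteractionMatrix) -> MetricVector:
    """Leading eigenvector of the symmetrized weight matrix.

    Power iteration to relative tolerance 1e-10, sign-normalized to be
    nonnegative and scaled to unit Euclidean norm.  In a disconnected
    network the iteration converges to the Perron vector of the dominant
    component; nodes outside it score ~0, which is accepted and
    documented.
    """
    w = (m.counts + m.counts.T).astype(float)
    if not np.any(w > 0):
        raise DegenerateNetworkError("eigenvector centrality needs at least one tie")
    n = m.n
    # positive diagonal shift: keeps the leading eigenvector unchanged but
    # makes the Perron root strictly dominant (bipartite graphs otherwise
    # oscillate with eigenvalues +/-lambda of equal magnitude)
    shift = w.sum(axis=1).max()
    w = w + shift * np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(_POWER_MAXITER):
        nxt = w @ v
        norm = np.linalg.norm(nxt)
        if norm == 0:  # pragma: no cover - impossible for nonneg w with a tie
            raise DegenerateNetworkError("power iteration collapsed to zero")
        nxt /= norm
        if np.linalg.norm(nxt - v) <= _POWER_TOL * np.linalg.norm(nxt):
            v = nxt
            break
        v = nxt
    v = np.abs(v)  # Perron vector of a nonnegative matrix is nonnegative
    v /= np.linalg.norm(v)
    return MetricVector("eigenvector", list(m.ids), v)


def weighted_clustering_coefficient(m: InteractionMatrix) -> MetricVector:
    """Barrat-style weighted clustering on the symmetrized graph.

    Vectorized form: with symmetric weights ``W``, adjacency ``A`` and the
    two-step count ``(A @ A)_{ij}`` (= number of common neighbors of i and
    j), the ordered-pair sum collapses to ``sum_j W_ij A_ij (A@A)_ij``.
    """
    w = (m.counts + m.counts.T).astype(float)
    a = (w > 0).astype(float)
    s = w.sum(axis=1)
    k = a.sum(axis=1)
    common = a @ a
    numer = (w * a * common).sum(axis=1)
    denom = s * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, numer / np.where(denom > 0, denom, 1.0), 0.0)
    return MetricVector("clustering", list(m.ids), c)


def all_metrics(m: InteractionMatrix) -> dict[str, MetricVector]:
    """The full metric battery for one network, keyed by metric name."""
    return {
        "outdegree": strength(m, "out"),
        "indegree": strength(m, "in"),
        "degree": strength(m, "total"),
        "eigenvector": eigenvector_centrality(m),
        "clustering": weighted_clustering_coefficient(m),
    }


def metrics_frame(m: InteractionMatrix) -> pd.DataFrame:
    """Long-format ``id,metric,value`` table of all five metrics."""
    frames = []
    for name, mv in all_metrics(m).items():
        frames.append(
            pd.DataFrame({"id": mv.ids, "metric": name, "value": mv.values})
        )
    return pd.concat(frames, ignore_index=True)
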
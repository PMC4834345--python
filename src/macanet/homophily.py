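"""Group-level homophily and heterophily tests.

Two statistics, both tested against a node-label permutation null:

* **Categorical difference of means** — for a categorical attribute
  (typically gender), the statistic is the mean tie weight over ordered
  *between*-group dyads minus the mean over ordered *within*-group
  dyads.  Zero-weight dyads enter both means, so the statistic mixes
  tie formation and tie strength; a negative value indicates homophily
  (within ties heavier than between ties).
* **Network Moran's I** — for a continuous attribute x,

  .. math::

      I = \\frac{n}{S_0}\\;\\frac{\\sum_{i \\ne j} w_{ij}(x_i-\\bar x)(x_j-\\bar x)}
                               {\\sum_i (x_i-\\bar x)^2}

  with raw directed weights and ``S_0 = sum_{i != j} w_ij``.  I is ~+1
  when ties connect individuals on the same side of the mean and ~-1
  when they connect opposite sides; under node-label permutation its
  null expectation is ``-1/(n-1)``.

Per-gender variants restrict the matrix and attributes to one gender
(induced submatrix) before testing.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeding import derive_seed
from .errors import (
    DegenerateAttributeError,
    DegenerateGroupError,
    DegenerateNetworkError,
)
from .io_core import AttributeTable, InteractionMatrix
from .perm_inference import permutation_pvalue

logger = logging.getLogger(__name__)


@dataclass
class HomophilyResult:
    kind: str  # "diff_of_means" | "moran_i"
    attribute: str
    subgroup: str  # "all" | "F_only" | "M_only"
    statistic: float
    p_value: float
    n_perm: int
    seed: int | None
    n_individuals: int
    note: str = ""
    network: str = ""
    null_sample: np.ndarray | None = field(default=None, repr=False)

    def as_row(self) -> dict:
        return {
            "network": self.network,
            "kind": self.kind,
            "attribute": self.attribute,
            "subgroup": self.subgroup,
            "statistic": self.statistic,
            "p": self.p_value,
            "n_perm": self.n_perm,
            "n": self.n_individuals,
            "seed": self.seed if self.seed is not None else "",
            "note": self.note,
        }


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def _diff_of_means(w: np.ndarray, labels: np.ndarray) -> float:
    """Between-dyad mean weight minus within-dyad mean weight."""
    same = labels[:, None] == labels[None, :]
    off = _offdiag_mask(len(labels))
    within = w[same & off]
    between = w[~same & off]
    return float(between.mean() - within.mean())


def categorical_homophily_test(
    m: InteractionMatrix,
    attrs: AttributeTable,
    attribute: str = "gender",
    n_perm: int | str = 10_000,
    seed: int | None = None,
) -> HomophilyResult:
    """Permutation difference-of-means test for a categorical attribute.

    Individuals with a missing level are excluded from the dyad sets.
    Negative statistic = homophily.  Two-sided permutation p.
    """
    attrs.check_covers(m)
    col = attrs.data.loc[m.ids, attribute]
    valid_ids = [i for i in m.ids if pd.notna(col.loc[i])]
    sub = m.induced(valid_ids)
    labels = col.loc[valid_ids].to_numpy()
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise DegenerateGroupError(
            f"attribute {attribute!r} has fewer than 2 levels among network members"
        )
    if counts.min() < 2:
        small = levels[counts < 2]
        raise DegenerateGroupError(
            f"level(s) {list(small)} of {attribute!r} have fewer than 2 members"
        )
    w = sub.counts.astype(float)
    observed = _diff_of_means(w, labels)
    rng = np.random.default_rng(seed)
    perms = _perm_indices(len(labels), n_perm, rng)
    null = np.array([_diff_of_means(w, labels[p]) for p in perms])
    p = permutation_pvalue(observed, null, "two_sided")
    return HomophilyResult(
        "diff_of_means", attribute, "all", observed, p, len(perms), seed, len(valid_ids),
        null_sample=null,
    )


def moran_i(m: InteractionMatrix, x: np.ndarray) -> float:
    """Network Moran's I with raw directed weights (no row standardization)."""
    w = m.counts.astype(float).copy()
    np.fill_diagonal(w, 0.0)
    x = np.asarray(x, dtype=float)
    if x.shape[0] != m.n:
        raise ValueError("attribute vector length must match the matrix")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise DegenerateAttributeError("constant attribute: Moran's I undefined")
    s0 = float(w.sum())
    if s0 == 0:
        raise DegenerateNetworkError("all-zero weights: Moran's I undefined")
    return float((m.n / s0) * (z @ w @ z) / denom)


def _perm_indices(n: int, n_perm: int | str, rng: np.random.Generator) -> np.ndarray:
    if n_perm == "exact":
        perms = [p for p in itertools.permutations(range(n)) if p != tuple(range(n))]
        return np.array(perms, dtype=np.intp)
    return np.array([rng.permutation(n) for _ in range(int(n_perm))], dtype=np.intp)


def moran_test(
    m: InteractionMatrix,
    x: np.ndarray,
    attribute: str = "x",
    n_perm: int | str = 10_000,
    seed: int | None = None,
) -> HomophilyResult:
    """Moran's I with a node-label permutation null (two-sided p).

    A significantly positive I is reported as homophily on the
    attribute.  ``n_perm="exact"`` enumerates all non-identity
    permutations (small n only).
    """
    w = m.counts.astype(float)
    x = np.asarray(x, dtype=float)
    observed = moran_i(m, x)
    z = x - x.mean()
    denom = float(z @ z)
    s0 = float(w.sum())
    rng = np.random.default_rng(seed)
    perms = _perm_indices(m.n, n_perm, rng)
    # identity permutation rides along as row 0 so the observed value used
    # in the tail count shares the exact floating-point path of the null
    stack = np.vstack([np.arange(m.n, dtype=np.intp)[None, :], perms])
    zp = z[stack]  # (1 + n_perm, n); mean is permutation-invariant
    vals = (m.n / s0) * np.einsum("pi,ij,pj->p", zp, w, zp) / denom
    null = vals[1:]
    p = permutation_pvalue(vals[0], null, "two_sided")
    return HomophilyResult(
        "moran_i", attribute, "all", observed, p, len(perms), seed, m.n,
        null_sample=null,
    )


def _gender_subsets(attrs: AttributeTable, m: InteractionMatrix):
    yield "all", m.ids
    for g, label in (("F", "F_only"), ("M", "M_only")):
        ids = [i for i in m.ids if attrs.data.loc[i, "gender"] == g]
        yield label, ids


def subgroup_tests(
    m: InteractionMatrix,
    attrs: AttributeTable,
    attribute: str,
    kind: str | None = None,
    n_perm: int | str = 10_000,
    seed: int | None = None,
) -> list[HomophilyResult]:
    """Pooled plus per-gender homophily tests for one attribute.

    ``kind`` defaults to ``diff_of_means`` for gender and ``moran_i`` for
    the numeric attributes (age, matriline, hierarchy).  Degenerate
    subgroups (too few members, constant attribute, one level) are
    reported as NaN rows with an explanatory note rather than aborting.
    """
    if kind is None:
        kind = "diff_of_means" if attribute == "gender" else "moran_i"
    attrs.check_covers(m)
    results: list[HomophilyResult] = []
    for label, ids in _gender_subsets(attrs, m):
        sub_seed = derive_seed(seed, f"homophily|{attribute}|{kind}|{label}") if seed is not None else None
        note = ""
        try:
            if len(ids) < 3:
                raise DegenerateGroupError(f"subgroup {label} has fewer than 3 members")
            sub_m = m.induced(ids)
            sub_attrs = attrs.subset(ids)
            if kind == "diff_of_means":
                res = categorical_homophily_test(sub_m, sub_attrs, attribute, n_perm, sub_seed)
            elif kind == "moran_i":
                col = sub_attrs.data[attribute]
                valid = [i for i in ids if pd.notna(col.loc[i])]
                if len(valid) < 3:
                    raise DegenerateGroupError(
                        f"subgroup {label}: fewer than 3 members with observed {attribute}"
                    )
                mm = sub_m.induced(valid)
                res = moran_test(mm, col.loc[valid].to_numpy(), attribute, n_perm, sub_seed)
            else:
                raise ValueError(f"unknown homophily kind {kind!r}")
            res.subgroup = label
            res.attribute = attribute
            results.append(res)
            continue
        except (DegenerateGroupError, DegenerateAttributeError, DegenerateNetworkError) as exc:
            note = str(exc)
            logger.warning("skipping %s homophily for %s: %s", attribute, label, note)
        results.append(
            HomophilyResult(kind, attribute, label, float("nan"), float("nan"),
                            0, sub_seed, len(ids), note=note)
        )
    return results


def homophily_frame(results: list[HomophilyResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])
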
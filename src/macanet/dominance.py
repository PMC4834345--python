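"""David's Score dominance ranking from the agonistic matrix.

For each ordered dyad let ``s_ij`` be the number of agonistic acts i
directed at j and ``n_ij = s_ij + s_ji`` the dyad's total.  The raw win
proportion is ``P_ij = s_ij / n_ij`` (0 when the dyad never interacted);
the chance-corrected variant is ``D_ij = P_ij - (P_ij - 0.5)/(n_ij + 1)``,
which shrinks proportions from sparsely observed dyads toward 0.5.

David's Score for individual i is

    DS_i = w_i + w2_i - l_i - l2_i

with ``w_i = sum_j P_ij`` (rate of winning), ``w2_i = sum_j P_ij w_j``
(wins weighted by opponents' winning rates), and ``l``, ``l2`` the losing
mirrors.  DS sums to zero over the group by construction.

The hierarchy covariate used by the regression stage is the ordinal rank
of DS: rank ``n`` for the highest score down to 1 for the lowest, ties
broken by mean rank, so that a positive regression coefficient reads
"the higher the hierarchical rank, the more ...".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import InteractionMatrix


@dataclass
class DominanceResult:
    ids: list[str]
    P: np.ndarray
    w: np.ndarray
    w2: np.ndarray
    l: np.ndarray
    l2: np.ndarray
    ds: np.ndarray
    rank: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "w": self.w,
                "w2": self.w2,
                "l": self.l,
                "l2": self.l2,
                "DS": self.ds,
                "rank": self.rank,
            },
            index=pd.Index(self.ids, name="id"),
        )

    @property
    def rank_series(self) -> pd.Series:
        return pd.Series(self.rank, index=self.ids, name="hierarchy")


def dyadic_dominance_matrix(m: InteractionMatrix, corrected: bool = False) -> np.ndarray:
    """Dyadic win proportions ``P_ij`` (or corrected ``D_ij``) from counts."""
    s = m.counts.astype(float)
    n_dyad = s + s.T
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_dyad > 0, s / np.where(n_dyad > 0, n_dyad, 1.0), 0.0)
    if corrected:
        p = np.where(n_dyad > 0, p - (p - 0.5) / (n_dyad + 1), 0.0)
    np.fill_diagonal(p, 0.0)
    return p


def davids_score(P: np.ndarray, ids: list[str]) -> DominanceResult:
    """David's Score and ordinal ranks from a dyadic proportion matrix."""
    P = np.asarray(P, dtype=float)
    w = P.sum(axis=1)
    w2 = P @ w
    l = P.sum(axis=0)
    l2 = P.T @ l
    ds = w + w2 - l - l2
    rank = ordinal_ranks(ds)
    return DominanceResult(list(ids), P, w, w2, l, l2, ds, rank)


def ordinal_ranks(ds: np.ndarray) -> np.ndarray:
    """Rank n for the highest score, 1 for the lowest, ties by mean rank."""
    return pd.Series(np.asarray(ds, dtype=float)).rank(method="average").to_numpy()


def dominance_from_matrix(m: InteractionMatrix, corrected: bool = False) -> DominanceResult:
    """Convenience: dyadic proportions then David's Score in one call."""
    return davids_score(dyadic_dominance_matrix(m, corrected=corrected), list(m.ids))
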
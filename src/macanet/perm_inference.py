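"""Node-label permutation inference for metric ~ attribute models.

Interaction data from one social group are not independent observations,
so classical regression p-values are invalid.  The protocol instead
keeps the network (and hence each individual's metric value) fixed and
permutes the attribute rows jointly over individuals.  The biological
null is that any individual could carry any attribute profile — i.e.,
that the metric carries no information about gender, age, matriline or
hierarchical rank.

Permuting attribute rows jointly is algebraically equivalent to
permuting the metric vector over individuals, which is how the engine
implements it: the design matrix is built once, its pseudoinverse is
reused for every permutation, and only the response vector is shuffled.
Point estimates are plain OLS — permutation affects inference only,
never the estimate.

Standard errors are bootstrap standard deviations over resamples of
individuals (cases) with replacement, matching the bootstrap option of
the GLM procedure the protocol emulates.  A term is flagged significant
when its two-sided permutation p-value is below ``alpha`` *and* the
absolute estimate exceeds ``effect_floor`` (default 0.009), an explicit
minimum-effect filter; terms suppressed by the floor alone are marked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeding import derive_seed
from .errors import DesignError
from .io_core import AttributeTable, InteractionMatrix
from .metrics import MetricVector, all_metrics

MAIN_EFFECT_TERMS = ("Intercept", "Gender", "Age", "Matriline", "Hierarchy")
INTERACTION_TERMS = (
    "Intercept",
    "Males*Age",
    "Females*Age",
    "Males*Matriline",
    "Females*Matriline",
    "Males*Hierarchy",
    "Females*Hierarchy",
)


def permute_node_labels(attrs: AttributeTable, rng: np.random.Generator) -> AttributeTable:
    """Reassign whole attribute rows to ids uniformly at random.

    All covariates travel together, so the attribute joint distribution
    and the network structure are both preserved; only the metric ~
    attribute association is broken.
    """
    perm = rng.permutation(attrs.n)
    df = attrs.data.iloc[perm].copy()
    df.index = pd.Index(attrs.ids, name="id")
    return AttributeTable(df)


def permutation_pvalue(observed: float, null_sample: np.ndarray, alternative: str = "two_sided") -> float:
    """Permutation p-value with the observed value counted in the null.

    ``p = (1 + #{null >= observed}) / (1 + n_perm)`` for ``greater``;
    mirrored for ``less``; ``two_sided`` doubles the smaller tail and
    caps at 1.  Ties count against rejection, and p is never exactly 0.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty permutation null sample")
    n = null_sample.size
    p_greater = (1 + np.sum(null_sample >= observed)) / (1 + n)
    p_less = (1 + np.sum(null_sample <= observed)) / (1 + n)
    if alternative == "greater":
        return float(p_greater)
    if alternative == "less":
        return float(p_less)
    if alternative == "two_sided":
        return float(min(1.0, 2.0 * min(p_greater, p_less)))
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass
class PermutationResult:
    """Observed statistic plus its permutation null and provenance."""

    observed: float
    null_sample: np.ndarray = field(repr=False)
    p_value: float
    alternative: str
    n_perm: int
    seed: int | None


@dataclass
class ModelFitTable:
    """Per-coefficient estimates, bootstrap SEs and permutation p-values."""

    metric: str
    model_kind: str
    terms: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    floor_suppressed: np.ndarray
    n_used: int
    n_dropped: int
    n_perm: int
    n_boot: int
    alpha: float
    effect_floor: float
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Factor": self.terms,
                "Estimate": self.estimates,
                "StdError": self.std_errors,
                "p": self.p_values,
                "Significant": self.significant,
                "FloorSuppressed": self.floor_suppressed,
            }
        )

    def estimate(self, term: str) -> float:
        return float(self.estimates[self.terms.index(term)])

    def p_value(self, term: str) -> float:
        return float(self.p_values[self.terms.index(term)])


def _design_matrix(attrs: AttributeTable, kind: str) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Build the design matrix and the keep-mask over attribute rows.

    Both model kinds contain matriline, so individuals with missing
    matriline are dropped (the mask reports which).  Gender is coded
    F=1 / M=0 so positive gender estimates read "females higher".
    """
    df = attrs.data
    keep = df["matriline"].notna().to_numpy()
    if df["hierarchy"].isna().any():
        raise DesignError(
            "hierarchy covariate missing for some individuals; "
            "compute dominance ranks first or supply a hierarchy column"
        )
    female = (df["gender"] == "F").to_numpy(dtype=float)[keep]
    age = df["age"].to_numpy(dtype=float)[keep]
    matriline = df["matriline"].to_numpy(dtype=float)[keep]
    hierarchy = df["hierarchy"].to_numpy(dtype=float)[keep]
    ones = np.ones_like(age)
    if kind == "main_effects":
        X = np.column_stack([ones, female, age, matriline, hierarchy])
        terms = list(MAIN_EFFECT_TERMS)
    elif kind == "gender_interaction":
        male = 1.0 - female
        X = np.column_stack(
            [
                ones,
                male * age,
                female * age,
                male * matriline,
                female * matriline,
                male * hierarchy,
                female * hierarchy,
            ]
        )
        terms = list(INTERACTION_TERMS)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return X, terms, keep


def _check_design(X: np.ndarray, terms: list[str]) -> None:
    n, k = X.shape
    if n < k + 2:
        raise DesignError(f"only {n} usable rows for {k} model terms")
    if np.linalg.matrix_rank(X) < k:
        sd = X.std(axis=0)
        flat = [t for t, s in zip(terms, sd) if s == 0 and t != "Intercept"]
        raise DesignError(
            "rank-deficient design matrix"
            + (f"; constant/collinear terms include {flat}" if flat else "")
        )


def _permutation_indices(n: int, n_perm: int | str, rng: np.random.Generator) -> np.ndarray:
    """Sampled permutations, or every non-identity permutation if 'exact'."""
    if n_perm == "exact":
        perms = [p for p in itertools.permutations(range(n)) if p != tuple(range(n))]
        return np.array(perms, dtype=np.intp)
    return np.array([rng.permutation(n) for _ in range(int(n_perm))], dtype=np.intp)


def fit_attribute_model(
    metric: MetricVector,
    attrs: AttributeTable,
    kind: str = "main_effects",
    n_perm: int | str = 10_000,
    n_boot: int = 1_000,
    alpha: float = 0.05,
    effect_floor: float = 0.009,
    seed: int | None = None,
) -> ModelFitTable:
    """OLS point estimates with node-label permutation p-values.

    ``n_perm="exact"`` enumerates all n!-1 non-identity permutations
    (small groups only).  ``n_boot=0`` skips the bootstrap (SEs NaN).
    """
    if list(metric.ids) != attrs.ids:
        order = {i: k for k, i in enumerate(metric.ids)}
        if set(metric.ids) != set(attrs.ids):
            raise DesignError("metric and attribute table must share the same ids")
        y_full = metric.values[[order[i] for i in attrs.ids]]
    else:
        y_full = metric.values
    y_full = np.asarray(y_full, dtype=float)

    X, terms, keep = _design_matrix(attrs, kind)
    _check_design(X, terms)
    y = y_full[keep]
    pinv = np.linalg.pinv(X)

    rng = np.random.default_rng(seed)
    perms = _permutation_indices(attrs.n, n_perm, rng)
    # permuting attribute rows jointly == permuting the metric over ids;
    # the keep-mask stays attached to the (fixed) attribute rows.  The
    # identity permutation rides along as row 0 so the observed estimate
    # goes through the *same* floating-point path as the null sample —
    # otherwise exact ties (e.g. a constant metric) break asymmetrically
    # on last-ulp rounding noise and the test spuriously rejects.
    identity = np.arange(attrs.n, dtype=np.intp)[None, :]
    stack = np.vstack([identity, perms]) if len(perms) > 0 else identity
    betas = y_full[stack][:, keep] @ pinv.T  # (1 + n_perm, k)
    beta = betas[0]
    if len(perms) > 0:
        beta_null = betas[1:]
        p_values = np.array(
            [permutation_pvalue(beta[j], beta_null[:, j], "two_sided") for j in range(len(terms))]
        )
    else:  # n_perm=0: point estimates only, no inference
        p_values = np.full(len(terms), np.nan)

    if n_boot > 0:
        n_keep = y.size
        boots = np.empty((n_boot, len(terms)))
        for b in range(n_boot):
            idx = rng.integers(0, n_keep, n_keep)
            boots[b] = np.linalg.lstsq(X[idx], y[idx], rcond=None)[0]
        std_errors = boots.std(axis=0, ddof=1)
    else:
        std_errors = np.full(len(terms), np.nan)

    is_intercept = np.array([t == "Intercept" for t in terms])
    passes_floor = np.abs(beta) > effect_floor
    significant = (p_values < alpha) & (passes_floor | is_intercept)
    floor_suppressed = (p_values < alpha) & ~passes_floor & ~is_intercept

    return ModelFitTable(
        metric=metric.metric,
        model_kind=kind,
        terms=terms,
        estimates=beta,
        std_errors=std_errors,
        p_values=p_values,
        significant=significant,
        floor_suppressed=floor_suppressed,
        n_used=int(keep.sum()),
        n_dropped=int((~keep).sum()),
        n_perm=len(perms),
        n_boot=n_boot,
        alpha=alpha,
        effect_floor=effect_floor,
        seed=seed,
    )


def metric_attribute_report(
    agonistic: InteractionMatrix,
    grooming: InteractionMatrix,
    attrs: AttributeTable,
    n_perm: int | str = 10_000,
    n_boot: int = 1_000,
    alpha: float = 0.05,
    effect_floor: float = 0.009,
    seed: int | None = None,
) -> dict[tuple[str, str, str], ModelFitTable]:
    """The full individual-level battery: 2 networks x 5 metrics x 2 kinds.

    Returns 20 tables keyed by ``(network, metric, model_kind)``.  Each
    table gets its own seed derived from the master seed and its key, so
    adding tables never perturbs existing ones.
    """
    attrs.check_covers(agonistic)
    attrs.check_covers(grooming)
    report: dict[tuple[str, str, str], ModelFitTable] = {}
    for net_name, matrix in (("agonistic", agonistic), ("allogrooming", grooming)):
        net_metrics = all_metrics(matrix.reorder(attrs.ids))
        for metric_name, mv in net_metrics.items():
            for kind in ("main_effects", "gender_interaction"):
                sub_seed = (
                    derive_seed(seed, f"model|{net_name}|{metric_name}|{kind}")
                    if seed is not None
                    else None
                )
                report[(net_name, metric_name, kind)] = fit_attribute_model(
                    mv,
                    attrs,
                    kind=kind,
                    n_perm=n_perm,
                    n_boot=n_boot,
                    alpha=alpha,
                    effect_floor=effect_floor,
                    seed=sub_seed,
                )
    return report
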
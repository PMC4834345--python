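"""Simulation-based validation harnesses.

Two reusable loops sit behind both the test suite and preset tuning:

* :func:`direction_recovery_checks` — does one simulated troop, analyzed
  by the full protocol, reproduce the qualitative sign structure of the
  headline findings (female grooming activity, female age decline, rank
  protection from received aggression, rank attraction of grooming
  toward high-ranking females, gender and age homophily)?
* :func:`null_battery` — on a troop with *no* planted effects, which
  coefficient tests and homophily tests reject at ``alpha``?  Running
  this over many troops estimates the type-I error of every test in the
  protocol.

Both analyze the troop exactly as the pipeline would: hierarchy ranks
are re-estimated from the generated agonistic matrix via David's Score,
never taken from the latent truth.
"""

from __future__ import annotations

import numpy as np

from ._seeding import derive_seed
from .dominance import dominance_from_matrix
from .homophily import categorical_homophily_test, moran_test
from .io_core import AttributeTable, InteractionMatrix
from .metrics import all_metrics
from .perm_inference import fit_attribute_model, permute_node_labels
from .synthetic_data import GeneratorConfig, generate_dataset, generate_null_dataset


def _analyzed_attrs(agonistic: InteractionMatrix, attrs: AttributeTable) -> AttributeTable:
    ranks = dominance_from_matrix(agonistic).rank_series
    return attrs.with_hierarchy(ranks)


def direction_recovery_checks(
    seed: int, cfg: GeneratorConfig | None = None, n_perm_hom: int = 200
) -> dict[str, bool]:
    """Sign-structure checks for one field-study synthetic troop.

    Coefficient checks compare the OLS point-estimate sign with the
    planted direction; homophily checks additionally require permutation
    significance at 0.05.  Returns a dict of named booleans.
    """
    cfg = cfg or GeneratorConfig()
    attrs, ago, gro, _ = generate_dataset(cfg, seed)
    attrs = _analyzed_attrs(ago, attrs)
    mago = all_metrics(ago)
    mgro = all_metrics(gro)

    def est(metrics, name, kind, term):
        t = fit_attribute_model(metrics[name], attrs, kind, n_perm=0, n_boot=0)
        return t.estimate(term)

    checks: dict[str, bool] = {}
    for met in ("degree", "indegree", "outdegree"):
        checks[f"grooming_{met}_female_positive"] = (
            est(mgro, met, "main_effects", "Gender") > 0
        )
    checks["grooming_degree_female_age_negative"] = (
        est(mgro, "degree", "gender_interaction", "Females*Age") < 0
    )
    checks["agonistic_degree_female_age_negative"] = (
        est(mago, "degree", "gender_interaction", "Females*Age") < 0
    )
    checks["agonistic_indegree_rank_negative_males"] = (
        est(mago, "indegree", "gender_interaction", "Males*Hierarchy") < 0
    )
    checks["agonistic_indegree_rank_negative_females"] = (
        est(mago, "indegree", "gender_interaction", "Females*Hierarchy") < 0
    )
    checks["grooming_indegree_female_rank_positive"] = (
        est(mgro, "indegree", "gender_interaction", "Females*Hierarchy") > 0
    )

    for net_name, matrix in (("agonistic", ago), ("grooming", gro)):
        hseed = derive_seed(seed, f"recovery|{net_name}")
        g = categorical_homophily_test(matrix, attrs, "gender", n_perm_hom, hseed)
        checks[f"{net_name}_gender_homophily"] = (g.statistic < 0) and (g.p_value < 0.05)
        a = moran_test(matrix, attrs["age"].to_numpy(), "age", n_perm_hom, hseed + 1)
        checks[f"{net_name}_age_homophily"] = (a.statistic > 0) and (a.p_value < 0.05)
    return checks


def direction_recovery_rate(
    n_seeds: int = 100, base_seed: int = 0, cfg: GeneratorConfig | None = None
) -> tuple[float, dict[str, float]]:
    """Fraction of seeds recovering the full sign structure, and per-check rates."""
    per_check: dict[str, int] = {}
    all_ok = 0
    for k in range(n_seeds):
        checks = direction_recovery_checks(derive_seed(base_seed, f"rec{k}"), cfg)
        all_ok += all(checks.values())
        for name, ok in checks.items():
            per_check[name] = per_check.get(name, 0) + ok
    return all_ok / n_seeds, {k: v / n_seeds for k, v in per_check.items()}


def null_battery(
    seed: int,
    cfg: GeneratorConfig | None = None,
    n_perm: int = 200,
    alpha: float = 0.05,
) -> dict[str, bool]:
    """Rejection indicators for every test on one zero-effect troop.

    Covers all slope coefficients (intercepts excluded) of both model
    kinds for all 5 metrics on both networks, plus the pooled homophily
    battery (gender difference of means; Moran's I for age, matriline
    and hierarchy) on both networks.  The effect floor is not applied:
    calibration concerns the permutation test itself.

    The global null is imposed by one node-label permutation of the
    analyzed attribute table (hierarchy included) before testing.  This
    matters because the hierarchy covariate is estimated from the same
    agonistic matrix as the metrics: David's Score mechanically couples
    rank to received aggression even with no planted effect, so without
    the pre-permutation the Hierarchy tests would (correctly) reject the
    literal independence null far above alpha.
    """
    attrs, ago, gro = generate_null_dataset(cfg, seed)
    attrs = _analyzed_attrs(ago, attrs)
    rng = np.random.default_rng(derive_seed(seed, "global_null"))
    attrs = permute_node_labels(attrs, rng)
    out: dict[str, bool] = {}
    degenerate: dict[str, bool] = {}
    for net_name, matrix in (("agonistic", ago), ("grooming", gro)):
        metrics = all_metrics(matrix)
        for met_name, mv in metrics.items():
            # a constant metric (e.g. clustering = 1 on a complete null
            # network) gives p = 1 under the tie convention: the test is
            # conservative, not miscalibrated, and callers should judge
            # its rejection rate accordingly
            is_const = bool(np.ptp(mv.values) == 0)
            for kind in ("main_effects", "gender_interaction"):
                t = fit_attribute_model(
                    mv,
                    attrs,
                    kind,
                    n_perm=n_perm,
                    n_boot=0,
                    alpha=alpha,
                    effect_floor=0.0,
                    seed=derive_seed(seed, f"null|{net_name}|{met_name}|{kind}"),
                )
                for term, p in zip(t.terms, t.p_values):
                    if term != "Intercept":
                        name = f"coef|{net_name}|{met_name}|{kind}|{term}"
                        out[name] = p < alpha
                        degenerate[name] = is_const
        hseed = derive_seed(seed, f"nullhom|{net_name}")
        g = categorical_homophily_test(matrix, attrs, "gender", n_perm, hseed)
        out[f"hom|{net_name}|gender"] = g.p_value < alpha
        degenerate[f"hom|{net_name}|gender"] = False
        for attr in ("age", "matriline", "hierarchy"):
            col = attrs[attr]
            valid = col.notna()
            ids = [i for i, ok in zip(attrs.ids, valid) if ok]
            mm = matrix.induced(ids)
            r = moran_test(mm, col[valid].to_numpy(), attr, n_perm, derive_seed(hseed, attr))
            out[f"hom|{net_name}|{attr}"] = r.p_value < alpha
            degenerate[f"hom|{net_name}|{attr}"] = False
    return out, degenerate


def null_rejection_rates(
    n_troops: int = 1000,
    base_seed: int = 0,
    cfg: GeneratorConfig | None = None,
    n_perm: int = 200,
    alpha: float = 0.05,
) -> tuple[dict[str, float], dict[str, float]]:
    """Per-test rejection rates over many zero-effect troops.

    Returns ``(rates, degenerate_fraction)`` where the second dict gives,
    per test, the fraction of troops on which the tested statistic was
    constant (zero resolution; see :func:`null_battery`).
    """
    totals: dict[str, int] = {}
    degen_totals: dict[str, int] = {}
    for k in range(n_troops):
        rejections, degenerate = null_battery(
            derive_seed(base_seed, f"null{k}"), cfg, n_perm, alpha
        )
        for name, rej in rejections.items():
            totals[name] = totals.get(name, 0) + rej
            degen_totals[name] = degen_totals.get(name, 0) + degenerate[name]
    return (
        {k: v / n_troops for k, v in totals.items()},
        {k: v / n_troops for k, v in degen_totals.items()},
    )
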
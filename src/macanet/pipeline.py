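"""End-to-end protocol orchestration.

The fixed sequence is:

1. **Dominance** — David's Score on the agonistic matrix yields the
   ordinal hierarchy covariate, unless the attribute table already
   supplies one (then the stage is skipped and provenance records
   "user-supplied ranks").
2. **Metrics** — the five weighted metrics on both networks.
3. **Individual level** — main-effects and gender-interaction models for
   all 10 network x metric pairs (20 tables).
4. **Group level** — the homophily battery: gender (difference of
   means), age, matriline and hierarchy (Moran's I), each pooled and
   per gender (24 rows).

No link filtering happens anywhere: the total weight entering the
metrics equals the total weight read from disk.  All randomness derives
from one master seed via stable per-stage splitting, so two runs with
the same seed produce byte-identical reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._seeding import derive_seed
from .dominance import DominanceResult, dominance_from_matrix
from .errors import PipelineError
from .homophily import HomophilyResult, homophily_frame, subgroup_tests
from .io_core import (
    AttributeTable,
    InteractionMatrix,
    export_network,
    read_attribute_table,
    read_interaction_matrix,
)
from .metrics import metrics_frame
from .perm_inference import ModelFitTable, metric_attribute_report

HOMOPHILY_ATTRIBUTES = ("gender", "age", "matriline", "hierarchy")

# file-name stems follow the protocol's four-table report layout
_TABLE_STEM = {
    ("agonistic", "main_effects"): "table1_agonistic_main",
    ("agonistic", "gender_interaction"): "table2_agonistic_interaction",
    ("allogrooming", "main_effects"): "table3_allogrooming_main",
    ("allogrooming", "gender_interaction"): "table4_allogrooming_interaction",
}


@dataclass
class ProtocolSettings:
    n_perm: int = 10_000
    n_boot: int = 1_000
    alpha: float = 0.05
    effect_floor: float = 0.009
    seed: int = 0
    dyadic_correction: str = "raw"  # "raw" | "dij"


@dataclass
class ProtocolReport:
    dominance: DominanceResult | None
    hierarchy_source: str
    metrics: pd.DataFrame
    model_tables: dict[tuple[str, str, str], ModelFitTable]
    homophily: list[HomophilyResult]
    attrs: AttributeTable
    agonistic: InteractionMatrix
    grooming: InteractionMatrix
    metadata: dict = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return wrap


def run_protocol(
    agonistic: InteractionMatrix | str | Path,
    grooming: InteractionMatrix | str | Path,
    attrs: AttributeTable | str | Path,
    settings: ProtocolSettings | None = None,
) -> ProtocolReport:
    """Run the full multilevel protocol and return the in-memory report."""
    s = settings or ProtocolSettings()
    if not isinstance(agonistic, InteractionMatrix):
        agonistic = _stage("read_agonistic")(read_interaction_matrix, agonistic, "agonistic")
    if not isinstance(grooming, InteractionMatrix):
        grooming = _stage("read_grooming")(read_interaction_matrix, grooming, "allogrooming")
    if not isinstance(attrs, AttributeTable):
        attrs = _stage("read_attributes")(read_attribute_table, attrs)
    try:
        attrs.check_covers(agonistic)
        attrs.check_covers(grooming)
    except Exception as exc:
        raise PipelineError(f"stage 'validate' failed: {exc}") from exc

    # stage 1: hierarchy covariate
    if attrs.has_hierarchy:
        dominance = None
        hierarchy_source = "user-supplied ranks"
    else:
        dominance = _stage("dominance")(
            dominance_from_matrix, agonistic, s.dyadic_correction == "dij"
        )
        attrs = attrs.with_hierarchy(dominance.rank_series)
        hierarchy_source = f"davids_score[{s.dyadic_correction}]"

    # stage 2: metrics on both networks
    metrics = pd.concat(
        [
            _stage("metrics")(metrics_frame, agonistic).assign(network="agonistic"),
            _stage("metrics")(metrics_frame, grooming).assign(network="allogrooming"),
        ],
        ignore_index=True,
    )[["network", "id", "metric", "value"]]

    # stage 3: individual-level models (20 tables)
    model_tables = _stage("individual_level")(
        metric_attribute_report,
        agonistic,
        grooming,
        attrs,
        n_perm=s.n_perm,
        n_boot=s.n_boot,
        alpha=s.alpha,
        effect_floor=s.effect_floor,
        seed=derive_seed(s.seed, "individual_level"),
    )

    # stage 4: homophily battery (24 rows)
    homophily: list[HomophilyResult] = []
    for net_name, matrix in (("agonistic", agonistic), ("allogrooming", grooming)):
        for attribute in HOMOPHILY_ATTRIBUTES:
            results = _stage("group_level")(
                subgroup_tests,
                matrix,
                attrs,
                attribute,
                None,
                s.n_perm,
                derive_seed(s.seed, f"group_level|{net_name}"),
            )
            for r in results:
                r.network = net_name
            homophily.extend(results)

    dropped = {
        f"{key[0]}/{key[1]}/{key[2]}": t.n_dropped for key, t in model_tables.items()
    }
    metadata = {
        "macanet_version": __version__,
        "schema_version": 1,
        "seed": s.seed,
        "n_perm": s.n_perm,
        "n_boot": s.n_boot,
        "alpha": s.alpha,
        "effect_floor": s.effect_floor,
        "dyadic_correction": s.dyadic_correction,
        "hierarchy_source": hierarchy_source,
        "n_individuals": attrs.n,
        "total_weight": {
            "agonistic": agonistic.total_weight,
            "allogrooming": grooming.total_weight,
        },
        "dropped_rows_per_model": dropped,
        "n_model_tables": len(model_tables),
        "n_homophily_rows": len(homophily),
    }
    return ProtocolReport(
        dominance=dominance,
        hierarchy_source=hierarchy_source,
        metrics=metrics,
        model_tables=model_tables,
        homophily=homophily,
        attrs=attrs,
        agonistic=agonistic,
        grooming=grooming,
        metadata=metadata,
    )


def write_report(report: ProtocolReport, outdir: str | Path) -> list[Path]:
    """Serialize the report: 20 model CSVs, homophily, dominance, metrics,
    run metadata and the two GraphML exports.  Deterministic content."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for (net, metric, kind), table in sorted(report.model_tables.items()):
        stem = _TABLE_STEM[(net, kind)]
        path = outdir / f"{stem}_{metric}.csv"
        table.to_frame().to_csv(path, index=False)
        written.append(path)

    hom = homophily_frame(report.homophily)
    hom_path = outdir / "homophily.csv"
    hom.to_csv(hom_path, index=False)
    written.append(hom_path)

    dom_path = outdir / "dominance.csv"
    if report.dominance is not None:
        report.dominance.to_frame().to_csv(dom_path)
    else:
        report.attrs.data[["hierarchy"]].to_csv(dom_path, index_label="id")
    written.append(dom_path)

    met_path = outdir / "metrics.csv"
    report.metrics.to_csv(met_path, index=False)
    written.append(met_path)

    meta_path = outdir / "run_metadata.json"
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(report.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(meta_path)

    for name, matrix in (
        ("agonistic", report.agonistic),
        ("allogrooming", report.grooming),
    ):
        gpath = outdir / f"network_{name}.graphml"
        export_network(matrix, report.attrs, gpath, "graphml")
        written.append(gpath)
    return written

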
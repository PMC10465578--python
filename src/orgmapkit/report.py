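"""Benchmark reports comparing quality metrics across experiments."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError
from .io import ComplexCatalog, SessionArchive
from .preprocessing import MapCollection, collection_from_session
from .quality import (
    depth_summary,
    inter_map_scatter,
    intra_complex_scatter,
    joint_pca,
    profiled_overlap,
)


@dataclass
class BenchmarkReport:
    """Per-experiment quality metrics on a shared protein space."""

    per_experiment: dict[str, dict]
    shared: dict
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_experiment": self.per_experiment,
            "shared": self.shared,
            "settings": self.settings,
        }


def run_benchmark(
    sessions: dict[str, SessionArchive],
    catalog: ComplexCatalog | None = None,
    quantile: float = 0.70,
    settings: dict | None = None,
) -> BenchmarkReport:
    """Compute comparable quality metrics for one or more sessions.

    Sessions must share one fraction scheme.  Metrics that compare profiles
    across experiments (joint PCA, intra-complex scatter, shared-space
    reproducibility) run on the proteins profiled in every experiment;
    sessions are matched on their stored protein ids.
    """
    if not sessions:
        raise AnalysisError("benchmark needs at least one session")
    collections: dict[str, MapCollection] = {
        name: collection_from_session(archive)
        for name, archive in sessions.items()
    }
    schemes = {tuple(c.design.fractions) for c in collections.values()}
    if len(schemes) > 1:
        raise AnalysisError(f"incompatible fraction schemes: {schemes}")

    shared_ids = None
    for coll in collections.values():
        ids = coll.complete_ids()
        shared_ids = ids if shared_ids is None else shared_ids.intersection(ids)
    if len(shared_ids) == 0:
        warnings.warn(
            "no protein is profiled in every experiment; shared-space "
            "metrics are empty",
            stacklevel=2,
        )

    per_experiment: dict[str, dict] = {}
    for name, coll in collections.items():
        depth = depth_summary(coll)
        entry: dict = {
            "depth": {
                "per_map": {
                    f"{c}/{r}": int(v)
                    for (c, r), v in depth.per_map["profiled"].items()
                },
                "per_condition": {
                    c: {
                        "in_any": int(row["in_any"]),
                        "in_all": int(row["in_all"]),
                    }
                    for c, row in depth.per_condition.iterrows()
                },
            }
        }
        scatter = {}
        for cond in coll.conditions:
            if len(coll.by_condition(cond)) >= 2:
                res = inter_map_scatter(
                    coll,
                    condition=cond,
                    quantile=quantile,
                    restrict_to=shared_ids if len(shared_ids) else None,
                )
                scatter[cond] = (
                    float(res.quantile_value) if len(res.scatter) else None
                )
        entry["inter_map_scatter_quantile"] = scatter
        per_experiment[name] = entry

    shared: dict = {"n_shared_profiled": int(len(shared_ids))}
    overlap = profiled_overlap(collections)
    shared["overlap_counts"] = {
        "|".join(k): len(v) for k, v in sorted(overlap.items())
    }
    if len(shared_ids):
        pca = joint_pca(list(collections.values()))
        shared["pca_explained_variance_ratio"] = [
            float(v) for v in pca.explained_variance_ratio
        ]
    if catalog is not None and len(shared_ids):
        result = intra_complex_scatter(collections, catalog)
        if len(result.per_complex):
            shared["intra_complex_scatter_median"] = {
                str(col): float(np.nanmedian(result.per_complex[col]))
                for col in result.per_complex.columns
            }
            shared["complexes_used"] = result.complexes_used
    return BenchmarkReport(
        per_experiment=per_experiment,
        shared=shared,
        settings=dict(settings or {"quantile": quantile}),
    )


def report_to_frame(report: BenchmarkReport) -> pd.DataFrame:
    """Flatten a benchmark report into a tidy metric table."""
    rows = []
    for name, entry in report.per_experiment.items():
        for map_name, count in entry["depth"]["per_map"].items():
            rows.append((name, f"profiled:{map_name}", count))
        for cond, counts in entry["depth"]["per_condition"].items():
            rows.append((name, f"in_any:{cond}", counts["in_any"]))
            rows.append((name, f"in_all:{cond}", counts["in_all"]))
        for cond, value in entry["inter_map_scatter_quantile"].items():
            rows.append((name, f"scatter_q:{cond}", value))
    return pd.DataFrame(rows, columns=["experiment", "metric", "value"])
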
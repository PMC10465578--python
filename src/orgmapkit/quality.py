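"""Map quality readouts: depth, joint PCA, precision and reproducibility.

Two scatter metrics gauge map quality.  Intra-complex scatter exploits the
fact that subunits of a stable complex co-fractionate with near-identical
profiles: the Manhattan (L1) distance of each subunit profile to the
element-wise median profile of its complex measures within-map quantification
precision.  Inter-map scatter is the average L1 distance of a protein's
replicate profiles to their mean profile and measures between-map
reproducibility.  Joint PCA embeds all compared maps in one shared space:
profiles are centered and scaled to unit variance per fraction across the
concatenation of all maps, then decomposed together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .errors import AnalysisError
from .io import ComplexCatalog
from .preprocessing import MapCollection, ProfileSet


@dataclass
class DepthSummary:
    """Identified/profiled counts per map and coverage counts per condition."""

    per_map: pd.DataFrame  # index (condition, replicate); identified, profiled
    per_condition: pd.DataFrame  # index condition; in_any, in_all

    def __post_init__(self) -> None:
        bad = self.per_map["profiled"] > self.per_map["identified"]
        if bad.any():
            raise AnalysisError("profiled count exceeds identified count")


def depth_summary(
    collection: MapCollection,
    raw_counts: dict[tuple[str, int], int] | None = None,
) -> DepthSummary:
    """Count identified (pre-filter) and profiled (post-filter) proteins.

    ``raw_counts`` supplies per-map identified counts; when absent, the
    profiled count stands in (the raw table is not retained in a collection).
    """
    rows = []
    for ps in collection.profile_sets:
        profiled = len(ps)
        identified = (
            raw_counts.get((ps.condition, ps.replicate), profiled)
            if raw_counts
            else profiled
        )
        rows.append((ps.condition, ps.replicate, identified, profiled))
    per_map = pd.DataFrame(
        rows, columns=["condition", "replicate", "identified", "profiled"]
    ).set_index(["condition", "replicate"])

    cond_rows = []
    for cond in collection.conditions:
        sets = collection.by_condition(cond)
        any_ids: set = set()
        for ps in sets:
            any_ids |= set(ps.ids)
        all_ids = set(collection.complete_ids(cond))
        cond_rows.append((cond, len(any_ids), len(all_ids)))
    per_condition = pd.DataFrame(
        cond_rows, columns=["condition", "in_any", "in_all"]
    ).set_index("condition")
    return DepthSummary(per_map=per_map, per_condition=per_condition)


def profiled_overlap(collections: dict[str, MapCollection]) -> dict[tuple, set]:
    """Overlap sets of fully profiled proteins between experiments.

    Returns, for every non-empty subset of experiment names, the set of
    proteins profiled in exactly those experiments (an upset-plot layout).
    """
    sets = {name: set(c.complete_ids()) for name, c in collections.items()}
    names = sorted(sets)
    universe = set().union(*sets.values()) if sets else set()
    out: dict[tuple, set] = {}
    for pid in universe:
        key = tuple(n for n in names if pid in sets[n])
        out.setdefault(key, set()).add(pid)
    return out


@dataclass
class PcaResult:
    """Shared-space PCA of one or more map collections."""

    scores: pd.DataFrame  # index (experiment, condition, replicate, protein)
    loadings: pd.DataFrame  # fraction x component
    explained_variance_ratio: np.ndarray

    def map_scores(self, experiment, condition, replicate) -> pd.DataFrame:
        return self.scores.loc[(experiment, condition, replicate)]

    def variance_scaled(self) -> pd.DataFrame:
        """Scores scaled by per-component variance share.

        Distances in this scaling reflect true displacement in profile space,
        which matters when reading translocations off a PCA plot.
        """
        return self.scores * self.explained_variance_ratio


def _all_profile_sets(
    collections,
) -> list[tuple[str, ProfileSet]]:
    if isinstance(collections, MapCollection):
        collections = {"experiment": collections}
    if isinstance(collections, (list, tuple)):
        collections = {f"experiment_{i + 1}": c for i, c in enumerate(collections)}
    return [(name, ps) for name, c in collections.items() for ps in c.profile_sets]


def _common_ids(collections) -> pd.Index:
    pairs = _all_profile_sets(collections)
    ids = pairs[0][1].ids
    for _, ps in pairs[1:]:
        ids = ids.intersection(ps.ids)
    return ids


def joint_pca(collections, k: int = 3) -> PcaResult:
    """Joint PCA of all maps after per-fraction standardization.

    Only proteins complete in every included map enter.  Standardization
    statistics are computed on the concatenated matrix of all maps, so every
    map is projected into one shared space.
    """
    pairs = _all_profile_sets(collections)
    ids = _common_ids(collections)
    if len(ids) == 0:
        raise AnalysisError("no protein is complete in all included maps")
    fractions = pairs[0][1].fractions

    blocks, index_tuples = [], []
    for name, ps in pairs:
        blocks.append(ps.profiles.loc[ids].to_numpy())
        index_tuples.extend(
            (name, ps.condition, ps.replicate, pid) for pid in ids
        )
    matrix = np.vstack(blocks)

    mean = matrix.mean(axis=0)
    std = matrix.std(axis=0)
    for j, frac in enumerate(fractions):
        if std[j] == 0:
            raise AnalysisError(f"fraction {frac!r} has zero variance")
    standardized = (matrix - mean) / std

    k = min(k, len(fractions))
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(standardized)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(
            scores,
            index=pd.MultiIndex.from_tuples(
                index_tuples,
                names=["experiment", "condition", "replicate", "protein_id"],
            ),
            columns=comp_names,
        ),
        loadings=pd.DataFrame(
            pca.components_.T, index=fractions, columns=comp_names
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class ComplexScatterResult:
    """Normalized within-complex profile scatter per (complex, map)."""

    per_complex: pd.DataFrame  # index complex, columns map labels
    per_subunit: pd.DataFrame  # columns: complex, protein_id, map, norm distance
    complexes_used: list[str] = field(default_factory=list)
    zero_baseline_proteins: list[str] = field(default_factory=list)


def intra_complex_scatter(
    collections,
    catalog: ComplexCatalog,
    min_subunits: int = 5,
    reference: str | None = None,
) -> ComplexScatterResult:
    """Within-map scatter of complex subunit profiles (precision metric).

    Per subunit and map: L1 distance to the element-wise median profile of
    its complex in that map.  Per protein the distances are divided by the
    protein's median distance across all experiments (or the distance in a
    chosen ``reference`` experiment), then aggregated per (complex, map) by
    median over subunits.  Complexes with fewer than ``min_subunits``
    subunits covered in every map are excluded.  A protein whose distance is
    0 in all experiments normalizes to 1 (0/0 := 1) and is flagged.
    """
    pairs = _all_profile_sets(collections)
    common = _common_ids(collections)
    map_labels = [
        f"{name}:{ps.condition}/{ps.replicate}" for name, ps in pairs
    ]

    rows = []
    used = []
    zero_baseline: set = set()
    for cname in sorted(catalog.members):
        members = [m for m in catalog.members[cname] if m in common]
        if len(members) < min_subunits:
            continue
        used.append(cname)
        # distances: subunit x map
        dist = np.empty((len(members), len(pairs)))
        for j, (_, ps) in enumerate(pairs):
            sub = ps.profiles.loc[members].to_numpy()
            median_profile = np.median(sub, axis=0)
            dist[:, j] = np.abs(sub - median_profile).sum(axis=1)
        if reference is None:
            baseline = np.median(dist, axis=1)
        else:
            j_ref = map_labels.index(reference)
            baseline = dist[:, j_ref]
        zero = baseline == 0
        zero_baseline.update(np.asarray(members)[zero & (dist == 0).all(axis=1)])
        norm = np.empty_like(dist)
        norm[~zero] = dist[~zero] / baseline[~zero, None]
        norm[zero] = np.where(dist[zero] == 0, 1.0, np.inf)
        for i, pid in enumerate(members):
            for j, label in enumerate(map_labels):
                rows.append((cname, pid, label, norm[i, j]))

    if not used:
        warnings.warn(
            "no complex has enough fully covered subunits", stacklevel=2
        )
        return ComplexScatterResult(
            per_complex=pd.DataFrame(),
            per_subunit=pd.DataFrame(
                columns=["complex", "protein_id", "map", "normalized_distance"]
            ),
        )

    per_subunit = pd.DataFrame(
        rows, columns=["complex", "protein_id", "map", "normalized_distance"]
    )
    per_complex = (
        per_subunit.pivot_table(
            index="complex",
            columns="map",
            values="normalized_distance",
            aggfunc="median",
        )
        .loc[used, map_labels]
    )
    return ComplexScatterResult(
        per_complex=per_complex,
        per_subunit=per_subunit,
        complexes_used=used,
        zero_baseline_proteins=sorted(zero_baseline),
    )


@dataclass
class ReproducibilityResult:
    """Per-protein inter-replicate profile scatter."""

    scatter: pd.Series  # index protein id
    quantile: float
    quantile_value: float

    def at_quantile(self, q: float) -> float:
        return float(self.scatter.quantile(q))


def inter_map_scatter(
    collection: MapCollection,
    condition: str | None = None,
    quantile: float = 0.70,
    common_only: bool = True,
    restrict_to=None,
) -> ReproducibilityResult:
    """Average L1 distance of replicate profiles to their mean profile.

    ``restrict_to`` limits the readout to proteins common to other compared
    maps; with ``common_only`` the intersection over this collection's
    replicates is used (proteins must be complete everywhere they enter).
    """
    if condition is None:
        if len(collection.conditions) != 1:
            raise AnalysisError("specify the condition for a multi-condition set")
        condition = collection.conditions[0]
    sets = collection.by_condition(condition)
    if len(sets) < 2:
        raise AnalysisError("inter-map scatter needs at least two replicates")

    ids = collection.complete_ids(condition)
    if not common_only:
        # still requires completeness within this condition's replicates
        pass
    if restrict_to is not None:
        ids = ids.intersection(pd.Index(restrict_to))

    stack = np.stack([ps.profiles.loc[ids].to_numpy() for ps in sets])
    mean = stack.mean(axis=0)
    scatter = np.abs(stack - mean).sum(axis=2).mean(axis=0)
    series = pd.Series(scatter, index=ids, name="scatter")
    return ReproducibilityResult(
        scatter=series,
        quantile=quantile,
        quantile_value=float(series.quantile(quantile)),
    )
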
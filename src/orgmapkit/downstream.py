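"""Downstream characterization of significant movers.

Hierarchical clustering groups delta profiles into coherent shift patterns
(complete linkage; distance = 1 - Pearson r, so anti-correlated — i.e.
biologically opposite — shifts separate).  Clusters are labeled by
annotation-term enrichment (one-sided Fisher exact test against the full
list of transitioning proteins, Benjamini-Hochberg corrected).  A targeted
correlation analysis detects subtle but coherent cycling behaviour: the full
pairwise correlation matrix of delta profiles of a curated candidate set is
itself clustered (Euclidean distance between correlation rows), which groups
proteins by their phenotype similarity to all other candidates rather than
by the raw profiles.  Finally, endosomal shift magnitudes are scored as the
change in correlation with the mean endosomal marker profile, robustly
z-scored (median / 1.4826*MAD), and binned into magnitude classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError
from .preprocessing import MapCollection

MAD_SCALE = 1.4826  # MAD -> SD under normality

SHIFT_BINS = (
    (4.0, "very large"),
    (3.0, "large"),
    (2.0, "medium"),
    (1.0, "small"),
    (0.5, "very small"),
)


def shift_magnitude_class(z: float) -> str:
    for cut, label in SHIFT_BINS:
        if z >= cut:
            return label
    return "no relevant shift"


@dataclass
class ShiftClustering:
    """Hierarchical clustering of shift profiles."""

    labels: pd.Series  # protein id -> flat cluster label
    linkage_matrix: np.ndarray
    method: str
    metric: str
    threshold: float

    @property
    def clusters(self) -> dict[int, list[str]]:
        return {
            int(c): sorted(self.labels.index[self.labels == c])
            for c in sorted(self.labels.unique())
        }


def _check_nonconstant(profiles: pd.DataFrame) -> None:
    constant = profiles.std(axis=1, ddof=0) == 0
    if constant.any():
        raise AnalysisError(
            "constant delta profiles have undefined correlations: "
            f"{sorted(profiles.index[constant])}"
        )


def cluster_delta_profiles(
    deltas: pd.DataFrame, threshold: float
) -> ShiftClustering:
    """Complete-linkage clustering of mean delta profiles, 1 - r distance.

    ``threshold`` cuts the dendrogram into flat clusters; it has no default
    because visually apparent shift groups dictate the choice.
    """
    if len(deltas) < 2:
        raise AnalysisError("clustering needs at least two proteins")
    _check_nonconstant(deltas)
    corr = np.corrcoef(deltas.to_numpy())
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # enforce exact symmetry
    Z = linkage(squareform(dist, checks=False), method="complete")
    flat = fcluster(Z, t=threshold, criterion="distance")
    return ShiftClustering(
        labels=pd.Series(flat, index=deltas.index, name="cluster"),
        linkage_matrix=Z,
        method="complete",
        metric="pearson",
        threshold=threshold,
    )


@dataclass
class EnrichmentResult:
    """Per (cluster, term) Fisher-exact enrichment against the background."""

    table: pd.DataFrame
    fdr: float

    def enriched(self) -> pd.DataFrame:
        return self.table[self.table["enriched"]]


def enrichment_test(
    clustering: ShiftClustering,
    annotations: dict[str, set],
    fdr: float = 0.10,
) -> EnrichmentResult:
    """One-sided Fisher exact enrichment of annotation terms per cluster.

    The background is the full set of clustered (transitioning) proteins.
    Terms annotating no background protein are skipped; clusters with no
    term passing the FDR cutoff simply remain unlabeled.
    """
    background = list(clustering.labels.index)
    n_bg = len(background)
    term_members: dict[str, set] = {}
    for pid in background:
        for term in annotations.get(pid, ()):
            term_members.setdefault(term, set()).add(pid)

    rows = []
    for cluster, members in clustering.clusters.items():
        member_set = set(members)
        n_cluster = len(member_set)
        if n_cluster == 0:
            continue
        for term in sorted(term_members):
            with_term = term_members[term]
            a = len(member_set & with_term)  # in cluster, has term
            b = n_cluster - a  # in cluster, no term
            c = len(with_term) - a  # rest of background, has term
            d = n_bg - n_cluster - c
            _, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append((cluster, term, a, b, c, d, p))

    table = pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "term",
            "in_cluster_with_term",
            "in_cluster_without_term",
            "background_with_term",
            "background_without_term",
            "p",
        ],
    )
    if len(table):
        _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
        table["q"] = q
        table["enriched"] = table["q"] < fdr
    else:
        table["q"] = []
        table["enriched"] = []
    return EnrichmentResult(table=table, fdr=fdr)


def cycling_cluster(
    deltas: pd.DataFrame, threshold: float
) -> tuple[ShiftClustering, pd.DataFrame]:
    """Cluster candidates by their rows of the delta-correlation matrix.

    Feature vector per protein = its row of pairwise Pearson correlations of
    delta profiles; Euclidean distance between rows, complete linkage.
    Returns the clustering and the (symmetric, unit-diagonal) correlation
    matrix.
    """
    if len(deltas) < 2:
        raise AnalysisError("clustering needs at least two proteins")
    _check_nonconstant(deltas)
    corr = np.corrcoef(deltas.to_numpy())
    corr = (corr + corr.T) / 2
    np.fill_diagonal(corr, 1.0)
    Z = linkage(corr, method="complete", metric="euclidean")
    flat = fcluster(Z, t=threshold, criterion="distance")
    matrix = pd.DataFrame(corr, index=deltas.index, columns=deltas.index)
    return (
        ShiftClustering(
            labels=pd.Series(flat, index=deltas.index, name="cluster"),
            linkage_matrix=Z,
            method="complete",
            metric="euclidean-on-correlations",
            threshold=threshold,
        ),
        matrix,
    )


def robust_z(values: np.ndarray) -> np.ndarray:
    """(x - median) / (1.4826 * MAD)."""
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        raise AnalysisError("MAD is zero; shifts cannot be robustly z-scored")
    return (values - med) / (MAD_SCALE * mad)


def _row_correlations(profiles: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row with one reference vector."""
    pc = profiles - profiles.mean(axis=1, keepdims=True)
    rc = reference - reference.mean()
    denom = np.linalg.norm(pc, axis=1) * np.linalg.norm(rc)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, pc @ rc / denom, np.nan)


def endosomal_shift_scores(
    control: MapCollection,
    treated: MapCollection,
    endosome_marker_ids,
    ids=None,
) -> pd.DataFrame:
    """Magnitude of each protein's shift towards the endosomal profile.

    Per condition the mean endosomal profile is the element-wise mean of the
    marker proteins' replicate-mean profiles.  The shift is the condition-
    matched change in correlation, delta_corr = r(treated protein, treated
    endosomal mean) - r(control protein, control endosomal mean), robustly
    z-scored over all scored proteins and binned into magnitude classes.
    """
    cond_c = control.conditions[0]
    cond_t = treated.conditions[0]
    common = control.complete_ids(cond_c).intersection(
        treated.complete_ids(cond_t)
    )
    markers = pd.Index(endosome_marker_ids).intersection(common)
    if len(markers) < 2:
        raise AnalysisError(
            "need at least two endosome markers profiled in both conditions"
        )
    ids = common if ids is None else pd.Index(ids).intersection(common)

    mean_c = control.mean_profiles(cond_c, ids=ids)
    mean_t = treated.mean_profiles(cond_t, ids=ids)
    endo_c = control.mean_profiles(cond_c, ids=markers).to_numpy().mean(axis=0)
    endo_t = treated.mean_profiles(cond_t, ids=markers).to_numpy().mean(axis=0)

    r_control = _row_correlations(mean_c.to_numpy(), endo_c)
    r_treated = _row_correlations(mean_t.to_numpy(), endo_t)
    delta_corr = r_treated - r_control
    z = robust_z(delta_corr)
    return pd.DataFrame(
        {
            "r_control": r_control,
            "r_treated": r_treated,
            "delta_corr": delta_corr,
            "z": z,
            "magnitude_class": [shift_magnitude_class(v) for v in z],
        },
        index=ids,
    )
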
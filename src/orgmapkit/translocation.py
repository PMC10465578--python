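"""Movement-Reproducibility (MR) analysis of induced protein translocations.

A protein that changes subcellular localization between two conditions
changes its fractionation profile.  Per cognate replicate pair the delta
profile (treated minus control, both 0-1 normalized) is computed; deltas of
static proteins scatter around zero, movers stick out.  Each replicate's
delta cloud is subjected to a multivariate outlier test based on the robust
Mahalanobis distance (Minimum Covariance Determinant location/scatter,
default support fraction 0.75, median over 31 fits with different random
states).  Squared robust distances of null deltas follow a chi-squared
distribution, giving a per-replicate p-value; the three replicate p-values
are combined with Fisher's method, corrected across proteins by
Benjamini-Hochberg, and -log10 transformed into the Movement score
(M score; FDR < 5% corresponds to M > 1.3).  The Reproducibility score
(R score) is the median pairwise Pearson correlation of a protein's
replicate deltas.  A shift is called significant when M > 1.3, R > 0.75
and at least two replicate p-values are below 0.1.

Delta profiles are exactly zero-sum (difference of two compositions), so
their 6-dimensional scatter is singular.  By default deltas are projected
onto an orthonormal basis of the zero-sum subspace (a Helmert contrast) and
the chi-squared test uses F-1 degrees of freedom; a raw-F mode is available
for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import helmert
from scipy.stats import chi2
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ConfigurationError
from .preprocessing import MapCollection

P_FLOOR = 1e-300  # p-values of exactly 0 are clamped before logs


@dataclass(frozen=True)
class OutlierParams:
    """Settings of the robust Mahalanobis outlier test."""

    support_fraction: float = 0.75
    iterations: int = 31
    seed: int = 0
    df_policy: str = "zero_sum"  # or "raw"

    def __post_init__(self) -> None:
        if not 0.5 <= self.support_fraction <= 1.0:
            raise ConfigurationError("support_fraction must be in [0.5, 1]")
        if self.iterations < 1 or self.iterations % 2 == 0:
            raise ConfigurationError("iterations must be a positive odd number")
        if self.df_policy not in ("zero_sum", "raw"):
            raise ConfigurationError(f"unknown df policy {self.df_policy!r}")


@dataclass
class DeltaProfileSet:
    """Treated-minus-control delta profiles, one frame per replicate pair."""

    deltas: dict[int, pd.DataFrame]  # replicate -> protein x fraction
    fractions: list[str] = field(default_factory=list)

    @property
    def replicates(self) -> list[int]:
        return sorted(self.deltas)

    @property
    def ids(self) -> pd.Index:
        return self.deltas[self.replicates[0]].index

    def array(self) -> np.ndarray:
        """Shape (replicates, proteins, fractions)."""
        return np.stack(
            [self.deltas[r].to_numpy() for r in self.replicates]
        )


def _pairwise_cosine_min(stack: np.ndarray) -> np.ndarray:
    """Minimum pairwise cosine similarity across replicates, per protein.

    ``stack`` has shape (replicates, proteins, fractions).
    """
    norms = np.linalg.norm(stack, axis=2)
    n_rep = stack.shape[0]
    mins = np.full(stack.shape[1], np.inf)
    for i in range(n_rep):
        for j in range(i + 1, n_rep):
            dot = (stack[i] * stack[j]).sum(axis=1)
            denom = norms[i] * norms[j]
            with np.errstate(invalid="ignore", divide="ignore"):
                cos = np.where(denom > 0, dot / denom, np.nan)
            mins = np.fmin(mins, cos)
    return mins


def consistency_filter(
    control: MapCollection,
    treated: MapCollection,
    min_cosine: float = 0.9,
) -> pd.Index:
    """Drop proteins with poorly reproduced profiles within a condition.

    A protein is removed when the smallest cosine similarity between any two
    replicate profiles within either condition falls below ``min_cosine``
    (strictly; a minimum of exactly 0.9 is retained).
    """
    cond_c = control.conditions[0]
    cond_t = treated.conditions[0]
    ids = control.complete_ids(cond_c).intersection(treated.complete_ids(cond_t))
    keep = np.ones(len(ids), dtype=bool)
    for coll, cond in ((control, cond_c), (treated, cond_t)):
        sets = coll.by_condition(cond)
        stack = np.stack([ps.profiles.loc[ids].to_numpy() for ps in sets])
        mins = _pairwise_cosine_min(stack)
        keep &= ~(mins < min_cosine)  # NaN minima are retained conservatively
    return ids[keep]


def compute_delta_profiles(
    control: MapCollection,
    treated: MapCollection,
    ids=None,
    pairing: dict[int, int] | None = None,
) -> DeltaProfileSet:
    """Delta profiles within each cognate (control, treated) replicate pair.

    ``pairing`` maps control replicate -> treated replicate; the default
    pairs matching replicate indices.
    """
    cond_c = control.conditions[0]
    cond_t = treated.conditions[0]
    reps_c = [ps.replicate for ps in control.by_condition(cond_c)]
    reps_t = [ps.replicate for ps in treated.by_condition(cond_t)]
    if pairing is None:
        if set(reps_c) != set(reps_t):
            raise AnalysisError(
                f"replicates {sorted(reps_c)} vs {sorted(reps_t)} cannot be "
                "paired by index; supply an explicit pairing"
            )
        pairing = {r: r for r in reps_c}
    for rc, rt in pairing.items():
        if rc not in reps_c or rt not in reps_t:
            raise AnalysisError(f"unpaired replicate in pairing ({rc}, {rt})")

    if ids is None:
        ids = control.complete_ids(cond_c).intersection(
            treated.complete_ids(cond_t)
        )
    ids = pd.Index(ids)
    deltas = {}
    for rc, rt in sorted(pairing.items()):
        c = control.get(cond_c, rc).profiles.loc[ids]
        t = treated.get(cond_t, rt).profiles.loc[ids]
        deltas[rc] = t - c.to_numpy()
    fractions = list(control.profile_sets[0].fractions)
    return DeltaProfileSet(deltas=deltas, fractions=fractions)


def _zero_sum_basis(n_fractions: int) -> np.ndarray:
    """Orthonormal (F-1) x F basis of the zero-sum subspace."""
    return helmert(n_fractions, full=False)


def _robust_squared_distances(
    Z: np.ndarray, params: OutlierParams
) -> np.ndarray:
    """Median squared robust Mahalanobis distance over MCD refits.

    With ``support_fraction == 1`` there is no trimming and the classical
    estimator (mean, ML covariance) is used directly.
    """
    n, p = Z.shape
    if n < p + 2:
        raise AnalysisError(
            f"need at least {p + 2} proteins for a {p}-dimensional outlier "
            f"test, got {n}"
        )
    if params.support_fraction >= 1.0:
        center = Z.mean(axis=0)
        cov = np.cov(Z, rowvar=False, ddof=0)
        try:
            precision = np.linalg.inv(cov)
        except np.linalg.LinAlgError as exc:
            raise AnalysisError(
                "singular scatter matrix; provide more proteins or project "
                "onto the zero-sum subspace (df_policy='zero_sum')"
            ) from exc
        diff = Z - center
        return np.einsum("ij,jk,ik->i", diff, precision, diff)

    all_d2 = np.empty((params.iterations, n))
    for it in range(params.iterations):
        mcd = MinCovDet(
            support_fraction=params.support_fraction,
            random_state=params.seed + it,
        )
        try:
            mcd.fit(Z)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise AnalysisError(
                "MCD scatter estimation failed (singular subset); provide "
                "more proteins or adjust the support fraction"
            ) from exc
        all_d2[it] = mcd.mahalanobis(Z)
    return np.median(all_d2, axis=0)


def replicate_outlier_pvalues(
    deltas: DeltaProfileSet, params: OutlierParams | None = None
) -> pd.DataFrame:
    """Per-protein, per-replicate outlier p-values from robust distances.

    Each replicate's deltas are projected onto the zero-sum subspace
    (default policy), MCD location/scatter is estimated, and the upper tail
    of chi2 with df = F-1 (or F in raw mode) converts the median squared
    robust distance into a p-value.
    """
    params = params or OutlierParams()
    F = len(deltas.fractions)
    if params.df_policy == "zero_sum":
        basis = _zero_sum_basis(F)
        df = F - 1
    else:
        basis = np.eye(F)
        df = F

    out = {}
    for rep in deltas.replicates:
        X = deltas.deltas[rep].to_numpy()
        Z = X @ basis.T
        d2 = _robust_squared_distances(Z, params)
        out[rep] = chi2.sf(d2, df)
    return pd.DataFrame(out, index=deltas.ids)


def combine_and_score(pvalues: pd.DataFrame) -> pd.DataFrame:
    """Fisher-combine replicate p-values, BH-adjust, derive the M score.

    X2 = -2 * sum(ln p) with 2k degrees of freedom; q-values by
    Benjamini-Hochberg across all tested proteins; M = -log10(q).
    """
    p = pvalues.to_numpy(dtype=float)
    if np.isnan(p).any():
        raise AnalysisError("replicate p-values contain missing entries")
    if (p == 0).any():
        import warnings

        warnings.warn("p-values of 0 clamped to 1e-300", stacklevel=2)
        p = np.maximum(p, P_FLOOR)
    k = p.shape[1]
    x2 = -2.0 * np.log(p).sum(axis=1)
    combined = chi2.sf(x2, 2 * k)
    combined = np.maximum(combined, P_FLOOR)
    _, q, _, _ = multipletests(combined, method="fdr_bh")
    q = np.maximum(q, P_FLOOR)
    return pd.DataFrame(
        {
            "fisher_x2": x2,
            "combined_p": combined,
            "q": q,
            "M": -np.log10(q),
        },
        index=pvalues.index,
    )


def reproducibility_score(deltas: DeltaProfileSet) -> pd.Series:
    """Median pairwise Pearson correlation of replicate deltas (R score).

    Proteins with a constant (zero-variance) delta in any replicate get a
    missing R.
    """
    stack = deltas.array()
    n_rep = stack.shape[0]
    if n_rep < 2:
        raise AnalysisError("the R score needs at least two replicates")
    centered = stack - stack.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centered, axis=2)
    corrs = []
    for i in range(n_rep):
        for j in range(i + 1, n_rep):
            denom = norms[i] * norms[j]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(
                    denom > 0,
                    (centered[i] * centered[j]).sum(axis=1) / denom,
                    np.nan,
                )
            corrs.append(r)
    r_matrix = np.stack(corrs)
    with np.errstate(invalid="ignore"):
        R = np.where(
            np.isnan(r_matrix).any(axis=0), np.nan, np.median(r_matrix, axis=0)
        )
    return pd.Series(R, index=deltas.ids, name="R")


def call_movers(
    records: pd.DataFrame,
    m_cut: float = 1.3,
    r_cut: float = 0.75,
    p_screen: float = 0.1,
    min_screen: int = 2,
) -> pd.DataFrame:
    """Flag significant, reproducible shifts and rank them by M score.

    Significance requires M > m_cut, R > r_cut and at least ``min_screen``
    replicate p-values below ``p_screen``.
    """
    p_cols = [c for c in records.columns if str(c).startswith("p")]
    n_small = (records[p_cols] < p_screen).sum(axis=1)
    significant = (
        (records["M"] > m_cut)
        & (records["R"] > r_cut)
        & (n_small >= min_screen)
    )
    out = records.copy()
    out["significant"] = significant.fillna(False)
    return out.sort_values("M", ascending=False)


def mr_analysis(
    control: MapCollection,
    treated: MapCollection,
    params: OutlierParams | None = None,
    min_cosine: float = 0.9,
    m_cut: float = 1.3,
    r_cut: float = 0.75,
    p_screen: float = 0.1,
    min_screen: int = 2,
    pairing: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Full MR pipeline: filter, deltas, outlier test, scores, calls.

    Returns one row per tested protein: p1..pk, combined_p, q, M, R,
    significant; sorted by M descending.
    """
    params = params or OutlierParams()
    ids = consistency_filter(control, treated, min_cosine=min_cosine)
    deltas = compute_delta_profiles(control, treated, ids=ids, pairing=pairing)
    pvals = replicate_outlier_pvalues(deltas, params)
    pvals.columns = [f"p{r}" for r in pvals.columns]
    scores = combine_and_score(pvals)
    R = reproducibility_score(deltas)
    records = pd.concat([pvals, scores, R], axis=1)
    return call_movers(
        records, m_cut=m_cut, r_cut=r_cut, p_screen=p_screen, min_screen=min_screen
    )
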
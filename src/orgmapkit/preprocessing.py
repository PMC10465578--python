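"""Per-map quality filters and normalization of abundance profiles.

A usable profile is complete after filtering and 0-1 normalized: each value
is divided by the profile's sum so the vector totals 1 (a compositional
profile).  For label-free data two stringency filters run first: intensities
must be present in at least ``min_consecutive`` consecutive fractions
(default 4 of 6), and the mean MS/MS count per fraction must reach
``min_mean_msms`` (default 2).  For SILAC data a ratio is kept if it rests
on at least three quantification events, or on two with ratio variability
below 30%; retained ratios are median-normalized per fraction, inverted
(heavy reference), and only complete profiles survive.

Fractions that were missing but passed the consecutive rule are set to 0
after normalization, so every retained profile is a complete numeric vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, ConfigurationError
from .io import ExperimentDesign, ProfileMatrix, RawQuantTable, SessionArchive

logger = logging.getLogger(__name__)


@dataclass
class ProfileSet:
    """Filtered, 0-1 normalized profiles of one replicate map.

    ``profiles`` is protein x fraction, rows sum to 1, all values >= 0.
    ``rejections`` maps dropped protein ids to the reason they failed.
    """

    condition: str
    replicate: int
    profiles: pd.DataFrame
    filters: list[str] = field(default_factory=list)
    rejections: dict[str, str] = field(default_factory=dict)

    @property
    def ids(self) -> pd.Index:
        return self.profiles.index

    @property
    def fractions(self) -> list[str]:
        return list(self.profiles.columns)

    def __len__(self) -> int:
        return len(self.profiles)


@dataclass
class MapCollection:
    """ProfileSets of one experiment sharing a single design."""

    design: ExperimentDesign
    profile_sets: list[ProfileSet]

    def __post_init__(self) -> None:
        schemes = {tuple(ps.fractions) for ps in self.profile_sets}
        if len(schemes) > 1:
            raise ConfigurationError(
                f"profile sets disagree on the fraction scheme: {schemes}"
            )

    def by_condition(self, condition: str) -> list[ProfileSet]:
        sets = [ps for ps in self.profile_sets if ps.condition == condition]
        return sorted(sets, key=lambda ps: ps.replicate)

    @property
    def conditions(self) -> list[str]:
        return sorted({ps.condition for ps in self.profile_sets})

    def get(self, condition: str, replicate: int) -> ProfileSet:
        for ps in self.profile_sets:
            if ps.condition == condition and ps.replicate == replicate:
                return ps
        raise KeyError((condition, replicate))

    def complete_ids(self, condition: str | None = None) -> pd.Index:
        """Proteins with a complete profile in every map (of one condition)."""
        sets = (
            self.profile_sets if condition is None else self.by_condition(condition)
        )
        if not sets:
            return pd.Index([])
        ids = sets[0].ids
        for ps in sets[1:]:
            ids = ids.intersection(ps.ids)
        return ids

    def stacked(self, condition: str, ids=None) -> pd.DataFrame:
        """Replicate profiles of one condition concatenated column-wise.

        Feature layout per protein: replicate 1 fractions, replicate 2
        fractions, ...  Only proteins complete in all replicates appear.
        """
        sets = self.by_condition(condition)
        ids = self.complete_ids(condition) if ids is None else pd.Index(ids)
        blocks = []
        for ps in sets:
            block = ps.profiles.loc[ids]
            block.columns = pd.MultiIndex.from_product(
                [[ps.replicate], block.columns], names=["replicate", "fraction"]
            )
            blocks.append(block)
        return pd.concat(blocks, axis=1)

    def mean_profiles(self, condition: str, ids=None) -> pd.DataFrame:
        """Element-wise mean of replicate profiles (complete proteins only)."""
        sets = self.by_condition(condition)
        ids = self.complete_ids(condition) if ids is None else pd.Index(ids)
        stack = np.stack([ps.profiles.loc[ids].to_numpy() for ps in sets])
        return pd.DataFrame(
            stack.mean(axis=0), index=ids, columns=sets[0].fractions
        )


def filter_artifacts(raw: RawQuantTable) -> RawQuantTable:
    """Drop reverse hits, contaminants and proteins only identified by site."""
    flagged = raw.flags.any(axis=1)
    n = int(flagged.sum())
    if n:
        logger.info("artifact filter removed %d of %d rows", n, len(raw))
    if n == len(raw):
        warnings.warn("all rows carried artifact flags; table is empty", stacklevel=2)
    return raw.subset(~flagged.to_numpy())


def _longest_run(present: np.ndarray) -> np.ndarray:
    """Row-wise longest run of True values."""
    n_rows, n_cols = present.shape
    best = np.zeros(n_rows, dtype=int)
    run = np.zeros(n_rows, dtype=int)
    for j in range(n_cols):
        run = np.where(present[:, j], run + 1, 0)
        best = np.maximum(best, run)
    return best


def _normalize_rows(values: np.ndarray) -> np.ndarray:
    filled = np.nan_to_num(values, nan=0.0)
    totals = filled.sum(axis=1, keepdims=True)
    return filled / totals


def build_lfq_profiles(
    raw: RawQuantTable,
    design: ExperimentDesign | None = None,
    min_consecutive: int = 4,
    min_mean_msms: float = 2.0,
) -> MapCollection:
    """Filter and 0-1 normalize label-free profiles, one ProfileSet per map.

    The MS/MS-count filter applies only when MS/MS metadata exist (generic
    tables usually lack them, and DIA counts are not comparable).
    """
    design = design or raw.design
    if tuple(design.fractions) != tuple(raw.design.fractions):
        raise ConfigurationError("fraction scheme of design and table disagree")

    sets = []
    for cond in design.conditions:
        for rep in range(1, design.replicates + 1):
            cols = [(cond, rep, f) for f in design.fractions]
            values = raw.quantities[cols].to_numpy(dtype=float)
            present = ~np.isnan(values)
            runs = _longest_run(present)
            ok_run = runs >= min_consecutive

            rejections: dict[str, str] = {}
            keep = ok_run.copy()
            for pid in raw.ids[~ok_run]:
                rejections[pid] = (
                    f"fewer than {min_consecutive} consecutive quantified fractions"
                )

            if raw.msms_counts is not None:
                msms = raw.msms_counts[cols].to_numpy(dtype=float)
                mean_msms = np.nanmean(np.nan_to_num(msms, nan=0.0), axis=1)
                ok_msms = mean_msms >= min_mean_msms
                for pid in raw.ids[ok_run & ~ok_msms]:
                    rejections[pid] = (
                        f"mean MS/MS count per fraction below {min_mean_msms}"
                    )
                keep &= ok_msms

            profiles = pd.DataFrame(
                _normalize_rows(values[keep]),
                index=raw.ids[keep],
                columns=list(design.fractions),
            )
            sets.append(
                ProfileSet(
                    condition=cond,
                    replicate=rep,
                    profiles=profiles,
                    filters=[
                        f"consecutive>={min_consecutive}",
                        f"mean_msms>={min_mean_msms}"
                        if raw.msms_counts is not None
                        else "mean_msms:skipped (no MS/MS metadata)",
                        "normalize:0-1",
                    ],
                    rejections=rejections,
                )
            )
    return MapCollection(design=design, profile_sets=sets)


def build_silac_profiles(
    raw: RawQuantTable,
    design: ExperimentDesign | None = None,
    max_variability: float = 30.0,
    min_count: int = 2,
) -> MapCollection:
    """Filter, median-normalize, invert and 0-1 normalize SILAC ratios.

    A ratio is valid with more than ``min_count`` quantification events, or
    exactly ``min_count`` events with variability below ``max_variability``
    percent.  Per-fraction medians are computed on the retained ratios, after
    the count/variability filter, so rejected low-quality ratios cannot
    distort them.  Only complete profiles survive.
    """
    design = design or raw.design
    if raw.silac_counts is None:
        raise ConfigurationError("SILAC processing requires ratio count columns")

    sets = []
    for cond in design.conditions:
        for rep in range(1, design.replicates + 1):
            cols = [(cond, rep, f) for f in design.fractions]
            ratios = raw.quantities[cols].to_numpy(dtype=float)
            counts = np.nan_to_num(
                raw.silac_counts[cols].to_numpy(dtype=float), nan=0.0
            )
            if raw.silac_variability is not None:
                var = raw.silac_variability[cols].to_numpy(dtype=float)
            else:
                var = np.full_like(ratios, np.nan)

            with np.errstate(invalid="ignore"):
                valid = (counts > min_count) | (
                    (counts == min_count) & (var < max_variability)
                )
            ratios = np.where(valid, ratios, np.nan)

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
                medians = np.nanmedian(ratios, axis=0)
            for j, frac in enumerate(design.fractions):
                if not np.isfinite(medians[j]) or medians[j] == 0:
                    raise AnalysisError(
                        f"fraction {frac!r} has no valid median ratio in map "
                        f"({cond}, {rep})"
                    )
            normalized = ratios / medians
            inverted = 1.0 / normalized

            complete = ~np.isnan(inverted).any(axis=1)
            rejections = {
                pid: "incomplete SILAC profile after ratio filtering"
                for pid in raw.ids[~complete]
            }
            profiles = pd.DataFrame(
                _normalize_rows(inverted[complete]),
                index=raw.ids[complete],
                columns=list(design.fractions),
            )
            sets.append(
                ProfileSet(
                    condition=cond,
                    replicate=rep,
                    profiles=profiles,
                    filters=[
                        f"silac_count>{min_count} or (=={min_count} & "
                        f"variability<{max_variability}%)",
                        "median-normalize per fraction",
                        "invert",
                        "complete profiles only",
                        "normalize:0-1",
                    ],
                    rejections=rejections,
                )
            )
    return MapCollection(design=design, profile_sets=sets)


def collection_to_session(
    collection: MapCollection, settings: dict | None = None
) -> SessionArchive:
    """Snapshot a filtered collection into a serializable session archive."""
    settings = dict(settings or {})
    settings.setdefault(
        "design",
        {
            "fractions": list(collection.design.fractions),
            "conditions": list(collection.design.conditions),
            "replicates": collection.design.replicates,
            "mode": collection.design.mode,
        },
    )
    matrices = {
        f"{ps.condition}/{ps.replicate}": ProfileMatrix.from_frame(ps.profiles)
        for ps in collection.profile_sets
    }
    return SessionArchive(settings=settings, matrices=matrices)


def collection_from_session(archive: SessionArchive) -> MapCollection:
    """Rebuild the filtered MapCollection stored in a session archive."""
    d = archive.settings["design"]
    conditions = tuple(d["conditions"])
    design = ExperimentDesign.simple(
        conditions=conditions,
        replicates=int(d["replicates"]),
        fractions=tuple(d["fractions"]),
        mode=d.get("mode", "generic"),
    )
    sets = []
    for name, matrix in archive.matrices.items():
        condition, replicate = name.rsplit("/", 1)
        sets.append(
            ProfileSet(
                condition=condition,
                replicate=int(replicate),
                profiles=matrix.to_frame(),
                filters=["restored from session"],
            )
        )
    return MapCollection(design=design, profile_sets=sets)


def intersect_complete(
    collection: MapCollection, scope: str = "all", condition: str | None = None
) -> pd.Index:
    """Proteins with complete profiles in every map of the chosen scope.

    ``scope="all"`` intersects all profile sets; ``scope="per_condition"``
    restricts to the sets of ``condition``.
    """
    if scope == "all":
        return collection.complete_ids()
    if scope == "per_condition":
        if condition is None:
            raise ConfigurationError("per_condition scope needs a condition")
        return collection.complete_ids(condition)
    raise ConfigurationError(f"unknown scope {scope!r}")
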
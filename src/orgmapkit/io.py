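"""Reading quantification tables, annotation lists and session archives.

Quantification input is either the MaxQuant ``proteinGroups.txt`` dialect
(tab-delimited, with per-sample ``LFQ intensity <name>``, ``MS/MS count
<name>``, ``Ratio H/L normalized <name>`` ... columns and ``+``-marked
artifact flags) or a generic wide table with one row per protein and one
column per sample.  The mapping from input column names to experimental
samples (condition, replicate, fraction) is always supplied explicitly via an
:class:`ExperimentDesign`; column naming schemes are site-specific and are
not inferred.

Intensities recorded as 0 are stored as missing: in label-free MS output a
zero means "not quantified", and the downstream consecutive-fraction filter
depends on presence/absence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputDataError, SchemaVersionError

SampleKey = tuple[str, int, str]  # (condition, replicate, fraction)

SESSION_SCHEMA_VERSION = 1

DEFAULT_FRACTIONS = ("1K", "3K", "6K", "12K", "24K", "80K")


@dataclass(frozen=True)
class ExperimentDesign:
    """Declares the sample layout of a profiling experiment.

    Parameters
    ----------
    fractions
        Ordered differential-centrifugation fraction labels (e.g. 1K ... 80K).
        Order matters: the consecutive-fraction filter runs along it.
    conditions
        Condition labels (e.g. ``("control", "treated")``).
    replicates
        Number of replicate maps per condition.
    column_map
        Input column name -> (condition, replicate, fraction).  For MaxQuant
        tables the keys are the ``<name>`` part of per-sample columns, i.e.
        ``"Map1_03K"`` for ``"LFQ intensity Map1_03K"``.
    mode
        Quantification mode: ``"lfq"``, ``"silac"`` or ``"generic"``.
    """

    fractions: tuple[str, ...]
    conditions: tuple[str, ...]
    replicates: int
    column_map: dict[str, SampleKey] = field(hash=False)
    mode: str = "lfq"

    def __post_init__(self) -> None:
        if len(self.fractions) < 3:
            raise ConfigurationError(
                f"need at least 3 fractions, got {len(self.fractions)}"
            )
        if len(set(self.fractions)) != len(self.fractions):
            raise ConfigurationError("fraction labels must be unique")
        if self.replicates < 1:
            raise ConfigurationError("need at least one replicate per condition")
        if self.mode not in ("lfq", "silac", "generic"):
            raise ConfigurationError(f"unknown quantification mode {self.mode!r}")
        seen = set(self.column_map.values())
        for cond in self.conditions:
            for rep in range(1, self.replicates + 1):
                for frac in self.fractions:
                    if (cond, rep, frac) not in seen:
                        raise ConfigurationError(
                            f"no column mapped to sample ({cond}, {rep}, {frac})"
                        )

    @property
    def samples(self) -> list[SampleKey]:
        """All (condition, replicate, fraction) triples in design order."""
        return [
            (cond, rep, frac)
            for cond in self.conditions
            for rep in range(1, self.replicates + 1)
            for frac in self.fractions
        ]

    @classmethod
    def simple(
        cls,
        conditions: tuple[str, ...] = ("control",),
        replicates: int = 3,
        fractions: tuple[str, ...] = DEFAULT_FRACTIONS,
        mode: str = "generic",
        pattern: str = "{condition}_R{replicate}_{fraction}",
    ) -> "ExperimentDesign":
        """Design with systematically generated column names."""
        column_map = {
            pattern.format(condition=c, replicate=r, fraction=f): (c, r, f)
            for c in conditions
            for r in range(1, replicates + 1)
            for f in fractions
        }
        return cls(
            fractions=tuple(fractions),
            conditions=tuple(conditions),
            replicates=replicates,
            column_map=column_map,
            mode=mode,
        )

    def sample_columns(self) -> pd.MultiIndex:
        keys = sorted(self.column_map.values(), key=self.samples.index)
        return pd.MultiIndex.from_tuples(
            keys, names=["condition", "replicate", "fraction"]
        )


@dataclass
class RawQuantTable:
    """Per-protein-group quantities keyed by (condition, replicate, fraction).

    ``quantities`` (and the optional SILAC/MS-MS metadata frames) are indexed
    by protein-group id with a (condition, replicate, fraction) MultiIndex on
    the columns; missing quantifications are NaN.
    """

    design: ExperimentDesign
    ids: pd.Index
    gene_names: pd.Series
    quantities: pd.DataFrame
    flags: pd.DataFrame  # columns: reverse, contaminant, only_by_site
    msms_counts: pd.DataFrame | None = None
    silac_counts: pd.DataFrame | None = None
    silac_variability: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, keep: np.ndarray | pd.Index) -> "RawQuantTable":
        """Row subset preserving all metadata frames."""
        def take(df: pd.DataFrame | None) -> pd.DataFrame | None:
            return None if df is None else df.loc[keep]

        return RawQuantTable(
            design=self.design,
            ids=pd.Index(self.quantities.loc[keep].index),
            gene_names=self.gene_names.loc[keep],
            quantities=self.quantities.loc[keep],
            flags=self.flags.loc[keep],
            msms_counts=take(self.msms_counts),
            silac_counts=take(self.silac_counts),
            silac_variability=take(self.silac_variability),
        )


_FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
}


def _numeric(frame: pd.DataFrame, context: str) -> pd.DataFrame:
    out = frame.apply(pd.to_numeric, errors="coerce")
    # locate unparsable cells (non-empty strings that failed conversion)
    bad = out.isna() & frame.notna()
    if bad.to_numpy().any():
        nonempty = frame.where(bad).astype(str).apply(
            lambda col: col.str.strip().ne("") & col.str.lower().ne("nan")
        )
        offending = (bad & nonempty)
        if offending.to_numpy().any():
            rows = list(np.flatnonzero(offending.any(axis=1))[:5])
            raise InputDataError(
                f"unparsable numeric cell(s) in {context}, e.g. at row(s) {rows}"
            )
    return out


def _sample_frame(
    table: pd.DataFrame,
    design: ExperimentDesign,
    prefix: str,
    ids: pd.Index,
    required: bool,
) -> pd.DataFrame | None:
    cols = {}
    for name, key in design.column_map.items():
        col = f"{prefix} {name}"
        if col not in table.columns:
            if required:
                raise ConfigurationError(
                    f"mapped column {col!r} not found in input table"
                )
            return None
        cols[key] = col
    keys = sorted(cols, key=design.samples.index)
    frame = table[[cols[k] for k in keys]].copy()
    frame.columns = pd.MultiIndex.from_tuples(
        keys, names=["condition", "replicate", "fraction"]
    )
    frame.index = ids
    return _numeric(frame, f"{prefix!r} columns")


def read_maxquant_table(path, design: ExperimentDesign) -> RawQuantTable:
    """Read a MaxQuant proteinGroups.txt-style table.

    Quantities of 0 are stored as missing; artifact flags are parsed from
    ``+`` marks in the Reverse / Potential contaminant / Only identified by
    site columns.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=True)
    if "Protein IDs" not in table.columns:
        raise ConfigurationError("column 'Protein IDs' not found in input table")
    ids = pd.Index(table["Protein IDs"], name="protein_group_id")
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise InputDataError(f"duplicate protein group ids: {dupes}")
    gene_names = pd.Series(
        table.get("Gene names", pd.Series([""] * len(table))).fillna("").to_numpy(),
        index=ids,
        name="gene_names",
    )

    flags = pd.DataFrame(index=ids)
    for key, col in _FLAG_COLUMNS.items():
        if col in table.columns:
            flags[key] = (table[col].fillna("") == "+").to_numpy()
        else:
            flags[key] = False

    if design.mode == "silac":
        quantities = _sample_frame(table, design, "Ratio H/L normalized", ids, True)
        silac_counts = _sample_frame(table, design, "Ratio H/L count", ids, False)
        silac_var = _sample_frame(
            table, design, "Ratio H/L variability [%]", ids, False
        )
        msms = _sample_frame(table, design, "MS/MS count", ids, False)
    else:
        quantities = _sample_frame(table, design, "LFQ intensity", ids, True)
        silac_counts = silac_var = None
        msms = _sample_frame(table, design, "MS/MS count", ids, False)

    quantities = quantities.where(quantities != 0)  # 0 == not quantified
    return RawQuantTable(
        design=design,
        ids=ids,
        gene_names=gene_names,
        quantities=quantities,
        flags=flags,
        msms_counts=msms,
        silac_counts=silac_counts,
        silac_variability=silac_var,
    )


def read_generic_profiles(path, design: ExperimentDesign) -> RawQuantTable:
    """Read a generic wide table: first column protein id, one column per sample.

    No artifact flags or MS/MS metadata are expected; flags default to False
    and metadata to absent.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    id_col = table.columns[0]
    ids = pd.Index(table[id_col], name="protein_group_id")
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise InputDataError(f"duplicate protein ids: {dupes}")

    cols = {}
    for name, key in design.column_map.items():
        if name not in table.columns:
            raise ConfigurationError(f"mapped column {name!r} not found in input table")
        cols[key] = name
    keys = sorted(cols, key=design.samples.index)
    quantities = table[[cols[k] for k in keys]].copy()
    quantities.columns = pd.MultiIndex.from_tuples(
        keys, names=["condition", "replicate", "fraction"]
    )
    quantities.index = ids
    quantities = _numeric(quantities, "sample columns")
    quantities = quantities.where(quantities != 0)

    flags = pd.DataFrame(
        False, index=ids, columns=["reverse", "contaminant", "only_by_site"]
    )
    gene_names = pd.Series("", index=ids, name="gene_names")
    return RawQuantTable(
        design=design,
        ids=ids,
        gene_names=gene_names,
        quantities=quantities,
        flags=flags,
    )


@dataclass
class MarkerAnnotation:
    """Protein id -> compartment label for classifier training and QC."""

    labels: pd.Series  # index protein id, values compartment

    @property
    def compartments(self) -> list[str]:
        return sorted(self.labels.unique())

    def restrict(self, ids) -> "MarkerAnnotation":
        keep = self.labels.index.intersection(pd.Index(ids))
        return MarkerAnnotation(self.labels.loc[keep])

    def __len__(self) -> int:
        return len(self.labels)


def read_marker_list(path) -> MarkerAnnotation:
    """Read a two-column TSV (protein id, compartment).

    A protein listed with two different compartments is a conflict error.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    except pd.errors.EmptyDataError:
        table = pd.DataFrame()
    if table.empty:
        warnings.warn("marker list is empty", stacklevel=2)
        return MarkerAnnotation(pd.Series(dtype=str))
    if _looks_like_header(table.iloc[0]):
        table = table.iloc[1:]
    table = table.iloc[:, :2]
    table.columns = ["protein_id", "compartment"]
    conflicts = (
        table.groupby("protein_id")["compartment"].nunique().loc[lambda s: s > 1]
    )
    if len(conflicts):
        raise InputDataError(
            f"conflicting compartment labels for: {sorted(conflicts.index)}"
        )
    table = table.drop_duplicates()
    labels = pd.Series(
        table["compartment"].to_numpy(),
        index=pd.Index(table["protein_id"], name="protein_id"),
        name="compartment",
    )
    return MarkerAnnotation(labels)


def _looks_like_header(row: pd.Series) -> bool:
    text = " ".join(str(v).lower() for v in row)
    return "protein" in text or "compartment" in text or "term" in text


@dataclass
class ComplexCatalog:
    """Stable protein complex name -> member protein ids."""

    members: dict[str, tuple[str, ...]]

    def __len__(self) -> int:
        return len(self.members)


def read_complex_table(path) -> ComplexCatalog:
    """Two-column TSV (complex name, member protein id)."""
    table = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if table.empty:
        return ComplexCatalog({})
    if _looks_like_header(table.iloc[0]):
        table = table.iloc[1:]
    table = table.iloc[:, :2]
    table.columns = ["complex", "protein_id"]
    members = {
        name: tuple(dict.fromkeys(group["protein_id"]))
        for name, group in table.groupby("complex", sort=True)
    }
    return ComplexCatalog(members)


def read_annotation_table(path) -> dict[str, set]:
    """Two-column TSV (protein id, annotation term), one row per pair."""
    table = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if table.empty:
        return {}
    if _looks_like_header(table.iloc[0]):
        table = table.iloc[1:]
    table = table.iloc[:, :2]
    table.columns = ["protein_id", "term"]
    out: dict[str, set] = {}
    for pid, term in table.itertuples(index=False):
        out.setdefault(pid, set()).add(term)
    return out


# --------------------------------------------------------------------------
# Session archives


@dataclass
class ProfileMatrix:
    """A named protein x fraction matrix inside a session archive."""

    ids: list[str]
    fractions: list[str]
    values: np.ndarray  # shape (len(ids), len(fractions))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProfileMatrix":
        return cls(
            ids=[str(i) for i in frame.index],
            fractions=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.ids, name="protein_id"),
            columns=self.fractions,
        )


@dataclass
class SessionArchive:
    """Serializable snapshot of an analysis session.

    A single JSON document: settings snapshot, the filtered profile matrices
    keyed as ``condition/replicate``, computed results keyed by analysis
    name, and a schema version tag.  Round-trips losslessly.
    """

    settings: dict
    matrices: dict[str, ProfileMatrix] = field(default_factory=dict)
    results: dict[str, object] = field(default_factory=dict)
    version: int = SESSION_SCHEMA_VERSION

    def write(self, path) -> None:
        doc = {
            "schema_version": self.version,
            "settings": self.settings,
            "matrices": {
                name: {
                    "ids": m.ids,
                    "fractions": m.fractions,
                    "values": np.asarray(m.values, dtype=float).ravel().tolist(),
                }
                for name, m in self.matrices.items()
            },
            "results": self.results,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def read(cls, path) -> "SessionArchive":
        with open(path) as fh:
            doc = json.load(fh)
        version = doc.get("schema_version")
        if version != SESSION_SCHEMA_VERSION:
            raise SchemaVersionError(
                f"session schema version {version} is not supported "
                f"(this build reads version {SESSION_SCHEMA_VERSION})"
            )
        matrices = {
            name: ProfileMatrix(
                ids=m["ids"],
                fractions=m["fractions"],
                values=np.asarray(m["values"], dtype=float).reshape(
                    len(m["ids"]), len(m["fractions"])
                ),
            )
            for name, m in doc.get("matrices", {}).items()
        }
        return cls(
            settings=doc["settings"],
            matrices=matrices,
            results=doc.get("results", {}),
            version=version,
        )


def roundtrip_session(archive: SessionArchive, path) -> SessionArchive:
    """Write then re-read an archive; the result equals the input."""
    archive.write(path)
    return SessionArchive.read(path)
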
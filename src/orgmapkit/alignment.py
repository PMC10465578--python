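"""Align protein groups across independently processed experiments.

Shotgun proteomics reports protein groups (sets of accessions that share the
identified peptides).  Grouping differs between search-engine runs, so
quantifications from different experiments must be aligned before they can
be compared.  The strategy prioritizes matching of single-gene-locus groups
with complete coverage across experiments, over matching of rare multi-gene
groups and groups with incomplete coverage:

Phase 1 - single-locus groups are reduced to the canonical accession if the
group contains it, otherwise to the first listed isoform; reduced ids found
in every experiment are matched and flagged ``primary id``.

Phase 2 - starting with the largest remaining multi-gene group across all
experiments, it is matched with its largest remaining subset in each other
experiment, and the matched groups leave the pool; this repeats until no
multi-gene group remains.  Subsets are evaluated at the locus level (isoform
accessions covering the same loci differ between search-engine runs).  A
match is flagged ``multiple genes`` when the matched groups cover identical
loci in every experiment, else ``gene level conflict``.

Phase 3 - leftover single-locus groups (incomplete coverage) are reduced as
in Phase 1 and flagged ``primary id``.

Ties in Phase 2 break deterministically: equal-size groups order by the
lexicographic sorted locus list; equal-size subsets prefer the most shared
accessions, then lexicographic order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputDataError

FLAG_PRIMARY = "primary id"
FLAG_MULTI = "multiple genes"
FLAG_CONFLICT = "gene level conflict"


@dataclass(frozen=True)
class AlignmentRecord:
    aligned_id: str
    flag: str
    originals: tuple[str | None, ...]  # per experiment, None = not covered

    @property
    def coverage(self) -> int:
        return sum(o is not None for o in self.originals)


def _parse_group(group: str) -> tuple[str, ...]:
    return tuple(a.strip() for a in group.split(";") if a.strip())


def _loci(accessions, canonical_map) -> set:
    missing = [a for a in accessions if a not in canonical_map]
    if missing:
        raise InputDataError(f"accessions without locus mapping: {sorted(missing)}")
    return {canonical_map[a][1] for a in accessions}


def _reduce_single_locus(accessions, canonical_map) -> str:
    """Canonical accession if the group lists it, else the first isoform."""
    canonicals = {canonical_map[a][0] for a in accessions}
    for acc in accessions:
        if acc in canonicals:
            return acc
    return accessions[0]


def align_groups(
    experiments: list[list[str]],
    canonical_map: dict[str, tuple[str, str]],
) -> tuple[list[AlignmentRecord], pd.DataFrame]:
    """Align protein-group strings (semicolon-joined accessions).

    Parameters
    ----------
    experiments
        One list of protein-group strings per experiment.
    canonical_map
        accession -> (canonical accession of its locus, locus id).

    Returns
    -------
    records, table
        The alignment records and a traceability table with one column per
        experiment holding the original group string.
    """
    n_exp = len(experiments)
    # unmatched[e]: group string -> accession tuple
    unmatched: list[dict[str, tuple[str, ...]]] = []
    for groups in experiments:
        seen: dict[str, tuple[str, ...]] = {}
        for g in groups:
            if g in seen:
                raise InputDataError(f"duplicate protein group {g!r} in experiment")
            seen[g] = _parse_group(g)
        unmatched.append(seen)

    records: list[AlignmentRecord] = []

    # ---- Phase 1: complete-coverage single-locus groups -------------------
    reduced_maps: list[dict[str, str]] = []  # per exp: reduced id -> group string
    for groups in unmatched:
        reduced: dict[str, str] = {}
        for g, accs in groups.items():
            if len(_loci(accs, canonical_map)) == 1:
                rid = _reduce_single_locus(accs, canonical_map)
                if rid in reduced:
                    raise InputDataError(
                        f"groups {reduced[rid]!r} and {g!r} both reduce to {rid!r}"
                    )
                reduced[rid] = g
        reduced_maps.append(reduced)

    common = set(reduced_maps[0]) if reduced_maps else set()
    for rm in reduced_maps[1:]:
        common &= set(rm)
    for rid in sorted(common):
        originals = tuple(rm[rid] for rm in reduced_maps)
        records.append(AlignmentRecord(rid, FLAG_PRIMARY, originals))
        for e in range(n_exp):
            del unmatched[e][reduced_maps[e][rid]]

    # ---- Phase 2: multi-gene groups, greedy by size -----------------------
    def multi_pool():
        return [
            (e, g, accs)
            for e, groups in enumerate(unmatched)
            for g, accs in groups.items()
            if len(_loci(accs, canonical_map)) > 1
        ]

    pool = multi_pool()
    while pool:
        # largest group; ties by lexicographic sorted locus list
        e0, g0, accs0 = min(
            pool,
            key=lambda item: (
                -len(item[2]),
                sorted(_loci(item[2], canonical_map)),
                item[0],
            ),
        )
        matched: list[str | None] = [None] * n_exp
        matched[e0] = g0
        union = set(accs0)
        loci0 = _loci(accs0, canonical_map)
        loci_sets = [loci0]
        del unmatched[e0][g0]
        acc_set0 = set(accs0)
        for e in range(n_exp):
            if e == e0:
                continue
            # subsets are evaluated at the locus level: isoform accessions
            # covering the same loci differ between search-engine runs
            candidates = [
                (g, accs)
                for g, accs in unmatched[e].items()
                if _loci(accs, canonical_map) <= loci0
            ]
            if not candidates:
                continue  # missing coverage in this experiment
            g, accs = min(
                candidates,
                key=lambda item: (
                    -len(_loci(item[1], canonical_map)),
                    -len(set(item[1]) & acc_set0),
                    sorted(item[1]),
                ),
            )
            matched[e] = g
            union |= set(accs)
            loci_sets.append(_loci(accs, canonical_map))
            del unmatched[e][g]
        flag = (
            FLAG_MULTI
            if all(ls == loci_sets[0] for ls in loci_sets)
            else FLAG_CONFLICT
        )
        records.append(
            AlignmentRecord(";".join(sorted(union)), flag, tuple(matched))
        )
        pool = multi_pool()

    # ---- Phase 3: leftover single-locus groups ----------------------------
    leftovers: dict[str, list[str | None]] = {}
    for e, groups in enumerate(unmatched):
        for g, accs in sorted(groups.items()):
            rid = _reduce_single_locus(accs, canonical_map)
            row = leftovers.setdefault(rid, [None] * n_exp)
            if row[e] is not None:
                raise InputDataError(
                    f"groups {row[e]!r} and {g!r} both reduce to {rid!r}"
                )
            row[e] = g
    for rid in sorted(leftovers):
        records.append(AlignmentRecord(rid, FLAG_PRIMARY, tuple(leftovers[rid])))

    table = pd.DataFrame(
        {
            "aligned_id": [r.aligned_id for r in records],
            "flag": [r.flag for r in records],
            **{
                f"experiment_{e + 1}": [r.originals[e] for r in records]
                for e in range(n_exp)
            },
        }
    )
    return records, table
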
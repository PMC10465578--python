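"""Synthetic organellar maps with known ground truth.

The generator emulates the data structure the analysis assumes: compartment
clusters of compositional profiles across six differential-centrifugation
fractions, stable complexes whose members co-fractionate with near-identical
profiles, replicate measurement noise, optional DDA-like missingness, and
planted translocations between conditions.

Every protein draws a base profile by jittering its compartment prototype
(complex members share one jittered prototype).  Replicate noise has two
components, mirroring how comparative maps are produced.  The dominant one
is multiplicative log-normal fractionation noise (per protein and fraction,
sigma = ``noise_sigma``): it varies between replicate batches but is shared
between the two condition maps of one batch, because cognate maps are
fractionated in parallel - which is exactly why the translocation analysis
subtracts profiles within cognate pairs, where this component cancels.  On
top of it, every individual map adds measurement noise to the normalized
profile, drawn isotropically in the zero-sum tangent space of the simplex
(any perturbation of a composition is zero-sum) with scale ``noise_floor``
and truncated at the detection floor of zero - the residual error that
remains after pairing.  A planted mover's treated base profile is
``(1 - lambda) * source + lambda * destination prototype``; lambda is the
mixing coefficient, so lambda = 0 leaves the protein static and lambda = 1
transplants it completely.  Missingness is independent Bernoulli per
(protein, fraction, replicate); profiles that lose the required consecutive
run are dropped from that map, like real label-free data.

The default prototypes are eleven unit-sum vectors with distinct dominant
fractions; the Golgi and endosome prototypes overlap deliberately, emulating
the blending of these compartments seen in real HeLa maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import (
    DEFAULT_FRACTIONS,
    ComplexCatalog,
    ExperimentDesign,
    MarkerAnnotation,
)
from .preprocessing import MapCollection, ProfileSet

DEFAULT_COMPARTMENTS = (
    "Nucleus",
    "Chromatin",
    "Mitochondrion",
    "ER",
    "Golgi",
    "Endosome",
    "Lysosome",
    "Peroxisome",
    "Plasma membrane",
    "Large protein complex",
    "Actin cytoskeleton",
)

# Unit-sum prototype profiles over (1K, 3K, 6K, 12K, 24K, 80K).  Dominant
# fractions differ per compartment; two pairs overlap on purpose (the "hard
# pairs"): Golgi/Endosome share mass in the 12K-80K range and
# Nucleus/Chromatin both peak in 1K.  No component exceeds ~0.5: under
# compositional closure a profile's dominant component absorbs the summed
# measurement noise of the whole profile, so extreme dominance would give
# those proteins systematically wider null deltas than everyone else.
DEFAULT_PROTOTYPES = np.array(
    [
        [0.45, 0.19, 0.13, 0.10, 0.08, 0.05],    # Nucleus
        [0.42, 0.33, 0.10, 0.07, 0.05, 0.03],    # Chromatin
        [0.05, 0.24, 0.40, 0.18, 0.08, 0.05],    # Mitochondrion
        [0.08, 0.14, 0.20, 0.30, 0.18, 0.10],    # ER
        [0.03, 0.06, 0.14, 0.32, 0.30, 0.15],    # Golgi
        [0.03, 0.05, 0.10, 0.24, 0.34, 0.24],    # Endosome
        [0.06, 0.30, 0.30, 0.18, 0.10, 0.06],    # Lysosome
        [0.03, 0.10, 0.34, 0.30, 0.15, 0.08],    # Peroxisome
        [0.12, 0.25, 0.15, 0.10, 0.18, 0.20],    # Plasma membrane
        [0.05, 0.06, 0.10, 0.15, 0.24, 0.40],    # Large protein complex
        [0.20, 0.08, 0.06, 0.10, 0.22, 0.34],    # Actin cytoskeleton
    ]
)


@dataclass
class SyntheticMapSpec:
    """Generator parameters with planted ground truth.

    noise_sigma is the per-fraction multiplicative log-normal sigma of the
    batch (fractionation) noise, drawn once per replicate and shared by the
    cognate condition maps of that replicate; noise_floor scales the
    per-map zero-sum measurement noise on the profile scale.
    protein_jitter is the
    per-protein deviation from the compartment prototype (fixed across
    replicates and conditions); complex_tightness the residual jitter of
    complex members around their shared profile.  mover_lambda bounds the
    mixing coefficient of planted
    translocations; min_mover_separation is the smallest admissible total
    variation distance between a mover's source and destination prototypes,
    so that lambda >= 0.5 always moves a substantial share of profile mass.
    """

    fractions: tuple[str, ...] = DEFAULT_FRACTIONS
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    prototypes: np.ndarray = field(
        default_factory=lambda: DEFAULT_PROTOTYPES.copy()
    )
    proteins_per_compartment: int = 50
    markers_per_compartment: int = 30
    n_complexes: int = 10
    complex_size: int = 6
    complex_tightness: float = 0.02
    protein_jitter: float = 0.05
    noise_sigma: float = 0.10
    noise_floor: float = 0.01
    missing_rate: float = 0.0
    min_consecutive: int = 4
    n_movers: int = 0
    mover_lambda: tuple[float, float] = (0.5, 1.0)
    min_mover_separation: float = 0.6
    replicates: int = 3
    conditions: tuple[str, str] = ("control", "treated")
    seed: int = 0

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        if len(self.compartments) < 2:
            raise ConfigurationError("need at least two compartments")
        if self.prototypes.shape != (
            len(self.compartments),
            len(self.fractions),
        ):
            raise ConfigurationError(
                "prototype matrix must be compartments x fractions"
            )
        if not np.allclose(self.prototypes.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("prototypes must sum to 1")
        lo, hi = self.mover_lambda
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("mover_lambda bounds must be in [0, 1]")
        if self.markers_per_compartment > self.proteins_per_compartment:
            raise ConfigurationError(
                "cannot have more markers than proteins per compartment"
            )


@dataclass
class GroundTruth:
    """What the generator planted: labels, markers, complexes, movers."""

    compartments: pd.Series  # protein id -> compartment
    markers: MarkerAnnotation
    complexes: ComplexCatalog
    movers: pd.DataFrame  # id, source, destination, mixing lambda


def _jitter(profile: np.ndarray, sigma: float, rng) -> np.ndarray:
    noisy = profile * np.exp(rng.normal(0.0, sigma, size=profile.shape))
    return noisy / noisy.sum()


def _total_variation(a: np.ndarray, b: np.ndarray) -> float:
    return 0.5 * float(np.abs(a - b).sum())


def generate_collection(
    spec: SyntheticMapSpec,
) -> tuple[MapCollection, MapCollection, GroundTruth]:
    """Generate a (control, treated) collection pair plus ground truth.

    The same seed always yields identical output.
    """
    rng = np.random.default_rng(spec.seed)
    F = len(spec.fractions)
    n_comp = len(spec.compartments)

    ids, labels = [], []
    for c, comp in enumerate(spec.compartments):
        for i in range(spec.proteins_per_compartment):
            ids.append(f"SYN{c:02d}{i:04d}")
            labels.append(comp)
    ids = pd.Index(ids, name="protein_id")
    compartments = pd.Series(labels, index=ids, name="compartment")
    comp_index = {comp: c for c, comp in enumerate(spec.compartments)}

    markers = {}
    for comp in spec.compartments:
        members = compartments.index[compartments == comp]
        for pid in members[: spec.markers_per_compartment]:
            markers[pid] = comp
    marker_annotation = MarkerAnnotation(
        pd.Series(markers, name="compartment").rename_axis("protein_id")
    )

    # complexes live in one compartment each, round-robin, drawn from the
    # tail (non-marker) proteins of the compartment
    complexes: dict[str, tuple[str, ...]] = {}
    complex_of: dict[str, str] = {}
    for k in range(spec.n_complexes):
        comp = spec.compartments[k % n_comp]
        members = compartments.index[compartments == comp]
        pool = [p for p in members[spec.markers_per_compartment:] if p not in complex_of]
        chosen = pool[: spec.complex_size]
        if len(chosen) < spec.complex_size:
            raise ConfigurationError(
                "not enough non-marker proteins to populate the complexes"
            )
        name = f"CPX{k:02d}_{comp}"
        complexes[name] = tuple(chosen)
        for pid in chosen:
            complex_of[pid] = name

    # base profiles (shared between conditions unless the protein moves)
    base = np.empty((len(ids), F))
    complex_base = {
        name: _jitter(
            spec.prototypes[comp_index[compartments[members[0]]]],
            spec.protein_jitter,
            rng,
        )
        for name, members in complexes.items()
    }
    for row, pid in enumerate(ids):
        if pid in complex_of:
            base[row] = _jitter(
                complex_base[complex_of[pid]], spec.complex_tightness, rng
            )
        else:
            base[row] = _jitter(
                spec.prototypes[comp_index[compartments[pid]]],
                spec.protein_jitter,
                rng,
            )

    # planted movers: non-marker, non-complex proteins whose compartment has
    # a destination far enough from the source prototype
    destination_candidates = {
        source: [
            comp
            for comp in spec.compartments
            if comp != source
            and _total_variation(
                spec.prototypes[comp_index[source]],
                spec.prototypes[comp_index[comp]],
            )
            >= spec.min_mover_separation
        ]
        for source in spec.compartments
    }
    mover_rows = []
    treated_base = base.copy()
    eligible = [
        p
        for p in ids
        if p not in marker_annotation.labels.index
        and p not in complex_of
        and destination_candidates[compartments[p]]
    ]
    if spec.n_movers > len(eligible):
        raise ConfigurationError("not enough eligible proteins to plant movers")
    chosen_movers = rng.choice(len(eligible), size=spec.n_movers, replace=False)
    for idx in chosen_movers:
        pid = eligible[idx]
        source = compartments[pid]
        candidates = destination_candidates[source]
        destination = candidates[rng.integers(len(candidates))]
        lam = float(rng.uniform(*spec.mover_lambda))
        dst_base = _jitter(
            spec.prototypes[comp_index[destination]], spec.protein_jitter, rng
        )
        row = ids.get_loc(pid)
        treated_base[row] = (1.0 - lam) * base[row] + lam * dst_base
        mover_rows.append((pid, source, destination, lam))
    movers = pd.DataFrame(
        mover_rows, columns=["protein_id", "source", "destination", "lambda"]
    ).set_index("protein_id")

    # batch fractionation factors: one draw per replicate, shared between
    # the cognate condition maps of that replicate
    batch_factors = [
        np.exp(rng.normal(0.0, spec.noise_sigma, size=base.shape))
        for _ in range(spec.replicates)
    ]

    def make_collection(cond: str, base_profiles: np.ndarray) -> MapCollection:
        design = ExperimentDesign.simple(
            conditions=(cond,),
            replicates=spec.replicates,
            fractions=spec.fractions,
            mode="generic",
        )
        sets = []
        for rep in range(1, spec.replicates + 1):
            values = base_profiles * batch_factors[rep - 1]
            values /= values.sum(axis=1, keepdims=True)
            # per-map measurement noise: a perturbation of a composition is
            # zero-sum by definition, so it is drawn isotropically in the
            # zero-sum tangent space of the simplex
            noise = rng.normal(size=values.shape)
            noise -= noise.mean(axis=1, keepdims=True)
            values = values + spec.noise_floor * noise
            np.clip(values, 0.0, None, out=values)  # detection floor
            values /= values.sum(axis=1, keepdims=True)
            if spec.missing_rate > 0:
                present = rng.random(size=values.shape) >= spec.missing_rate
                keep = _has_run(present, spec.min_consecutive)
                values = np.where(present, values, 0.0)
                values = values[keep]
                values /= values.sum(axis=1, keepdims=True)
                idx = ids[keep]
            else:
                idx = ids
            sets.append(
                ProfileSet(
                    condition=cond,
                    replicate=rep,
                    profiles=pd.DataFrame(
                        values, index=idx, columns=list(spec.fractions)
                    ),
                    filters=["synthetic"],
                )
            )
        return MapCollection(design=design, profile_sets=sets)

    control = make_collection(spec.conditions[0], base)
    treated = make_collection(spec.conditions[1], treated_base)
    truth = GroundTruth(
        compartments=compartments,
        markers=marker_annotation,
        complexes=ComplexCatalog(complexes),
        movers=movers,
    )
    return control, treated, truth


def _has_run(present: np.ndarray, min_run: int) -> np.ndarray:
    best = np.zeros(present.shape[0], dtype=int)
    run = np.zeros(present.shape[0], dtype=int)
    for j in range(present.shape[1]):
        run = np.where(present[:, j], run + 1, 0)
        best = np.maximum(best, run)
    return best >= min_run


def null_collection(
    spec: SyntheticMapSpec,
) -> tuple[MapCollection, MapCollection, GroundTruth]:
    """Both conditions drawn from the identical generative process.

    Used for null calibration of the MR statistic; the spec must not plant
    movers.
    """
    if spec.n_movers != 0:
        raise ConfigurationError("a null collection cannot contain movers")
    return generate_collection(spec)


def write_fixture(spec: SyntheticMapSpec, out_dir) -> None:
    """Write generic wide TSVs per condition plus ground-truth tables."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    control, treated, truth = generate_collection(spec)
    for coll, cond in ((control, spec.conditions[0]), (treated, spec.conditions[1])):
        frames = []
        for ps in coll.by_condition(cond):
            frame = ps.profiles.copy()
            frame.columns = [
                f"{cond}_R{ps.replicate}_{f}" for f in frame.columns
            ]
            frames.append(frame)
        wide = pd.concat(frames, axis=1)
        wide.insert(0, "protein_id", wide.index)
        wide.to_csv(out / f"profiles_{cond}.tsv", sep="\t", index=False)
    truth.markers.labels.rename("compartment").to_csv(
        out / "markers.tsv", sep="\t", header=False
    )
    rows = [
        (name, pid)
        for name, members in truth.complexes.members.items()
        for pid in members
    ]
    pd.DataFrame(rows).to_csv(
        out / "complexes.tsv", sep="\t", index=False, header=False
    )
    truth.movers.to_csv(out / "movers.tsv", sep="\t")
    truth.compartments.to_csv(out / "compartments.tsv", sep="\t", header=False)
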
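import numpy as np
import pandas as pd
import pytest

from orgmapkit.io import ExperimentDesign
from orgmapkit.preprocessing import MapCollection, ProfileSet
from orgmapkit.simulate import SyntheticMapSpec, generate_collection

FRACTIONS = ("1K", "3K", "6K", "12K", "24K", "80K")


def make_profile_set(condition, replicate, profiles, ids=None):
    frame = pd.DataFrame(
        np.asarray(profiles, dtype=float),
        index=ids or [f"P{i + 1}" for i in range(len(profiles))],
        columns=list(FRACTIONS),
    )
    return ProfileSet(condition=condition, replicate=replicate, profiles=frame)


def make_collection(condition, replicate_profiles, ids=None):
    """One condition, one ProfileSet per replicate matrix given."""
    design = ExperimentDesign.simple(
        conditions=(condition,),
        replicates=len(replicate_profiles),
        fractions=FRACTIONS,
    )
    sets = [
        make_profile_set(condition, rep + 1, profiles, ids=ids)
        for rep, profiles in enumerate(replicate_profiles)
    ]
    return MapCollection(design=design, profile_sets=sets)


@pytest.fixture(scope="session")
def small_maps():
    """A small noisy synthetic (control, treated, truth) triple."""
    spec = SyntheticMapSpec(
        proteins_per_compartment=20,
        markers_per_compartment=10,
        n_complexes=6,
        complex_size=5,
        n_movers=6,
        min_mover_separation=0.45,
        seed=4,
    )
    return generate_collection(spec)


@pytest.fixture(scope="session")
def clean_maps():
    """Noise-free synthetic maps: replicates are exact copies."""
    spec = SyntheticMapSpec(
        proteins_per_compartment=12,
        markers_per_compartment=6,
        n_complexes=4,
        complex_size=5,
        noise_sigma=0.0,
        noise_floor=0.0,
        seed=8,
    )
    return generate_collection(spec)
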
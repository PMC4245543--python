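import numpy as np
import pytest

from ahlscreen import masslib, synthetic_data as syn
from ahlscreen.profiles import load_strains, load_detection_matrix


@pytest.fixture(scope="session")
def library():
    return masslib.build_library()


@pytest.fixture(scope="session")
def fixture_strains():
    return load_strains()


@pytest.fixture(scope="session")
def fixture_matrix(fixture_strains):
    return load_detection_matrix(fixture_strains)


def make_planted(library, names_rts, abundance=400.0):
    return tuple(
        syn.PlantedAhl(library.get(name), rt_center=rt, abundance=abundance)
        for name, rt in names_rts
    )


@pytest.fixture(scope="session")
def planted_run(library):
    """One standard-tune run with three planted AHLs and one decoy."""
    spec = syn.RunSpec(
        planted=make_planted(library, [("OH-C6", 2.0), ("C8", 3.2), ("O-C10", 4.5)]),
        decoys=(syn.DecoyCompound(mz=250.123, rt_center=2.8, abundance=400.0),),
        seed=11,
    )
    return syn.generate_run(spec), spec
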
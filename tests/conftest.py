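import numpy as np
import pytest

from ttmd.fingerprint import InteractionClass as IC
from ttmd.synthetic import SyntheticBackend, SyntheticLigandSpec, make_fixture_complex

ALL_CLASSES_SPEC = [
    (IC.HYDROPHOBIC, 0),
    (IC.AROMATIC_FACE_TO_FACE, 1),
    (IC.AROMATIC_EDGE_TO_FACE, 2),
    (IC.HBOND_PROTEIN_DONOR, 3),
    (IC.HBOND_PROTEIN_ACCEPTOR, 4),
    (IC.SALTBRIDGE_PROTEIN_POSITIVE, 5),
    (IC.SALTBRIDGE_PROTEIN_NEGATIVE, 6),
    (IC.METAL_IONIC, 7),
]

FOUR_CLASS_SPEC = [
    (IC.HYDROPHOBIC, 1),
    (IC.HBOND_PROTEIN_DONOR, 3),
    (IC.HBOND_PROTEIN_ACCEPTOR, 5),
    (IC.SALTBRIDGE_PROTEIN_POSITIVE, 7),
]


@pytest.fixture(scope="session")
def all_class_spec():
    return SyntheticLigandSpec(
        native_interactions=ALL_CLASSES_SPEC,
        characteristic_temperatures=[400.0] * len(ALL_CLASSES_SPEC),
    )


@pytest.fixture(scope="session")
def all_class_complex(all_class_spec):
    return make_fixture_complex(all_class_spec, 8)


@pytest.fixture()
def stable_backend():
    spec = SyntheticLigandSpec(
        native_interactions=FOUR_CLASS_SPEC,
        characteristic_temperatures=[5000.0] * 4,
    )
    return SyntheticBackend(spec, 9)


def make_backend(characteristic_temperature, sharpness=5.0, rebind=0.0):
    spec = SyntheticLigandSpec(
        native_interactions=FOUR_CLASS_SPEC,
        characteristic_temperatures=[float(characteristic_temperature)] * 4,
        sharpness=sharpness,
        rebind_probability=rebind,
    )
    return SyntheticBackend(spec, 9)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230311)
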
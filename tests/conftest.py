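import numpy as np
import pytest
from hypothesis import settings

from parafold import lattice as LT
from parafold import topology as T

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def topologies_3_6():
    return T.enumerate_topologies(3, 6)


@pytest.fixture(scope="session")
def clash_free_summary(topologies_3_6):
    return T.summarize_topology_set(topologies_3_6, clash_free_only=True)


@pytest.fixture(scope="session")
def l16_annotations():
    return LT.annotate_conformations(LT.enumerate_conformations(16))


@pytest.fixture(scope="session")
def l16_scan(l16_annotations):
    return LT.designability_scan(annotations=l16_annotations)


@pytest.fixture(scope="session")
def l16_reverse_indices(l16_annotations):
    return l16_annotations.conformations.reverse_indices()


@pytest.fixture(scope="session")
def l16_sweep(l16_annotations):
    """Designability results at the swept penalty strengths."""
    return {
        eps: LT.designability_scan(
            annotations=l16_annotations, params=LT.EnergyParams(1.0, eps)
        )
        for eps in (0.1, 0.5, 1.0, 3.0, 4.0)
    }


@pytest.fixture(scope="session")
def l10_sets():
    confs = LT.enumerate_conformations(10)
    return confs, LT.annotate_conformations(confs)
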
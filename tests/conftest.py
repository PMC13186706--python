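import pytest

from mitoribo.fixtures import (
    human_mtdna_like_annotation,
    human_mtdna_like_topology,
    toy_annotation,
)
from mitoribo.simulate import study_conditions


@pytest.fixture(scope="session")
def human_ann():
    return human_mtdna_like_annotation()


@pytest.fixture(scope="session")
def human_topo():
    return human_mtdna_like_topology()


@pytest.fixture(scope="session")
def topo_by_id(human_topo):
    return {t.protein_id: t for t in human_topo}


@pytest.fixture(scope="session")
def study(human_ann, human_topo):
    """Default study-condition dwell models and abundances."""
    return study_conditions(human_ann, human_topo)


@pytest.fixture(scope="session")
def toy_ann():
    return toy_annotation()
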
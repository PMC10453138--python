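import numpy as np
import pytest

from herbauth import SpeciesAssay


@pytest.fixture(scope="session")
def equal_assays():
    """Two-species assay map with equal genome sizes and single-copy targets,
    so mass%, copy% and GE share one scale."""
    return {
        "oregano": SpeciesAssay("oregano", genome_size_1c_pg=1.0,
                                class_label="ingredient"),
        "olive": SpeciesAssay("olive", genome_size_1c_pg=1.0,
                              class_label="adulterant"),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
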
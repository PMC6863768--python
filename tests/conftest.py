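import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from predgwas import PhenotypePanel, PresenceAbsenceMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix() -> PresenceAbsenceMatrix:
    """Six strains, five clusters: one core, one empty, three informative."""
    presence = pd.DataFrame(
        {
            "s1": [True, False, True, False, True],
            "s2": [True, False, True, False, False],
            "s3": [True, False, True, True, False],
            "s4": [True, False, False, True, False],
            "s5": [True, False, False, True, True],
            "s6": [True, False, False, False, False],
        },
        index=["core1", "empty1", "geneA", "geneB", "geneC"],
    )
    return PresenceAbsenceMatrix(presence, {"geneA": "putative protease"})


@pytest.fixture
def tiny_panel() -> PhenotypePanel:
    """Six strains, two prey; one missing assay."""
    zone = pd.DataFrame(
        {
            "preyX": [30.0, 25.0, 20.0, 15.0, 10.0, 5.0],
            "preyY": [12.0, np.nan, 14.0, 11.0, 9.0, 13.0],
        },
        index=["s1", "s2", "s3", "s4", "s5", "s6"],
    )
    return PhenotypePanel(zone)
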
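import numpy as np
import pytest

from polyscaf.catalog import LIBRARY_IDS
from polyscaf.voids import PRINTED_RATIOS, availability_score


@pytest.fixture(scope="session")
def evaluation_rows():
    """Group labels and availability scores for all six libraries.

    Computed once per session: the classification voxelizes 54 tiled
    assemblies at two pitches and dominates the suite runtime.
    """
    rows = {}
    for pid in LIBRARY_IDS:
        score, labels = availability_score(pid)
        rows[pid] = (score, labels)
    return rows


@pytest.fixture(scope="session")
def porosity_fits():
    """Porosity curves and Logistic Power fits for all six libraries."""
    from polyscaf.porosity import fit_logistic_power, porosity_curve

    out = {}
    for pid in LIBRARY_IDS:
        curve = porosity_curve(pid)
        out[pid] = (curve, fit_logistic_power(curve))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120926)
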
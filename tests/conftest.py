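import numpy as np
import pytest

from mrsquant.acquisition import AcquisitionParams
from mrsquant.basis import default_basis, load_basis_library, render_basis


@pytest.fixture(scope="session")
def basis():
    """Full 20-compound basis on the default 7 T grid."""
    return default_basis()


@pytest.fixture(scope="session")
def small_acq():
    return AcquisitionParams(n_points=2048)


@pytest.fixture(scope="session")
def small_basis(small_acq):
    """Six-metabolite basis on a coarser grid for fast fitting tests."""
    keep = {"NAA", "NAAG", "Cr", "Ins", "Glu", "GPC"}
    tpls = [t for t in load_basis_library() if t.name in keep]
    return render_basis(tpls, small_acq)


@pytest.fixture(scope="session")
def ms_lesion_profile():
    """Full MS-lesion concentration profile (mmol/L)."""
    return {
        "Ins": 8.1, "NAA": 8.94, "NAAG": 2.09, "Cr": 4.5, "PCr": 4.0,
        "Glu": 7.5, "Gln": 2.5, "GPC": 1.3, "PCho": 0.6, "GABA": 1.3,
        "Asp": 2.0, "Asc": 1.0, "Ala": 0.5, "Glc": 1.0, "Lac": 0.8,
        "PE": 1.5, "sIns": 0.3, "Tau": 1.5, "GSH": 1.5,
    }
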
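import warnings

import pytest
from hypothesis import settings

import mcfmkm as m

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: (rounded Rn [µm], rounded rd [µm], Rn is DNA-derived) for the bundled lines
TABLE2_EXPECTED = {
    "C3H10T1/2": (4.0, 0.26, False),
    "CHO,CHO-K1": (4.2, 0.27, False),
    "HeLa": (5.6, 0.29, False),
    "HF19": (4.7, 0.29, True),
    "HL-60": (4.6, 0.29, True),
    "M/10": (4.7, 0.29, True),
    "NB1RGB": (5.1, 0.32, False),
    "PDV": (5.1, 0.29, True),
    "RAT-1": (5.0, 0.29, True),
    "SQ20B": (4.5, 0.30, True),
    "T1": (4.7, 0.29, True),
    "TK1": (4.7, 0.29, True),
    "U-87": (4.5, 0.30, True),
    "U-251MG": (4.9, 0.29, True),
}

#: The one bundled line whose photon set admits no non-negative alpha0.
INCONSISTENT_LINES = {"U-251MG"}


@pytest.fixture(scope="session")
def default_grid():
    return m.LinealEnergyGrid.default()


@pytest.fixture(scope="session")
def cell_library():
    return m.load_cell_line_library()


@pytest.fixture(scope="session")
def built_params(cell_library):
    """CellLineParams for every bundled line with a consistent photon set."""
    params = {}
    for name, cfg in cell_library.items():
        if name in INCONSISTENT_LINES:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # derivations must stay in-window
            params[name] = m.build_cell_line(cfg)
    return params


@pytest.fixture(scope="session")
def hela_params(built_params):
    return built_params["HeLa"]
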
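import numpy as np
import pytest

from sorgspec import (
    AlignedDataset,
    BandLibrary,
    EffectModel,
    ReferenceChemistry,
    SpectraSet,
)
from sorgspec.io import ANALYTES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spectra():
    """Five samples x 9 wavelengths with mixed formats."""
    rs = np.random.default_rng(7)
    wn = np.linspace(4000, 10000, 9)
    return SpectraSet(
        sample_ids=[f"S{i}" for i in range(5)],
        wavenumbers=wn,
        absorbance=0.3 + 0.05 * rs.standard_normal((5, 9)),
        sample_format=["whole_grain"] * 3 + ["hulled_flour"] * 2,
    )


@pytest.fixture
def small_reference():
    import pandas as pd

    rs = np.random.default_rng(8)
    values = np.abs(rs.normal(100, 20, size=(5, len(ANALYTES))))
    return ReferenceChemistry(
        sample_ids=[f"S{i}" for i in range(5)],
        analytes=pd.DataFrame(values, columns=list(ANALYTES)),
    )


@pytest.fixture
def toy_library():
    """Matrix-free two-band-per-analyte library on a short grid (pure mixture)."""
    grid = np.linspace(4000, 10000, 120)
    rs = np.random.default_rng(11)
    spectra = {}
    for i, analyte in enumerate(ANALYTES):
        c1, c2 = 4200 + 600 * i, 4500 + 600 * i
        s = np.exp(-0.5 * ((grid - c1) / 150) ** 2) + 0.5 * np.exp(
            -0.5 * ((grid - c2) / 200) ** 2
        )
        spectra[analyte] = 1e-3 * s
    return BandLibrary(grid=grid, spectra=spectra)

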
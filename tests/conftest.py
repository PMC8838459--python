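import numpy as np
import pytest

from mcbp.mc import DetectorSpec
from mcbp.table import IntensityTable, generate_table, monotonize
from mcbp.tissue import compact_benchmark_geometry


@pytest.fixture(scope="session")
def mc_table():
    """Coarse Monte Carlo intensity table on the compact benchmark geometry.

    Built once per session (42-200 mmHg in 20 mmHg steps, 2e5 packets per
    point, full-face transmission detector, common random numbers) and
    shared by the table, pipeline and acceptance tests.
    """
    table = generate_table(
        42, 200, 20, wavelength=940, mode="transmission",
        n_photons=200_000, seed=20,
        geometry=compact_benchmark_geometry(),
        detector=DetectorSpec("transmission", half_width=-1),
    )
    return monotonize(table)


@pytest.fixture()
def synthetic_table():
    """Analytic strictly monotone intensity table (no Monte Carlo noise)."""
    pressures = np.arange(42.0, 201.0, 2.0)
    intensities = 0.05 * np.exp(-pressures / 150.0) + 0.01
    return IntensityTable(
        pressures=pressures, intensities=intensities,
        mc_se=np.zeros_like(pressures), wavelength=940.0,
        mode="transmission", monotone=True,
        provenance={"kind": "synthetic-analytic"},
    )
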
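import numpy as np
import pytest

import dgnrange as dg
from dgnrange.projector import ProjectionGeometry


@pytest.fixture(scope="session")
def beam():
    return dg.default_beam()


@pytest.fixture(scope="session")
def small_spec():
    return dg.BreastSpec(11.29, 3.29, 5.645, 0.20, "top")


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return dg.build_breast(small_spec)


@pytest.fixture(scope="session")
def small_geom(small_phantom):
    return dg.default_geometry(small_phantom)


def parallel_geometry(phantom) -> ProjectionGeometry:
    """Near-parallel beam: source pushed to 1e6 mm so adjacent rays no
    longer share voxels (isolates per-ray logic from ray overlap)."""
    g = dg.default_geometry(phantom)
    return ProjectionGeometry((g.source[0], g.source[1], -1.0e6),
                              g.det_z, g.pixel_pitch, g.npix)


def mono_spectrum(E_keV: float) -> dg.EnergySpectrum:
    return dg.EnergySpectrum(np.array([E_keV]), np.array([1.0]))
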
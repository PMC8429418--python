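"""Shared fixtures: phantoms and synthetic kernels used across test modules.

Heavy artefacts (the 1 mm case-1-like phantom, Monte Carlo kernels) are
session-scoped so they are built once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

import spinepdt as sp
from spinepdt.transport import FluenceKernel, RNGSpec


@pytest.fixture(scope="session")
def case1_vol():
    """Case-1-like phantom at the default 1 mm pitch."""
    return sp.build_vertebra_phantom(sp.PhantomSpec.case1())


@pytest.fixture(scope="session")
def toy_vol():
    """Small deterministic anatomy (21x21x5, 1 mm) with all four tissues."""
    labels = np.full((21, 21, 5), sp.LABELS["muscle"], np.uint8)
    labels[6:15, 4:12, 1:4] = sp.LABELS["bone"]
    labels[8:13, 5:10, 1:4] = sp.LABELS["metastasis"]
    labels[8:13, 16:19, 1:4] = sp.LABELS["spinal_cord"]
    return sp.LabelVolume(labels=labels, spacing=(1, 1, 1), origin=(0, 0, 0))


def make_synthetic_kernel(vol, center, scale=0.05, attenuation=0.35,
                          wavelength_nm=690):
    """Deterministic smooth pseudo-kernel (attenuated point spread) for
    optimizer tests that do not need Monte Carlo transport."""
    xs, ys, zs = vol.voxel_centers_1d()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    R = np.sqrt((X - center[0]) ** 2 + (Y - center[1]) ** 2
                + (Z - center[2]) ** 2) + 0.5
    v = scale * np.exp(-attenuation * R) / R
    return FluenceKernel(values=v, rel_error=None, spacing=vol.spacing,
                         origin=vol.origin, n_packets=0, rng=RNGSpec(0),
                         source=None, wavelength_nm=wavelength_nm)


@pytest.fixture(scope="session")
def toy_kernels(toy_vol):
    """A mirror-symmetric pair of synthetic kernels on ``toy_vol``.

    Attenuation is mild enough that the spinal-cord rows of the anatomy see
    an appreciable dose, so cord constraints/penalties are active.
    """
    k1 = make_synthetic_kernel(toy_vol, (9.0, 7.0, 2.5), attenuation=0.15)
    k2 = FluenceKernel(values=k1.values[::-1].copy(), rel_error=None,
                       spacing=toy_vol.spacing, origin=toy_vol.origin,
                       n_packets=0, rng=RNGSpec(0), source=None,
                       wavelength_nm=690)
    return [k1, k2]


@pytest.fixture(scope="session")
def homogeneous_muscle_vol():
    """Homogeneous 41 mm muscle cube for fast transport checks."""
    n = 41
    labels = np.full((n, n, n), sp.LABELS["muscle"], np.uint8)
    return sp.LabelVolume(labels=labels, spacing=(1, 1, 1),
                          origin=(-n / 2, -n / 2, -n / 2))
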
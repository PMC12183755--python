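"""Shared fixtures: model systems, reaction paths and oracle references."""

import numpy as np
import pytest

from sbg.basis_builder import BuildConfig, build_basis_set
from sbg.fixtures import (DOUBLE_WELL_V_CONST_CM, DvrSpec, dvr_eigenvalues,
                          pseudo_triatomic, synthetic_irc)
from sbg.pes import DoubleWellProvider

SEED = 20250607


@pytest.fixture(scope="session")
def dw1d():
    """1D quartic double well with the default desk-scale parameters."""
    return DoubleWellProvider(1.6e-2, 25.0)


@pytest.fixture(scope="session")
def dw1d_path(dw1d):
    return synthetic_irc(dw1d, step=0.5)


@pytest.fixture(scope="session")
def dw1d_build(dw1d, dw1d_path):
    """9-IRC-basis automatic build on the 1D double well."""
    cfg = BuildConfig(n_irc_bases=9, v_const_wavenumber=DOUBLE_WELL_V_CONST_CM)
    bases, report = build_basis_set(dw1d_path, dw1d, cfg)
    return bases, report, cfg


@pytest.fixture(scope="session")
def dw1d_dvr(dw1d):
    """Grid-oracle reference for the lowest four 1D double-well levels."""
    spec = DvrSpec((-60.0,), (60.0,), (256,))
    return dvr_eigenvalues(
        lambda q: dw1d.evaluate(q, need_hessian=False).energy, spec, 4)


@pytest.fixture(scope="session")
def triatomic():
    return pseudo_triatomic()


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
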
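"""Shared fixtures: small geometries and cached transport runs.

Transport runs are session-scoped so the Monte Carlo cost is paid once per
configuration across the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import phototherm as pt


@pytest.fixture(scope="session")
def small_geom() -> pt.Geometry:
    return pt.Geometry(radius=7.5, height=20.0, n_lateral=30, n_depth=40)


@pytest.fixture(scope="session")
def beam() -> pt.BeamSpec:
    return pt.BeamSpec(power=0.5, beam_radius=5.0)


@pytest.fixture(scope="session")
def blank_medium() -> pt.CompositeOptics:
    return pt.CompositeOptics(mu_a_total=0.01, mu_s_total=0.1, g_eff=0.9, n=1.34)


@pytest.fixture(scope="session")
def absorber_medium() -> pt.CompositeOptics:
    """Blank gel plus a pure-absorber contribution of 0.05 mm^-1."""
    return pt.CompositeOptics(mu_a_total=0.06, mu_s_total=0.1, g_eff=0.9, n=1.34)


@pytest.fixture(scope="session")
def scatterer_medium() -> pt.CompositeOptics:
    """Blank gel plus an isotropic scatterer contribution of 3 mm^-1."""
    return pt.CompositeOptics(
        mu_a_total=0.01, mu_s_total=3.1, g_eff=0.9 * 0.1 / 3.1, n=1.34
    )


@pytest.fixture(scope="session")
def blank_run(small_geom, beam, blank_medium):
    return pt.run_transport(
        blank_medium, small_geom, beam, pt.TransportSettings(n_photons=100_000, seed=301)
    )


@pytest.fixture(scope="session")
def absorber_run(small_geom, beam, absorber_medium):
    return pt.run_transport(
        absorber_medium, small_geom, beam, pt.TransportSettings(n_photons=100_000, seed=302)
    )


@pytest.fixture(scope="session")
def scatterer_run(small_geom, beam, scatterer_medium):
    return pt.run_transport(
        scatterer_medium, small_geom, beam, pt.TransportSettings(n_photons=100_000, seed=303)
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
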
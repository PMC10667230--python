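"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from suturegrowth.geometry import Label, SphericalMap
from suturegrowth.synthetic import SynthConfig, build_true_model, make_template


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig()


@pytest.fixture(scope="session")
def template(default_config):
    return make_template(default_config)


@pytest.fixture(scope="session")
def true_model(default_config):
    """The default generating model: template, anchors, weights, velocities."""
    return build_true_model(default_config)


@pytest.fixture(scope="session")
def small_config():
    """A light configuration for tests that run optimization."""
    return SynthConfig(grid_shape=(16, 12), anchor_spacing_mm=15.0,
                       n_subjects=6, age_max_days=300.0, age_dist="uniform",
                       noise_sd=0.3, seed=7)


@pytest.fixture(scope="session")
def small_model(small_config):
    return build_true_model(small_config)


def sphere_map(n_az=32, n_el=16, radius=1.0, max_elev_deg=60.0,
               suture_col=None):
    """A sphere patch map; optionally one meridian column labeled as a suture
    (metopic) with the two neighboring halves as frontal bones."""
    phi = 2 * np.pi * np.arange(n_az) / n_az
    theta = np.radians(max_elev_deg) * np.arange(n_el) / (n_el - 1)
    P, T = np.meshgrid(phi, theta, indexing="ij")
    coords = radius * np.stack([np.sin(P) * np.cos(T),
                                np.cos(P) * np.cos(T),
                                np.sin(T)], axis=-1)
    lab = np.full((n_az, n_el), int(Label.LF), dtype=np.uint8)
    lab[n_az // 2:, :] = Label.RF
    if suture_col is not None:
        lab[suture_col, :] = Label.M
    return SphericalMap(coords=coords, label=lab, age_days=0.0, subject_id="sphere")


def flat_patch_map(n=8, spacing=1.0, suture_col=3):
    """A flat n x n patch (grid = x/y plane, z = 0) with one vertical suture
    column separating two 'frontal' half-plates.  Used where controlled
    Euclidean distances are needed."""
    x = spacing * np.arange(n)
    X, Y = np.meshgrid(x, x, indexing="ij")
    coords = np.stack([X, Y, np.zeros_like(X)], axis=-1)
    lab = np.full((n, n), int(Label.LF), dtype=np.uint8)
    lab[suture_col + 1:, :] = Label.RF
    lab[suture_col, :] = Label.M
    return SphericalMap(coords=coords, label=lab, age_days=0.0, subject_id="flat")


@pytest.fixture
def flat_map():
    return flat_patch_map()


def mirror_map(smap):
    """Mirror a map left-right: negate x and remap azimuth columns."""
    n_az = smap.grid_shape[0]
    idx = (-np.arange(n_az)) % n_az
    coords = smap.coords[idx].copy()
    coords[..., 0] *= -1
    swap = {Label.LF: Label.RF, Label.RF: Label.LF, Label.LP: Label.RP,
            Label.RP: Label.LP, Label.LC: Label.RC, Label.RC: Label.LC,
            Label.LL: Label.RL, Label.RL: Label.LL}
    lab = smap.label[idx].copy()
    out = lab.copy()
    for a, b in swap.items():
        out[lab == a] = b
    return SphericalMap(coords=coords, label=out, age_days=smap.age_days,
                        subject_id=smap.subject_id + "-mirror")
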
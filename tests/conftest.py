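"""Shared fixtures.

The expensive session fixtures build one head-scale layered-sphere phantom
(95 mm outer radius — roughly an adult head — with the default 6.9 / 6.1 /
2 / 4 mm layers) and run one 10^6-photon Monte Carlo simulation per
injection point: a reference point at the pole plus one point near each
studied source-detector separation.  Everything downstream (3-point maps,
tissue fractions, depth profiles) reuses these grids.
"""

from __future__ import annotations

import numpy as np
import pytest

import nirsens as ns

SPHERE_RADIUS_MM = 95.0
STUDY_SEPARATIONS_MM = (20, 25, 30, 35, 40, 45, 55)
N_PHOTONS = 1_000_000
BASE_SEED = 20260


@pytest.fixture(scope="session")
def optics() -> ns.OpticalProperties:
    return ns.OpticalProperties.default_head()


@pytest.fixture(scope="session")
def head_sphere() -> ns.HeadVolume:
    return ns.build_layered_sphere(SPHERE_RADIUS_MM)


@pytest.fixture(scope="session")
def sphere_points(head_sphere):
    return ns.place_surface_points(head_sphere, spacing=5.0)


@pytest.fixture(scope="session")
def sphere_shells(head_sphere) -> ns.ShellSet:
    return ns.compute_shells(head_sphere, include_core=True)


def pick_pair_points(points, separations):
    """The pole point plus the point nearest each requested chord distance."""
    pos = np.asarray([p.position for p in points])
    ref = points[int(np.argmax(pos[:, 2]))]
    chosen = {}
    d = np.linalg.norm(pos - ref.position, axis=1)
    for s in separations:
        chosen[s] = points[int(np.argmin(np.abs(d - s)))]
    return ref, chosen


@pytest.fixture(scope="session")
def fluence_bank(head_sphere, optics, sphere_points):
    """Normalized 2-point fluence grids: pole source + one per separation."""
    ref, per_sep = pick_pair_points(sphere_points, STUDY_SEPARATIONS_MM)
    grids = {}
    cfg = dict(n_photons=N_PHOTONS, t_max_ns=10.0)
    g, _ = ns.run_mc(head_sphere, optics, ref,
                     config=ns.SimConfig(seed=BASE_SEED, **cfg))
    grids["ref"] = ns.normalize_fluence(g)
    for k, (s, pt) in enumerate(per_sep.items(), start=1):
        g, _ = ns.run_mc(head_sphere, optics, pt,
                         config=ns.SimConfig(seed=BASE_SEED + k, **cfg))
        grids[s] = ns.normalize_fluence(g)
    return grids


@pytest.fixture(scope="session")
def pair_maps(fluence_bank):
    """3-point sensitivity maps, keyed by nominal separation (mm)."""
    maps = {}
    for s in STUDY_SEPARATIONS_MM:
        maps[s] = ns.three_point(fluence_bank["ref"], fluence_bank[s])
    return maps


# --- small, cheap fixtures ------------------------------------------------


@pytest.fixture(scope="session")
def small_slab() -> ns.HeadVolume:
    return ns.build_layered_slab(extent=(40.0, 40.0, 40.0),
                                 thicknesses=(7.0, 6.0, 2.0, 4.0),
                                 voxel_size=2.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
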
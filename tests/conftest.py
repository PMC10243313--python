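"""Shared fixtures: one synthetic audit dataset reused across the suite.

Everything is generated at test time from seeded scenarios; nothing is
stored on disk in the repository.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from vaudit.arrays import arccheck_geometry, delta4_geometry
from vaudit.dose_model import DoseGrid2D, extract_plane
from vaudit.synth import Scenario, make_c_shape_dose, make_film_scan, write_rt_files


@pytest.fixture(scope="session")
def base_scenario() -> Scenario:
    return Scenario(seed=11)


@pytest.fixture(scope="session")
def plan_data(tmp_path_factory, base_scenario):
    """C-shaped planned dose grid with its RT Dose / RT Plan files."""
    out = tmp_path_factory.mktemp("plan")
    grid, plan_info = make_c_shape_dose(base_scenario)
    dose_path, plan_path = write_rt_files(grid, plan_info, out, seed=base_scenario.seed)
    return SimpleNamespace(grid=grid, plan_info=plan_info, dose_path=dose_path, plan_path=plan_path)


@pytest.fixture(scope="session")
def iso_plane(plan_data) -> DoseGrid2D:
    """Axial planned plane at the isocenter, isocenter-origin coordinates."""
    iso = plan_data.plan_info.isocenter
    return extract_plane(plan_data.grid, "axial", iso[2]).recentered(iso[0], iso[1])


@pytest.fixture(scope="session")
def film_files(tmp_path_factory, plan_data, iso_plane, base_scenario):
    """Error-free composite film scan + layout + unset scan."""
    out = tmp_path_factory.mktemp("film")
    tiff, layout, unset = make_film_scan(iso_plane, base_scenario, out)
    return SimpleNamespace(tiff=tiff, layout=layout, unset=unset)


@pytest.fixture(scope="session")
def arccheck():
    return arccheck_geometry()


@pytest.fixture(scope="session")
def delta4():
    return delta4_geometry()


def smooth_field(rng: np.random.Generator, shape=(41, 41), spacing=1.0, sigma=4.0,
                 peak=2.0) -> DoseGrid2D:
    """A smooth random non-negative dose plane spanning [0, peak] Gy."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    f = (f - f.min()) / (f.max() - f.min() + 1e-12)
    return DoseGrid2D(peak * f, origin=(0.0, 0.0), spacing=(spacing, spacing))


def perturbed_copy(plane: DoseGrid2D, rng: np.random.Generator, rel_amp=0.03,
                   sigma=6.0) -> DoseGrid2D:
    """The same plane with a smooth few-percent multiplicative perturbation."""
    p = gaussian_filter(rng.standard_normal(plane.values.shape), sigma, mode="reflect")
    p = rel_amp * p / (np.abs(p).max() + 1e-12)
    return DoseGrid2D(np.clip(plane.values * (1 + p), 0, None), plane.origin, plane.spacing)
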
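"""Shared fixtures: phantom geometry, machine models and rendered images.

All fixtures are generated programmatically; the fast aS500-format panel
(384 x 512) is used wherever full-resolution imaging is not the point.
"""

import numpy as np
import pytest

from arcsag.marker_detection import PhantomGeometry
from arcsag.synthetic_phantom import (
    AcquisitionPlan,
    MachineModel,
    NoiseModel,
    PanelSpec,
    project_markers,
    render_image,
)


@pytest.fixture(scope="session")
def geometry() -> PhantomGeometry:
    return PhantomGeometry()


@pytest.fixture(scope="session")
def small_panel() -> PanelSpec:
    return PanelSpec.as500()


@pytest.fixture(scope="session")
def null_model() -> MachineModel:
    return MachineModel.null()


@pytest.fixture
def make_image(geometry, small_panel):
    """Factory: render one image of a model at an angle on the fast panel."""

    def _make(
        model: MachineModel | None = None,
        theta_deg: float = 0.0,
        *,
        panel: PanelSpec | None = None,
        noise: NoiseModel | None = None,
        seed: int | None = None,
    ):
        model = model or MachineModel.null()
        markers, edges = project_markers(model, theta_deg, geometry)
        rng = np.random.default_rng(seed) if seed is not None else None
        return render_image(
            markers,
            edges,
            geometry=geometry,
            panel=panel or small_panel,
            sdd_mm=model.sdd0_mm,
            gantry_angle_deg=theta_deg,
            noise=noise,
            rng=rng,
        )

    return _make


@pytest.fixture(scope="session")
def integrated_plan() -> AcquisitionPlan:
    return AcquisitionPlan.integrated()
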
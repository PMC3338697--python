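import numpy as np
import pytest

from oligofluct import DetectorModel, PopulationSpec, PsfModel, SimulationSpec

# Standard study conditions: 488 nm / 1.4 NA-class PSF (w0 = 0.2 µm) sampled
# at 0.046 µm pixels, analog PMT with variance law 2 + 0.5*I, 16-bit range.
W0 = 0.2
PIXEL = 0.046
DET_SLOPE = 0.5
DET_INTERCEPT = 2.0
SATURATION = 65535.0


@pytest.fixture(scope="session")
def psf() -> PsfModel:
    return PsfModel(e2_radius=W0, pixel_size=PIXEL)


@pytest.fixture(scope="session")
def detector() -> DetectorModel:
    return DetectorModel(slope=DET_SLOPE, intercept=DET_INTERCEPT, saturation=SATURATION)


def monomer_spec(
    psf: PsfModel,
    n_per_ba: float,
    eps: float,
    shape=(256, 256),
    detector=None,
    background: float = 0.0,
    seed: int = 0,
    oligomer_order: int = 1,
) -> SimulationSpec:
    """Single-population simulation spec with density given per beam area."""
    return SimulationSpec(
        image_shape=shape,
        pixel_size=psf.pixel_size,
        psf=psf,
        populations=(
            PopulationSpec(
                surface_density=n_per_ba / psf.beam_area,
                oligomer_order=oligomer_order,
                per_subunit_brightness=eps,
            ),
        ),
        background=background,
        detector=detector,
        seed=seed,
    )
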
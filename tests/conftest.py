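import numpy as np
import pytest

from vdcyto.detection import Background
from vdcyto.synth import ImagingConfig, SyntheticTruth


@pytest.fixture
def imaging() -> ImagingConfig:
    return ImagingConfig()


@pytest.fixture
def flat_background(imaging) -> Background:
    """Ideal background model: uniform at the configured level, unit noise."""
    shape = (imaging.roi_height_px, imaging.roi_width_px)
    return Background(
        image=np.full(shape, float(imaging.background_level)),
        noise_sd_image=np.full(shape, 1.0),
        noise_sd=1.0,
    )


def place_shape(shape, x_um: float, y_um: float, velocity: float = 0.0,
                contrast: float = 0.45) -> SyntheticTruth:
    """Wrap a BulletShape into a placed SyntheticTruth for rendering."""
    from vdcyto.shapes import (
        deformability,
        polygon_area,
        polygon_centroid,
        polygon_perimeter,
    )

    poly = shape.polygon()
    cx, cy = polygon_centroid(poly)
    poly = poly - [cx, cy] + [x_um, y_um]
    a = polygon_area(poly)
    l = polygon_perimeter(poly)
    return SyntheticTruth(
        polygon=poly,
        area_true=a,
        perimeter_true=l,
        deformability_true=float(deformability(a, l)),
        centroid_true=(x_um, y_um),
        velocity=velocity,
        shape=shape,
        origin_um=(x_um - cx, y_um - cy),
        intensity_contrast=contrast,
    )
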
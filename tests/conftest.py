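import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from relrbl.measure import Calibration, LandmarkPoint, SiteAnnotation

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150908)


def make_site(
    y_inc=2.0,
    y_apex=23.5,
    y_cej=4.0,
    y_ac=11.0,
    mm_per_px=1.0,
    image_id="img1",
    tooth_id="T01",
    aspects=("mesial", "distal"),
    roots=("single",),
):
    """Build a site annotation from axis positions given in mm on a
    1 mm/px image (or scaled through mm_per_px)."""
    scale = 1.0 / mm_per_px
    points = [LandmarkPoint("INC_OCL", x=50.0, y=y_inc * scale)]
    for i, root in enumerate(roots):
        points.append(LandmarkPoint("APEX", x=50.0 + i, y=y_apex * scale, root=root))
    for aspect in aspects:
        x = 40.0 if aspect == "mesial" else 60.0
        points.append(LandmarkPoint("CEJ", x=x, y=y_cej * scale, aspect=aspect))
        points.append(LandmarkPoint("AC", x=x, y=y_ac * scale, aspect=aspect))
    return SiteAnnotation(
        image_id=image_id,
        tooth_id=tooth_id,
        points=tuple(points),
        calibration=Calibration(mm_per_px=mm_per_px),
    )


@pytest.fixture
def simple_site():
    return make_site()
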
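import numpy as np
import pytest

from canalmorph.image_io import ContourSet


@pytest.fixture
def square_annulus_contours() -> ContourSet:
    """Outer square (0,0)-(100,100) with inner square (40,40)-(60,60)."""
    return ContourSet(
        periosteal=[[0, 0], [100, 0], [100, 100], [0, 100]],
        endosteal=[[[40, 40], [60, 40], [60, 60], [40, 60]]],
    )


@pytest.fixture
def circle_annulus_contours() -> ContourSet:
    """Concentric circular annulus, outer r=200 px, inner r=100 px."""
    th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    peri = np.column_stack([220 + 200 * np.cos(th), 220 + 200 * np.sin(th)])
    endo = np.column_stack([220 + 100 * np.cos(th), 220 + 100 * np.sin(th)])
    return ContourSet(periosteal=peri, endosteal=[endo])


def rasterise_disc(shape, cx, cy, r):
    """Pixel-centre rasterisation of a disc (test oracle helper)."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


def make_pore_record(area_mm2, circ=0.9, feret_um=50.0, rid=0,
                     centroid=(10.0, 10.0)):
    """A synthetic PoreRecord with consistent derived fields (25 um spacing)."""
    from canalmorph.pore_analysis import PoreRecord

    return PoreRecord(id=rid, area_mm2=area_mm2, perimeter_um=100.0,
                      circularity=circ, centroid=centroid,
                      eq_diameter_um=2000 * np.sqrt(area_mm2 / np.pi),
                      feret_um=feret_um, n_px=max(1, round(area_mm2 * 1e6 / 625)))
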
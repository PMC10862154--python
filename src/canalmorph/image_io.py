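"""Reading and writing microradiographs, boundary contours and study metadata.

Microradiographs are 8-bit single-channel TIFFs with a known physical pixel
spacing.  16-bit originals (e.g. DICOM exports from a point-projection X-ray
microscope) are converted to 8 bits by a global min-max linear rescale.

Coordinate convention: pixel centres sit at integer coordinates, origin at the
top-left pixel, x increasing rightward, y increasing downward.  All physical
quantities are obtained by multiplying pixel units by ``pixel_spacing_um``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

SITES = ("rib", "tibia", "mc_diaphysis", "mc_metaphysis")
GROUPS = ("exercised", "rested")

#: Columns required in a study metadata table.
METADATA_COLUMNS = (
    "subject_id", "group", "site", "image_path", "roi_path", "pixel_spacing_um",
)


@dataclass
class Microradiograph:
    """A 2-D greyscale microradiograph with physical scale and metadata.

    Parameters
    ----------
    pixels:
        2-D ``uint8`` array of intensities in [0, 255].
    pixel_spacing_um:
        Physical edge length of one pixel, in micrometres (> 0).
    site, subject_id, group:
        Optional study metadata.
    """

    pixels: np.ndarray
    pixel_spacing_um: float
    site: str | None = None
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {self.pixels.dtype}")
        if not self.pixel_spacing_um > 0:
            raise ValueError("pixel_spacing_um must be positive")
        if self.site is not None and self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _as_vertex_array(vertices) -> np.ndarray:
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("a polygon needs an (N, 2) vertex list with N >= 3")
    # drop an explicit closing vertex; shapely closes rings itself
    if np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    if arr.shape[0] < 3:
        raise ValueError("polygon degenerates after removing the closing vertex")
    return arr


@dataclass
class ContourSet:
    """Periosteal and endosteal boundary polygons of one cortical section.

    Vertices are (x, y) pixel coordinates.  The periosteal polygon must be
    simple; every endosteal polygon must be simple and lie strictly inside the
    periosteal polygon.
    """

    periosteal: np.ndarray
    endosteal: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.periosteal = _as_vertex_array(self.periosteal)
        self.endosteal = [_as_vertex_array(e) for e in self.endosteal]
        peri = self.periosteal_polygon()
        if not peri.is_valid:
            raise ValueError("periosteal polygon is self-intersecting or invalid")
        for i, endo in enumerate(self.endosteal_polygons()):
            if not endo.is_valid:
                raise ValueError(f"endosteal polygon {i} is self-intersecting or invalid")
            # strictly inside: interior containment, no boundary contact
            if not (peri.contains(endo) and not peri.exterior.intersects(endo)):
                raise ValueError(
                    f"endosteal polygon {i} is not strictly inside the periosteal polygon"
                )

    def periosteal_polygon(self) -> Polygon:
        return Polygon(self.periosteal)

    def endosteal_polygons(self) -> list[Polygon]:
        return [Polygon(e) for e in self.endosteal]


def convert_16bit_to_8bit(pixels16: np.ndarray) -> np.ndarray:
    """Min-max linear rescale of a 16-bit grid to [0, 255], round half up.

    A constant image maps to all-zero (degenerate range, documented).  The map
    is monotone: x <= y implies f(x) <= f(y).
    """
    arr = np.asarray(pixels16)
    if arr.size == 0:
        raise ValueError("empty input grid")
    lo = int(arr.min())
    hi = int(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    scaled = (arr.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.floor(scaled + 0.5).astype(np.uint8)


def load_microradiograph(
    path,
    pixel_spacing_um: float,
    *,
    site: str | None = None,
    subject_id: str | None = None,
    group: str | None = None,
    allow_conversion: bool = False,
) -> Microradiograph:
    """Read an 8-bit single-channel TIFF and attach physical scale + metadata.

    No intensity rescaling is applied to 8-bit input.  A 16-bit file is only
    accepted with ``allow_conversion=True``, in which case it is min-max
    rescaled by :func:`convert_16bit_to_8bit`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pixels = tifffile.imread(path)
    if pixels.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {pixels.shape}")
    if pixels.dtype != np.uint8:
        if pixels.dtype == np.uint16 and allow_conversion:
            pixels = convert_16bit_to_8bit(pixels)
        else:
            raise ValueError(
                f"{path}: expected 8-bit data, got {pixels.dtype}; "
                "pass allow_conversion=True for 16-bit input"
            )
    return Microradiograph(pixels, pixel_spacing_um, site=site,
                           subject_id=subject_id, group=group)


def load_dicom_16bit(path) -> np.ndarray:
    """Read the pixel array of a 16-bit single-frame DICOM (optional input)."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = np.asarray(ds.pixel_array)
    if arr.ndim != 2:
        raise ValueError(f"{path}: multi-frame or multi-channel DICOM not supported")
    return arr


def save_microradiograph(path, micro: Microradiograph) -> None:
    """Write an 8-bit single-plane TIFF (lossless round trip)."""
    tifffile.imwrite(str(path), micro.pixels, photometric="minisblack")


def load_contours(path) -> ContourSet:
    """Read a JSON contour file.

    Dialect: ``{"periosteal": [[x, y], ...], "endosteal": [[[x, y], ...], ...]}``
    with vertices in pixel coordinates (origin top-left, x rightward, y down).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        data = json.load(fh)
    if "periosteal" not in data:
        raise ValueError(f"{path}: missing 'periosteal' polygon")
    endo = data.get("endosteal", [])
    return ContourSet(periosteal=data["periosteal"], endosteal=list(endo))


def save_contours(path, contours: ContourSet) -> None:
    data = {
        "periosteal": contours.periosteal.tolist(),
        "endosteal": [e.tolist() for e in contours.endosteal],
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def load_metadata(path) -> pd.DataFrame:
    """Read a study metadata CSV and validate its columns and values."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata table is missing columns: {missing}")
    if df.empty:
        raise ValueError("metadata table has no rows")
    bad_groups = set(df["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown groups in metadata: {sorted(bad_groups)}")
    bad_sites = set(df["site"]) - set(SITES)
    if bad_sites:
        raise ValueError(f"unknown sites in metadata: {sorted(bad_sites)}")
    if not (df["pixel_spacing_um"] > 0).all():
        raise ValueError("pixel_spacing_um must be positive")
    return df
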
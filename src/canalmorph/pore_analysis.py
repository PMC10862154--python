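"""Pore extraction, measurement, filtering and remodelling-stage classification.

Individual pores are 8-connected components of the binary pore phase.  Each
component is measured after filling interior holes (a canal with a central
bone island counts its full lumen): area as pixel count x spacing^2, perimeter
as the length of the 8-connected outer boundary chain (edge steps = spacing,
diagonal steps = spacing*sqrt(2)), circularity as 4*pi*A/P^2 clipped at 1.0
(digitisation can push the ratio above 1 for tiny particles).

Retention filters follow the study conventions: circularity within
[0.3, 1.0] and area strictly greater than 0.002 mm^2; smaller canals are
mature Haversian canals and are excluded from remodelling analysis.  Large
(> 600 um wide) irregular pores hugging the endosteal margin represent the
transition to cancellous bone and are flagged by a width-plus-proximity rule.

Canal classes by cross-sectional area Ca.Ar:
  mature        Ca.Ar <= 0.002 mm^2   (finished Haversian canal)
  closing_cone  0.002 < Ca.Ar <= 0.04 (infilling canal)
  cutting_cone  Ca.Ar > 0.04          (active resorption space)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure as skmeasure

from canalmorph.image_io import ContourSet, Microradiograph
from canalmorph.morphometry import canal_diameter

_SQRT2 = np.sqrt(2.0)

# clockwise Moore neighbourhood in (row, col), starting due north
_NEIGH = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


@dataclass(frozen=True)
class FilterConfig:
    """Retention and exclusion thresholds for detected pores."""

    circ_min: float = 0.3
    circ_max: float = 1.0
    area_min_mm2: float = 0.002
    cutting_min_mm2: float = 0.04
    endosteal_width_um: float = 600.0
    endosteal_margin_um: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.circ_min <= self.circ_max <= 1:
            raise ValueError("need 0 <= circ_min <= circ_max <= 1")
        if not 0 < self.area_min_mm2 < self.cutting_min_mm2:
            raise ValueError("need 0 < area_min_mm2 < cutting_min_mm2")


@dataclass
class PoreRecord:
    """One detected pore with its measurements and exclusion flags."""

    id: int
    area_mm2: float
    perimeter_um: float
    circularity: float
    centroid: tuple[float, float]  # (x, y) pixel coordinates
    eq_diameter_um: float
    feret_um: float
    n_px: int
    canal_class: str = "mature"
    excluded_by: tuple[str, ...] = ()
    boundary_px: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def retained(self) -> bool:
        return len(self.excluded_by) == 0


def classify_canal(area_mm2: float, config: FilterConfig | None = None) -> str:
    """Map a canal cross-sectional area to its remodelling stage."""
    if not area_mm2 > 0:
        raise ValueError("canal area must be positive")
    cfg = config or FilterConfig()
    if area_mm2 <= cfg.area_min_mm2:
        return "mature"
    if area_mm2 <= cfg.cutting_min_mm2:
        return "closing_cone"
    return "cutting_cone"


def label_pores(pore_grid: np.ndarray) -> list[np.ndarray]:
    """8-connected components of a binary grid as (N, 2) row/col index arrays.

    Deterministic ordering: by raster position of each component's
    topmost-leftmost pixel.
    """
    grid = np.asarray(pore_grid, bool)
    labels, n = skmeasure.label(grid, connectivity=2, return_num=True)
    if n == 0:
        return []
    comps = []
    for lab in range(1, n + 1):
        pts = np.argwhere(labels == lab)
        comps.append(pts)
    comps.sort(key=lambda p: (int(p[0, 0]) * grid.shape[1] + int(p[0, 1])))
    return comps


def _boundary_chain_length(patch: np.ndarray) -> float:
    """Length of the 8-connected outer boundary chain (Moore tracing).

    Edge steps count 1, diagonal steps sqrt(2); the chain of a 1-px-wide
    feature runs down one side and back the other.  A single pixel has a
    degenerate chain of length 0.
    """
    m = np.pad(np.asarray(patch, bool), 1)
    fg = np.argwhere(m)
    if len(fg) == 1:
        return 0.0
    start = (int(fg[0, 0]), int(fg[0, 1]))
    back = (start[0], start[1] - 1)  # background: start is topmost-leftmost
    cur = start
    first_move = None
    length = 0.0
    while True:
        db = (back[0] - cur[0], back[1] - cur[1])
        i = _NEIGH.index(db)
        nxt = None
        for k in range(1, 9):
            d = _NEIGH[(i + k) % 8]
            cand = (cur[0] + d[0], cur[1] + d[1])
            if m[cand]:
                dprev = _NEIGH[(i + k - 1) % 8]
                back = (cur[0] + dprev[0], cur[1] + dprev[1])
                nxt = cand
                break
        if nxt is None:  # isolated pixel
            return 0.0
        move = (cur, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break
        length += _SQRT2 if (cur[0] != nxt[0] and cur[1] != nxt[1]) else 1.0
        cur = nxt
    return length


def _boundary_pixels(patch: np.ndarray) -> np.ndarray:
    """Pixels of the patch that touch the background (4-connected erosion rim)."""
    p = np.asarray(patch, bool)
    eroded = ndimage.binary_erosion(p, structure=ndimage.generate_binary_structure(2, 1))
    return np.argwhere(p & ~eroded)


def _max_feret_px(points: np.ndarray) -> float:
    """Maximum caliper (Feret) diameter of a pixel-coordinate point set."""
    if len(points) < 2:
        return 0.0
    pts = points.astype(float)
    if len(pts) > 3:
        try:
            from scipy.spatial import ConvexHull

            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (collinear) sets fall through to brute force
            pass
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def measure_pore(component: np.ndarray, pixel_spacing_um: float,
                 pore_id: int = 0) -> PoreRecord:
    """Measure one connected component (row/col index array) in physical units."""
    pts = np.asarray(component, dtype=int)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("component must be a non-empty (N, 2) index array")
    r0, c0 = pts.min(axis=0)
    r1, c1 = pts.max(axis=0)
    patch = np.zeros((r1 - r0 + 3, c1 - c0 + 3), bool)
    patch[pts[:, 0] - r0 + 1, pts[:, 1] - c0 + 1] = True
    patch = ndimage.binary_fill_holes(patch)

    filled = np.argwhere(patch)
    n_px = len(filled)
    s = pixel_spacing_um
    area_mm2 = n_px * s * s * 1e-6
    chain_px = _boundary_chain_length(patch)
    perimeter_um = chain_px * s
    if perimeter_um > 0:
        circularity = min(1.0, 4.0 * np.pi * n_px / chain_px**2)
    else:
        circularity = 1.0  # degenerate tiny particle
    boundary = _boundary_pixels(patch)
    feret_um = _max_feret_px(boundary) * s
    # back to global coordinates, (x, y) = (col, row)
    cy = filled[:, 0].mean() + r0 - 1
    cx = filled[:, 1].mean() + c0 - 1
    boundary_global = boundary + np.array([r0 - 1, c0 - 1])
    return PoreRecord(
        id=pore_id,
        area_mm2=area_mm2,
        perimeter_um=perimeter_um,
        circularity=float(circularity),
        centroid=(float(cx), float(cy)),
        eq_diameter_um=canal_diameter(area_mm2),
        feret_um=feret_um,
        n_px=n_px,
        canal_class=classify_canal(area_mm2),
        boundary_px=boundary_global,
    )


def filter_pores(records: list[PoreRecord],
                 config: FilterConfig | None = None) -> list[PoreRecord]:
    """Apply circularity and minimum-area retention filters.

    A pore is retained iff circ_min <= circularity <= circ_max and
    area > area_min_mm2 (strict); otherwise it is flagged with the first
    failing criterion.  Endosteal flags set elsewhere are preserved
    (exclusions are additive); measured values never change, and the
    operation is idempotent.
    """
    cfg = config or FilterConfig()
    out = []
    for rec in records:
        flags = tuple(f for f in rec.excluded_by if f == "endosteal")
        if not (cfg.circ_min <= rec.circularity <= cfg.circ_max):
            flags = ("circularity",) + flags
        elif not rec.area_mm2 > cfg.area_min_mm2:
            flags = ("min_area",) + flags
        out.append(dataclasses.replace(rec, excluded_by=flags,
                                       canal_class=classify_canal(rec.area_mm2, cfg)))
    return out


def exclude_endosteal(records: list[PoreRecord], contours: ContourSet,
                      config: FilterConfig | None = None,
                      manual_ids: set[int] | None = None) -> list[PoreRecord]:
    """Flag wide pores hugging the endosteal margin (cancellous transition).

    A pore is flagged iff its maximum Feret width exceeds
    ``endosteal_width_um`` and its boundary comes within
    ``endosteal_margin_um`` of an endosteal contour.  ``manual_ids`` allows an
    explicit per-id exclusion list for exact replication of a manual
    segmentation.  Flags add to any existing exclusion.
    """
    cfg = config or FilterConfig()
    endos = [Polygon(e).exterior for e in contours.endosteal]
    manual_ids = manual_ids or set()
    out = []
    for rec in records:
        flagged = rec.id in manual_ids
        if not flagged and endos and rec.feret_um > cfg.endosteal_width_um:
            margin_px = cfg.endosteal_margin_um / _spacing_from_record(rec, cfg)
            flagged = _near_any_contour(rec, endos, margin_px)
        if flagged and "endosteal" not in rec.excluded_by:
            out.append(dataclasses.replace(rec, excluded_by=rec.excluded_by + ("endosteal",)))
        else:
            out.append(rec)
    return out


def _spacing_from_record(rec: PoreRecord, cfg: FilterConfig) -> float:
    # spacing recoverable from the record itself: area_mm2 = n_px * s^2 * 1e-6
    return float(np.sqrt(rec.area_mm2 * 1e6 / rec.n_px))


def _near_any_contour(rec: PoreRecord, exteriors, margin_px: float) -> bool:
    import shapely

    if rec.boundary_px is None:
        pts = np.array([[rec.centroid[1], rec.centroid[0]]])
    else:
        pts = rec.boundary_px
    xs = pts[:, 1].astype(float)
    ys = pts[:, 0].astype(float)
    for ext in exteriors:
        d = shapely.distance(ext, shapely.points(xs, ys))
        if np.min(d) <= margin_px:
            return True
    return False


def analyze_section(
    micro: Microradiograph,
    contours: ContourSet,
    config: FilterConfig | None = None,
    side: str = "pores_below",
    full_frame: bool = False,
):
    """Run the per-section chain mask -> threshold -> label -> measure -> flag.

    Returns ``(records, cortical_mask, threshold_result)`` with exclusion
    flags fully populated.
    """
    from canalmorph.segmentation import binarize_pores, cortical_mask, threshold_section

    cfg = config or FilterConfig()
    cmask = cortical_mask(contours, micro.shape, micro.pixel_spacing_um)
    thr = threshold_section(micro, cmask, side=side, full_frame=full_frame)
    pores = binarize_pores(micro, cmask, thr.level, side=thr.side)
    comps = label_pores(pores)
    records = [measure_pore(c, micro.pixel_spacing_um, pore_id=i)
               for i, c in enumerate(comps)]
    records = filter_pores(records, cfg)
    records = exclude_endosteal(records, contours, cfg)
    return records, cmask, thr


def records_to_frame(records: list[PoreRecord], subject_id: str | None = None,
                     site: str | None = None, group: str | None = None) -> pd.DataFrame:
    """Tabulate pore records in the pores.csv dialect."""
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "subject_id": subject_id,
            "site": site,
            "group": group,
            "area_mm2": r.area_mm2,
            "perimeter_um": r.perimeter_um,
            "circularity": r.circularity,
            "x_px": r.centroid[0],
            "y_px": r.centroid[1],
            "eq_diameter_um": r.eq_diameter_um,
            "canal_class": r.canal_class,
            "excluded_by": ";".join(r.excluded_by) if r.excluded_by else "none",
        })
    cols = ["id", "subject_id", "site", "group", "area_mm2", "perimeter_um",
            "circularity", "x_px", "y_px", "eq_diameter_um", "canal_class",
            "excluded_by"]
    return pd.DataFrame(rows, columns=cols)
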
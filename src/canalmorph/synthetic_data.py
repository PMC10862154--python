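"""Seeded synthetic microradiographs with per-pore ground truth.

The generator emulates the structure of transverse cortical-bone
microradiographs: a radiopaque annular (or half-annular) cortex containing
radiolucent near-circular canals of the three remodelling size classes,
elongated low-circularity Volkmann-like distractors, large irregular pores at
the endosteal margin, a multiplicative background-intensity gradient (uneven
sample thickness) and additive Gaussian noise.  Every stamped pore is logged
in a truth table, so each pipeline stage and the full group comparison can be
tested against known ground truth.

A complete two-group study (exercised n=6 vs rested n=6, four skeletal sites)
can be generated with per-group canal densities per mm^2 matching the study's
summary tables; section geometry is scaled down (cortical areas of roughly
9-46 mm^2 per site) to keep full-cohort runs cheap while preserving densities,
size laws and effect directions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from canalmorph.image_io import ContourSet, Microradiograph, save_contours, save_microradiograph
from canalmorph.segmentation import cortical_mask

#: (median_mm2, geometric SD, lower bound, upper bound) of the truncated
#: log-normal canal-area law per remodelling class.  Bounds sit inside the
#: class intervals so rasterisation jitter cannot flip a class.
AREA_LAWS = {
    "mature": (0.0008, 1.6, 0.0003, 0.0018),
    "closing_cone": (0.0055, 1.9, 0.003, 0.035),
    "cutting_cone": (0.06, 1.35, 0.045, 0.12),
}

_VOLKMANN_LAW = (0.010, 1.5, 0.005, 0.03)


@dataclass
class SyntheticSectionSpec:
    """Parameters of one synthetic section."""

    site: str = "tibia"
    pixel_spacing_um: float = 25.0
    outer_radius_mm: float = 5.0
    inner_radius_mm: float = 3.2
    half: bool = False  # half-annulus (metaphyseal half-section)
    matrix_intensity: float = 180.0
    pore_intensity: float = 60.0
    background_intensity: float = 25.0
    background_gradient: float = 0.1  # peak-to-peak fractional ramp across x
    noise_sd: float = 3.0
    n_mature: int = 0
    n_closing: int = 0
    n_cutting: int = 0
    n_volkmann: int = 0
    n_endosteal: int = 0
    volkmann_aspect: float = 9.0
    endosteal_width_um: float = 800.0
    margin_px: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_mm < self.outer_radius_mm:
            raise ValueError("need 0 < inner radius < outer radius")
        if self.pore_intensity == self.matrix_intensity:
            raise ValueError("pore and matrix intensities must differ")
        for v in (self.matrix_intensity, self.pore_intensity, self.background_intensity):
            if not 0 <= v <= 255:
                raise ValueError("intensities must lie in [0, 255]")
        if min(self.n_mature, self.n_closing, self.n_cutting,
               self.n_volkmann, self.n_endosteal) < 0:
            raise ValueError("pore counts must be non-negative")


@dataclass
class SyntheticGroundTruth:
    """Per-pore truth table and per-section truth for one synthetic section."""

    truth: pd.DataFrame
    ct_ar_mm2: float
    spec: SyntheticSectionSpec
    seed: int


def _circle_vertices(cx: float, cy: float, r: float, n: int = 128,
                     start: float = 0.0, stop: float = 2 * np.pi) -> np.ndarray:
    th = np.linspace(start, stop, n, endpoint=stop - start < 2 * np.pi - 1e-9)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def _section_contours(spec: SyntheticSectionSpec):
    """Contours, frame shape and centre in pixel coordinates."""
    s = spec.pixel_spacing_um
    r_out = spec.outer_radius_mm * 1000.0 / s
    r_in = spec.inner_radius_mm * 1000.0 / s
    m = spec.margin_px
    c = r_out + m
    size = int(np.ceil(2 * (r_out + m))) + 1
    if not spec.half:
        peri = _circle_vertices(c, c, r_out)
        endo = _circle_vertices(c, c, r_in)
    else:
        # right half-section: each ring closes itself with a vertical chord;
        # the endosteal chord sits at x = c + 3 so it stays strictly inside
        peri = _circle_vertices(c, c, r_out, n=96, start=-np.pi / 2, stop=np.pi / 2)
        th = np.arcsin(min(0.99, 3.0 / r_in))
        endo = _circle_vertices(c, c, r_in, n=64,
                                start=-np.pi / 2 + th, stop=np.pi / 2 - th)
    return ContourSet(periosteal=peri, endosteal=[endo]), (size, size), (c, c)


def _draw_area(law, rng: np.random.Generator) -> float:
    median, gsd, lo, hi = law
    sigma = np.log(gsd)
    for _ in range(64):
        a = median * np.exp(rng.normal(0.0, sigma))
        if lo <= a <= hi:
            return float(a)
    return float(np.clip(a, lo, hi))


def _stamp_disc(shape, cx: float, cy: float, r_px: float) -> np.ndarray:
    x0, x1 = int(np.floor(cx - r_px)) - 1, int(np.ceil(cx + r_px)) + 2
    y0, y1 = int(np.floor(cy - r_px)) - 1, int(np.ceil(cy + r_px)) + 2
    yy, xx = np.mgrid[max(0, y0):min(shape[0], y1), max(0, x0):min(shape[1], x1)]
    hit = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
    pts = np.column_stack([yy[hit], xx[hit]])
    if len(pts) == 0:  # sub-pixel pore: stamp the nearest pixel
        pts = np.array([[int(round(cy)), int(round(cx))]])
    return pts


def _stamp_ellipse(shape, cx, cy, a_px, b_px, phi) -> np.ndarray:
    r = a_px + 1
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
    yy, xx = np.mgrid[max(0, y0):min(shape[0], y1), max(0, x0):min(shape[1], x1)]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    hit = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return np.column_stack([yy[hit], xx[hit]])


def _place_in_cortex(rng, spec, centre, r_in, r_out, r_eff, placed,
                     max_tries: int = 500):
    """Centre for a pore of effective radius ``r_eff`` fully inside the cortex,
    at least ~3 px clear of both contours and of every previously placed pore."""
    cx0, cy0 = centre
    clear = 3.0
    lo = r_in + r_eff + clear
    hi = r_out - r_eff - clear
    if hi <= lo:
        raise RuntimeError("cortex too thin for the requested pore size")
    for _ in range(max_tries):
        rho = np.sqrt(rng.uniform(lo**2, hi**2))
        th = rng.uniform(-np.pi / 2, np.pi / 2) if spec.half else rng.uniform(0, 2 * np.pi)
        x, y = cx0 + rho * np.cos(th), cy0 + rho * np.sin(th)
        if spec.half and x < cx0 + r_eff + clear + 3.0:
            continue
        if all(np.hypot(x - px, y - py) > r_eff + pr + clear for px, py, pr in placed):
            return x, y
    raise RuntimeError("could not place pore without overlap after bounded retries")


def generate_section(spec: SyntheticSectionSpec, seed: int):
    """Render one synthetic section.

    Returns ``(Microradiograph, ContourSet, SyntheticGroundTruth)``.
    Identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(seed)
    s = spec.pixel_spacing_um
    contours, shape, centre = _section_contours(spec)
    cmask = cortical_mask(contours, shape, s)
    r_out = spec.outer_radius_mm * 1000.0 / s
    r_in = spec.inner_radius_mm * 1000.0 / s

    img = np.full(shape, spec.background_intensity, dtype=float)
    img[cmask.mask] = spec.matrix_intensity

    placed: list[tuple[float, float, float]] = []
    rows = []

    def log_pore(pts, x, y, area_mm2, cls, volkmann=False, endosteal=False):
        inside = cmask.mask[pts[:, 0], pts[:, 1]]
        pts = pts[inside]
        img[pts[:, 0], pts[:, 1]] = spec.pore_intensity
        rows.append({
            "x_px": x, "y_px": y, "area_mm2": area_mm2,
            "area_px": int(len(pts)), "true_class": cls,
            "volkmann": volkmann, "endosteal": endosteal,
        })

    # endosteal macro-pores first (largest): centred on the endosteal contour
    for _ in range(spec.n_endosteal):
        rb = spec.endosteal_width_um / 2.0 / s
        th = (rng.uniform(-np.pi / 3, np.pi / 3) if spec.half
              else rng.uniform(0, 2 * np.pi))
        x = centre[0] + r_in * np.cos(th)
        y = centre[1] + r_in * np.sin(th)
        pts_list = [_stamp_disc(shape, x, y, rb)]
        # lobes along the tangent make the outline irregular
        tx, ty = -np.sin(th), np.cos(th)
        for sgn in (-1.0, 1.0):
            lob = rng.uniform(0.4, 0.6) * rb
            pts_list.append(_stamp_disc(shape, x + sgn * 0.8 * rb * tx,
                                        y + sgn * 0.8 * rb * ty, lob))
        pts = np.unique(np.vstack(pts_list), axis=0)
        area = np.pi * (rb * s) ** 2 * 1e-6
        log_pore(pts, x, y, area, "cutting_cone", endosteal=True)
        placed.append((x, y, 2.0 * rb))

    for cls, n in (("cutting_cone", spec.n_cutting),
                   ("closing_cone", spec.n_closing),
                   ("mature", spec.n_mature)):
        for _ in range(n):
            area = _draw_area(AREA_LAWS[cls], rng)
            r_px = 1000.0 * np.sqrt(area / np.pi) / s
            x, y = _place_in_cortex(rng, spec, centre, r_in, r_out, r_px, placed)
            pts = _stamp_disc(shape, x, y, r_px)
            log_pore(pts, x, y, area, cls)
            placed.append((x, y, r_px))

    for _ in range(spec.n_volkmann):
        area = _draw_area(_VOLKMANN_LAW, rng)
        area_px = area * 1e6 / s**2
        a_px = np.sqrt(area_px * spec.volkmann_aspect / np.pi)
        b_px = max(a_px / spec.volkmann_aspect, 0.8)
        phi = rng.uniform(0, np.pi)
        x, y = _place_in_cortex(rng, spec, centre, r_in, r_out, a_px, placed)
        pts = _stamp_ellipse(shape, x, y, a_px, b_px, phi)
        cls = ("cutting_cone" if area > 0.04
               else "closing_cone" if area > 0.002 else "mature")
        log_pore(pts, x, y, area, cls, volkmann=True)
        placed.append((x, y, a_px))

    # uneven sample thickness: multiplicative ramp across the frame
    if spec.background_gradient > 0:
        g = spec.background_gradient
        ramp = 1.0 - g / 2.0 + g * np.arange(shape[1]) / max(1, shape[1] - 1)
        img = img * ramp[None, :]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=shape)
    pixels = np.floor(np.clip(img, 0, 255) + 0.5).astype(np.uint8)

    cols = ["x_px", "y_px", "area_mm2", "area_px", "true_class", "volkmann",
            "endosteal"]
    truth = pd.DataFrame(rows, columns=cols)
    micro = Microradiograph(pixels, s, site=spec.site)
    gt = SyntheticGroundTruth(truth=truth, ct_ar_mm2=cmask.area_mm2,
                              spec=spec, seed=seed)
    return micro, contours, gt


def truth_morphometry(truth: pd.DataFrame, ct_ar_mm2: float,
                      selection: str = "combined") -> dict:
    """Truth-derived section indices: canals only (no distractors/endosteal)."""
    canals = truth[~truth["volkmann"] & ~truth["endosteal"]]
    if selection == "combined":
        sel = canals[canals["true_class"].isin(["closing_cone", "cutting_cone"])]
    elif selection == "cutting_only":
        sel = canals[canals["true_class"] == "cutting_cone"]
    else:
        raise ValueError(f"unknown selection {selection!r}")
    n = len(sel)
    tt = float(sel["area_mm2"].sum())
    return {"Ct_Ar_mm2": ct_ar_mm2, "N_Ca": n, "Tt_Ca_Ar_mm2": tt,
            "N_Ca_per_Ct_Ar": n / ct_ar_mm2, "Tt_Ca_Ar_per_Ct_Ar": tt / ct_ar_mm2}


# ---------------------------------------------------------------------------
# study-level generation

@dataclass
class SiteParams:
    """Geometry and per-group canal densities (per mm^2) for one site."""

    pixel_spacing_um: float
    outer_radius_mm: float
    inner_radius_mm: float
    half: bool
    combined_density: dict  # group -> canals with Ca.Ar > 0.002 per mm^2
    cutting_density: dict   # group -> canals with Ca.Ar > 0.04 per mm^2
    mature_density: float = 0.5
    n_volkmann: int = 3
    n_endosteal: int = 1

    def analytic_ct_ar_mm2(self) -> float:
        a = np.pi * (self.outer_radius_mm**2 - self.inner_radius_mm**2)
        return float(a / 2 if self.half else a)


def default_site_params() -> dict[str, SiteParams]:
    """Scaled-down site geometries with the study's printed group densities."""
    return {
        "rib": SiteParams(10.0, 2.5, 1.5, False,
                          {"exercised": 2.82, "rested": 3.27},
                          {"exercised": 0.04, "rested": 0.06}),
        "tibia": SiteParams(25.0, 5.0, 3.2, False,
                            {"exercised": 1.86, "rested": 2.21},
                            {"exercised": 0.02, "rested": 0.06}),
        "mc_diaphysis": SiteParams(25.0, 4.5, 2.8, False,
                                   {"exercised": 1.77, "rested": 1.92},
                                   {"exercised": 0.02, "rested": 0.11}),
        "mc_metaphysis": SiteParams(16.7, 4.0, 2.6, True,
                                    {"exercised": 2.03, "rested": 2.91},
                                    {"exercised": 0.014, "rested": 0.26}),
    }


@dataclass
class StudyDesign:
    """Design of a synthetic two-group, multi-site study."""

    sites: dict[str, SiteParams] = field(default_factory=default_site_params)
    n_per_group: int = 6
    drop_missing: bool = False  # drop rested subject 11's tibia + mc_diaphysis
    count_model: str = "poisson"  # or "bounded" (deterministic +/-10 % jitter)
    subject_sigma_log: float = 0.2  # between-subject log-normal density factor
    noise_sd: float = 3.0
    background_gradient: float = 0.1


def separation_design(sites=("mc_diaphysis", "mc_metaphysis")) -> StudyDesign:
    """A study constructed with complete rested/exercised separation.

    Bounded counts (no Poisson overlap) and no subject heterogeneity make
    every rested section's cutting-cone count exceed every exercised one at
    the selected sites, which forces U = 0 downstream.
    """
    params = {k: v for k, v in default_site_params().items() if k in sites}
    return StudyDesign(sites=params, count_model="bounded", subject_sigma_log=0.0)


@dataclass
class SectionBundle:
    subject_id: str
    group: str
    site: str
    micro: Microradiograph
    contours: ContourSet
    ground_truth: SyntheticGroundTruth


@dataclass
class StudyData:
    """A generated cohort: sections plus the design and master seed."""

    sections: list[SectionBundle]
    design: StudyDesign
    seed: int

    def write(self, outdir) -> Path:
        """Emit TIFFs, contour JSONs, truth.csv and metadata.csv; return the
        metadata path (the pipeline's entry point)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta_rows, truth_frames = [], []
        for b in self.sections:
            stem = f"{b.subject_id}_{b.site}"
            save_microradiograph(outdir / f"{stem}.tif", b.micro)
            save_contours(outdir / f"{stem}.roi.json", b.contours)
            t = b.ground_truth.truth.copy()
            t.insert(0, "subject_id", b.subject_id)
            t.insert(1, "site", b.site)
            truth_frames.append(t)
            meta_rows.append({
                "subject_id": b.subject_id, "group": b.group, "site": b.site,
                "image_path": f"{stem}.tif", "roi_path": f"{stem}.roi.json",
                "pixel_spacing_um": b.micro.pixel_spacing_um,
            })
        pd.concat(truth_frames, ignore_index=True).to_csv(outdir / "truth.csv",
                                                          index=False)
        meta = pd.DataFrame(meta_rows)
        meta_path = outdir / "metadata.csv"
        meta.to_csv(meta_path, index=False)
        return meta_path


def _subject_counts(design: StudyDesign, params: SiteParams, group: str,
                    factor: float, rng) -> tuple[int, int, int]:
    area = params.analytic_ct_ar_mm2()
    closing_d = max(0.0, params.combined_density[group] - params.cutting_density[group])
    lam = (params.cutting_density[group] * area * factor,
           closing_d * area * factor,
           params.mature_density * area)
    if design.count_model == "poisson":
        return tuple(int(rng.poisson(v)) for v in lam)
    if design.count_model == "bounded":
        return tuple(int(round(v * rng.uniform(0.9, 1.1))) for v in lam)
    raise ValueError("count_model must be 'poisson' or 'bounded'")


def generate_study(design: StudyDesign | None = None, seed: int = 0) -> StudyData:
    """Generate a complete synthetic study, deterministic by seed."""
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    subjects = ([(f"E{i + 1:02d}", "exercised") for i in range(design.n_per_group)]
                + [(f"R{i + 1 + design.n_per_group:02d}", "rested")
                   for i in range(design.n_per_group)])
    sections = []
    for subject_id, group in subjects:
        factor = (float(np.exp(rng.normal(0.0, design.subject_sigma_log)))
                  if design.subject_sigma_log > 0 else 1.0)
        for site, params in design.sites.items():
            if (design.drop_missing and group == "rested"
                    and subject_id.endswith("11")
                    and site in ("tibia", "mc_diaphysis")):
                continue
            n_cut, n_close, n_mat = _subject_counts(design, params, group,
                                                    factor, rng)
            spec = SyntheticSectionSpec(
                site=site, pixel_spacing_um=params.pixel_spacing_um,
                outer_radius_mm=params.outer_radius_mm,
                inner_radius_mm=params.inner_radius_mm, half=params.half,
                n_mature=n_mat, n_closing=n_close, n_cutting=n_cut,
                n_volkmann=params.n_volkmann, n_endosteal=params.n_endosteal,
                noise_sd=design.noise_sd,
                background_gradient=design.background_gradient,
            )
            sec_seed = int(rng.integers(2**31))
            micro, contours, gt = generate_section(spec, sec_seed)
            micro = dataclasses.replace(micro, subject_id=subject_id, group=group)
            sections.append(SectionBundle(subject_id, group, site, micro,
                                          contours, gt))
    return StudyData(sections=sections, design=design, seed=seed)


# ---------------------------------------------------------------------------
# fast index-level sampling (no rasterisation) for statistical checks

def sample_study_indices(design: StudyDesign | None = None, seed: int = 0,
                         site: str = "mc_metaphysis") -> pd.DataFrame:
    """Per-section morphometric indices drawn straight from the count/size laws.

    The group comparison operates on section indices, so statistical
    properties of the pipeline's comparison (e.g. its null behaviour) can be
    studied without rendering images.  Returns a sections table with both
    selections for one site.
    """
    design = design or StudyDesign()
    params = design.sites[site]
    rng = np.random.default_rng(seed)
    area = params.analytic_ct_ar_mm2()
    rows = []
    subjects = ([(f"E{i + 1:02d}", "exercised") for i in range(design.n_per_group)]
                + [(f"R{i + 7:02d}", "rested") for i in range(design.n_per_group)])
    for subject_id, group in subjects:
        factor = (float(np.exp(rng.normal(0.0, design.subject_sigma_log)))
                  if design.subject_sigma_log > 0 else 1.0)
        n_cut, n_close, _ = _subject_counts(design, params, group, factor, rng)
        cut_areas = [_draw_area(AREA_LAWS["cutting_cone"], rng) for _ in range(n_cut)]
        close_areas = [_draw_area(AREA_LAWS["closing_cone"], rng) for _ in range(n_close)]
        for selection, areas, n in (
            ("combined", cut_areas + close_areas, n_cut + n_close),
            ("cutting_only", cut_areas, n_cut),
        ):
            tt = float(np.sum(areas)) if areas else 0.0
            rows.append({
                "subject_id": subject_id, "site": site, "group": group,
                "selection": selection, "Ct_Ar_mm2": area, "N_Ca": n,
                "Tt_Ca_Ar_mm2": tt, "N_Ca_per_Ct_Ar": n / area,
                "Tt_Ca_Ar_per_Ct_Ar": tt / area,
            })
    return pd.DataFrame(rows)
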
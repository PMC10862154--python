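# Methods

## Model and conventions

**Coordinates and scale.** Pixel centres sit at integer coordinates, origin
top-left, x rightward, y downward. Every physical quantity derives from the
pixel spacing `s` (μm/pixel): areas are pixel counts × `s²` (reported in mm²),
lengths are chain/Euclidean lengths × `s` (μm).

**Cortical mask.** The cortex is the interior of the periosteal polygon minus
the interiors of the endosteal polygons. Pixel membership uses a half-open
rule applied identically to both polygon kinds — the strict-interior test is
evaluated at the pixel centre shifted by ε = 2⁻⁶ px in +x and +y, so
left/top boundary pixels count as inside and right/bottom boundary pixels as
outside. Abutting regions therefore partition the plane without double
counting, and an axis-aligned w×h-pixel rectangle contains exactly w·h pixel
centres. `Ct.Ar` is the masked pixel count × `s²`; the section's centre of
mass is the mean masked pixel coordinate.

**Triangle threshold.** The 256-bin intensity histogram is computed from the
masked cortical pixels by default. Restricting to the cortex stops empty
background from dominating the histogram; a full-frame mode is provided for
replicating analyses that thresholded whole frames (which of the two a given
legacy dataset used may be unknown, so neither is asserted). The Zack
construction normalises the bin axis by 255 and the count axis by the peak
count, draws the line from the peak to the farthest nonzero bin on the
longer-tail side (on equal tail lengths, the side with less mass), and
returns the bin with maximum perpendicular distance to that line; distance
ties break toward the peak, and a single-nonzero-bin histogram returns that
bin. Pore polarity defaults to `pores_below` (radiolucent pores rendered
dark); binarisation is strict (`intensity < level`) and confined to the mask.

**Pore measurement.** Pores are 8-connected components, ordered by the raster
position of their topmost-leftmost pixel. Interior holes are filled before
measurement, so a canal with a central bone island counts its full lumen.
Perimeter is the length of the 8-connected outer boundary chain (Moore
tracing): edge steps = `s`, diagonal steps = `s·√2`; a one-pixel-wide feature
is traversed down one flank and back, and an isolated pixel has a degenerate
chain of length 0. Circularity `4πA/P²` is clipped at 1.0 because
digitisation pushes the ratio above 1 for tiny particles (a clipped value is
reported for degenerate chains). The maximum Feret width is the largest
pairwise distance between boundary-pixel centres (convex hull first, brute
force for collinear sets).

**Retention and classification.** A pore is retained iff circularity ∈
[0.3, 1.0] and `Ca.Ar` > 0.002 mm² (strict); the first failing criterion is
recorded. Class boundaries: mature ≤ 0.002 mm² < closing cone ≤ 0.04 mm² <
cutting cone, i.e. retention is strict at 0.002 and the cutting-cone
threshold strict at 0.04, making the closing-cone interval inclusive at
0.04. Both cut-offs derive from nominal circular diameters (50 μm and
225 μm) via `A = π(d/2)²` rounded to one significant figure. Endosteal
macro-pores — the transition to cancellous bone — are flagged automatically
when the Feret width exceeds 600 μm *and* the pore boundary comes within
100 μm (configurable) of an endosteal contour; an explicit id list is also
accepted for replicating a manual exclusion. Exclusion flags are additive
and never alter measured values, so the order of shape filtering vs
endosteal exclusion is immaterial and both operations are idempotent. Pores
clipped by the mask edge are measured on their masked portion (the cortical
boundary is the biological boundary).

**Indices.** For each section and selection (combined: `Ca.Ar` > 0.002 mm²;
cutting-only: `Ca.Ar` > 0.04 mm²): `N.Ca` (count), `Tt.Ca.Ar` (summed area,
mm²), `N.Ca/Ct.Ar` (mm⁻²), `Tt.Ca.Ar/Ct.Ar` (unitless). Indices are reported
in mm-based units even where μm-based definitions are conventional; the
conversion is exact. Group summaries are arithmetic means with sample SD
(n−1); a single-section cell reports SD 0 and is flagged via its n. The
minimum resolvable canal diameter of an imaging configuration is the
equivalent circular diameter of one pixel, `2s/√π` — distinct from the 50 μm
retention diameter, which is a biological cut-off set to twice the largest
pixel spacing across configurations; the two are implemented separately and
never conflated. Size histograms use right-open bins `[lo, hi)`; the default
canal-size distribution uses 30 logarithmic bins from 0.002 mm² to the
maximum observed area (log-spacing matches the right-skew of canal areas; the
bin count is a display choice).

**Statistics.** Mann–Whitney U is implemented from first principles:
joint mid-rank ranking, `U₁ = R₁ − n₁(n₁+1)/2`, reported `U = min(U₁, U₂)`
(tending to 0 as rank overlap vanishes). The default p-value is the normal
approximation with continuity correction, `z = (U − n₁n₂/2 + 0.5)/σ` with
tie-corrected `σ² = n₁n₂/12 · ((N³−N) − Σ(t³−t))/(N(N−1))`, two-sided
`p = 2Φ(z)` capped at 1. This convention — not the exact distribution — is
what published small-sample comparison tables of this kind print (complete
separation at n = 6, 6 gives p = 0.005; the exact p would be 0.002), so it is
the replication default; exact enumeration over all `C(N, n₁)` labelings is
available for tie-free data. The asymptotic and exact p agree within 0.01
whenever the exact p ≤ 0.25 for n₁ = n₂ = 4 (verified exhaustively; the
worst-case discrepancy over all such configurations is ≈ 0.03, at
mid-range p where the decision is unaffected). No multiple-testing
correction is applied across indices or sites, matching common practice for
descriptive comparison tables; interpret accordingly. Fold ratios are
rested/exercised means, flagged unbounded on a zero denominator.

**BMU kinetics.** Radial infilling is modelled at a constant apposition rate:
duration = (r_start − r_end)/rate, with defaults 100 → 10 μm at
1.0–1.5 μm/day (60–90 days) and a longitudinal cutting-cone advance of
40 μm/day. Real osteons show substantial resting periods, so these are
lower-bound estimates, not a spatiotemporal BMU simulation.

## Synthetic data generator

Each synthetic section is an annulus (or right half-annulus, for metaphyseal
half-sections) of radiopaque matrix (default intensity 180) on dark
background (25), containing: non-overlapping radiolucent discs (intensity
60) for canals of the three classes; high-aspect (default 9:1) ellipses
emulating obliquely cut Volkmann's canals; irregular multi-lobed blobs
(~800 μm across) straddling the endosteal contour; a multiplicative
intensity ramp across the frame (default 10% peak-to-peak) emulating uneven
sample thickness; and additive Gaussian noise (default SD 3 grey levels).
Canal areas are drawn from truncated log-normals per class — the truncation
bounds sit strictly inside each class interval so rasterisation jitter
cannot flip a class. Pore centres keep ≥ ~3 px clearance from each other and
from both contours; placement failure after bounded retries raises rather
than silently dropping pores. Every stamped pore is logged with its centre,
nominal and rasterised area, class and distractor/endosteal flags; identical
seeds give byte-identical images.

Study-level generation covers two groups (n = 6 each) across four sites with
per-group canal densities per mm² set to the published group means for each
site, and an option to drop one rested tibia and one rested metacarpal
diaphysis section to mirror a damaged-specimen design. Section geometry is
scaled down (Ct.Ar ≈ 9–46 mm² per site rather than the real 80–900 mm²) —
densities, size laws and effect directions are preserved, and full-cohort
runs complete in seconds; this is the package's default study size. Canal
counts per section are Poisson by default, with a log-normal between-subject
density factor (σ_log = 0.2); a "bounded" count model (density × area with
±10% uniform jitter) supports constructing cohorts with guaranteed complete
group separation. An index-level sampler draws per-section indices directly
from the count/size laws without rasterisation; since the group comparison
consumes only section indices, this is the appropriate (and fast) route for
statistical calibration studies such as null-rejection-rate checks.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: partial-volume blur and focal-spot unsharpness,
osteocyte lacunae and canaliculi, cortical-thickness variation and
anatomically realistic cross-sections, spatially clustered remodelling
(e.g. dorsal-cortex concentration), correlated noise and film artefacts.
Recovery results on synthetic sections bound the pipeline's algorithmic
correctness, not its robustness to every acquisition artefact.

## Numerical choices and degenerate inputs

- Constant 16-bit images convert to all-zero 8-bit (degenerate min–max
  range); conversion rounds half up and is monotone.
- The half-open containment ε (2⁻⁶ px) only matters when a polygon edge
  passes within ε of a pixel centre — measure-zero for generic contours,
  and exactly what yields integer-exact areas for integer-aligned
  rectangles.
- Circularity of a single-pixel or two-pixel pore is reported as 1.0
  (clipped); such pores are always excluded by the area filter anyway at
  realistic spacings.
- `exclude_endosteal` recovers the pixel spacing from each record's
  area/pixel-count pair, so records carry no separate spacing field.
- Mann–Whitney with all observations identical returns p = 1 (zero
  variance); the exact method refuses ties rather than approximating them.
- Empty histograms, empty samples, zero-area masks, unsorted bin edges and
  out-of-bounds polygons raise `ValueError` rather than propagating NaNs.

## Known limitations

- No shading/background correction is applied before thresholding; strong
  intensity gradients shift the triangle threshold and can shed spurious
  low-circularity fragments (these are caught by the shape filters, but
  extreme gradients would degrade area accuracy near the dim edge).
- Contours must be supplied (the tracing step that produces them is manual
  by nature); there is no automatic periosteal/endosteal detection.
- The endosteal width-plus-proximity rule automates what is inherently a
  judgement call; the manual id list exists for exact replication.
- 2-D cross-sections cannot distinguish one long canal from several short
  ones; the indices are per-section, not per-BMU.
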
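# canalmorph

Intracortical canal histomorphometry from 2-D bone microradiographs.

Cortical bone is continuously remodelled by basic multicellular units (BMUs):
osteoclasts cut a tunnel through the matrix (the *cutting cone*), osteoblasts
refill it (the *closing cone*), and a narrow *Haversian canal* remains at the
centre of the finished secondary osteon. On a transverse microradiograph these
stages appear as radiolucent pores of decreasing cross-sectional area, so the
size distribution of intracortical canals is a readout of remodelling
activity — for example, when comparing heavily exercised versus rested
athletic animals (racehorses being the classic model, with plentiful osteonal
remodelling and well-documented exercise histories).

`canalmorph` implements that readout as a reusable, tested pipeline:

1. **Segmentation** — rasterise manually traced periosteal/endosteal contours
   into a cortical mask; binarise pore vs bone with a triangle-method
   (Zack) threshold computed on the masked intensity histogram.
2. **Pore analysis** — 8-connected particle labelling; per-pore area
   (`Ca.Ar`), boundary-chain perimeter, circularity `4πA/P²`, equivalent
   diameter (`Ca.Dm`) and maximum Feret width; retention filters
   (circularity 0.3–1.0, `Ca.Ar` > 0.002 mm²); automatic exclusion of wide
   (> 600 μm) irregular pores at the endosteal margin; classification into
   mature (`Ca.Ar` ≤ 0.002 mm²), closing-cone (0.002–0.04 mm²) and
   cutting-cone (> 0.04 mm²) canals.
3. **Morphometry** — per-section indices `Ct.Ar`, `N.Ca`, `Tt.Ca.Ar`,
   `N.Ca/Ct.Ar`, `Tt.Ca.Ar/Ct.Ar` for the combined (> 0.002 mm²) and
   cutting-only (> 0.04 mm²) selections, size histograms, group summaries.
4. **Statistics** — two-group Mann–Whitney U from first principles
   (U = min(U₁, U₂); continuity- and tie-corrected normal p-value by default,
   exact enumeration optionally) and rested/exercised fold ratios.
5. **Synthetic data** — a seeded generator of microradiograph-like sections
   with per-pore ground truth (canals of all three classes, elongated
   Volkmann-like distractors, endosteal macro-pores, intensity gradients and
   noise), up to a full two-group, four-site study.
6. **BMU kinetics** — closed-form cutting-cone advance (40 μm/day) and
   radial infill durations (100 → 10 μm radius at 1.0–1.5 μm/day → 60–90
   days).

## Worked example

Generate a small synthetic study and analyse it end to end:

```python
from canalmorph import RunConfig, run_study
from canalmorph.synthetic_data import generate_study, separation_design

study = generate_study(separation_design(), seed=5)   # 24 metacarpal sections
meta = study.write("scratch/study")                    # TIFFs + contours + CSVs
res = run_study(RunConfig(metadata_path=str(meta), output_dir="scratch/out"))
print(res["comparisons_cutting_only"][["site", "N_Ca_U", "N_Ca_p"]])
```

prints

```
            site  N_Ca_U    N_Ca_p
0   mc_diaphysis     0.0  0.001821
1  mc_metaphysis     0.0  0.001262
```

i.e. with every rested section's cutting-cone density constructed to exceed
every exercised one, the rank distributions do not overlap and U falls to 0.
(The p-values here fall below the tie-free 0.005 for n = 6 vs 6 because the
integer canal counts are heavily tied within each group, which shrinks the
tie-corrected variance.)

The same chain runs from the shell:

```sh
canalmorph synth --seed 5 --out scratch/study
canalmorph run --config run.yaml
canalmorph measure section.tif --roi section.roi.json --spacing 25.0
canalmorph compare scratch/out/sections.csv --method asymptotic_cc
canalmorph kinetics
```

Outputs per run: `pores.csv` (one row per detected pore), `sections.csv`
(per-section indices for both selections), `comparisons_<selection>.csv`
(U and p per site and index), polar canal maps and size-distribution plots
(SVG/PNG), and `manifest.json` (config hash, versions, per-stage counts).

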
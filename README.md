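# shgquant

Automated, observer-independent quantification of early liver fibrosis and
fat from label-free SHG/CARS microscopy mosaics of biopsy sections.

Fibrillar collagen (types I and III) generates second-harmonic (SHG)
signal without staining, and lipid generates CARS signal at the CH₂
vibration, so a two-channel mosaic of a native liver section carries both
a fibrosis and a steatosis readout. The difficulty is that the liver
capsule and portal tracts are collagen-rich in *healthy* tissue: their
bright SHG signal, and their variable share of a biopsy's area, mask the
weak wavy parenchymal fibrils (20–200 µm) that distinguish fibrosis stage
0 from stage 1 — exactly the range where pathologists disagree most.
`shgquant` implements the standard automated recipe:

1. **sample border** — SHG+CARS overlay → percentile (p-tile, p = 0.5)
   auto-threshold → mean/max/mean disc filtering (50/15/50 µm) →
   threshold at 9.8 % of the 8-bit maximum;
2. **capsule / portal exclusion** — SHG thresholded at its mean over the
   sample → 15/35/25 µm mean/max/mean filtering → threshold at 1.17 % of
   maximum → particle analysis; particles that are large (≥ 2000 µm²) and
   roundish (roundness = 4·area/(π·major-axis²) ≥ 0.15), or that touch the
   specimen border, are excluded;
3. **scoring** — per-biopsy background (mean intensity outside the
   sample) is subtracted and the mean SHG and CARS intensities over the
   remaining parenchyma are reported, along with the fold of the raw
   parenchymal mean over background.

Because raw mosaics of this kind are not publicly deposited, the package
also ships a phantom generator (`shgquant.phantom`) that emulates the
reported biopsy morphology — capsule band, portal areas, wavy fibrils
whose density scales with fibrosis stage 0–4, lipid droplets scaling with
steatosis grade 0–3 — with ground-truth masks, plus the nonparametric
statistics used on such cohorts (exact small-sample Mann–Whitney U,
Spearman ρ, weighted Cohen's κ). See `docs/methods.md` for the model and
its assumptions.

## Worked example

```python
from shgquant import PhantomSpec, generate_phantom, segment, quantify

spec = PhantomSpec(stage=1, steatosis_grade=2,
                   frame_px=(1024, 1024), pixel_size_um=4.0, seed=7)
img, truth = generate_phantom(spec)          # 4 x 4 mm synthetic biopsy

seg = segment(img)                           # steps 1-2
result = quantify(img, seg)                  # step 3

print(f"sample area      : {result.sample_area_um2 / 1e6:.2f} mm^2")
print(f"parenchyma       : {100 * result.parenchyma_fraction:.1f} % of sample")
print(f"background SHG   : {result.background_shg:.2f}")
print(f"mean SHG         : {result.mean_shg:.2f}")
print(f"mean CARS        : {result.mean_cars:.2f}")
print(f"fold over bkgd   : {result.fold_over_background:.1f}")
print(f"true fibril area : {100 * truth.true_fibril_area_fraction:.1f} %")
```

prints

```
sample area      : 9.09 mm^2
parenchyma       : 73.0 % of sample
background SHG   : 2.00
mean SHG         : 27.58
mean CARS        : 45.37
fold over bkgd   : 14.8
true fibril area : 23.7 %
```

The biopsy blob covers ~9 mm² of the 16.8 mm² frame; the capsule and six
portal areas (plus the smoothing halo around them) are excluded, leaving
73 % of the specimen as parenchyma. The stage-1 fibril meshwork lifts the
parenchymal SHG mean to 27.6 counts above the 2-count background (the
generator's defaults put stage 0 near 8-fold over background and stage 1
near double that, and the 14.8-fold here matches). The CARS mean of 45
reflects the hepatocyte signal plus grade-2 droplet load.

The same pipeline is available from the shell:

```sh
shgquant simulate --n-per-stage 5 --seed 1 -o phantoms/   # phantom cohort + manifest
shgquant quantify phantoms/*_stage*.tif --pixel-size 2.0 -o out/
shgquant report cohort.csv -o report/                     # stage summary + tests
```

`quantify` writes one CSV row per biopsy plus sample/excluded masks as
8-bit TIFFs (`--save-intermediates` adds the intermediate masks and the
particle table), and records the full effective configuration in
`run_config.json`. Runs are bit-reproducible: identical inputs and config
give byte-identical CSVs and masks.

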
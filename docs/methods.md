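# Methods

`shgquant` quantifies early liver fibrosis and steatosis from two-channel,
label-free microscopy mosaics of native biopsy sections: a second-harmonic
generation (SHG) channel, in which fibrillar collagen (types I/III) is
bright, and a coherent anti-Stokes Raman scattering (CARS) channel tuned to
the CH₂ stretch, in which lipid is bright. The readout per biopsy is the
background-subtracted mean SHG intensity over the *parenchyma* — the
specimen minus its capsule and portal areas — together with the analogous
CARS mean as a fat score. Portal tracts and the capsule are physiologically
collagen-rich; their prominent SHG signal would otherwise swamp the weak,
wavy parenchymal fibrils that distinguish fibrosis stage 0 from stage 1,
and their highly variable share of a biopsy's area would add noise to any
whole-specimen mean.

## Segmentation pipeline

All filter radii are physical (µm) and converted to pixels by
round-half-up with a floor of 1 px, so behaviour is tied to tissue scale,
not pixel pitch. Pixel pitch is a required input (metadata or argument)
and is never assumed.

**Sample border (step A).** The two channels are overlaid by pixelwise
maximum (tissue support from either modality, no integer overflow), then
auto-thresholded by the percentile (p-tile) method at p = 0.5: the
threshold is the observed intensity t minimising |F(t) − 0.5|, F the
cumulative pixel fraction, ties to the smallest candidate. Restricting
candidates to observed values makes the operator purely rank-based (it is
invariant to any strictly monotone intensity rescaling) and gives the
sensible degenerate behaviour that a constant frame has no foreground and
raises a "no tissue detected" error. The binary mask (scaled 0/255) is
smoothed with mean → maximum → mean disc filters of radii 50/15/50 µm
(circular kernels, dr² + dc² ≤ r², edges clamped to the nearest pixel so
no dark rim forms at the frame border), converted to 8-bit and thresholded
at 9.8 % of 255, i.e. level 25. The largest connected component is kept,
plus any component at least 1 % of its size (fragmented sections).

**Capsule and portal exclusion (step B).** On the SHG channel (float
arithmetic throughout), pixels above the mean over the sample area retain
their values and the rest are zeroed; the mean is taken over the sample
rather than the frame so that framing and background do not drag it down
(a config flag restores whole-frame semantics). The retained image is
smoothed with a 15/35/25 µm mean/max/mean chain and thresholded at 1.17 %
of the observed maximum (the 8-bit level-3 analogue). Connected components
(8-connectivity, which keeps thin fibrillar bridges intact) become
particles with area (µm²), centroid, and roundness
4·area/(π·major_axis²), the equivalent-ellipse convention (1 for a disc,
b/a for an ellipse; clipped to ≤ 1 since tiny blocky components can
nominally exceed it; a single pixel is defined as 1). A particle is
excluded when it is both large (≥ 2000 µm²) and roundish (≥ 0.15) —
portal areas — or when it touches the inner 50 µm border band of the
sample mask — the capsule, which is a bright band at the specimen edge
regardless of shape. The union of excluded particles, clipped to the
sample mask, is the excluded mask; parenchyma = sample \ excluded, and the
three areas are consistent by construction.

**Quantification (step C).** The background is the per-channel mean
outside the sample mask (an error if the sample fills the frame). The
per-biopsy scores are max(0, parenchymal mean − background) per channel —
clamped because intensities are physical magnitudes — plus
fold-over-background, the *raw* parenchymal SHG mean divided by the SHG
background (NaN when the background is 0). Both the subtracted mean and
the fold are emitted since either presentation of the same pair is in
use. Adding a constant to the whole frame cancels exactly; altering pixels
inside the excluded mask changes nothing.

## Statistics

Group comparisons use the Mann–Whitney U test with midranks for ties. For
combined n ≤ 20 the two-sided p value is exact: the classical
count-recurrence for the null rank-sum distribution when there are no
ties, full enumeration of all C(n+m, n) midrank subsets otherwise; above
that, a normal approximation with tie and continuity correction. The exact
small-sample path matters because biopsy cohorts of this kind have groups
of n ≤ 12. At n = 8 vs 8 the achievable two-sided rejection rate at
α = 0.05 is 0.0499 (642/12870), which the acceptance suite verifies by
simulation. Spearman's ρ is Pearson correlation of midranks (NaN for a
constant input). Weighted Cohen's κ over a declared ordered category set
uses disagreement weights |i−j|/(k−1) (linear, the default for ordinal
fibrosis stages with arguably equidistant steps) or their square, with a
flag to switch; κ = 1 − Σw·o / Σw·e. Adjacent-stage pairwise p values are
reported unadjusted, as is conventional for this design; a Holm option
exists but is off by default.

## Phantom generator

No raw biopsy mosaics are publicly deposited for this kind of study, so
the package ships a generator whose phantoms carry ground-truth masks. It
emulates the reported morphology, not SHG physics (no polarisation or
coherence modelling, no hepatocyte texture synthesis):

* **Tissue**: one smooth blob (radial Fourier perturbation of a disc,
  ≤ ~8 % amplitude) covering ~50 % of the frame — a biopsy occupies
  roughly half of a cropped mosaic. Default frame 2048 × 2048 at 2 µm/px
  ≈ 4 × 4 mm, the typical wedge-biopsy mosaic extent.
* **Capsule**: a 60 µm band inside the tissue boundary at portal-level
  SHG brightness.
* **Portal areas**: 4 + 2·stage near-round ellipses, diameter 100–400 µm,
  SHG amplitude 4000 (16-bit scale), kept clear of the capsule.
* **Fibrils**: random-walk polylines (heading diffusion 0.3 rad/step),
  lengths uniform in 20–200 µm, drawn 1 px wide and clipped to the
  parenchyma; 15 % start at a portal and head toward another, giving
  bridging septa. The drawn amplitude is
  `fibril_intensity × fibril_width_um / pixel_size_um` — a 1 µm fibril is
  sub-pixel at mosaic pitch, and this partial-volume scaling makes the
  parenchymal mean independent of pitch while keeping fibrils an order of
  magnitude below the portal/capsule plateau, as in real data. Density
  scales with stage: {320, 650, 1100, 1700, 2500} per mm². These defaults
  were set analytically from two reported anchors — a stage-0 parenchymal
  mean about 8-fold above background (noise mean 2 counts, so a fibril
  area fraction × amplitude of ≈ 14 counts at stage 0) and roughly a
  doubling from stage 0 to stage 1 — then extended geometrically to
  stage 4, where nominal coverage (~27 %) matches severe-fibrosis collagen
  proportionate areas.
* **CARS**: hepatocyte level 30 modulated by a smooth (150 µm) texture
  field, plus droplet discs of radius 8–40 µm at amplitude 250, density
  {2, 15, 35, 60} per mm² by steatosis grade (grade-3 fat area ≈ 13 %).
* **Noise**: i.i.d. gamma (mean 2, sd 1.5) added to both channels —
  nonnegative, offset-Poisson-like detector counts.

Cohorts derive per-sample seeds from one master seed and draw steatosis
grades uniformly, so a cohort carries independent fibrosis and fat
gradients. Evaluation cohorts in the tests and the acceptance script use
1024 × 1024 frames at 4 µm/px — the same 4 × 4 mm scene at coarser pitch —
to keep a 25-phantom end-to-end run around a minute.

What passing on phantoms does **not** show: robustness to stitching
artefacts, illumination gradients, saturation, real fibril texture or
anatomically realistic portal-tract shapes. The phantoms test the
geometry and arithmetic of the pipeline, not its behaviour on real tissue.

## Known limitations

* **Boundary dilation.** The low fractional cutoffs (9.8 %, 1.17 %) sit
  deep in the tails of the mean/max/mean chains, so detected masks are
  dilated ~55–70 µm beyond the true boundaries. The sample mask therefore
  includes a thin background halo (~8 % of background pixels on default
  phantoms, though recall of tissue pixels is 1.00), and excluded regions
  are supersets of the true portal/capsule (coverage 1.00, IoU ~0.3–0.4).
  For quantification this errs on the safe side — a slightly generous
  exclusion and a background estimate diluted only marginally — and the
  stage gradient and stage-0/1 separation are unaffected.
* **Relative exclusion threshold needs a bright reference.** Step B's
  1.17 % cutoff is relative to the filtered image's own maximum. In a
  frame with no capsule or portal tract at all, the cutoff adapts down to
  the dim fibril field and essentially the whole tissue is flagged for
  exclusion. Real biopsy mosaics (and default phantoms) always contain
  such structures; parenchyma-only crops are out of scope.
* The inter-rater κ reported for pathologist fibrosis staging in this
  setting cannot be recomputed here: per-sample scores from two raters are
  not published. `weighted_kappa` is validated against exact hand-worked
  cases, a null simulation, and an independent library implementation
  instead.
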
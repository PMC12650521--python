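# Methods

## Measurement model

The chip's chemistry converts glucose to gluconic acid and H₂O₂ (glucose
oxidase); H₂O₂ then oxidises TMB under peroxidase catalysis, turning the
analysis zone blue and, as oxidation proceeds, green. The readout model makes
one central assumption: **the amount of reacted color in the analysis zone is
proportional to glucose concentration, and a phone camera sees "amount of
reacted color" as the number of pixels whose HSV triple falls inside the
blue/green detection ranges.**

HSV is used instead of RGB because it decouples chroma from brightness: the
hue and saturation of a pixel are ratios of channel values, so a multiplicative
change in illumination moves V but leaves H and S nearly fixed (exactly fixed
when the scaled channel values are exactly representable; within ±1 step
otherwise — see *Numerical choices*). The convention is the 8-bit one: hue in
half-degrees 0–179, S and V in 0–255. Hue wraparound (red) is always
represented as a pair of ranges, never as an inverted interval.

The color-intensity score of a photo is

```
I = 255 · white / A
```

where `white` is the in-range pixel count inside the extracted reacted
component and `A` is the analysis-zone pixel area. Dividing by `A` makes the
score a fraction of the zone rather than a raw count, hence invariant to image
resolution and comparable across photos; the raw count is always retained in
reports. The 0–255 axis keeps the score commensurate with the characterisation
table shipped with the package.

**Scoring denominator.** A raw photo does not carry its own scale, so `A`
comes from the configured chip layout (default: 4 mm zone with pointed tip)
rasterised at the configured pixels-per-mm (default 20 px/mm ≈ a 10 cm phone
shot). The synthetic renderer expresses its intended color fraction over the
same rasterised count, so generator and scorer share one convention end to
end. For real photographs this means the configured scale must match the
acquisition protocol; a fiducial-based scale estimate is future work.

## Pipeline

1. `detect_chip` — brightness plane = max(R,G,B); global Otsu threshold;
   largest 8-connected bright component (ties: leftmost, then topmost bounding
   box); interior holes (the colored zones sit darker than paper) are filled.
   Frames with < 16 grey levels of spread have no object/background contrast
   and raise chip-not-found, as does a best component under 1% of the frame.
2. `label_regions` — inside the chip, red-pair pixels are blood, blue∪green
   pixels are the reaction zone, everything else is plain chip.
3. `extract_reaction_roi` — largest 8-connected reacted component (8-
   connectivity tolerates 1-pixel diagonal breaks from noise). Ties break by
   larger mean saturation, then leftmost. An empty reaction zone raises
   no-reaction-detected — an unusable photo, deliberately distinct from a
   measured score of zero.
4. `intensity_score` — as above; mask mode `union` (default) counts blue and
   green together, matching the blue→green TMB transition; `blue` or `green`
   alone are available by configuration.
5. `predict_glucose` — G = a·I + b, reported to one decimal. Out-of-range
   values (including negative ones) are flagged, never clamped: the detection
   range bounds (50–140 mg/dL) are approximate properties of the strip, not
   hard mathematical limits.
6. `classify` — Low < 70 ≤ Normal ≤ 110 < High by default, both band edges
   inclusive in the normal window (the boundary convention is a package
   choice; the clinical window itself is configuration).

## Calibration

Ordinary least squares with glucose as the response and intensity as the
predictor — the orientation in which the line is applied. No
errors-in-variables correction is attempted; intensity measurement error is
folded into the residual. `r_squared` is reported as undefined (None) when the
training glucoses have zero variance, and fitting is refused when all
intensities coincide (singular design). RMSE is the root mean square residual
in mg/dL.

Two characterised reference lines ship with the package (whole blood:
a = 1.4686, b = −157.16; plasma: a = 1.5278, b = −194.35), marked `fixed`.
They are near-parallel (Δa = 0.0592) with a constant offset: whole blood reads
a higher color intensity at equal glucose, consistent with residual red cells
and traces of haemoglobin tinting the zone. The bundled characterisation
pairs carry both the chip-measured glucose column (generated by these lines,
used for coefficient-recovery checks) and the commercial-kit column; fitting
the kit column gives a much shallower line and is not used as a check —
the two columns answer different questions.

## Synthetic chip generator

`render_chip` draws the strip geometry in physical units — 5 mm sample disc,
10 × 2 mm channel, 4 mm analysis zone built as a half-disc plus a triangular
tip (closed-form area πr²/2 + 2r²) — on a darker benchtop, at a configurable
scale with a 2 mm paper margin.

Color development is **model-based, not photochemical**: a calibration line is
inverted to map target glucose → intended intensity `I*`, and exactly
`round(I*/255 · N)` of the zone's `N` pixels receive an in-range blue color
(default hue 108, S 224, V 205). Reacted pixels are chosen nearest the tip
under a V-shaped priority field `(x_apex − x) + 0.8·|y − y₀|` with a row-major
tie-break, mimicking the V-shaped color front capillary flow produces at the
pointed termination, and keeping the reacted set connected and deterministic.
Defaults for the degradations are the documented study conditions: additive
Gaussian sensor noise of SD 5 (8-bit channel units) and a 10% multiplicative
illumination ramp across the frame; paper fibre texture is a constant mild
(SD 2) perturbation of unreacted paper. All randomness flows from one seed;
identical specs give bit-identical PNGs.

**What the generator does not emulate** — and therefore what passing tests do
not show about real photographs: real TMB development changes hue and
saturation jointly and continuously with concentration rather than flipping
pixels between "paper" and one fixed reacted color; real strips show uneven
reagent spreading, shadows, perspective and focus errors; and real scenes do
not guarantee that no background object falls inside the detection ranges.
The round-trip results (leave-one-out error ≤ 5 mg/dL across a 50–140 mg/dL
ladder) validate the *software pipeline* — segmentation, counting,
normalisation, fitting — under controlled degradations, not the assay's
clinical accuracy.

## Numerical choices

- Hue is computed in degrees, halved, rounded half-up, modulo 180; saturation
  rounds half-up from 255·(max−min)/max; achromatic pixels get S = 0, H = 0.
- The ±1 tolerance on H/S brightness invariance is exact quantisation
  reasoning: when scaled channel values are integers the ratios are unchanged;
  re-quantisation of arbitrary values perturbs hue by ≈ 60·δ/d half-degrees
  (d = chroma), so the invariance test constructions keep d·s large or exact.
- Range membership is inclusive on both bounds, matching the inclusive
  convention of 8-bit in-range masking.
- All tie-breaks (component selection, reacted-pixel ordering) are
  deterministic; renders are reproducible to the byte under a fixed seed.
- Ladder seeds derive as `(1000003·seed + index) mod 2³¹`.
- Degenerate inputs are errors, not silent defaults: empty images, zero-area
  ROIs, white counts exceeding the ROI, non-positive flow distances/times,
  all-identical calibration intensities, targets that invert outside [0, 255].

## Problem sizes

Default renders are 500 × 180 px (20 px/mm); the round-trip suite uses a
10-rung ladder at that scale, and the property suites use 100–200 randomised
16×16 images or 1000-pixel batches — sizes at which every oracle (per-pixel
loops, BFS flood fill, closed-form normal equations) is exact and fast.

## Known limitations

- No white-balance or color-constancy correction, and no internal color
  reference: measurements depend on consistent acquisition (daylight/cold LED,
  ~10 cm, no flash).
- No perspective correction or fiducials; photos are assumed roughly frontal.
- The linear model is only claimed inside ≈50–140 mg/dL; predictions outside
  are flagged and should not be trusted.
- The configured pixels-per-mm must match the acquisition distance for
  absolute scoring with the built-in lines; a refitted line absorbs any
  constant scale mismatch.
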
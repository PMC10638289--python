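# Methods

## The model

A nucleus is an 8-bit intensity grid (0 = dark, 255 = bright) with a
binary mask marking the manually extracted nucleus region. For a
threshold t ∈ {0, …, 255}, the binarized image has foreground
(chromatin) at exactly the inside-mask pixels with intensity ≤ t;
outside-mask pixels are always background. Because the predicate is a
sublevel condition, foreground(t) ⊆ foreground(t+1): the sweep is a
filtration, and every chromatin structure is born once and never dies
until the background that it encloses fills in.

On each binary image we count the Betti numbers:

- b0 — connected foreground components, 8-connected;
- b1 — holes: background components with no 4-connected path to the
  border. The image is padded with a one-pixel background ring before
  counting, so every border-touching background component merges into a
  single outer component and holes are exactly the remaining ones.

The (8, 4) connectivity pairing is fixed, not configurable: it is the
standard Jordan-consistent convention for binary images, under which a
closed foreground loop encloses its interior and a 2×2 checkerboard is
one component with no hole. Holes are counted globally, without
attribution to a particular foreground component.

The Euler characteristic is computed independently by bit-quad
counting (2×2 pattern census with the 8-connectivity weights) and obeys
χ = b0 − b1 on every image; the test suite asserts this identity
against both a queue-based flood-fill oracle and scikit-image's Euler
number, giving a dual-route check of the Betti engine.

Features per nucleus:

- b1MAX = max over t of b1(t);
- HV = the smallest t with b1(t) ≥ h, with hole threshold h = 5 by
  default. Two phrasings circulate for this definition ("exceeding 5"
  vs "b1 ≥ 5"); the operational one, ≥, is implemented, and h is a
  config knob. When the curve never reaches h, HV is absent (None in
  memory, an empty CSV field) rather than a sentinel value;
- ns = √(w² + h²), the diagonal of the tight bounding box (w × h
  inclusive pixel extents) of the mask. The bounding-box diagonal is a
  reproducible stand-in for a diagonal measured by hand in a GUI, and
  is monotone with nucleus size. A single-pixel mask gives √2;
- ns² and the chromatin density b1MAX/ns², in holes·pixel⁻². Density
  scales as 1/k² under k-fold upsampling while b1MAX is unchanged, so
  any density cutoff is tied to a pixel scale; an optional µm/pixel
  calibration can be applied to ns, off by default.

All 256 thresholds are always reported (no early exit), so the curve
is complete for plotting and audit; internally b1 is evaluated once
per distinct inside-mask intensity and filled forward across the
constant runs, which is an exact optimization.

## Brightness normalization

HV is covariant with global brightness: adding c to all intensities
(without clamping) shifts HV by exactly c and leaves b1MAX unchanged.
Two corrections address this:

- median offset: median(reference) − median(target), added by the
  caller to each target-group value. It is generic over the feature
  being corrected (HV, b1MAX, …); the worked normalization constants
  (+9 for HV between a normal-brightness and a dark image group with
  medians 50 and 41) are outputs of this computation, never stored
  constants. Medians of even-sized lists are the mean of the two
  central values.
- Brightness-Index correction: the BI is the mode of the inside-mask
  intensity histogram (ties break toward the darker value, a fixed
  documented choice); each nucleus is shifted additively so its BI
  lands on a target, 127 by default (the brightness midpoint), with
  clamping to [0, 255]. Additive shifting is the minimal
  interpretation consistent with the group-median correction; without
  clamping it is idempotent and removes global additive brightness
  differences exactly (equal post-correction profiles).

The BI histogram uses raw, pre-shift intensities inside the mask only;
cytoplasm and background brightness are not modeled.

## Classification and evaluation

A fixed decision tree over univariate cutoffs:

1. optionally, HV ≥ hv_cutoff → non_cancerous (cancer nuclei have
   lower HV). This stage ships disabled: no validated default cutoff
   exists;
2. b1MAX < b1max_cutoff → small_cell;
3. density ≥ density_cutoff → adeno, else squamous.

Values equal to a cutoff fall on the "≥" side in every stage.
Defaults are the clinical constants 25 and 0.05. `evaluate_cutoff`
returns sensitivity TP/(TP+FN) and specificity TN/(TN+FP) for a single
cutoff, with "positive" on the high side (value ≥ cutoff) or the low
side (value < cutoff, matching the small-cell stage's boundary).

## Synthetic data

Ring phantoms provide exact ground truth: pairwise-disjoint dark
annuli (width ≥ 2 px, inner radius ≥ 1.5 px, so the rasterized loop is
closed and has a nonempty interior) at chosen intensities on a bright
background inside an elliptical mask. Each ring contributes exactly
one hole from its own intensity up to the background intensity, where
the whole mask floods solid; the expected 256-step profile is computed
by counting rings, independently of the Betti engine, and the two must
agree exactly.

Textured nuclei emulate three chromatin patterns with seeded granule
placement (filled dark disks, darkest-wins compositing, uniform
positions over the nucleus disk, granules kept inside the nucleus):

| preset | emulates | nucleus radius | granules | radius (px) |
|---|---|---|---|---|
| fine_granular | adenocarcinoma: fine granular chromatin | 40 | 220 | 1.5–2.5 |
| coarse | squamous: coarse clumps, larger nucleus | 55 | 60 | 4–8 |
| dense_packed | small cell: chromatin floods the nucleus | 35 | 260 | 4–7 |

Granule intensities are uniform in class-specific dark ranges on
background 200. Additive Gaussian noise (SD 3) is spatially correlated
over 1.5 px before rounding and clamping: real camera noise on
micrographs is correlated at the pixel scale, and uncorrelated speckle
would fill the near-background threshold range with thousands of
single-pixel holes and dominate b1MAX, which no real profile shows.
Holes in textures arise from granule contact, not from explicit rings,
so their exact counts are not known analytically — phantoms carry the
exactness burden, textures the realism burden.

These presets are illustrative, not biological ground truth. They
reproduce the qualitative class orderings (small-cell-like b1MAX below
the others; adeno-like density above squamous-like) but none of the
photometric complexity of stained specimens: no cytoplasm, no staining
variability, no focus blur, no resolution mismatch. Passing tests on
them demonstrates the pipeline's correctness and the orderings'
mechanism, not clinical performance.

Cutoffs for the synthetic presets were tuned once, on an independent
tuning cohort (master seed 999, 30 nuclei per class), as midpoints of
the adjacent class ranges — b1MAX 38.0, density 0.0035 — and frozen as
`PRESET_RULE`. The clinical cutoffs (25, 0.05) are not expected to
transfer to the synthetic image scale, for the density cutoff because
of its explicit 1/k² resolution dependence.

Cohort generation derives one child seed per nucleus from a master
seed via a `SeedSequence`, making cohorts bit-reproducible; the same
(parameters, seed) pair always yields a byte-identical image.

## Numerical and I/O choices

- Coordinates are row-major, origin top-left, 0-based; bounding boxes
  are inclusive pixel extents.
- RGB input converts to brightness with Rec.601 luma weights
  (0.299 R + 0.587 G + 0.114 B, rounded half-up) by default; the mean
  and single-channel modes are available since the original
  acquisition pipeline's color handling is unspecified. 16-bit input
  is rescaled to 8-bit with a warning.
- Masks are separate image files; any nonzero pixel is inside.
- Feature CSVs use the fixed header
  `nucleus_id,label,b1max,hv,bi,ns,ns2,density,predicted`; floats are
  written with `repr` so round-trips are exact; absent HV is an empty
  field.
- Test and acceptance problem sizes (1000 random images ≤ 64×64 for
  the oracle comparison, 25 random phantoms, 30 nuclei per class)
  keep the full suite in the tens of seconds while exercising every
  code path; a single 512×512 nucleus sweeps all 256 thresholds in
  about half a second.

## Known limitations

- Only single 2D images are analyzed; z-stacks and per-plane analysis
  are out of scope, as are b2 / 3D homology.
- Nucleus extraction is assumed done (mask input); no automated
  segmentation.
- The density cutoff is resolution-bound; transfer across
  magnifications or cameras requires recalibration.
- Group statistics (t-tests and the like) are left to standard
  statistics packages.
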
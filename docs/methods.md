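# Methods

## The measurement

`septamorph` quantifies alveolar septal wall thickness from 2-D histology
fields of view (FOVs). The readout chain is:

1. **Greyscale conversion.** Colour images are reduced with Rec. 601 luma,
   `Y = round(0.299 R + 0.587 G + 0.114 B)`, the default of the common
   image-analysis tools; the weights are configurable in
   `septamorph.segmentation.LUMA_WEIGHTS` only by design choice, not exposed
   per run.
2. **Huang–Wang fuzzy-entropy thresholding.** For a candidate threshold
   `t`, grey levels split into a low class (`g ≤ t`, mean μ0) and a high
   class (`g > t`, mean μ1). Each level's membership to its class is
   `u(g) = 1 / (1 + |g − μ| / C)` with `C = g_max − g_min`, and the image
   fuzziness is the histogram-weighted mean Shannon entropy
   `S(t) = −(1/N) Σ_g h(g) [u ln u + (1−u) ln(1−u)]`. The selected
   threshold minimizes `S` over every candidate that leaves both classes
   populated; ties break to the smallest `t` for determinism. A constant
   image has no definable threshold and is an error. The implementation is
   a vectorized search over all candidates; the test suite holds it equal
   to a naive exhaustive minimizer on random histograms, which *is* the
   contract.
3. **Binarization.** H&E tissue is darker than airspace, so the default
   polarity takes `g ≤ t` as septal foreground; `bright_foreground`
   (`g ≥ t`) is available for inverted or fluorescence-like inputs.
4. **Hole filling.** Enclosed background components with pixel area
   strictly `< 5` px (1.38 μm² at the default calibration) are filled so
   that the distance map measures distance to genuine airspace, not to
   staining dropouts. Components touching the image border are never holes.
   Background components are 4-connected (the dual of the 8-connected
   foreground convention). The rule could also be read as a linear extent
   rather than an area; area is the default and the limit is configurable
   (`hole_max_area_px`). The operation is idempotent and never removes
   foreground.
5. **Distance map.** Exact Euclidean distance from each foreground pixel
   centre to the nearest background pixel centre
   (`scipy.ndimage.distance_transform_edt`). By default the world outside
   the image is treated as a virtual background ring at unit distance from
   edge pixels (`border_is_background`), matching the common distance-map
   tool; disabling it requires in-image background. The per-pixel thickness
   value is the raw distance (`edt` mode) — the distance to the airspace,
   i.e. a half-thickness at the wall midline. `double_edt` reports twice
   the distance, approximating the full wall width at the medial axis, for
   users who want the axis label "wall thickness" to be literal. No
   maximal-inscribed-disk (local thickness) transform is attempted.
6. **Histogram and mean.** Thickness values are binned into half-open bins
   `[k·w, (k+1)·w)`; the relative frequency of a bin is its foreground
   pixel count over the image's total foreground count, so each image's
   curve sums to one. The per-image statistic is the arithmetic mean
   thickness in μm. Default bin width is one pixel expressed in μm
   (0.276 μm); nothing fixes this physically, it simply avoids aliasing
   against the quantized distance values.

Physical calibration: 5 px = 1.38 μm, i.e. **0.276 μm/px**, the package
default. Real images must supply their own `pixel_size_um`.

## Genotype inference

Each mouse contributes 4–6 FOVs; per-image mean thickness is regressed on
genotype with per-mouse terms:

    Thickness = β0 + β1·Condition(genotype) + Σ_i βi·Mouse_i

Because each mouse has exactly one genotype, the mouse indicators span the
genotype contrast and the design is rank deficient: β1 is not separately
identifiable. Three resolutions are implemented:

- **`sequential_anova`** (default, the model of record): pivoted least
  squares drops aliased columns; the genotype F uses the sequential
  (type-I) sum of squares over the image-level residual mean square,
  `F = SS(genotype | intercept) / MS_resid`, mirroring standard software.
  Caveat stated wherever the package reports it: this treats FOVs of the
  same mouse as independent, so it is **anti-conservative** with respect
  to mouse-to-mouse variation.
- **`mouse_stratum`**: one-way ANOVA of per-mouse mean thickness across
  genotypes — genotype tested against mouse-within-genotype variation,
  `F = SS_between / (SS_within / (M − 2))` with `(1, M − 2)` df for two
  genotypes. This is the correctly calibrated test for the nested design
  and is what the Monte-Carlo calibration below checks.
- **`mouse_aggregated`**: pooled two-sample t on per-mouse means, reported
  as `F = t²`. For two genotypes it coincides with `mouse_stratum`; both
  surfaces are kept so the choice is explicit in run metadata.

p-values come from the F distribution, two-sided; no multiplicity
correction (one planned contrast). Degenerate inputs: a single genotype,
fewer than 2 mice per genotype (mouse-level methods), or zero variance in
the response are errors; a perfect within-cell fit with a genotype shift
yields an unbounded F and p = 0 rather than an error.

Per-genotype frequency curves: a mouse's curve pools raw bin counts over
its images (weighting FOVs by foreground size) and renormalizes; the
genotype curve is the unweighted mean over its mice, so it also sums to 1.

## Synthetic data: what it emulates and what it does not

No histology is distributed with the package, so validation runs entirely
on generated images with known ground truth.

- **Geometry.** Septal walls are emulated as the dilation of the edges of
  a Voronoi tessellation of `n_seeds` uniform random sites: each pixel is
  labelled by its nearest site, label changes against the right/lower
  neighbour mark a one-pixel edge set, and the foreground is every pixel
  within `wall_half_width_px` of that set. This gives a foam of convex
  airspaces separated by walls of approximately uniform width
  `≈ 2·wall_half_width_px + 1` px — the simplest structure with a tunable
  thickness distribution. It does not model real septal curvature,
  alveolar ducts, vessels or proximal airways (airway exclusion is a
  manual step on real data and is not simulated).
- **Rendering.** Two intensity levels (tissue 60, airspace 230 by
  default) plus additive Gaussian noise clipped to [0, 255]. The 170-level
  separation with noise SD 10 is the stress condition under which the
  segmentation stage is required to reach Dice ≥ 0.98 against the
  generating mask; no H&E colour chemistry, illumination gradients or
  scanner artifacts are modelled. Consequently, passing tests show the
  pipeline recovers *this* class of two-level images — they bound
  algorithmic error, not stain-variability error on real slides.
- **Cohorts.** Mouse `j`'s true wall thickness is
  `base + effect·[cKO] + N(0, mouse_sd)`; each of its FOVs is an
  independent foam at that thickness. Defaults are the emulated study
  design: 4 mice per genotype, 5 FOVs each (the design specifies 4–6),
  512² px at 0.276 μm/px, base 5 μm, cKO effect +3 μm (septa visibly
  thickened, roughly half again the control), mouse SD 0.5 μm (10% of
  base; biological replicate scatter). A drawn thickness ≤ 0 or below one
  pixel aborts the simulation — it is never clamped silently. All
  randomness flows from a single `numpy` `default_rng` seed; identical
  specs give bitwise-identical images within this implementation (no
  cross-language guarantee).

Note the mapping from true full-wall thickness to the pipeline's `edt`
readout: for a straight wall of width `w` the mean distance-to-airspace is
`≈ (w+3)/4` px (e.g. `{1,2,3,2,1}` for `w = 5`, mean 1.8), so measured
means sit well below the generating thickness and slightly below half of
it. Comparisons between genotypes are unaffected (the map is strictly
monotone; the suite checks Spearman ρ > 0.99 across a wall-width sweep).

## Assay reductions

- **Basal OCR** = mean(baseline cycles) − mean(antimycin A + piericidin A
  cycles), per well. **Coupled OCR** = basal − mean(oligomycin cycles), as
  the protocol states it; `correct_oligo_for_nonmito=True` subtracts the
  non-mitochondrial OCR from the oligomycin term first (equivalently
  baseline − oligomycin), which is the variant invariant under a constant
  offset to all phases. Phase summaries average all cycles by default
  (`last_k_cycles` restricts to the final k). Negative results are flagged,
  never clamped.
- **TIC normalization** divides each sample by its total ion count and
  rescales by the cohort mean total, so sample totals equalize while
  magnitudes stay on the raw a.u. scale. Idempotent; within-sample ratios
  are preserved — which is why **NADH/NAD⁺**, computed strictly within a
  sample, is invariant to it. A zero NAD⁺ peak (below detection limit)
  makes the ratio undefined and is an error. Limitation: TIC normalization
  is compositional — a large shift in one abundant feature deflates all
  others in that sample, which can make un-shifted metabolites pass the
  filter (visible in `analysis/04_assay_reductions.py`).
- **Metabolite filter**: per-metabolite one-way ANOVA, Benjamini–Hochberg
  adjustment across metabolites, selection at adjusted p < 0.05; Fisher's
  LSD pairwise comparisons (pooled within-group MSE, N − k df) label which
  groups drive each selected metabolite. FDR control is applied at the
  ANOVA stage; LSD is post hoc labelling only.

## Validation problem sizes and numerical choices

The Monte-Carlo checks run image-based at reduced scale — 128² px fields,
8 Voronoi seeds, 0.5 μm/px, base 4 μm, mouse SD 0.4 μm — chosen so a full
cohort (8 mice × 5 FOVs) takes well under a second while walls remain
several pixels wide:

- **Size**: with zero genotype effect, the `mouse_stratum` rejection rate
  at α = 0.05 over 500 simulated cohorts must fall inside the binomial
  95% interval around 0.05, and the null p-values must pass a KS test for
  uniformity.
- **Power**: ≥ 0.9 at effect = 3 × mouse SD with 4 mice/genotype × 5 FOVs
  (200 cohorts).
- `scripts/acceptance.py` re-runs the same battery at 200 null / 100
  power cohorts and records every `n` it used.

Other numerics: distances are computed between pixel centres, so the
virtual border ring sits at distance 1 from edge pixels (logged in run
metadata); histogram bin indices use `floor(v / w)`, and distance values
are square roots of integers, so bin-edge collisions only arise for bin
widths that are exact divisors of such values — the refinement-consistency
test pins the behaviour; fuzziness ties in thresholding and rank decisions
in the pivoted fit are broken deterministically (smallest threshold, first
independent columns in pivot order). CSV floats are written with a fixed
`%.10g` format so identical runs are byte-identical.

## Known limitations

- The `edt` thickness is distance-to-airspace, not a local full-width
  measure; `double_edt` is exact only at the medial axis of straight
  walls.
- Real-slide effects (stain variability, colour, airways, out-of-focus
  regions) are outside the synthetic model; on real data the Huang
  threshold and the hole rule should be audited via the per-image run log
  (threshold, foreground fraction, holes filled).
- `sequential_anova` is reported because it is the model of record, but
  its image-level residual makes it anti-conservative; `mouse_stratum` is
  the test the calibration study validates.
- The OCR reduction assumes phases are labelled upstream; no drift or
  outlier-cycle handling is attempted.
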
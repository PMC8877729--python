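# Methods

`somaquant` implements an automated analysis chain for 4-channel confocal
z-stacks of neocortical tissue labeled with a fluorescent Nissl counterstain
(NeuroTrace), the neuronal marker NeuN, phospho-c-Jun (Ser63, a somatic
marker of axotomized neurons) and the DNA dye DRAQ5.  This note records the
model assumptions, the parameters that matter, the numerical choices made
where the design was open, and what the synthetic phantoms do and do not
establish about real tissue.

## Geometry and units

All volumes live on a regular voxel grid with axis order `(z, y, x)`,
0-based indices and voxel-center physical coordinates.  Default voxel size
is 0.67 × 0.67 µm lateral × 0.44 µm axial (20x spinning-disk sampling).  The
voxel volume is always the product of the configured edge lengths
(≈0.197516 µm³ at the defaults).  A rounded figure of 0.196 µm³ circulates
for this voxel size; the package deliberately computes the exact product
rather than hard-coding the rounded constant, and all µm³ quantities flow
through this single conversion.

The analysis ROI is a 630 × 200 µm rectangle (940 × 299 voxels at default
sampling), full stack depth.  Placement within layer V/VI is judged from
the NeuN channel by the experimenter; the package takes explicit ROI offsets
from configuration and does not attempt automatic laminar detection.

## Channel restoration

Stage order is fixed: deconvolution → background subtraction → static
thresholding.

**Deconvolution** is Richardson–Lucy maximum-likelihood iteration (default
18 iterations, within the conventional 15–20 band) with a parametric 3D
Gaussian PSF (defaults σ_xy = 0.3 µm, σ_z = 0.6 µm).  Convolutions use
nearest-boundary handling, making flat signal an exact fixed point at stack
edges; flux is conserved to well under 1% on non-clipped inputs.  The
configured SNR (default 25) enters only through an optional early-stopping
rule (stop when the mean relative update falls below 1/SNR²), documented as
a heuristic.  The stage is skippable in configuration: synthetic phantoms
whose optics are generated with a known, mild PSF are processed without it.

**Background** is estimated per channel by grayscale opening with a
19-pixel-radius disk applied slice-wise in XY, and subtracted (white
top-hat).  Slice-wise 2D was chosen because the radius is quoted in pixels
and the axial extent of a 40 µm stack is small relative to a 19-voxel
element; a 3D ball is selectable.  For speed the disk is realized by
scikit-image's sequence decomposition, a standard fast approximation of the
disk by a composition of small structuring elements; the exact disk remains
available (`footprint="disk"`) and the small-array oracle tests use it.
The top-hat is idempotent and non-negative by construction.

**Thresholding** is static per channel across the whole experiment, exactly
as a unified acquisition setting demands.  A voxel at or above the threshold
is positive (inclusive boundary); sub-threshold voxels are zeroed, and all
downstream intensity measurements operate on these retained intensities.
Thresholds must be supplied in configuration; an Otsu-based suggestion
utility exists but never silently overrides the configured values.

## Segmentation

1. **Nuclei** — connected components of the DRAQ5 mask (26-connectivity by
   default), components smaller than 27 voxels discarded, touching nuclei
   split by watershed on the negated Euclidean distance transform.  The
   nominal object-size phrase "27 voxels (8-connected)" mixes a 2D
   connectivity term with a 3×3×3 voxel count; the package reads it as
   26-connectivity in 3D with a 27-voxel minimum size, both configurable so
   the alternative reading is available.
2. **Watershed seeds** — regional maxima of the distance transform after
   Gaussian smoothing (σ = 1 voxel, suppressing plateau fragmentation),
   restricted to maxima at least 1 voxel deep, with maxima closer than
   2 voxels merged into a single seed.  Components yielding no seed keep one
   seed at their distance-transform argmax so no object is lost.  The
   distance transform is computed in voxel units (anisotropy uncorrected),
   matching the growth stage.
3. **Cells** — constrained dilation of nuclear seeds inside the union of the
   thresholded NeuroTrace and NeuN masks, one face-connected voxel shell per
   round, at most 10 rounds.  Growth claims only unclaimed mask voxels;
   nuclear voxels always belong to their cell even where the mask is false.
   When two seeds reach a voxel in the same round the lowest label ID wins —
   realized exactly by a vectorized minimum over positive neighbour labels,
   which makes the rule deterministic and order-independent.  The full
   26-neighbourhood is selectable per round.
4. **Surrogate cells** — a nucleus whose grown cell never left the nucleus
   and which the signal mask does not touch is dilated 5 rounds
   unconstrained by signal (but never into other cells' territory) to form
   a surrogate cell.
5. **Anucleate rescue** — NeuroTrace mask voxels outside all existing cells
   are watershed-partitioned into additional cells (same seeding rule);
   fragments below the 27-voxel minimum are treated as debris and dropped.
   These cells carry `has_nucleus = False` and NCVR 0 downstream.
6. **Cytoplasm** — cell minus its own nucleus, label-matched, so
   |cell| = |nucleus| + |cytoplasm| holds exactly for every cell.

## Per-cell measurement and screening

For each cell and compartment (whole cell / nucleus / cytoplasm) the table
records cumulative intensity (total marker amount), mean intensity
(concentration; cumulative ÷ voxel count, 0 for an empty compartment) and
maximum intensity of each of NeuroTrace, NeuN and p-c-Jun, plus volumes in
µm³ and the nuclear-to-cellular volume ratio (NCVR).

**Positivity** for a marker uses the maximum whole-cell voxel intensity
against the channel threshold, inclusive at the boundary — the same
per-voxel convention lifted to cells, and the quantity that separates
positive from negative subpopulations in max-intensity distributions.  A
mean-based rule is available for sensitivity analysis.

**Glial screen.**  Nissl dye also stains glia, but glia lack a cytoplasmic
Nissl reaction, so glial detections are either small or nucleus-dominated.
A cell is excluded iff its volume is strictly below the volume cut or its
NCVR strictly exceeds 0.5; both boundaries retain the cell.  The cut is the
99th percentile (linear-interpolation definition) of the cell volumes of
the NeuroTrace−/NeuN− population, or an explicit value in configuration
(the reference dataset's published cut is 231.77 µm³).  Anucleate cells
have NCVR 0 by definition and can only be screened by volume.  The screen
is idempotent and reports counts per exclusion reason.

**Normalization.**  p-c-Jun intensities are expressed in units of the
p-c-Jun positivity threshold (a normalized mean of 1.0 marks the boundary).
NeuN intensities are normalized to the median of an explicit reference
population (e.g. the sham group, or the sham group's p-c-Jun− cells); the
reference rule is a parameter recorded in the output.

**Volume quintiles.**  Within each animal, cells are ranked by volume (ties
broken by stable cell-id order) and cut into Ex-S/S/M/L/Ex-L at 20-percent
rank steps; occupancy per animal is balanced to within one cell.

## Population accounting and statistics

Accounting tracks the four reactivity classes (NT+NN+, NT+NN−, NT−NN+,
NT−NN−) before and after the screen.  Percentages are computed over the sum
of the four class counts of the same stage and reported to one decimal.  An
externally declared detection total may be recorded; if it disagrees with
the class-count sum (as the reference dataset's published figures do — the
declared 627,905 exceeds the printed class sum of 529,394, while the printed
percentages are consistent with the class sum) the accounting exposes the
discrepancy rather than silently reconciling it, and the excluded-cell count
uses the declared total.

Two-group endpoints on animal-level values (the animal is the statistical
unit) go through a normality-gated dispatcher: Shapiro–Wilk on both samples
at α = 0.05; both normal → Welch's unequal-variance t test (paired: paired
t test); otherwise Brunner–Munzel (paired: Wilcoxon signed-rank).  All
tests are two-sided.  The standard inter-group family — sham vs each
injured group, single vs repetitive injury at matched time points, acute vs
chronic at matched injury mode — is Holm-adjusted per endpoint (step-down
with monotonicity enforcement).  Effect size r is √(t²/(t²+df)) for t
tests and |Z|/√N otherwise, with Z recovered from the two-sided p value.
Degenerate inputs are handled explicitly: zero-variance samples are flagged
with p = 1; complete separation under Brunner–Munzel (where the statistic
diverges) falls back to the exact two-sided enumeration bound 2/C(n₁+n₂,n₁)
and is flagged.

Proportions get Wilson score intervals (the interval method behind
estimate-with-CI outputs is otherwise unspecified; Wilson keeps coverage at
extreme fractions).  Proportion contrasts use Pearson chi-square on the
2×2 table without continuity correction, pooled across animals at the cell
level (an animal-level alternative is a caller choice), with the
cross-product odds ratio; a zero cell triggers the Haldane–Anscombe +0.5
convention and a flag.  Multi-group physiological-background comparisons
use Kruskal–Wallis with tie correction; all-identical data yield H = 0,
p = 1 by convention, flagged.

## Synthetic phantoms

The generator plants axis-aligned ellipsoidal somata with interior
ellipsoidal nuclei on the default voxel grid, enforcing a configurable
minimum gap (default 3 voxels) between objects by dart-throwing with
bounded retries.  Populations and defaults:

- **Neurons** — soma radius lognormal, median 4.6 µm (≈470 µm³, matching
  reported neuronal soma volumes), log-σ 0.13, clipped to 3.6–5.6 µm;
  nucleus-to-soma radius ratio N(0.49, 0.03) clipped to 0.45–0.60
  (≈0.12 nuclear-to-cellular volume ratio).  The radius clip guarantees
  that 10 face-connected growth rounds reach the soma surface from the
  nucleus (worst-case L1 gap ≈ 9.5 voxels at the upper clip), so clean-
  phantom recovery is exact rather than contingent.  P(NeuN+) = 0.87 (the
  sham-level NeuN+ fraction); P(p-c-Jun+) is the study dial — 0.015 for the
  sham-like condition, 0.103 for the acute-repetitive-like condition.
  p-c-Jun is nuclear-enriched (nuclear : cytoplasmic level 400 : 100 above
  a background of 20).
- **Glia** — two screenable regimes, half each by default: small somata
  (radius ≈2.6 µm, volume ≈75 µm³, below the 231.77 µm³ cut) with
  cytoplasmic Nissl, and nucleus-dominated profiles (nucleus ≈3.6 µm, soma
  only 1.12× larger → true NCVR ≈ 0.71 > 0.5) whose Nissl reaction is
  confined to the nucleus.
- **Anucleate somata** — neuron-like Nissl+ cells without a DRAQ5 nucleus
  (never planted p-c-Jun+, since the marker model ties p-c-Jun to the
  nucleus), exercising the rescue path.
- **Debris** — DRAQ5-only detections exercising the surrogate path.

Channels are composed from truth, blurred with the Gaussian PSF, then
degraded with Poisson shot noise and Gaussian read noise (σ = 2), a coarse
EMCCD phenomenology.  Generation is deterministic given (spec, seed) on a
fixed platform/numpy version.  Phantom thresholds are placed at background
plus 35% of each channel's signal level — far above the noise-driven maxima
of negative cells and far below positive plateaus, mirroring how static
thresholds split well-separated bimodal intensity distributions.

What the phantoms do **not** emulate: neurites and membrane texture,
intensity gradients and autofluorescence, vasculature, anisotropic PSF
asymmetries, tile-stitching seams, chromatic offsets, or biologically
realistic covariance between size and marker state.  Passing recovery tests
therefore demonstrates the correctness of the pipeline's rules and
arithmetic under the stated population model, not segmentation performance
on real tissue.

## Evaluation problem sizes

The reference evaluation suite (`somaquant.evaluation`) uses: the published
reactivity-class counts of the reference dataset as arithmetic inputs; a
200-soma clean phantom (blur- and noise-free, ≥2-voxel gaps) for exact
recovery, where detected counts must match planted counts exactly and every
per-cell volume error must stay within that cell's one-voxel-shell bound
(the only detections measured smaller than their planted truth are
nucleus-dominated glia, whose cytoplasm carries no signal by construction —
their deficit is also within the shell bound); two marker-recovery
conditions of 2000 planted neurons each (four 500-neuron stacks treated as
separate animals, 48×512×512 voxels per stack) with recovery required
within 3 binomial standard errors; and 2000 null replicates (n = 7 per
group) for the dispatcher's type-I error, required to lie in [0.03, 0.07]
at α = 0.05.

## Known limitations

- Constrained growth counts rounds in voxels, not µm, so growth is
  anisotropic in physical space (documented; matches the "dilate by N
  voxels" convention).
- The NCVR of nucleus-dominated glia is measured near 1 rather than at its
  true ≈0.71, because their cytoplasm presents no signal to grow into; the
  screen direction is unaffected.
- The percentile defining the volume cut needs a NeuroTrace−/NeuN−
  population; tables without one must supply an explicit cut.
- Brunner–Munzel is unreliable below ~7 values per group; the dispatcher
  enforces only n ≥ 3 (needed by Shapiro–Wilk) and leaves sample-size
  adequacy to the study design.
- Richardson–Lucy with a Gaussian PSF approximates, but is not, a
  vendor-calibrated constrained-ML deconvolution; it is exposed as an
  optional stage with the approximation documented.
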
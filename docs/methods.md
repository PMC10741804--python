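# Methods

This note records the models, conventions and numerical choices behind
`contourqa`, and what its synthetic fixtures do and do not demonstrate.

## Geometry substrate

Masks live on a regular voxel grid in patient-space millimetres, LPS
convention by default (+x left, +y posterior, +z superior), axial
slices along the third axis, voxel centers at `origin + index·spacing`.
The grid carries an explicit flag naming the posterior in-plane
direction so anatomical margins resolve unambiguously on exported data
with other orientations.

**Rasterization.** A voxel is set iff its center lies inside an odd
number of the slice's polygons (even-odd rule), so holes arrive as
separate polygons and need no nesting metadata. Each simple polygon is
tested with `shapely.contains_xy` and combined by XOR; the test suite
checks the result against an independent ray-casting implementation.
Contour z positions must sit within half a slice thickness of a grid
plane; anything else signals a coordinate mismatch rather than being
silently snapped.

**Margin expansion** (clinical target volume → planning target volume)
is an anisotropic Euclidean reach split per half-axis: each of the six
anatomical directions carries its own radius, and a voxel is reached
when Σ (d_i / r_i)² ≤ 1 with the radius chosen by the sign of each
displacement component. The default target margin is 5 mm in all
directions except 3 mm posterior, the common prostate-site prescription
that spares the rectum. Implemented as a binary dilation with a
precomputed lattice kernel; verified against brute-force pairwise
reach on small masks.

**Surfaces** are the centers of set voxels with at least one
6-connected unset or out-of-grid neighbour. Hausdorff distances are
computed between these surface-point sets in mm (kd-tree nearest
neighbours), so results are meaningful on anisotropic grids; the
classic 100th-percentile Hausdorff is the default and the only value
reported, with an HD95 variant available but off. Comparisons always
happen on one shared grid, recorded in report metadata.

**Empty-structure conventions.** Both masks empty → metric undefined,
excluded from summaries and counted. One empty → DSC 0; HD undefined;
RVD −1 when the test mask is empty and undefined when the reference is
(division by zero volume). RVD is computed signed and summarized as a
magnitude, since cohort tables conventionally print nonnegative volume
differences.

## Dosimetry

Dose fields are stored in cGy with their prescription. When dose and
structures disagree on grid, the dose is trilinearly resampled to the
structure grid (structure rasterization fidelity dominates metric
sensitivity; resampling contours instead would degrade the masks).
Target voxels outside the dose grid get 0 with a warning.

Cumulative DVHs use a default 1 cGy bin width; the cumulative curve is
exact at bin edges (volume receiving at least that dose). Inverse
lookups (D_x%, D_v) return the largest bin edge still covering the
requested volume: exact for bin-aligned doses — so a uniform field has
HI exactly 0 — and within one bin width of direct voxel sorting
otherwise, which at 1 cGy is far below clinical relevance. Near-maximum
point statistics (D_0.03cc, D_0.1cc) instead use descending-sorted
voxel doses with fractional-voxel linear interpolation, the usual
planning-system convention; plain D_max is the maximum voxel dose, and
scorecards choose explicitly which of the two they mean.

The homogeneity index (D_2% − D_98%)/D_50% is scale-invariant and 0
for a uniform target dose. The conformity index uses the Paddick form
TV_PV²/(V_PTV·V_TV) with V_TV the volume receiving 95% of the
prescription; it is 1 iff the 95% isodose coincides with the PTV and
penalizes both under-coverage and spill.

## Plan-quality scorecards

Objectives are declarative YAML rows: structure, statistic keyword
(`Dmean`, `Dmedian`, `Dmin`, `Dmax`, `D<x>%`, `D<v>cc`, `V<d>cGy%`,
`V<d>cGycc`), direction (at-least / at-most), scoring function, and
(value, score) thresholds. Threshold scoring is all-or-nothing. Linear
scoring interpolates between a minimally acceptable and an ideal
threshold; published scorecards disagree with their own prose about the
score exactly at the acceptable threshold, so both readings are
implemented — the default awards the printed lower score there, a
`"prose"` convention forces it to 0 — and every result records the
active convention. Fractional points are kept; rounding would distort
the normalized score nPQM = 100·PQM/PQM_max, where PQM_max counts each
objective once at its peak score (38 for the bundled prostate card, 101
for head-and-neck). Structure names resolve through a shipped
alias table (e.g. `Parotid_C` ↔ `Contralateral Parotid`; `_O`/`_Ho`
suffixes are read as ipsilateral, their usual clinical meaning).
Missing or empty structures score 0 with a flag and the evaluation
continues. Planning constraint sets use the same statistic grammar but
yield descriptive pass/fail rows, no points.

## Cohort statistics

Summaries report mean, sample SD (n−1), median, and range per structure
and metric, excluding undefined values with an explicit count. Dose
differences between arms are the relative deltas above, signed in raw
per-patient files and absolute in summary tables. Significance per
structure × metric uses the two-sample Wilcoxon rank-sum test,
two-sided at α = 0.05 with no multiplicity correction (a paired
signed-rank variant and Benjamini–Hochberg adjustment exist behind
flags); for tie-free samples up to size 25 the exact null distribution
is used, and the suite verifies it against exhaustive enumeration of
rank assignments for small cohorts. Time saving is
(T_man − T_adj)/T_man, reported as an integer percentage in summary
output. Reports are deterministic: fixed cohort and seed give
byte-identical CSVs.

## Synthetic phantoms

The generator stands in for clinical cohorts that cannot be shipped.

* **Anatomy.** Prostate-like: target ellipsoid with a bladder
  superior-anterior, a rectum tube posterior, an anal-canal tube
  inferior and two femoral-head cylinders lateral, on a 64×64×44 grid
  at 2.5 mm. Head-and-neck-like: a reduced nine-structure roster
  (brain, brainstem, spinal cord, paired parotids, paired 3 mm-scale
  cochleas, oral cavity, target tube) at 2 mm, chosen to span the
  large / small / paired metric regimes rather than for anatomical
  fidelity. Primitives get per-patient Gaussian jitter (1.5 mm s.d.)
  and are carved in order so organs never overlap; the PTV is derived
  by margin expansion and may overlap neighbours, as in reality.
* **Contour perturbation.** The new contour is the zero level set of
  the mask's signed distance field (half-voxel centred so sub-voxel
  displacements act) plus a systematic offset, a dilation/erosion bias,
  and a smooth random field (5³ coarse normals upsampled with cubic
  interpolation, unit variance) scaled by an amplitude in mm. Smooth
  fields make Hausdorff behave like observer disagreement, not
  speckle. A requested target DSC is met by bisection on the amplitude
  (40 iterations, ±0.05 acceptance); unreachable targets raise.
* **Cohort construction.** AI contours are a 2.5 mm-amplitude
  perturbation of the manual phantom plus a small random offset;
  each observer's adjusted set is a 0.7 mm perturbation of the AI set.
  This makes adjusted contours agree better with the AI output than
  with the manual gold standard by construction — the qualitative
  signature of review-and-adjust workflows. The head-and-neck target is
  copied unperturbed into every arm (targets are not autocontoured
  there). Manual times are N(23, 4) min (prostate) / N(150, 20) min
  (head-and-neck); adjusted times are a clipped-normal fraction of the
  same patient's manual time (mean 0.279 / 0.157), so savings are
  positive per patient with cohort means near 72% / 84%. Reviewer
  ratings are drawn from a fixed categorical distribution
  (0.08 / 0.17 / 0.30 / 0.45 from severe to no correction). All
  randomness flows from one cohort seed through spawned per-patient
  streams.
* **Dose.** Prescription inside the target and out to a 3 mm coverage
  shell, exponential decay exp(−d/6 mm) beyond, and a ±2% smooth
  modulation inside the target. This yields HI in roughly (0, 0.1] and
  CI in roughly (0.6, 0.9) — a caricature of an optimized plan with
  the right qualitative behaviour (near-maximum statistics react to the
  hot tail, organs near the target see steep gradients), not a dose
  calculation. A sharp-falloff, noise-free variant produces a plan
  meeting every bundled prostate objective exactly (nPQM = 100), used
  as the scorecard end-to-end check.

**What passing tests show — and don't.** The fixtures exercise every
code path at realistic scales and verify the metric engines against
independent oracles; they do not validate any clinical claim. Real CT
anatomy, optimizer dose textures, delineation-protocol differences and
true interobserver behaviour are all outside the generator's model, so
cohort-level numbers from synthetic runs characterize the pipeline,
not any autocontouring product.

## Problem sizes

Default test and acceptance runs use 5-patient cohorts on the grids
above, 100 random mask pairs of ≤10³ voxels for the brute-force
geometry cross-check, ≤20³-voxel fields for DVH cross-checks, and 60
seeded calibration trials; these sizes give stable statistics while
keeping a full run in the low minutes on one core.

## Known limitations

Rasterization attributes each contour to exactly one slice (no
inter-slice interpolation). Surface extraction is voxel-based, so HD
carries grid-resolution granularity (values on coarse grids are
multiples of the spacing). The DICOM adapters read and write minimal
RT STRUCT / RT DOSE objects and ignore frame-of-reference registration.
The rank-sum test treats the two arms as independent samples even
though per-patient pairing exists; the paired variant is provided but
not the default.
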
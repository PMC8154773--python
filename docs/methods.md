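# Methods

`flseg` implements a semi-automated 3D segmentation of the fascia lata (FL)
of the thigh from T1-weighted MR stacks and the downstream quantification of
intermuscular adipose tissue (IMAT) and muscle-tissue fat fraction (FF_MT)
from Dixon fat-fraction (FF) maps. This note documents the model behind each
stage, the tunable parameters and their defaults, what the synthetic phantom
does and does not emulate, and the numerical choices made where the design
was genuinely open.

## Pipeline model

The FL is a thin fibrous sheath separating subcutaneous adipose tissue (SAT)
from the muscle compartment. On T1w images it appears as a dark sheet inside
bright SAT. The pipeline exploits two of its properties: it is *plate-like*
locally, and it forms a *closed surface* around the muscle ensemble
globally. Stages:

1. **Bias correction** (`preprocess`). Scanner inhomogeneity is modelled as
   a multiplicative field `exp(P(x,y,z))` with `P` a polynomial of order 3
   over normalized coordinates (strictly positive by construction). The fit
   alternates (a) a deterministic 1D k-means tissue assignment on log
   intensity (6 classes — background-adjacent air is excluded, and thigh
   tissue spans roughly fibrous/muscle/skin/adipose/marrow plus mixtures)
   with (b) a least-squares polynomial fit of the log residuals, until the
   RMS relative field change falls below 1e-3 (max 20 iterations). Voxels
   darker than 2% of the 99th-percentile intensity (bone cortex, residual
   air) carry no multiplicative information on the log scale and are
   excluded from the fit. An external N4 implementation can be substituted
   upstream; the pipeline only assumes its input is bias-corrected.

2. **Fuzzy c-means clustering** (`cluster`). Standard scalar-intensity FCM
   with k = 4, fuzziness m = 2, convergence at 1e-4 relative center shift,
   centers initialized at the 5/35/65/95th intensity percentiles (so the
   result is deterministic without random initialization). Clusters are
   named by ascending center: bone/background < fibrous < muscle < adipose.
   The thigh surface is the complement of border-connected background,
   closed per slice (disk radius 2), largest component, with a 2-voxel
   outer rind removed where intensity exceeds the muscle/adipose midpoint
   (skin). The femur is the interior bone component nearest the thigh
   centroid, hole-filled per slice to include the marrow.

3. **Muscle envelope** (`envelope`). A discrete (morphological) geodesic
   active contour shrinks from the thigh boundary and stops on the
   muscle-membership edge. The edge map is
   `g = exp(-ln(1/0.1) * G / G_90)` with `G` the gradient magnitude (in mm)
   of the Gaussian-smoothed (sigma 1 mm) muscle membership and `G_90` its
   90th percentile, so g = 0.1 at that gradient level and 1 in homogeneous
   regions. Per iteration: balloon erosion gated by `g > 0.35`, an
   advection step removing boundary voxels where the edge-map gradient
   points outward, and one sup-inf/inf-sup curvature pass; all operators
   act in-plane because the slice spacing (3 mm) is six times the in-plane
   spacing. The evolution is *strictly contractive* (the region never
   grows), which makes the enclosed volume monotone and the scheme
   unconditionally stable; after convergence an advection-only phase slides
   the boundary onto the edge-map minimum, which the curvature operator can
   otherwise hold a voxel or two outside. Convergence: fewer than 0.01% of
   voxels change over 5 iterations. Muscle-labelled islands in SAT (veins)
   pinch off and are discarded with the non-largest components.

4. **Fascia filtering and surface** (`fascia`). Hessian eigenvalues are
   computed on the Gaussian-smoothed volume at scales {1.0, 1.5, 2.5} mm
   (derivatives in mm, scale-normalized by sigma^2, eigenvalues sorted by
   magnitude). Through-slice Hessian entries are down-weighted by the
   spacing ratio (0.5/3): 3 mm slices undersample a ~1.5 mm sheet, and an
   unweighted z-curvature term mostly adds noise. The sheetness of a dark
   plate is

       weight = exp(-R_sheet^2/2a^2) * exp(-R_blob^2/2b^2) * (1 - exp(-S^2/2c^2))

   with `R_sheet = |l2|/|l3|`, `R_blob = |l1|/sqrt(|l2 l3|)`,
   `S = sqrt(l1^2+l2^2+l3^2)`, gated to `l3 > 0` (a dark sheet inside
   bright SAT has positive curvature across its normal), a = b = 0.5, and
   an adaptive `c` of one quarter of the maximum S over the support
   (fibrous cluster outside the muscle envelope). A quarter rather than
   Frangi's half is used so the strongest sheet responses saturate near
   weight 1 (with c = max/2 the structureness term caps at 0.86 even at
   the maximum response). Scales combine by maximum; the weight is zeroed
   off the support.

   The FL surface is found by a second contractive level set from the
   thigh surface with edge map `g = 1 - weight`, locked open inside the
   muscle envelope (those voxels are frozen inside the region, so the
   front can never cross the envelope). Before forming g the weights pass
   a 3x3 in-plane grey maximum filter: single-voxel holes in the discrete
   weighted sheet would otherwise let the 4-connected erosion slip
   through. Open fascia-like fragments — the saphenous fascia arc, vessel
   walls — do not enclose the envelope, so the front wraps around their
   ends and they end up outside the final boundary; this is the
   closed-surface property doing the work of distinguishing the FL from
   its decoys. If the front collapses onto the envelope (no fascia
   evidence), the intra-fascia (IF) region falls back to the envelope with
   a warning flag rather than failing the batch.

5. **Livewire refinement** (`livewire`). A scripted (non-GUI) editing
   tool: per-slice cost `0.6*(1 - G) + 0.4*(1 - weight)` with `G` the
   slice-normalized T1w gradient magnitude; A* over 8-connected voxels
   (edge cost = mean endpoint cost x Euclidean step; heuristic = Euclidean
   distance x minimum slice cost, admissible and consistent, hence exactly
   optimal); seeds propagate to the following 10 slices, snapping to the
   window minimum (window 3). The traced closed contour replaces the IF
   region on its slice only (even-odd fill, boundary voxels inside);
   self-intersecting contours are rejected, but zero-area backtrack spikes
   where traced segments join are cleaned first.

6. **Quantification** (`quantify`). IMAT_FL = adipose-cluster volume inside
   IF minus femur; IMAT_ME uses the envelope instead of IF through the
   identical code path. The first and last 3 slices are trimmed. T1w and FF
   stacks are aligned by masked rigid registration maximizing mutual
   information (32 bins, Powell, three resolutions with per-axis smoothing
   2.0/1.0/0.4 mm in-plane; the through-slice sigma stays >= 1.5 mm even
   at the finest level because an unsmoothed metric is measurably biased in
   the out-of-plane parameters with 3 mm slices). The joint histogram is
   accumulated with partial-volume (trilinear) weights rather than
   interpolated intensities — interpolated-intensity MI showed a ~0.4 deg
   optimum displacement on phantoms — and the fixed sample planes carry a
   fixed sub-voxel z-jitter: with equal slice thickness in both stacks,
   grid-coincident sampling otherwise pulls the z-translation toward zero
   relative offset (the classic partial-volume artifact). Both choices are
   bit-deterministic. The muscle/adipose
   threshold is the minimum of the log(1+count), moving-average-smoothed
   (window 5) histogram (bin width 10 = 1% FF) of FF intensities in the IF
   VOI, between its two most prominent modes; when the count floor between
   well-separated modes is flat, the middle of the minimal plateau is used
   (that is where the density valley of a two-mode mixture lies). Muscle
   tissue is `FF < threshold` (strict, for determinism); FF_MT is its mean
   FF / 10 in percent. A unimodal histogram returns fallback threshold 500
   with a flag.

7. **Precision** (`precision`). Reanalysis precision over r >= 2 replicates
   per subject: RMS-SD = sqrt(mean_i SD_i^2) with sample (n-1) standard
   deviations, RMS-CV = sqrt(mean_i (100 SD_i / mean_i)^2), reported per
   parameter overall and per group.

## Synthetic phantom

The phantom (`phantom`) emulates a mid-thigh axial stack: star-convex
perturbed-circle thigh outline; a 1 mm bright skin rind; bright SAT; a
1.5 mm dark FL sheet whose outline drifts in-plane across slices (a genuine
3D surface); a perimuscular fat lobe between the muscle surface and the FL
whose size is controlled by `perimuscular_fat_fraction`; intramuscular fat
streaks (capsules around chords, jittered smoothly in z, kept >= 1 mm below
the muscle surface — fat open to the surface would be perimuscular by
definition); a femur with dark cortex and bright marrow; a saphenous-fascia
decoy arc plus a small muscle-intensity vein in SAT; an order-2
multiplicative bias field (mean 1 over the thigh); additive Gaussian noise
(sigma 12 at class means 0/150/400/800, i.e. 8% of the smallest class gap).
All geometry is a continuous function of world coordinates, so the paired FF
volume (its own 0.8 x 0.8 x 3.0 mm grid, intensities 0-1000 = 0-100% FF,
0.5-voxel in-plane partial-volume blur, noise sigma 15) is generated by
evaluating the same tissue-role field at rigidly transformed coordinates:
the ground-truth offset is exact by construction. Between-sequence motion is
modelled as predominantly in-plane (defaults 0.3/-0.2/1.5 deg,
2.0/-1.5/0.4 mm), as expected for an immobilized thigh scanned in one
session.

Problem sizes: the default grid is 144 x 144 x 10 voxels at the clinical
0.5 x 0.5 x 3.0 mm spacing — a 72 mm field of view (thigh radius 28 mm),
i.e. a geometrically faithful but scaled-down thigh chosen so that a
20-phantom validation suite with registration runs in minutes on one CPU.
Unit tests use a 104 x 104 x 8 variant. One consequence of the reduced
scale is a higher interface-to-area ratio than clinical data: partial-volume
voxels at tissue boundaries make up a larger share of the IF region, which
inflates the measured FF_MT (boundary voxels below the threshold carry
intermediate FF values) relative to the muscle-only mean. The validation
suite (`phantom_suite`) spans fat levels from lean (no perimuscular fat,
2 narrow streaks) to moderately infiltrated (fraction 0.35, 8 wide
streaks), with both depots co-varying across the simulated cohort — the
premise behind the observed near-linear IMAT_FL vs IMAT_ME relation with
slope above one.

What passing phantom tests do **not** show about clinical data: no partial
volume in the T1w model (sharp class boundaries plus noise), Gaussian
rather than Rician noise, no per-muscle anatomy, no chemical-shift or
motion artifacts, a schematic saphenous decoy, and scaled-down geometry.
They do validate the pipeline's logic: class separation under bias and
noise, envelope tightness, sheet detection and closed-surface fusion, decoy
rejection, registration recovery, threshold placement, and the FL-vs-
envelope IMAT relationship.

## Numerical choices and degenerate inputs

- FCM ties in hardening break toward the lower-intensity cluster; cluster
  permutation cannot change the result because clusters are sorted by
  center.
- A voxel coinciding with an FCM center receives full membership there.
- The level set refuses expanding balloons; collapse to the empty set is an
  error for the muscle envelope and a flagged fallback (IF = ME) for the
  fascia surface.
- Livewire ties (equal path cost, equal snap cost) break by lexicographic
  voxel order; all results are independent of dict/heap iteration order.
- `resample` uses linear interpolation for scalar volumes and
  nearest-neighbour for masks; out-of-field voxels take the declared fill
  value. Linear interpolation of the piecewise-constant phantom is only
  accurate away from tissue interfaces; geometric consistency of the rigid
  offset is therefore verified outside a 2-voxel interface band.
- Registration is bit-deterministic: fixed sampling (stride, no random
  sampling), deterministic initialization (mask centroids), Powell with
  fixed tolerances.
- The whole pipeline is deterministic given the input volumes and the
  configuration; the manifest records config, seed and stage checksums.

## Known limitations

- The bias model is a global polynomial; it cannot represent the
  high-frequency coil shading N4's B-spline field can.
- The contractive level set cannot re-expand: a front that overshoots an
  exceptionally weak edge cannot recover (mitigated by the balloon gate and
  the max-filtered weights; the livewire tool exists for exactly the
  remaining cases).
- Only plate polarity dark-on-bright is filtered; a bright fascia (unusual
  on T1w) would be invisible to the weight map.
- Out-of-plane registration parameters are intrinsically weakly constrained
  by 10-slice slabs; accuracy to ~0.4 deg is achieved by keeping the metric
  smoothed in z, not by more optimization.
- DICOM series are read only when axis-aligned; oblique acquisitions must
  be resampled upstream.
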
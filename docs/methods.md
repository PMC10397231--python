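# Methods

`fvs3d` reconstructs a three-dimensional model of the retinal vasculature
from a single colour fundus photograph and derives hemodynamic features from
it for disease classification. This note records the models, the numerical
choices, and what the synthetic test bed does and does not demonstrate.

## Problem setting

A fundus photograph is a 2D projection: it shows the planar course of the
optic-disc vessels and their apparent widths, but no depth. The package's
central modelling convention is that the missing third dimension is supplied
by the cross-section: centerlines are taken to lie in the image plane
(z = 0) and every vessel cross-section is assumed circular, with the radius
measured from the image. Everything downstream — surface, flow simulation,
features — follows from that convention.

## Channel fusion

Vessel/background contrast in fundus photographs lives mostly in the green
channel, but the red channel carries complementary information. The input
to segmentation is the fused grayscale `g·G + r·R` with `g + r = 1`. Three
coarse proportions (0.5/0.5, 0.75/0.25, 1/0) are scanned, then a 1-D
hill-climb on a 0.01 lattice refines the weight around the best coarse
value: neighbours `g ± i·0.01` are scored outward in `i` and the search
stops after the first radius at which neither side improves the incumbent.
Ties keep the weight closest to the start. Weights beyond [0, 1] are
clipped rather than renormalized. On the synthetic images (vessel darkening
placed 70% in G, 30% in R by default) the search is exercised with
synthetic evaluators; on real data the score would be a segmentation
metric such as AUC.

## Segmentation

Two segmenters sit behind one probability-map interface:

* **DenseBlock-Unet** — a U-shaped encoder/decoder. Each level of the
  contraction path applies a DenseBlock and 2×2 max pooling; the expansion
  path upsamples with 2×2 stride-2 transposed convolutions and concatenates
  the encoder skip at each level. A DenseBlock holds exactly two 3×3
  convolutions, each preceded by batch normalization and a ReLU, with dense
  concatenation (the block output is the input stacked with both
  convolution outputs, so each layer sees all previous layers). A 1×1
  convolution produces single-channel logits; the head is zero-initialized
  so an untrained network outputs probability 0.5 everywhere. The network,
  including backpropagation and the Adam optimizer, is implemented directly
  in numpy; it is deliberately desk-scale (the default configuration used
  in tests has ~10⁵ parameters) and trains on random 32×32 patches with
  binary cross-entropy. Depth, widths, learning rate and patch size are
  configurable; defaults (depth 2, base 8 channels, 3·10⁻³ learning rate)
  were chosen as the smallest configuration that cleanly learns the
  synthetic contrast. Training is bit-deterministic given the seed.
* **Vesselness fallback** — multi-scale ridge (Sato) filtering of the
  inverted fused grayscale, normalized to [0, 1], thresholded by hysteresis
  (defaults 0.2/0.4 of the response range). It requires no training, which
  decouples the geometric pipeline from the learning stage; the cohort
  pipeline uses it by default. Small disconnected fragments are removed by
  keeping the largest 8-connected component, since flow can only be
  simulated on a connected tree.

Pixel metrics (ACC/SE/SP from TP/FN/TN/FP at a threshold; AUC as the
Mann-Whitney rank statistic with ties counted half) are computed per image;
a leave-one-out harness trains on N−1 images and scores the held-out one.

## Skeleton and graph

The mask is thinned with the classic two-subiteration Zhang–Suen algorithm
(delete pixels with 8-neighbour count in [2, 6], exactly one circular 0→1
transition, and the subiteration's two directional products zero; iterate to
a fixed point). The implementation is faithful to the textbook conditions,
including the known property that the parallel scheme erases a pattern that
erodes to an isolated 2×2 square; on elongated, vessel-like shapes the
8-connected component count is preserved (property-tested on random
stroke-blob masks), and scikit-image's protected variant serves as an
independent cross-check in the tests.

Skeleton pixels are classified by their 8-neighbour count n: n = 0 isolated,
n = 1 endpoint, n ≥ 3 intersection. Adjacent intersection pixels are merged
into a single node at the cluster centroid. Segments are traced from node
pixels along unvisited skeleton pixels; node-free cycles get one synthetic
break node and survive as closed segments.

On thick vessels the raw trace contains junction-scale artifacts (stub
spurs, split junction clusters). A pruning pass removes spur segments
shorter than 10 px that hang off a junction, contracts junction–junction
links shorter than 4 px, and dissolves the degree-2 nodes left behind. On
the synthetic cohort this recovers the exact ground-truth topology
(5 endpoints, 3 bifurcations, 7 segments) for 27 of 30 seeds; the remaining
seeds yield a near-miss topology that degrades gracefully downstream. An
optional rectangular ROI crops the mask before skeletonization, standing in
for a manually outlined optic-disc region.

## Radius profiling

Vessel boundaries come from a Canny edge map. For each sampled centerline
point the tangent is the principal direction of a least-squares fit over
±3 neighbours (oriented along increasing index) and the normal is the
tangent rotated +90°. The radius is measured by marching along ±normal and
taking the first edge pixel within a 1 px corridor of each ray; the radius
is the mean of the two wall distances. A single-wall hit is used as-is but
flagged; no hit within the search range drops the point. Two-sided
averaging makes the estimate robust to a centerline that sits slightly off
the true axis.

Canny scale matters on binary input: at σ = 1 the non-maximum suppression
of a hard 0/1 step lands on the background pixel and every radius inflates
by about one pixel. The package therefore uses σ = 0.6 when the edge source
is a segmentation mask (`edges_from_mask`), which recovers straight tubes
of integer radius exactly; σ = 1.0 remains the default for intensity
images. Measured accuracy on noiseless tubes with radii 2–10 px: RMSE
≤ 0.5 px (about 0.23 px pooled over straight and curved fixtures), and a
90° rotation changes recovered radii by ≤ 0.25 px.

Centerlines are downsampled before contour construction; the interval is
chosen per segment as ⌈median radius⌉ so that the spacing between
successive cross-section contours exceeds the contour radius, which is what
prevents neighbouring contours from intersecting. A fixed interval can be
configured instead.

## Surface construction

Each sampled point contributes a circular contour (default 24 vertices) in
the plane normal to the local tangent. Ring frames are propagated by
parallel transport from the first ring, which minimizes twist; for the
planar centerlines used here the frame reduces to (in-plane normal, ẑ). If
consecutive rings still cross (jagged tangents on noisy centerlines), the
offending interior contour is dropped — a local re-downsampling — keeping
the first and last contours of every segment.

Tubes are lofted ring-to-ring (2·n·(k−1) triangles for k rings of n
vertices). At each junction the terminal contours of the incident segments
are compared: while the max/min radius ratio exceeds a threshold (default
1.5), the contour deviating most from the junction median is pulled halfway
toward the median — this removes the protruding silhouette a mismatched
contour leaves at a branch point. Each tube end incident to the junction is
then closed by a triangle fan converging on the junction point, so every
component is a closed surface and the merged wall has no boundary edges;
the components meet at geometrically coincident junction apexes.
Consistent outward orientation is enforced per component (positive enclosed
volume). Endpoint caps are labelled inlet (the widest terminal by default)
and outlets.

Local Laplacian smoothing (`v ← v + λ(centroid(neighbours) − v)`, default
λ = 0.5, 3 iterations) fairs the junction neighbourhoods; coincident
junction apexes are smoothed as one group with the union of their
neighbourhoods so the bridged tubes stay joined. Vertex and triangle counts
never change. Export formats: binary STL and OBJ via trimesh, plus a
minimal ASCII VTK PolyData (.vtp) writer that carries the face labels.

## Mesh quality

Four standard indicators, each anchored at the equilateral ideal:
element quality `4√3·A/Σlᵢ²` (equilateral → 1), aspect ratio `R/(2r)`
(circumradius over twice inradius, equilateral → 1), maximum interior
angle (best 60°), and equiangular skewness
`max((θmax−60)/120, (60−θmin)/60)` (best 0). Reports aggregate mean ± SD
over wall triangles, caps excluded by default. All four are invariant under
rigid motion and uniform scaling (property-tested). The absolute values on
lofted tubes reflect the ring/axial spacing anisotropy of the lofting and
are reported descriptively, not optimized.

## Hemodynamics

Full 3D CFD is out of scope; the simulation is a quasi-static lumped
(0D) Poiseuille network that reproduces the same feature schema. Each
vessel segment becomes one edge with hydraulic resistance
`R = 8μL/(πr⁴)` (L = polyline length, r = median segment radius, both
converted to cm through `px_size`; μ defaults to 0.035 dyn·s/cm², whole
blood). The inlet is the widest terminal node; all other terminals are
outlets at a fixed gauge pressure (default 0). At each of T time steps
(default 32 over one 1 s cardiac period) of the inlet waveform (half-sine
pulse by default, configurable peak flow), nodal pressures solve the linear
mass-conservation system with edge law `Q = ΔP/R`. There are no inertial,
compliance or non-Newtonian terms: pressures respond instantaneously to the
inflow. Mass conservation holds to machine precision and the solver is
verified against an independent series/parallel resistance-reduction oracle
on trees.

Per face (inlet + outlets) the solution yields flowrate and pressure
series plus mean/max/min summaries: `2FT + 6F` values — for F = 2 faces and
T = 32 steps, 140 features, the single-tube configuration. Derived
features: `Qmax_Time`, the time at which the across-face mean flowrate
peaks (ties broken to the earliest step); `Qmax_Time_from_cm`, the same
statistic with flow expressed in L/min (identical by construction, since
the argmax is invariant under positive rescaling — kept for schema
fidelity); and `Step_k_mean`, the across-face mean flowrate at step k, for
every k.

## Feature selection and classification

Three procedures over the subjects × features table:

1. **t-test filter** — per-feature two-sample equal-variance two-sided
   t-test, keep p < α (default 0.05); constant features are excluded with a
   warning. Type-I calibration is property-tested (null selection rate
   0.05 ± 0.02).
2. **F-test threshold scan** — one-way ANOVA F-test p-values per feature;
   a grid of p-value thresholds (default 0.001–0.100, step 0.001) is
   scanned and each induced subset is scored by leave-one-out accuracy of a
   given classifier (SVM by default); highest accuracy wins, ties resolve
   to the smaller subset, then the smaller threshold. For two classes
   F = t², so the two filters rank features identically and differ only in
   how the cut-off is chosen.
3. **Best-first search** — forward search over subsets with a priority
   queue keyed by LOOCV accuracy, expanding the best unexpanded subset by
   each absent feature, stopping after a fixed number of consecutive
   non-improving expansions. Deterministic under the feature-order
   tie-break; verified against exhaustive subset enumeration on a
   four-feature fixture whose unique separating pair is known.

The classifier battery (XGBoost, SVM, nearest neighbour, decision tree,
naive Bayes, logistic regression, random forest; library defaults, seeded)
is evaluated with leave-one-out cross-validation. By default selection runs
once on the full table and LOOCV measures the classifier only — the
protocol natural for 20-subject cohorts, but optimistic because selection
has seen every subject. A nested mode that re-selects inside each fold is
provided (`nested_loocv_accuracy`) and its honesty is property-tested on
pure-noise tables.

## Synthetic test bed

The generator produces what the pipeline needs to be tested end to end with
known truth: seeded planar vascular trees (default three branching levels,
8 px root radius, daughter radius = 0.8 × parent — about the proximal
optic-disc vessel scale at ~10 μm/px), exact pixel-center rasterized masks,
and fundus-like renderings (dark tubes, contrast mainly in G, smooth
Gaussian background texture). The two-class cohort multiplies every radius
by 0.7 in half the subjects, a diffuse narrowing whose r⁴ resistance effect
(≈ 4.2× higher pressures at fixed inflow) is the planted signal. The
feature-table generator plants standardized mean differences in a chosen
number of features, with the rest pure noise.

What passing on this bed shows: the geometric operators are correct at the
stated tolerances, the solver obeys its conservation laws, and the feature
machinery detects a physiologically-motivated global effect through the full
image→diagnosis chain. What it does not show: robustness to real fundus
photography (optic disc and fovea structure, lesions, illumination
gradients, vessel tortuosity and crossings, artery/vein contrast
differences), to projection effects, or to calibration error in `px_size`
— that scale is a required input with no universal default.

## Problem sizes used in tests

Unit and acceptance tests run at desk scale by choice: 128–256 px images,
20-subject cohorts, a ~10⁵-parameter network trained for 25 epochs on
64 patches/epoch, and 200-mask property sweeps. The same code paths accept
larger configurations unchanged.

## Known limitations

* The 0D flow model shares only the feature schema with a 3D simulation;
  absolute pressures and the time structure of the response are those of a
  resistive network, not of pulsatile 3D flow.
* Planar centerlines cannot represent vessels crossing at different depths;
  a crossing becomes a spurious 4-way junction.
* Radius estimates quantize at the pixel scale; sub-pixel edge localization
  is not attempted.
* Classic Zhang–Suen erases isolated compact blobs that erode to a 2×2
  square; irrelevant for connected vasculature but visible on speckle.
* The default (non-nested) selection protocol is optimistic on small
  cohorts; the nested option quantifies that gap.
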
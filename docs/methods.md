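# Methods

## The problem

Small deep-brain structures such as the substantia nigra (SN) change
subtly in neurodegenerative disease: quantitative MRI parameters — the
longitudinal relaxation time T1 (ms), the effective transverse relaxation
time T2\* (ms), and the total free water content FW (% of CSF) — decrease
by a few percent, which is invisible to ROI-averaged group statistics
because of partial-volume dilution and small cohorts.  qmriclust
implements a voxel-wise alternative: test every voxel for a *decrease* in
patients, and separate signal from the flood of uncorrected false
positives by the spatial structure of the rejections rather than by a
family-wise error correction.

## The estimator

Per voxel, the estimator E is a single parameter used in its native units
(E_T1 = T1, E_T2\* = T2\*, E_FW = FW) or the joint metric

    E_joint = s_FW · FW/n_FW + s_T1 · T1/n_T1 + s_T2* · T2*/n_T2*

with CSF normalization factors n_m and signs s_m ∈ {+1, −1}.  Because FW
is already expressed relative to CSF, its normalized term is ≈ 1 and
dominates; T1 and T2\* act as contrast enhancers when their group trends
point the same way.  Choices made here:

- **n_m statistic**: median over the CSF mask (robust to partial-volume
  voxels surviving the 0.95 threshold); mean available via
  `norm_statistic="mean"`.
- **Global, not per-subject**: one n_m per study, computed on the control
  cohort's voxel-wise mean map.  A cross-subject joint metric needs a
  common scale; a per-subject variant would additionally suppress global
  per-subject calibration offsets, but entangles the metric with each
  subject's own CSF estimate.
- **Signs**: s_m = +1 when the ROI median of the single-metric group
  difference d(E_m) is ≤ 0, else −1, so every term contributes a decrease.
  Sign suggestion runs only when a search ROI is supplied
  (`sign_mode="auto"`); aligning signs on the whole analysis mask with no
  hypothesis region is circular — under a global null it manufactures a
  decreased-looking joint metric — so without an ROI all signs default
  to +1.  `sign_mode="suggest"/"fixed"` force either behavior.

## Group inference

Each in-mask voxel carries a control vector (15 values by default) and a
patient vector (18).  The group difference map is d(E) = mean(E_p) −
mean(E_c).

**Voxel elimination.** A voxel is dropped — both vectors at once — when
any of its values deviates from the reference mean by more than k = 4
reference SDs.  The reference scope matters: within one group of n
values, the inclusive standardized deviation is bounded by (n−1)/√n
(≈ 3.61 at n = 15), so a literal per-group 4-SD rule can never fire in a
small cohort.  The default scope therefore pools all 33 values per voxel;
`per_group` (the literal, essentially inert reading) and `per_group_loo`
(leave-one-out per group) are available.  Constant vectors (0/0) are
never flagged.  Note the pooled scope deliberately flags true
between-group separations ≳ 4 pooled SDs as artifacts; at the 2-SD effect
sizes of interest this cannot trigger.

**Test.** Per voxel, a two-sample t-test with pooled variance
(df = n_c + n_p − 2), one-tailed against H0 "the metric has not
decreased"; p is the lower-tail probability of the t statistic, so small
p indicates a credible decrease in patients.  Welch's form is available
(`ttest_variant="welch"`).  Zero-variance voxels: p = 1 for equal means,
else 0/1 by the sign of the difference.  The H1 map is p < α with α =
0.05 strict.  **No multiple-comparison correction is applied by design**;
cluster filtering replaces it.

## Cluster filtering

H1 voxels are labeled into 18-connected components (6 face + 12 edge
neighbors; corner-only contact does not connect, which severs the weak
diagonal bridges typical of noise).  Two per-cluster predicates follow:

- **size ≥ 27** (inclusive — the 3×3×3 cube survives), the conventional
  noise floor for segmented volumes;
- **solidity ≥ 0.1**, solidity = voxel count / voxel count of the filled
  convex hull.  The hull is filled discretely (voxel centers inside or on
  the hull), keeping solidity a ratio of commensurable counts and exactly
  testable against brute-force point-in-hull enumeration.  Clusters
  spanning fewer than three dimensions are filled within the affine
  subspace they span, so thin planar sheets — the shape of
  tissue-interface misregistration residue — score low instead of being
  treated as degenerate.

Survivors are ranked from biggest to smallest (ties broken by ascending
centroid in index order).  The two filters are per-cluster predicates, so
their order is immaterial; they never merge or alter voxel sets.

## The synthetic phantom

Real co-registered cohorts of quantitative maps are rarely shareable, so
every stage is exercised on a generated study with known truth:

- **Geometry**: three nested ellipsoids on a 91×109×91 (2 mm MNI-like)
  grid — WM core (outer semi-axes 0.55 of the half grid), GM ribbon
  (0.80), CSF shell (0.92) — giving ≈ 242k GM∪WM voxels.  A user label
  volume can replace it.
- **Values**: subject map = compartment mean + per-subject compartment
  offset (drawn from the between-subject SD) + iid voxel noise.
  Compartment statistics default to published control-cohort values
  (GM: FW 83±1 %, T1 1501±40 ms, T2\* 56±5 ms; WM: FW 73±2 %,
  T1 1169±85 ms, T2\* 48±5 ms).  CSF values are not tabulated in that
  source; the defaults FW 100±0.5 % (CSF is the 100% reference by
  definition), T1 4000±100 ms and T2\* 1500±100 ms are physically
  plausible long-relaxation fluid values, chosen once.  Within-map noise
  defaults to 1% of the compartment mean; no within-subject noise figure
  is available from real data, so this is a stated convention.
- **Effects**: patients' values inside injected ellipsoids are scaled by
  (1 − f_m).  `bilateral_sn_layout` places two mirror-symmetric ~700-voxel
  spheres in deep tissue left/right of the midline; the default f_m is a
  2-between-subject-SD decrease of the host (GM) compartment per modality.
- **Outliers**: per subject, brain voxels are picked with probability
  1e−3 (positions shared across modalities, as a registration error
  would) and shifted ±6 between-subject SDs.  At that magnitude the
  pooled 4-SD rule flags most but not all of them: the outlier inflates
  the very SD it is measured against, capping its own standardized
  deviation near 4 (the cap is M(1−1/n)/√(σ² + M²(1−1/n)²/(n−1)) ≈
  3.5–4.1 for M = 6σ_b across the three modalities).  Recovery is
  essentially complete from ~10 SDs; voxels spiked by two subjects with
  opposing signs can mask each other at any magnitude.
- **Seeding**: one `SeedSequence` spawns three child streams (controls,
  patients, outliers), so reruns are bit-identical and stages are
  reproducible in isolation.

### What the phantom does and does not show

The phantom has no anatomy, no spatial autocorrelation of noise, no
actual misregistration warps, and — importantly — its between-subject
variation is a *single scalar per subject, compartment and modality*.
That last point has a consequence worth understanding: all voxels of a
compartment share their subject offsets, so voxel-wise tests are strongly
correlated, and the per-seed whole-mask rejection fraction is essentially
driven by the t statistic of the 15-vs-18 offset draw, not by
per-voxel binomial noise.  Roughly one seed in four draws offsets extreme
enough that a large fraction of a compartment rejects at once, producing
one giant (10⁴–10⁵ voxel) compact cluster that survives all filters even
with no injected effect — and, in effect seeds, swallows the injected
clusters.  This is not a pipeline artifact: it is the model's analogue of
a globally shifted cohort, the same phenomenon that makes T2\* decreases
appear brain-wide in real patient data.  Detection performance should
therefore be read per regime: in the ~75–80% of seeds without a global
offset event, the two injected clusters are recovered at ranks 1–2 with
Dice > 0.95; in offset-event seeds the method (correctly, given its
inputs) reports a global decrease instead.  Type-I calibration of the
*test itself* is asserted in the iid regime (independent values per
voxel), where the 5% nominal rate is recovered within binomial
tolerance.

## Numerical and degenerate-input conventions

- Tissue probability threshold 0.95, strict (`>`); a voxel exactly at the
  threshold is excluded.
- The analysis mask is (WM ∪ GM) ∩ elimination — WM and GM are disjoint
  at 0.95, so a literal three-way conjunction would be empty.
- ROI dilation uses discrete Euclidean balls of integer-increasing
  radius applied to the original seed; the first radius reaching the
  target voxel count wins.
- p-values outside the mask are 1; H1 thresholding is strict.
- Histograms are density-normalized over the reported range (default:
  100 bins across the central 99% of values) with the cropped tail mass
  reported separately, so a handful of extreme voxels cannot flatten the
  display while total mass stays accounted for.
- Cluster hull filling uses Qhull on the hull vertices only, so solidity
  of 10⁵-voxel clusters stays cheap; `find_simplex` tolerance is 1e−9.
- All grids are treated in voxel index space; affines are carried to
  outputs but never used to resample (inputs are co-registered by
  contract).

## Problem sizes used in the test suite

Unit and integration tests run on 20³–48³ grids with phantoms of ≈ 2×150
effect voxels; the end-to-end recovery and null studies run the joint
metric on the full default 91×109×91 phantom over 20 seeds each.  The
type-I calibration uses a 40³ iid simulation (64,000 voxels, 15 vs 18).

## Known limitations

- Inputs must be finished, co-registered quantitative maps; no
  registration, B1 correction or parameter fitting is performed.
- Cluster rank and geometry are reported without cluster-level corrected
  p-values; interpretation relies on the size gap between true structure
  (~700 voxels) and noise clusters (≲100 voxels).
- With global per-subject offsets and small cohorts, whole-compartment
  false positives are possible by construction (see above); a per-subject
  normalization or covariate adjustment would be needed to suppress them
  and is out of scope here.
- The solidity filter assumes artifacts are thin/sparse; a compact false
  positive passes it.
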
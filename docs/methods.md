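# Methods

## The measurement model

A subject contributes two breath-hold CT volumes — expanded (full
inspiration) and contracted (full expiration) — each with a lobe label map
assigning voxels to the right upper (RU, incorporating the right middle
lobe, whose minor fissure is often undetectable), right lower (RL), left
lower (LL) and left upper (LU) lobes. Lobe splitting itself is out of
scope: fissure identification is not algorithmically well-posed on
fibrotic lungs and is assumed done upstream (manually or by a dedicated
tool). The pipeline consumes the label maps as ground truth.

Threshold segmentation (default window −1024 to −500 HU, largest
connected components retained) is provided for whole-lung quality control
rather than as the source of the label maps. Its one arbitrary element,
the upper bound, is stress-tested by `upper_bound_sensitivity`: the lung
is re-segmented with the bound swept over −700…−300 HU and the relative
volume change reported; on well-behaved scans this stays under a few
percent. The same window must be used for both breath-hold states
(`check_state_consistency`), otherwise the inspiration–expiration volume
difference is confounded. Component filtering (default: the two largest
components of at least 1000 voxels, 26-connectivity) is an extension to
plain thresholding that removes airway lumina and noise islands; it is
configurable, and tests that compare against exact phantom ground truth
disable it or keep all four lobe components.

## Histogram statistics

For any masked region the HU distribution is summarized by mean, median,
and the population-moment shape statistics

    skewness = m3 / σ³        kurtosis = m4 / σ⁴   (normal → 3)

computed from raw voxel values (the histogram and its bin width, default
1 HU, matter for plotting only; no small-sample bias correction, since
lung regions contain ~10⁶ voxels). Vasculature is deliberately not
excluded: the soft-tissue peak near 0 HU is part of the signature, which
is why lung histograms are bimodal (air peak near −1000 HU, water peak
near 0). Degenerate regions (fewer than 2 voxels, zero variance) raise
errors rather than returning NaN.

## Lobar mechanics

With per-lobe volumes `v_e,i` (expanded) and `v_c,i` (contracted), the
package computes volume fractions `V_i`, lobar flow `Q_i` and lobar
strain `S_i` (formulas in the README). Conservation (`Σ V_i = 1`,
`Σ Q_i = 1`) and invariance under global volume rescaling hold to 1e-9
and are property-tested. Negative flow (a lobe that grows during
exhalation) is physically meaningful paradoxical motion and produces a
warning, not an error. A lobe with no labelled voxels yields zero volume
with a warning; strain is undefined for a zero expanded volume and raises.

## The discriminant score and its leave-one-out validation

The score of a subject's per-lobe quantity X against a healthy reference
(per-lobe sample mean and SD, n−1 denominator, at least two subjects,
strictly positive SD) is the mean of the four absolute standardized
deviations. The literature calls this an RMSD; the printed formula's
square root applies per lobe, so it is algebraically a mean absolute
deviation, not a quadratic mean. The literal form is the default; a
quadratic form `sqrt(mean z_i²)` is available for comparison and always
dominates the literal form (power-mean inequality).

Leave-one-out validation with n healthy subjects builds n references,
each omitting one healthy subject, and scores every subject against all
of them; the spread (SD) across references measures sensitivity to the
reference cohort's composition. A cohort of literally identical healthy
subjects makes the reference SD zero and the score undefined — this is
treated as a degenerate-input error, and near-zero leave-one-out spread
is instead exercised with duplicated-profile cohorts.

## Group statistics

Group comparisons use the Welch unequal-variance t-test computed from
summary statistics (Satterthwaite degrees of freedom) — robust to the
unequal sizes and variances of small clinical cohorts; a pooled-variance
variant is available. Family-wise correction is Bonferroni with the
family defaulting to the rows of the table being produced. Normality
screening uses the one-sample Kolmogorov–Smirnov test with mean and SD
estimated from the sample; this is anti-conservative (a Lilliefors
correction would reject more often) and is documented as a screening
check, not a calibrated test. Percent differences between group means are
reported as integers, rounded half away from zero. The GAP index follows
the standard bucket rules: G (0 women / 1 men), A (age ≤60 / 61–65 / >65
→ 0/1/2), P_FVC (>75 / 50–75 / <50 %predicted → 0/1/2), P_DLCO (>55 /
36–55 / ≤35 → 0/1/2, or 3 when DLCO cannot be measured), total 0–8.

## Synthetic data: what it emulates, and what it does not

**Phantoms.** Four disjoint quasi-ellipsoidal lobes are rasterized into
fixed grid quadrants by taking exactly N voxels of smallest normalized
ellipsoidal radius, where N is the litre target rounded to the nearest
voxel — so per-lobe volumes are exact to half a voxel, and the contracted
lobe (smaller N, same centre) is nested inside the expanded one. Default
volumes follow the healthy cohort means (5.56 L expanded / 2.46 L
contracted, flow split 22/30/27/21%); the fibrotic factory uses 4.07 L /
1.82 L with flow shifted to RU (36/20/21/23%) and a lower-lobe-dominant
fibrosis mixture component. Lung voxels draw HU from a Gaussian mixture:
air (−950 ± 40), tissue (0 ± 60, weight 0.2) and optionally fibrosis
(−400 ± 150), clipped to [−1024, 100]; background is soft tissue
(+40 ± 10). In the contracted state the air component's mean is shifted
so that per-lobe air content, `(1000 + mean HU) × volume`, is conserved
between states; with default lobe sizes the measured conservation error
stays under 1% (sampling noise on a lobe-mean at ~10⁵ voxels plus a small
clipping bias).

Not emulated: fissure geometry, airways, vasculature trees, honeycombing
texture, scanner noise and deformation between states (contraction is
re-rasterization, not registration — the pipeline never registers the
states, so nothing downstream depends on this). One real-data discrepancy
matters for testing: conserving air by shifting the *whole* air component
moves the contracted air peak to ≈ −500 HU, whereas real contracted lungs
keep an air peak near −700/−800 with more tissue per voxel. The threshold
window therefore bisects the contracted phantom's air peak, and the
upper-bound robustness check is accordingly run on expanded phantoms,
where it is meaningful. Consequently, passing phantom tests demonstrates
correct volume/flow/histogram *measurement*, not segmentation performance
on real expiration scans.

**Tabular cohorts.** Per-subject per-lobe quantities are truncated-normal
draws at configurable group means/SDs; fraction-valued quantities (Q, V)
are renormalized to sum to one per subject. Defaults: 13 healthy / 9
fibrotic subjects at the published group-mean flow and volume-fraction
profiles, plus whole-lung HU summary columns at the published group
means/SDs.

The flow dispersions are calibrated, once and deterministically, so that
simulated cohorts reproduce the published *fibrotic* flow-score summary
(mean 2.56, SD 1.08): a least-squares moment match over simulated cohorts
with common random numbers, bounded at per-lobe SD 0.12 (above which
paradoxical negative flows would exceed ~5% per lobe). The calibrated
values are σ ≈ 0.050 (healthy) and 0.12 (fibrotic, at the bound; the
printed mean/SD pair is slightly outside the Gaussian family's attainable
frontier). The healthy group's own score summary cannot constrain the
calibration at all: for any dispersion scale, the mean absolute
self-standardized deviation of a Gaussian sample is pinned near
√(2/π) ≈ 0.80, so simulated healthy cohorts score ≈ 0.78 ± 0.33 rather
than the published 0.46 ± 0.16. Reproducing a healthy summary that far
below the Gaussian floor would require a heavy-tailed/outlier covariance
structure across subjects and lobes that per-lobe truncated normals
cannot express.

This has one important consequence. On simulated cohorts the two score
*distributions* separate strongly (group means ≈ 0.78 vs ≈ 2.6), but the
strict range-separation event — every healthy subject scoring below every
fibrotic subject — occurs in only ~25–35% of replicates, because the
simulated healthy maximum (≈ 1.4 at n = 13) sits above the simulated
fibrotic minimum in most draws. Real cohorts, with their much tighter
healthy score distribution, can show clean range separation that this
generator family does not reproduce; the package reports the measured
separation rate rather than asserting the clean split.

## Numerical and reproducibility choices

* All generators take explicit integer seeds; identical spec + seed gives
  bit-identical output. The pipeline driver threads one seed through all
  stages, and reruns are byte-identical (metadata excluded).
* Median of an even count is the mean of the two central order
  statistics. Histogram bins cover [min, max] in steps of the bin width.
* Ties in phantom voxel selection are broken by stable sort on flat
  index, so geometry is deterministic across platforms.
* Voxel-to-litre conversion is `count × ∏spacing(mm) × 1e−6`; recovery
  tolerances are stated in voxel volumes (half a voxel per lobe target,
  one voxel per measured difference, with the flow tolerance propagated
  as `(1 + 4·max Q) × voxel/Δv`).
* Default problem sizes: 128³ phantoms (≈ 2.1 M voxels) for recovery
  studies, 48³ for unit-test phantoms, 100 replicates for cohort
  simulations — sizes at which every sampling-error tolerance in the test
  suite has at least 3σ headroom.

## Known limitations

* The discriminant score assumes a nondegenerate healthy reference; very
  small or duplicated reference cohorts make the leave-one-out spread
  unstable (visible as large loo_sd with fewer than ~5 healthy subjects).
* The KS normality p-value is anti-conservative (estimated parameters).
* Printed p-values in published summary tables depend on unstated family
  sizes and t-test variants; the package exposes both choices but does
  not claim to reproduce any specific printed p-value.
* DICOM ingestion, fissure detection, emphysema cluster analysis and
  mortality mapping from GAP stages are out of scope.
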
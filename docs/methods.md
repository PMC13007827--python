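# Methods

`epimap` implements a multimodal abnormality-mapping analysis for temporal
lobe epilepsy (TLE) surgery evaluation: regional features from three
modalities are z-scored against normative reference cohorts, patient-specific
abnormal region sets are derived by change-point thresholding of the ranked
z-scores, and the proportion of abnormal regions that fall inside the
resection is used to differentiate postsurgical seizure outcome
(ILAE class 1–2, free of disabling seizures, versus ILAE 3+).

## Feature extraction

**Gray-matter (GM) volume** is a per-region scalar (mm³). When computed from
label volumes, it is voxel count × voxel volume (`voxel.gm_roi_volume`).

**Superficial white matter (SWM) mean diffusivity (MD)** is the mean MD
(mm²/s) over white-matter voxels within 5 mm of a region's gray matter.
The "GM–WM boundary" is operationalized as distance to the nearest GM voxel
of the region, and each WM voxel contributes to the region whose GM is
nearest, computed with a Euclidean distance transform that respects
anisotropic voxel sizes. Regions with no qualifying voxel are missing, not
zero. All volumes are assumed pre-registered on one grid; no resampling is
performed.

**Interictal iEEG band power**: recordings are anti-alias resampled to
200 Hz, common-average referenced, and a 70-s interictal epoch is analyzed
with Welch's method (2-s Hamming windows, 1-s overlap, 0.5-Hz resolution).
Band powers integrate the PSD over half-open bins in delta (1–4 Hz), theta
(4–8), alpha (8–13), beta (13–30), and gamma (30–80 Hz); shared edges belong
to the upper band so nothing is counted twice. Per contact, the five band
powers are normalized to relative powers summing to 1; the log10 of the
relative power is what enters normative z-scoring. Normalizing *before* the
log is a deliberate choice: normalizing log-powers to sum to one is
ill-defined when logs are negative, whereas relative power is a
scale-invariant, interpretable quantity. Contacts are assigned to the
nearest region by Euclidean distance to the region's representative points;
contacts >5 mm from every region are excluded, as are white-matter contacts
>2 mm from gray matter and contacts flagged as artifactual. Regional values
average the log relative power over assigned contacts (averaging after the
transform). Regions without contacts are *unsampled* and propagate as
missing, never as z = 0. No notch filter is applied by default (synthetic
data carry no line noise); one is available for real recordings.

## Normative modelling

Batch (scanner) effects are removed with a parametric empirical-Bayes
location/scale model (the ComBat family): per region, batch offsets and
scales are estimated after covariate adjustment, shrunk across regions
(normal prior on offsets, inverse-gamma on squared scales, moment-matched,
iteratively solved), and removed while age and sex effects are preserved.
Batch parameters are estimated on the *controls only* and the resulting
transform applied to everyone; fitting on the pooled sample lets disease
effects leak into the batch estimates and measurably attenuates patient
z-scores (this is verified by a test planting a pathological shift).

The normative map stores, per region (× frequency band for iEEG), a linear
age + sex model fitted on controls and the residual SD (floored at
`sd_floor`, default 1e-6 in feature units, to keep z finite on degenerate
data). Patients are z-scored against the model prediction for their own age
and sex, signs preserved: GM atrophy is negative z, increased SWM MD is
positive z. Choosing covariate-adjusted residual z (rather than absorbing
covariates into the harmonization) is conventional normative-modelling
practice; a leave-one-out self-calibration utility reports the pooled
control z mean and SD so miscalibration (e.g. heavy tails) is visible
rather than hidden.

For iEEG, the regional abnormality score is the maximum |z| across the five
bands, with the achieving band and signed z recorded. The normative iEEG
map is built from designated reference channels (emulating channels outside
the clinically defined seizure onset zone).

## Abnormal region sets

Per modality, regions are ranked abnormal-first: GM z ascending, SWM z and
iEEG max-|z| descending, ties broken by region id. The threshold between
"abnormal" and "the rest of the distribution" is found on this ranked curve.

A subtlety drives the design: the ranked curve of a patient with *no*
abnormality is not flat — it is the quantile curve of the null score
distribution, and a piecewise-constant mean-shift model will always prefer
to cut it near the middle. The detector therefore works on the residual
between the ranked curve and the expected null order statistics (Blom
plotting positions of the standard normal for signed z; of the maximum of
five absolute standard normals for the iEEG score):

1. **Detection gate.** The scan statistic `max_k sqrt(k)·mean(r[1..k])`
   over the oriented residual `r` is compared with its null quantile,
   obtained from a deterministic Monte-Carlo simulation of the null score
   model (4000 draws, cached per sequence length). The gate level is 0.2
   for the MRI modalities and 0.1 for iEEG; these were calibrated jointly
   against two design requirements of the synthetic model — null cohorts
   must yield a median abnormal-set size of at most 10% of regions, and
   planted 2-SD structural effects must be recovered at ≥90% sensitivity by
   the multimodal union — before the corresponding tests were frozen.
2. **Segmentation.** A single-change-point Bayesian model with conjugate
   normal-inverse-gamma priors per segment (closed-form marginal
   likelihood, exhaustive scan over cut points, uniform prior, minimum
   segment length 2) is applied recursively: the first accepted segment
   must exceed 0.3 robust-SD units above the null curve, extensions the
   smaller 0.1. Priors are vague and scale with the sequence
   (`kappa0 = 0.01`, `alpha0 = 1`, `beta0 = var/2`), making detection
   invariant to affine transforms of the scores.
3. **Fallback.** If the gate fires but no segment clears its threshold, the
   scan maximizer is used as the cut.

Signed-z residuals are robust-standardized (median/MAD), so MRI abnormal
sets are exactly invariant to affine maps of the z-scores. iEEG scores are
compared to the null curve in their own calibrated units because
implantation deliberately targets suspect tissue: the sampled regions can
be majority-abnormal, and a within-patient scale estimate would be
contaminated (median/MAD tolerates at most ~50% contamination).

The direction conventions are enforced structurally: positive GM outliers
(the wrong direction for atrophy) can never enter the GM set, because the
residual is oriented abnormal-first before detection.

Modalities are combined by set union (MRI = GM ∪ SWM; multimodal =
MRI ∪ iEEG), with per-region provenance. iEEG contributes only over its
sampled coverage. Intersection ("concordance") combination is deliberately
not offered.

## Resection overlap and outcome statistics

A region is *resected* when strictly more than 10% of its volume overlaps
the resection mask. The per-patient score is the proportion of abnormal
regions resected; a patient with an empty abnormal set has an undefined
score and is excluded from the corresponding group comparison with an
explicit count (imputing 0 or 1 would fabricate signal).

Group comparisons between ILAE 1–2 and ILAE 3+ use: Mann–Whitney AUC
(equals pair counting; verified against an O(n²) oracle), step-rule AUPRC
(positives = seizure-free), a one-tailed Wilcoxon rank-sum test (exact by
enumeration up to 12 subjects, tie- and continuity-corrected normal
approximation beyond), and the DeLong placement-value test for comparing
the two correlated AUCs (pairwise deletion of patients missing either
score; z convention multimodal − MRI). Colocalization — is an MRI-abnormal
region more likely to be implanted, or iEEG-abnormal? — is a binomial
logistic regression pooling (patient, region) observations per outcome
group, restricted to ipsilateral regions (implantations are ipsilateral in
the synthetic model, so contralateral regions carry no information);
complete separation raises an explicit error rather than returning a huge
coefficient. Patient-level clustering is not modelled, matching a plain
binomial regression. Cohort description uses Yates-corrected chi-square
and tie-corrected Kruskal–Wallis. A leave-one-out cross-validation selects,
for each held-out patient, the threshold maximizing balanced accuracy on
the rest (ties toward the lower threshold) and reports held-out accuracy
and AUC.

## Synthetic cohort model

The generator emulates the *structure* of a two-scanner TLE surgery study:
97 MRI controls, 40 surgical patients (19 with a favorable profile), and a
normative iEEG channel cohort, on a 60-region two-hemisphere parcellation
(4 deep regions; a full-resolution mode is a config switch). All
randomness derives from one integer seed; identical configurations are
bit-identical.

Controls: per region, value = baseline + age/sex effect + batch offset +
batch-scaled Gaussian noise. GM volumes are a few cm³ with ~10%
between-subject spread and a subtle scanner offset; SWM MD is ~8×10⁻⁴ mm²/s.
Patients are drawn from the same model, then shifted in their true abnormal
regions: GM −2 control SD, SWM +2 SD by default — the subtle-atrophy regime
in which structural mapping is informative but imperfect. Each patient has
8 ipsilateral abnormal regions; the hippocampus analogue is involved in 60%
of patients, emulating mesial-temporal concentration without being
universal.

iEEG channels are sums of five band-limited noise components (4th-order
Butterworth bands, unit-variance, mixed with a 1/f-like profile) with
per-channel log-normal band-power jitter (SD 0.1 log10 units), 72 s at
256 Hz. A planted spectral effect of `e` z-units multiplies the designated
band's raw power by the factor that shifts its *relative* power by
`e × 0.1` log10 units after renormalization (naively scaling raw power is
compressed by the sum-to-one constraint, drastically so for the dominant
delta band — hence the default planted band is beta, where headroom
exists).

The outcome model encodes the clinical premise that seizure freedom
requires removing both the structural abnormality and the
electrophysiologically active focus:

    logit P(ILAE 1,2) = −5.5 + 3·(structural fraction resected)
                              + 10·(spectral-focus fraction resected)

Favorable profiles implant the abnormal regions with fidelity 0.9 and their
spectral focus coincides with the structural abnormality (misalignment
0.05); unfavorable profiles implant at chance level (fidelity 0.4 against
a 0.47 ipsilateral base rate) and their spectral focus is largely displaced
onto other implanted tissue (misalignment 0.95). Surgical thoroughness is
patient-specific (resect fraction ~ N(0.75, 0.2), clipped), independent of
profile, and surgery can only target implicated tissue: implanted abnormal
regions are removed with that probability, unimplanted ones only
incidentally (0.15), plus a few non-abnormal ipsilateral neighbours. The
spectral-dominant outcome weighting gives the iEEG modality genuine
incremental information over MRI, which is what lets the multimodal map
beat the MRI-only map in outcome differentiation — the qualitative
structure the analysis is designed to detect. Overlap fractions are drawn
so the strict >10% rule reconstructs the resected set exactly.

### What the generator does not emulate

No spatial autocorrelation between neighbouring regions, no realistic
seizure dynamics or spikes, no line noise or artifacts, no registration
error, no electrode trajectory geometry, and outcome depends only on
resected fractions. Passing tests therefore demonstrate the pipeline's
statistical machinery (calibration, recovery, ordering of effects) under
the stated model, not clinical performance on real data.

## Problem sizes and numerical choices

Default test and demonstration runs use 60 regions, 97 controls, 40
patients, 30 normative iEEG subjects and 70-s epochs; property tests reuse
the same model at 20–60 regions and tens of replicates, sizes chosen to
keep a full run in the order of minutes on one CPU. Degenerate inputs have
defined behaviour throughout: constant sequences yield no change point,
constant controls clamp to the SD floor (z = 0), empty abnormal sets
propagate as missing scores, zero-variance DeLong comparisons and separated
logistic fits raise explicit errors, and ties are broken deterministically
(region id in rankings, lower threshold in cross-validation).

## Known limitations

The change-point gate levels are calibrated for the score distributions
the normative model produces (approximately standard normal signed z); on
data with grossly miscalibrated z-scores, the null baseline is wrong and
the leave-one-out self-calibration should be consulted first. The iEEG
null baseline treats the five bands as exchangeable and independent, which
is conservative for the correlated relative-power bands. The DeLong AUC
comparison and the colocalization regressions are asymptotic and can be
unstable below ~10 subjects per group.
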
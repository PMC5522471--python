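# Methods

## Measurement model

A planar gamma-camera frame is modelled as a raster of counts with its
acquisition metadata (minutes post-injection, frame duration, tracer,
magnification). All quantification reduces an ROI on a frame to its
*per-pixel mean count*; totals are carried for audit but never enter an
index, so differently sized ROIs cannot bias a ratio. Under per-pixel
means, "area correction" of background activity is automatic: subtracting
the background *mean* from a nodule *mean* is independent of either ROI's
area.

ROIs are hand-drawn in clinical practice, so they are inputs here, not the
product of a segmentation step. Three geometric operations are modelled
explicitly:

- **Mirroring** about a vertical axis (`c' = round(2·axis − c)`,
  half-away-from-zero). With an integer or half-integer axis the map is an
  exact involution. The same operation serves both protocols: mirroring
  the nodule ROI *outside* the gland yields the wash-out background;
  mirroring it about the gland midline yields the contralateral
  normal-tissue ROI. A mirrored ROI that overlaps its source is flagged
  (`mirror_overlaps_source`) rather than rejected, since the validity of a
  background placement is a judgement call.
- **Copying to the late frame.** Identical grids copy verbatim. Differing
  matrices (the acquisition protocol allows 256×256 and 128×128) require an
  explicitly declared scale; pixels map through their centres
  (`floor((i+0.5)·s)`) with duplicates collapsed. The package never guesses
  which matrix was quantified — an undeclared mismatch is an error.
- **Decay correction**, `counts × 2^((t − t_ref)/T½)` with T½ = 360.4 min
  for ⁹⁹ᵐTc and reference time t_ref = 0 (injection). Correction is *off*
  by default: with both frames corrected to a common reference it cancels
  exactly in R.I. and multiplies the WOind ratio `LR/ER` by the analytic
  factor `2^((t_late−t_early)/T½)` (≈ 1.101 for the 50-min window), so the
  uncorrected values are primary and the corrected variant is a reported
  alternative, not a different method. The choice of reference time is
  therefore documented rather than consequential.

## Indices and decision rule

The wash-out index uses background-subtracted nodular means only
(`WOind = 100·LR/ER − 100`); the retention index uses
background-subtracted nodule-to-normal ratios
(`R.I. = 100·(DR − ER)/ER`). `ER ≤ 0` (nodule indistinguishable from
background) and non-positive ratio denominators are errors with dedicated
types; a *late* nodular mean below background is physically meaningful
deep wash-out and yields `WOind < −100` with a flag instead of an error.
Timepoints come from image metadata, not from hard-coded constants — the
formulas are time-agnostic and the +10/+60 min protocol belongs to the
data.

Classification is boundary-inclusive on both cutoffs (suspicious iff
value ≥ cutoff; −19 % for WOind, −11.94 for R.I.), matching the only
explicit inequality published (R.I.'s ≥). No reference-cohort value sits
on a boundary, so the convention is documented rather than data-forced.
Positive WOind values (net accumulation) are a fortiori suspicious.

Performance metrics are the standard 2×2 quantities on the percent scale
with exact Clopper–Pearson 95 % intervals (via `statsmodels`,
`method="beta"`); a metric with a zero denominator is reported as absent
with a reason string, never as 0. The published summary for R.I.
(specificity 57.1 %, accuracy 62.5 %) is inconsistent with the published
per-patient values, which give 4 TN / 12 FP among 16 benign nodules
(25 % / 40 %) while matching the same summary's PPV 25 %, NPV 100 %,
12 false positives and 4 benign calls; the package computes the
table-consistent values and attaches a note rather than attempting to
reverse-engineer the irreproducible pair.

## Phantom and cohort simulator

The simulator's job is to exercise the pipeline and the cutoffs with known
ground truth, not to claim physiological fidelity. Geometry: a 256×256
matrix (1.5 mm pixels) with two elliptical lobes placed symmetrically about
the midline, an isthmus band, a disc nodule inside one lobe (radius from
its physical size), and a thoracic background rectangle. Truth ROIs are
generated by the same mirroring operations the quantifier assumes, and the
geometry is validated (nodule ⊆ one lobe, lobes disjoint, mirrored
background disjoint from the gland).

Kinetics: each compartment has a count-rate density `a0`
(counts·px⁻¹·s⁻¹) and a retention factor `f ∈ (0, 1]` — the fraction of
its early rate remaining at the late frame, i.e. a single-exponential
wash-out collapsed to one number over the 50-min window. The ordering
`f_parenchyma < f_nodule` (parenchyma clears fastest) is enforced by
default because it is the kinetic fact that separates the two indices.
Defaults: `a0 = 0.20 / 0.12 / 0.02` for nodule/parenchyma/body background,
chosen so a ~220-pixel nodule ROI collects ~2.6×10⁴ counts in a 600 s
frame; `f = 0.70` (benign nodule), `0.90` (malignant), `0.50`
(parenchyma), `0.70` (body background). With `f_background = f_benign` the
benign analytic WOind is exactly −30 %, the malignant ≈ −7.8 %, straddling
the −19 % cutoff; both classes produce strongly positive R.I. values
(≈ +52 and +100), reproducing the retention index's false-positive
behaviour on benign nodules.

Counts are independent per-pixel Poisson draws from the compartment
intensities (`noise="poisson"`, seed required); `noise="none"` emits the
exact real-valued intensities so the pipeline can be checked against the
closed-form oracle to relative 1e−9. No detector blur, scatter,
attenuation or collimator response is modelled, and Poisson pixels are
independent — passing tests therefore validate the *arithmetic and
geometry* of the pipeline under counting statistics, not its robustness to
the spatially correlated blur, patient motion and manual-ROI variability
of real gamma-camera data.

Cohorts draw nodule and parenchyma retention factors from truncated
normals (support (0, 1], sd 0.05, class means as above), with the
parenchyma redrawn until it clears faster than the nodule; the malignant
count is fixed by deterministic rounding of `n × malignant_fraction`
(default 0.2, the reference cohort's prevalence). One seeded generator
drives labels, kinetic draws and per-patient Poisson seeds, making whole
cohorts byte-reproducible. With sd 0.05 the two classes sit roughly 2
standard deviations from the cutoff on either side, so a per-patient
misclassification probability of ~2 % is an intended feature of the
default conditions, not noise to be tuned away.

## Numerical and interface choices

- Pixel coordinates are 0-based `(row, col)`, row 0 at top; polygon ROIs
  include a pixel when its centre lies inside, top/left boundary
  inclusive (implemented as a +1e−9 nudge of the test point, exact for
  axis-aligned edges).
- Invariant checks in tests use relative tolerance 1e−9; the underlying
  arithmetic is exact ratios of float means, so anything looser would hide
  bugs.
- 16-bit PGM/PNG rasters are the reference image dialect (pixel value =
  count, metadata in a JSON sidecar); DICOM secondary capture is supported
  for interchange. Writing a real-valued raster (noiseless synthetic or
  decay-corrected) to an integer dialect is an error, never a silent
  rounding.
- The test suite and the acceptance script size their simulations to run
  on one CPU in well under a minute each: 200 Poisson replicates for
  calibration, 100 random kinetic parameter sets for oracle equivalence,
  and a 100-patient simulated screening cohort.

## Known limitations

- The reference cohort carries printed index values, not images or ROI
  counts, so per-patient indices can be validated only against the phantom
  oracle; the cohort validates the classification and evaluation layers.
- The simulator's count scale and kinetic distributions are engineering
  defaults consistent with the acquisition protocol (600 s frames), not
  fitted to measured data.
- The visual-pattern column of the cohort is carried as inert metadata;
  no visual-classification model is implemented.
- Exact binomial intervals are reported per metric; no correlation between
  metrics or paired-method inference (e.g. McNemar) is attempted at n=20.
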
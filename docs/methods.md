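# Methods

## The planning model

A limb is 13 named landmarks in a canonical coronal frame (+x medial,
+y proximal, mm); left limbs are mirrored on ingest so one code path
serves both sides.  The femoral mechanical axis runs from the femoral
head centre to the intercondylar notch, the tibial axis from the
eminence centre to the plafond centre; the two knee-centre points are
kept distinct (1 mm apart by default), matching how the axes are drawn
on radiographs.  All angles are computed from direction vectors with
`atan2`/`acos` — no small-angle approximations anywhere in measurement
code — and every measurement is invariant under rigid motions and
mirroring to 1e-9.

Signs: HKA is negative in varus.  In this frame a varus limb has its
ankle deviated medially relative to the prolonged femoral axis, which
places the weight-bearing line medial to the knee; the WBL ratio is the
intersection parameter on the *infinite* plateau line (medial edge 0,
lateral edge 100), so over-varus limbs produce negative ratios.  JLCA
is the signed angle between the joint lines, positive when the joint
opens laterally; with these conventions the closure identity

    HKA = (mMPTA − 90) + (90 − mLDFA) − JLCA

holds exactly in 2-D, not just to small-angle order.

## Osteotomy simulation

Opening and closing wedges are both pure rotations of the distal
fragment about a cortical hinge (closing = resect then close ≡ rotate
into the removed wedge); no translation component.  Cut and hinge
placement follows the planning protocol:

* DFO: transverse cut 40 mm proximal to the technique's reference
  epicondyle; hinge on the opposite supracondylar cortex line, inset
  `hinge_inset_femur_mm` (default 5 mm) along the cut.
* MOWHTO: transverse cut 35 mm distal to the medial plateau; hinge
  leaves a 5 mm lateral bone bridge inside the lateral cortex.
* LCWHTO (hybrid): cut from the lateral cortex 40 mm distal to the
  lateral plateau to the medial cortical inflection point; hinge at
  parameter 0.75 along the cut from its lateral end (a 3:1 split).

Cut levels are horizontal in the canonical frame and fragment
membership is decided by y-comparison against the hinge level; limbs
stand near-vertical (≤ ~8° tilt), so this matches cutting transverse to
the bone to well under a millimetre.  A landmark within 1e-6 mm of the
cut level is an error rather than an arbitrary assignment.

Correction angles are solved by bisection on [0°, 25°] (tolerance
1e-4°) of the *measured* post-osteotomy quantity: mLDFA for the femur,
WBL ratio for the tibia.  The naive guess (angle = mLDFA − target) is
~15% too small because rotating the notch swings the mechanical axis
itself; the solvers absorb this feedback.  Both responses are strictly
monotone over the bracket, so roots are unique; a limb already within
measurement slack of the target (0.009° / 0.045 points) gets zero
correction.  Achieved residuals are |mLDFA − 85| ≤ 0.01° and
|WBL − 62.5| ≤ 0.05 points on every planned limb.

The protocol order is fixed: femur first to mLDFA 85°, then the
residual varus in the tibia to WBL 62.5% (both targets configurable in
`StudyConfig`; the study pipeline uses these defaults).  A knee whose
pre-operative mLDFA is already below the femoral target receives zero
femoral correction with a warning, never a varus-producing wedge.
Length outcomes are Δfemur, Δtibia, Δtotal (post − pre, positive =
lengthening); the symptomatic flag is the strict two-sided rule
|Δtotal| > 6 mm.

A structural note: the "same target ⇒ same angle" symmetry between the
two DFO techniques is only approximate.  The cut sits 40 mm above the
technique's *own* epicondyle and the hinge on the opposite cortex, so
cut level and axis feedback differ; measured over the cohort the two
angles agree to 0.17° on average, degrading to ~0.35° at the largest
(~7°) corrections.

## The synthetic cohort

The generator emulates the pre-operative radiographs of a 44-knee
varus-osteoarthritis cohort on one-leg standing films.  Five quantities
are drawn per limb from truncated normals (mean ± sd, truncated to the
observed range):

| quantity | mean ± sd | bounds |
|---|---|---|
| HKA (°) | −11.0 ± 2.5 | (−16.4, −6.1) |
| mLDFA (°) | 88.9 ± 1.9 | (85.9, 93.3) |
| mMPTA (°) | 83.7 ± 2.0 | (79.9, 87.8) |
| femur (mm) | 411.2 ± 37.0 | (350.8, 542.3) |
| tibia (mm) | 340.6 ± 27.5 | (303.7, 422.1) |

Sampling is by inverse CDF on the truncated interval so that rejection
accounting is reserved for the closure step: the three angles of a
standing varus knee are mutually inconsistent without a joint-line
convergence term, so JLCA is set to the closure residual (mean ≈ 5.8°,
plausible for varus knees with medial cartilage loss under load) and
the draw is rejected outside [0°, 12°] (~11% rejection under defaults;
a rate above 50% raises a parameter-inconsistency error).  Draws are
independent before closure — the true covariance structure of such
cohorts is unreported — and one global seed with per-limb counter
substreams makes the first k limbs independent of n.

The WBL ratio is never drawn.  It emerges from the constructed
geometry, which makes its cohort statistics a non-circular check of the
anatomy constants: with the defaults the emergent mean/sd land near
−2.0% / 11.1% (the reference values), validating the plateau-width
choice.

## Anatomy constants and their calibration

Alignment statistics do not pin down bone silhouettes, so a handful of
constants are calibrated rather than measured, and all are exposed in
`CohortParams` / `StudyConfig`:

* `plateau_width_frac` = 0.20 of tibial length (~68 mm) — sets the
  HKA→WBL conversion; validated by the emergent WBL statistics above.
* `condyle_width_frac` = 0.195 of femoral length (~80 mm).
* `hinge_inset_femur_mm` = 5 — the protocol says only "between the
  condyle and the cortex"; 5 mm inside the far cortex gives a
  hinge-to-axis lever of ~35 mm, reproducing the published femoral
  length changes (±~2.8 mm at the mean correction).
* `tibial_flare_mm` = 14 — lateral cortical silhouette at the HTO cut
  level extends beyond the articular plateau edge (metaphyseal flare
  plus marginal osteophytes in grade-3/4 knees); sets the MOWHTO hinge
  lever (~43 mm) and hence the tibial lengthening (~+7 mm at typical
  corrections).
* `inflection_overhang_mm` = 4, `inflection_depth_mm` = 55 — place the
  medial cortical inflection landmark; together with the 3:1 rule they
  set the LCWHTO hinge lever (~16.5 mm) and the tibial shortening
  (~−4 mm).
* `notch_eminence_gap_mm` = 1, epicondyles 25 mm proximal to the joint
  line, condylar-cortex landmarks 45 mm proximal to the notch (their
  height does not enter any measurement or lever; only the cortex line
  through them does).

The hinge-lever constants were fixed once, by solving the planning
mechanics at the cohort means against the published mean length changes
of the four procedures, and are not tuned per run.  Because they are
calibrated to outcome statistics, agreement of the simulated mean
length changes with the reference is a consistency check of the whole
pipeline, not an independent prediction; the *distributional* structure
— per-procedure spreads, the symptomatic proportions, the sign pattern,
the near-cancellation in LCWDFO+LCWHTO, and the correlation of pre-op
HKA with Δtotal (strongest for the double opening wedge, absent-to-weak
for the double closing wedge) — emerges from the model.

## Statistics

Paired t (hand formula, two-sided, t-distribution with n−1 df; zero
difference variance is flagged, with equal samples reported as t = 0,
p = 1), Cochran Q from the textbook formula with df = k−1 (a fully
degenerate matrix reports Q = 0, p = 1, flagged), exact binomial
McNemar for the six pairwise follow-ups with Bonferroni factor 6 (the
standard matched-pairs follow-up; the reference protocol names only
"the Bonferroni test"), and Pearson r via `scipy.stats.pearsonr`.
Histograms are binned at 1 mm from −10 to 25 mm.  P-values are kept at
full precision in JSON; "<0.001" rendering is left to consumers.
Measurement reliability statistics (ICC) are deliberately absent:
measurements here are deterministic code, so reliability is replaced by
determinism tests (same seed ⇒ byte-identical reports).

## What the tests do and do not show

The synthetic cohort reproduces marginal distributions, the closure
identity and the emergent WBL statistics of a real varus cohort, but
not: inter-variable covariances (unreported), real bone silhouettes
(two-parameter cortex model), soft-tissue JLCA change after correction
(planning is on rigid bones), measurement noise, or side-to-side
structure.  Passing tests therefore validate the planning *geometry*
and the statistical machinery under the stated cohort model; they do
not validate predictions for an individual patient's radiograph beyond
that model.  Problem sizes: property checks run on 50–300 limbs;
stochastic reproduction targets use 2,000 limbs (chosen so Monte-Carlo
error is well inside the tolerance bands) plus a 44-knee study-size
run; the statistical oracles use 200 random small datasets.
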
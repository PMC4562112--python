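# Methods

## Problem and measurement model

Periapical radiographs are the standard instrument for following marginal
bone loss around teeth over time. The direct approach measures the
radiographic bone level (RBL) — the distance from the cemento-enamel
junction (CEJ) to the alveolar crest (AC) — in millimetres on the image.
That distance is only meaningful if the projection geometry is identical at
every examination; in practice the angle α between the receptor and the
plane perpendicular to the central beam varies between exposures
(especially in the maxilla), and the image of every structure is elongated,
foreshortened and magnified by amounts that change from visit to visit.

The indirect technique implemented here measures instead the
*length-adjusted* bone level

    relRBL = 100 · b / a   [%]

where `b` is the CEJ→AC distance and `a` the tooth length (crown reference
INC/OCL → root apex), both taken as coordinates on an imaginary vertical
axis parallel to the vertical edge of the receptor — i.e. only the y pixel
coordinate of each clicked landmark enters, scaled by the image calibration
(mm/px). Any distortion that rescales that axis uniformly multiplies `a`
and `b` by the same factor and cancels in the ratio; the measurement
becomes a property of the tooth, not of the exposure geometry.

Distances are absolute values of axis-coordinate differences, so image
orientation (origin upper-left, y downward) never flips signs. Euclidean
2-D point-to-point distance is deliberately *not* used: the vertical-axis
rule is what makes the two aspects of a tilted root commensurable and the
ratio exactly invariant.

On multi-rooted teeth the mesial aspect's relRBL uses the mesial root's
length and the distal aspect the distal root's; single-rooted teeth use
their only root. The pairing is a documented package choice (the
alternative — whole-tooth length for both aspects — is not exposed).
`b > a` raises a warning but returns the value; silently clamping would
bias study means.

## Projection geometry

The simulator places the receptor plane through the origin, the central
beam along −z and the point source at (0, 0, f). Receptor tilt α_r is a
rotation about the horizontal x-axis, so the receptor's in-plane vertical
is (0, cos α_r, sin α_r). Two modes exist:

* **parallel** — projection along the beam direction; receptor tilt
  produces exact uniform elongation 1/cos α_r of all vertical coordinates
  (independent of depth), tooth tilt α_t produces foreshortening cos α_t.
* **central** — ray/plane intersection from the point source; an object at
  standoff d is additionally magnified by f/(f−d) (≈5.3 % at f = 300 mm,
  d = 15 mm, inside the 5–6 % band typical of periapical imaging).

`scale_factor` returns the nominal product of the three factors. In
central mode with a tilted receptor the true local scale varies along the
tooth, so elongation is *not* uniform: a simulated 30° central exposure
inflates tooth length by ≈10 % (not 1/cos 30° = 15.5 %) and leaves a small
residual bias of order −1 % in relRBL. This is a genuine property of
divergent-beam geometry, surfaced by the simulator and documented here.

The **default study geometry is parallel mode** (0° vs 30°). A dual-angle
bench comparison in which direct tooth length and direct bone level
inflate by nearly the same factor while the ratio stays put is the
uniform-elongation regime, and parallel projection renders it exactly;
central mode is provided for magnification scenarios and for exploring the
non-uniform regime.

`bias_comparison` quantifies the trade-off governing when length
adjustment is worthwhile: between two exposures differing in angle, the
direct technique's error on an object of size s is s·(1/cos α − 1) (so
small objects, below ~2 mm, suffer little absolute error), while the
ratio technique's error is zero under uniform scaling regardless of s.

## Synthetic study generator

`run_experiment` reproduces a dry-mandible bench experiment in silico:

| parameter | default | rationale |
|---|---|---|
| n_teeth | 20 | bench cohort size |
| tooth length | U(18.2, 24.1) mm | observed caliper range |
| bone level | N(7.0, 1.0) mm, clipped | artificial elevation ≈7 mm; the SD matches the observed ≈1 mm between-site spread, without which reliability coefficients are degenerate |
| cej_offset | 2.0 mm | CEJ below the crown reference |
| fraction multirooted | 0.35 | mandibular mix of molars and single-rooted teeth |
| aspect offsets | ±3 mm | lateral CEJ/AC displacement; makes the vertical-axis rule consequential |
| examiners × repeats | 4 × 2 | blinded multi-reader design |
| click noise | 0.15 mm isotropic Gaussian per landmark coordinate | not an empirical datum; chosen so simulated ICCs land in the 0.8–1.0 band reported for trained periodontists, and exposed as a knob |
| mm_per_px | 0.06 | typical storage-phosphor plate resolution |

Teeth are held perfectly still between exposures (the bench used stents
and wax seating), so angle is the only systematic difference between
conditions. Examiner bias defaults to zero; when set, it shifts the AC
click apically, modelling a systematic crest-reading tendency.

What the generator does *not* emulate: pixel-level image content (no blur,
noise or contrast physics — readers click on geometric truth plus Gaussian
error), landmark-specific error anisotropy, occasional gross misreads, and
tooth movement between visits. Passing tests therefore demonstrate the
geometric and statistical machinery, not reader performance on real
radiographs.

## Statistics

* Paired two-sided t-test between angle conditions, site as the unit
  (each tooth contributes a mesial and a distal site; a site's value at an
  angle is the mean over all examiner × repeat reads). Zero-variance
  differences are reported as t = 0, p = 1 (identical) or p = 0 with a
  flag (constant shift) rather than NaN.
* Inter-examiner reliability: ICC(2,1) — two-way random effects, absolute
  agreement, single measures — on the (site × angle) × examiner matrix of
  repeat-mean reads, with Shrout–Fleiss F-based 95 % CIs. The estimator
  and intervals were verified against pingouin's ICC(A,1) and a
  brute-force ANOVA mean-squares oracle.
* Intra-examiner reliability: one-way single-measure ICC(1,1) across the
  two blinded reads within each examiner; the pooled value is the
  target-count-weighted mean of per-examiner estimates (pooled CI bounds
  averaged the same way — an approximation, flagged as such).
* Degenerate inputs: all-constant data → NaN with `no_variance`; an
  estimate ≤ 0 (no between-site signal) is returned but flagged.
* No multiplicity correction across the three metrics; α = 0.05.

The site-level paired test treats the 40 sites as independent although the
two aspects of one tooth share the same tooth-length clicks; the resulting
mild anti-conservativeness is inherent to the bench design itself and left
as is.

## Numerical choices

* All computation in double precision; rounding to 0.1 mm / 0.1 % happens
  only in presentation (reports, `--round`), never before analysis.
* Millimetres everywhere in the geometry layer; the single mm↔px
  conversion point is the measurement layer's calibration.
* Parallel mode is an explicit flag, not a large-f sentinel; the central
  projector rejects points at or behind the source and rays parallel to
  the receptor plane with a dedicated error.
* Simulated pixel frames add a 5 mm margin so click noise cannot push
  coordinates negative.
* Seeds: cohort and reader streams are separate `numpy` Generators; an
  experiment-level seed overrides both (reader offset by a fixed prime) so
  one integer reproduces a full study bit-for-bit, including CSV bytes.

## Scale of the shipped experiments

The default experiment (20 teeth × 2 angles × 4 examiners × 2 reads) runs
in well under a second; property checks use 1000 random configurations and
Monte-Carlo checks 500 replicates — sizes at which every documented
tolerance is comfortably resolved on a single CPU.

## Known limitations

* The nominal `scale_factor` is first-order in central mode with tilt; use
  the projector itself when the non-uniformity matters.
* The pooled intra-examiner CI is an average of per-examiner bounds, not a
  joint interval.
* Reported empirical behaviour (distortion percentages, ICC ranges,
  p-value patterns) refers to quantities the test suite and
  `scripts/acceptance.py` recompute at run time; no bench data ships with
  the package.
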
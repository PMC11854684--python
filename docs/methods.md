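# Methods

This note documents the measurement model behind `ghostgrade`, the
parameter defaults and why they hold, what the synthetic cohorts do and do
not emulate, and the numerical choices that matter for reproducing its
numbers.

## Image-formation model

A fundus photograph of a nystagmic eye is modelled as a weighted sum of
rigidly transformed copies of a still retina — *discrete foveation
positions*, not continuous motion blur. The eye spends most of each
oscillation cycle dwelling near foveation points, so the exposure
integrates a few sharp copies rather than a smear; photographs of real
nystagmic eyes show exactly this "double or triple image" appearance.
Copy *i* of *n* ∈ {1, 2, 3} is displaced by `(i − (n−1)/2) · (dx, dy)`
pixels and rotated by `(i − (n−1)/2) · θ` degrees about the macula
(fixation) centre; adjacent copies are therefore exactly `(dx, dy)` and
θ apart, and the set of copies is symmetric about the resting position.
Torsion is applied about the macula because torsional nystagmus rotates
the globe about the line of sight. Exposure weights default to uniform; a
dominant-foveation preset (0.7/0.3) models asymmetric dwell. Gaussian
pixel noise is added after compositing and the result is clipped to
[0, 1].

Whether real ghost images arise from multi-flash capture or intra-exposure
dwell is not established; the discrete-copy model is an explicit
assumption of this package.

Coordinates are image coordinates: origin top-left, 0-based, x rightward,
y downward; angles counterclockwise-positive as displayed. Displacement of
the eye is reported as displacement of the retinal image (no sign flip).

## Synthetic retina

The vessel phantom consists of a vignetted background, a bright optic disc
(diameter 11% of image width, matching a ~1.5 mm disc on a 45° field), a
darker macula at the canvas centre, and a dark random binary-branching
vessel tree rooted at the disc with geometrically decreasing caliber
(decay 0.78/branch, 5 trunks, depth 5), yielding 60–130 bifurcation
landmarks. Everything is a pure function of `(size, seed, branching
parameters)`.

What the phantom does **not** emulate: photorealistic retinal texture,
pathology (albinotic fundus, foveal hypoplasia), colour, optics/defocus,
non-rigid distortion, eyelash/blink artifacts. Passing recovery tests on
phantoms therefore demonstrates correctness of the measurement chain under
the stated image-formation model, not clinical-grade performance on real
photographs.

## Displacement estimation

The photograph is vessel-enhanced with a Sato ridge filter (sigmas 1.0 and
1.6 px; ghost contrast lives in vessel structure, and ridge filtering
suppresses low-frequency shading). The estimator computes the
window-compensated (Hann, zero-padded ×2) autocorrelation of the
*gradient* of the enhanced field — the negated Laplacian of the plain
autocorrelation — which narrows the central lobe from the vessel width to
the vessel-edge width; without this sharpening, offsets below ~8 px merge
into the lobe. Off-centre local maxima above `peak_threshold` (default
0.2 of the central peak) outside the exclusion radius `min_separation`
(default 4 px) are candidate ghost peaks; the strongest gives `(dx, dy)`,
refined to sub-pixel by separable quadratic fits. A secondary peak at
twice the offset (collinear within max(3 px, 20%)) marks a triple image;
the confirmation peak needs only half the primary threshold because it is
sought at a predicted location.

Offsets below the `displacement_floor` (default 3 px) report as a single
exposure. This makes the small-amplitude failure mode of still
photographs explicit: subtle oscillations produce almost no artifact. In
practice the *resolution* floor of the autocorrelation route on
vessel-width structure is ~5–6 px; between 3 and 6 px detection is
possible but not guaranteed.

Sign convention: a still composite is invariant under negation of the
offset, so the dominant-magnitude component is made positive (ties toward
x). Folding on the dominant component (rather than strictly on dx) keeps
the convention stable when a near-vertical offset has a tiny, noisy dx.
All recovery metrics compare vectors up to global negation — the
physically meaningful equivalence.

## Torsion estimation

An annulus of radii [0.15, 0.45]·min(side) around the fixation centre is
resampled to polar coordinates (0.5° angular bins, 2-px radial steps,
bilinear interpolation). Rows are mean-subtracted, sharpened by a circular
first difference along the angle axis (the angular analogue of the
gradient trick: without it a 2° rotation sits on the central lobe's
shoulder and is not a local maximum), weighted by radius (outer rings have
finer angular resolution), and their circular autocorrelations are
averaged. The strongest off-centre angular peak above threshold, refined
by a quadratic fit, gives θ; values below `rotation_floor` (default 1.5°)
report 0. The autocorrelation is an even function, so only |θ| is
recoverable; the sign of a torsional beat cannot be read from one still
image.

When a linear ghost offset is present the angular autocorrelation is
smeared by translation, so the torsion threshold is doubled in the
combined quantifier to avoid spurious rotary calls on purely linear
nystagmus. The converse limitation is physical and worth stating plainly:
when torsion and translation are *both* large, the copies differ by a
rotation, the translation autocorrelation peak collapses, and neither
component is reliably measurable from the composite. The synthetic
cohort's "combined" class is therefore generated as diagonal linear
displacement; the classifier still maps a torsion-plus-linear estimate to
"combined" if one is presented.

## Landmark matching

Bifurcations are skeleton pixels of the thresholded (Otsu) vesselness map
with ≥ 3 branch neighbours, merged within 3 px. All pairwise offsets
within a 0.3·min(side) search radius are sign-folded and histogrammed in
2-px bins. Regular vessel geometry alone produces accidental bins with up
to ~9% of the landmark count as support, while duplicated anatomy votes
with ~30%, so consensus requires support ≥ max(3 pairs, 15% of landmarks);
the modal offset is refined as the mean of its supporters. A secondary
consensus at twice the modal offset with ≥ 47.5% of the primary support
marks a triple (true triples measure 60–70%, doubles' same-copy background
30–36%). Fewer than six landmarks is an error, not a silent zero.

## Disc geometry and grading

The optic disc is the brightest blob above half-maximum contrast (after
Gaussian smoothing, σ = width/128) whose *minor axis* — robust to ghost
elongation — falls in 2–15% of image width; detection failure falls back
to 8% of width with a warning. On double exposures the estimated diameter
runs 10–20% low (each copy has half contrast), which biases normalised
displacement slightly upward in the fully-automatic path; pipelines that
know the true geometry (simulation, calibrated cameras) should pass it in.

Amplitude is `|displacement| / disc diameter`; a torsion-only estimate is
converted to the arc length swept at the annulus mid radius
(0.30·min(side)). Grade cut-points 0.15 and 0.40 DD are configurable
defaults chosen to reproduce the canonical small/medium/large exemplar
ladder on matched phantoms; intervals are half-open, lower-inclusive on
the upper bin (exactly 0.15 → grade 2, exactly 0.40 → grade 3). No
anatomically-normalised published cut-points exist for this scale; raw
pixel distances would tie grades to camera magnification, which is why
normalisation by the disc is the default.

Direction: the offset angle folded to [0°, 90°] from horizontal is binned
at 30°/60° (≤ 30° horizontal, ≥ 60° vertical, else combined); torsion
above floor with no linear component is rotary, with a linear component
combined (the multi-component class). Ghost count is reported but does not
alter the grade.

The qualitative arm emulates a by-eye grader: no sub-pixel refinement,
peak threshold 0.15, and grade cut-points scaled by 0.8 — a by-eye grader
saturates earlier, reproducing the tendency of qualitative assessment to
assign the large grade more often than pixel measurement does.

## Synthetic cohorts

`sample_cohort` draws per-eye direction classes from a mix anchored to the
photographic direction distribution of the motivating 53-eye cohort
(horizontal 17, vertical 3, rotary 4, combined 11, no ghost 18 of 53) and
amplitude grades among detected eyes from its quantitative amplitude row
(5/12/17 of 34). Normalised displacements are sampled uniformly within
per-grade bands (0.110–0.135, 0.165–0.360, 0.440–0.700 DD) that keep every
eye ≥ 10% away from both cut-points, and — for the small grade — above the
~6 px practical resolution floor discussed above. Ghost count is 2 with
probability 0.7, else 3. Pixel noise defaults to σ = 0.01.

Clinical records add two documented disagreement mechanisms, both
configurable: with probability `p_over = 0.2` the clinician over-calls the
amplitude by one grade (capped at 3; clinicians tend to overestimate
amplitude), and with probability `p_missrot = 0.5` a true torsional
component is recorded as its linear projection (torsion is under-called at
the slit lamp relative to the photograph; the 0.5 default mirrors the
observed "half of the cases" discrepancy). Eyes with no photographic ghost
(latent-like) are still clinically recorded — as small horizontal
nystagmus — because clinical examination was the inclusion criterion of
the emulated study; the clinical amplitude is never 0.

## Statistics

Percent agreement is raw exact-match percentage; the default denominator
for photo-vs-clinic agreement is the eyes detected by that photographic
arm (an undetected photograph expresses no direction or amplitude); the
all-eyes denominator is exposed because the two arms detect slightly
different eye sets. Percentages are rounded half-up: one decimal for
cohort tables, two for detection rates. Cross-arm agreement is computed
over eyes detected by at least one arm. Cohen's kappa is available as an
optional extra but is deliberately not part of the core report, which uses
raw agreement only.

Mann–Whitney U uses midranks. Exact mode enumerates all C(n, n_a) group
assignments and reports the two-tailed `p = P(|U − μ| ≥ |u − μ|)`
(μ = n_a·n_b/2; the permutation distribution is symmetric under rank
reversal, so this equals the doubled tail). Normal mode applies the
tie-corrected variance and a 0.5 continuity correction. All observations
identical across both samples is a degenerate comparison reported as
p = 1. Which two groups the motivating analysis compared is not stated;
this package applies the test to the two photographic arms' grade
distributions and labels it as such.

Longitudinal comparison reports per-interval grade deltas and detection
changes, a `resolved` flag (last session grade 0 after an earlier nonzero
grade, the post-surgical resolution pattern) and an `intermittent` flag
(detection toggling more than once, the paroxysmal/latent pattern).

## Determinism and problem sizes

Every stage is a pure function of `(config, seed)`: cohort draws, phantom
seeds and noise seeds all derive from one seed sequence; JSON is written
with sorted keys and files atomically (temp + rename), so a rerun is
bit-identical. The validation suites use a 200-image displacement grid
(8–80 px, 4 directions, noise up to σ = 0.05), 9 rotations spanning
2–10°, a 40-eye noise-free grade-recovery cohort, 100 noise-free doubles
for cross-estimator agreement, and a 200-eye default-noise cohort for
cross-arm statistics — sizes chosen to estimate the ≥ 90–95% rates in the
checks with comfortable margins while keeping a full run in minutes on one
CPU.

## Known limitations

* Still photographs carry no temporal information: beat direction, slow
  vs fast phase, frequency and waveform are out of reach by construction.
* Simultaneous large torsion and large translation defeat both estimators
  on a single composite (see above).
* Disc-diameter underestimation on strong doubles biases the
  fully-automatic normalised amplitude upward by up to ~20%.
* The phantom's regularity flatters the landmark matcher; real vessel
  trees with pathology may not reach the 15%-support consensus, in which
  case the autocorrelation route is the fallback.
* Grade cut-points are package defaults, not clinically validated
  thresholds; concordance percentages on synthetic cohorts depend on them
  and on the clinician-noise parameters.
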
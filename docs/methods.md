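# Methods

## Quantification conventions

All quantities derive from mean counts per pixel inside ROI masks on the
early (`e`, ~15 min) and delayed (`l`, ~4 h) anterior planar images:

- `H/M = H / M` with no background subtraction.
- `WR method 1 = (Hₑ − Hₗ)/Hₑ × 100` (heart counts only).
- `WR method 2 = [(Hₑ − Mₑ) − (Hₗ − Mₗ)]/(Hₑ − Mₑ) × 100` (mediastinal
  background subtracted). When `Hₑ ≤ Mₑ` — possible with severe
  denervation — the formula is undefined; the library raises by default,
  and the cohort pipeline records NaN and drops the study from
  method-2 tables (complete-case analysis).
- Physical ¹²³I decay (half-life 13.2 h) is deliberately **not** corrected
  between phases, matching routine clinical practice for these indices; a
  `decay_correct=True` flag applies the correction for sensitivity studies.
- Washout is computed from mean counts per pixel, so early and delayed ROIs
  may legitimately have different pixel counts (e.g. independently redrawn
  ROIs per phase — the pipeline default; a shared-ROI mode exists).

## ROI geometry and rasterization

Coordinates are 0-based `(row, col)` with pixel centers at integers;
geometry is real-valued. A pixel belongs to an ROI iff its **center** lies
inside the region, boundary-inclusive (`≤` against rectangle/circle/oval
boundaries; for polygons, even-odd interior test plus an explicit on-edge
check with a 1e-9 tolerance). There is no partial-pixel weighting: the rule
is deterministic and verifiable against an exhaustive point-in-region
oracle, which the test suite does (shapely for polygons, brute-force
enumeration for circles/ovals). Integer-placed rectangles therefore contain
exactly `width × height` pixels (13 × 20 = 260 for the mediastinal ROI).

The mediastinal rectangle is 13 columns × 20 rows (read as taller than
wide, matching its upper-mediastinal position between the lungs; both
dimensions are configurable since the convention is ambiguous). It is
horizontally centered between the medial lung contours with its top edge at
the lung-apex row; when the column slack is odd the tie breaks toward the
smaller column, and a `row_offset` allows anchoring lower within the upper
half of the landmark square.

Fixed-size cardiac ROIs: an oval with semi-axes (35, 30) px whose long axis
is rotated to the heart axis (angle measured from the image vertical), and
a circle of radius 21 px at the apex. Placements that extend outside the
image frame are rejected. At the default 1.42 mm/px spacing (derived from
the oval's 60 × 70 px ≈ 85 × 100 mm equivalence) the circle radius is
~30 mm.

## Phantom model

The phantom is a minimal 2-D anterior-thorax anatomy on a 256 × 256 frame
(scaled linearly for other matrix sizes): a body ellipse, two lung
ellipses, a mediastinal corridor between their medial contours, a liver
block adjacent to the cardiac apex (a realistic placement hazard for the
apex circle), and a heart modelled as a rotated ellipse (semi-axes 34.5 ×
29 px, axis 40° from vertical) with a 7 px myocardial wall around a cavity
at 75 % of wall intensity — the left-ventricular cavity holds less tracer
than the wall, which is what makes the apex-circle ROI read systematically
lower mean counts than the full polygon.

Default expected count levels (early image, counts/pixel): mediastinum 100,
lung 60, liver 140, body 50, plus an optional uniform `background_offset`
over the whole field (default 0). The heart level is solved so the ideal
cardiac polygon (a 16-vertex inscribed polygon on the epicardial ellipse)
and the landmark-placed mediastinal rectangle reproduce the configured
early H/M exactly on the noise-free image; the delayed heart level is the
early one scaled by `1 − WR₁/100`.

Between phases the non-cardiac tissue compartments clear by a common
`mediastinal_washout_pct` (default 36.2 %). A non-zero tissue clearance is
required for the three headline cohort quantities of a heart-failure
population — early H/M ≈ 1.56, delayed H/M ≈ 1.43, method-1 washout ≈
41.5 % — to be mutually consistent: with a constant mediastinum those
targets would force a delayed H/M near 0.9. The default value is the one
those three moments jointly imply, and it places method-2 washout in its
expected ~50 % regime; physically it subsumes both ¹²³I decay (~18 % over
3.75 h) and nonspecific tissue clearance.

`background_offset` is interpreted as a uniform measurement contaminant on
top of the tissue signal (the H/M and washout targets describe the
signal). Consequently, at the default zero offset the observed ideal-ROI
quantities equal the targets exactly, while a positive offset dilutes the
measured method-1 washout but leaves method-2 unchanged (the mediastinal
subtraction cancels any uniform term exactly) — the diagnostic contrast
between the two formulas.

Noise: `"poisson"` draws independent Poisson counts per pixel per phase
from the expectation images, seeded. At the default mediastinal level of
100 counts/px, the H/M estimation error over ideal ROIs is below 0.03 in
well over 95 % of replicates (the acceptance suite measures this at 200
replicates); the truth bookkeeping always records the noise-free values.

Cohort sampling: per subject, early H/M ~ Normal(1.56, 0.18²) truncated
below at 1.05 and WR₁ ~ Normal(41.5, 6.6²) truncated to [0, 95], the
moments of a typical NYHA III/IV heart-failure population. Under these
defaults roughly half the cohort falls in the delayed H/M ≤ 1.4
severe-denervation subgroup.

## Observer model

Manual redrawing variability is modelled as Gaussian jitter: independent
2-D displacement of each polygon vertex (`vertex_jitter_sd_px`), whole-ROI
translation of the rectangle, oval and circle (`roi_shift_sd_px`), and an
angular error on the oval axis (`axis_angle_jitter_deg`). Draws that leave
the image frame or self-intersect are rejected and resampled (bounded
retries, then an error naming the ROI). Zero SDs reproduce the ideal set
exactly, and everything is deterministic by seed.

Defaults: experienced observers use 1.5 px vertex/shift SD and 4° axis SD;
the "inexperienced" observer uses double (3 px, 8°). Observer experience
has no accepted quantitative model, so these are modelling choices; with
them, simulated intra-/inter-observer delayed-H/M ICCs land in the
0.97–0.995 range and the experienced-vs-inexperienced ICC around
0.95–0.97 — the "excellent agreement, slightly degraded by inexperience"
regime expected of this measurement. The intra-observer repeat is modelled
as two independent jitter draws from the same model (a multi-week interval
between readings justifies independence).

## Reliability statistics

The ICC comes from the explicit two-way crossed ANOVA mean squares
(subjects × raters): consistency single `(MSR − MSE)/(MSR + (k−1)MSE)`,
consistency average `(MSR − MSE)/MSR`, with absolute-agreement variants
including the rater mean square per the McGraw–Wong conventions. The
two-way mixed default here is the **consistency** definition — the common
statistics-package default for "two-way mixed" — with absolute agreement
available by flag. CIs: exact F-distribution bounds for consistency,
Satterthwaite-approximation bounds for absolute agreement (both verified
against pingouin). Degenerate tables are explicit: all-identical values →
ICC 1 with a warning; zero between-subject variance with disagreement →
ICC 0 with a warning. In the perfect-reproducibility limit (zero jitter,
no noise) MSE is exactly 0 and the ICC is exactly 1.

Qualitative bins: < 0.49 poor, 0.49–0.59 fair, 0.60–0.74 good, > 0.74
excellent. The printed convention leaves gaps (e.g. 0.595); they are closed
with contiguous half-open bins [0.49, 0.60) and [0.60, 0.75) so every
estimate classifies.

Bland-Altman: differences `x − y`, limits = mean ± 1.96 × sample SD (n−1);
per-pair means and differences are exported for plotting.

Subgroup: one designated reference observer's *first* delayed H/M
measurement selects subjects with values ≤ 1.4 (boundary included); the
agreement analyses are then re-run on that subgroup.

Sample-size planning inverts the large-sample ICC variance
`2(1−ρ)²(1+(k−1)ρ)²/(k(k−1)(n−1))` for a symmetric 95 % interval of the
requested width. For ρ₀ = 0.75, width 0.20 and k = 2 it returns n = 75;
design-table methods for the same planning problem give values in the
same tens-of-subjects regime (a published figure of 70 exists for this
scenario), and the exact choice of planning approximation is documented
rather than tuned.

## Study pipeline and problem sizes

`run_study` simulates the cohort (default n = 70, Poisson noise), draws
four observer sessions per subject (independent ROIs per phase by
default), quantifies the reference session under all three cardiac ROI
modes, and emits: per-measurand observer-agreement tables (means ± SD, ICC
with CI and class, Bland-Altman), the subgroup table, the
fixed-vs-manual-ROI table (ICC vs polygon, mean H/M and counts-per-mm²
differences), Bland-Altman point exports, and a JSON summary. Everything is
deterministic by a single seed (per-session RNG streams spawned from it).
Fixed-vs-manual agreement uses average-measures consistency ICC, mirroring
the between-method character of the comparison.

Tests use scaled-down problem sizes chosen for speed without changing the
science: 128-px frames for geometry-heavy property tests, 12–20-subject
cohorts for pipeline tests, 200–500 replicates for Monte-Carlo checks; the
acceptance suite runs the full 70-subject default study.

## Known limitations

- The anatomy is a 2-D cartoon: no attenuation, scatter, collimator or
  septal-penetration physics; observed count levels are plausible but not
  calibrated to any camera. Passing tests demonstrate correctness of the
  quantification and statistics pipeline under the stated noise model, not
  clinical accuracy on real images.
- Observer behaviour is stationary Gaussian jitter; real observers make
  structured errors (e.g. systematically excluding the apex) that a
  translation/jitter model cannot produce.
- The simulated ICCs sit near the top of the clinically reported range
  because the phantom's compartments are internally uniform, making ROI
  placement more forgiving than on real, textured images.
- SPECT-based regional analysis is out of scope; only planar indices are
  computed.
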
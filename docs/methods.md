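# Methods

## System and scope

`guvkit` analyzes equatorial-plane, two-channel fluorescence images of
giant unilamellar vesicles (lipid channel: a Texas-Red-like membrane dye;
actin channel: a labeled-actin conjugate) and models the coalescence of
liquid-disordered (Ld) lipid domains with and without branched actin
networks. Because no raw imaging data accompany the measurements the
package emulates, all analyses are exercised end-to-end on synthetic scenes
with embedded ground truth; the synthetic generator is first-class, tested
code, not a fixture.

## Synthetic imaging model

A vesicle of diameter d (default 20 µm; the microtrap geometry selects
10–60 µm) is rendered as an annular Gaussian ridge of the membrane dye at
radius d/2 with σ = 0.3 µm, approximating a diffraction-limited
epifluorescence ring and giving sub-pixel peak localization a realistic
test. Default sampling is 0.2 µm/px (63×-objective scale). The actin
channel contains an annulus outside the membrane: constant thickness
(symmetric shell), thickness modulated by a raised-cosine angular profile
peaking at the break angle with a thinnest/thickest ratio of 0.25
(asymmetric shell), or a thin shell plus a tapered tail polygon reaching
2.5 vesicle radii (comet; comets are observed but not parameterized in the
source experiments, so the taper — 25° half-width at the membrane to 4° at
the tip — is a rendering choice). Phase-separated vesicles carry n_d
disjoint bright Ld arcs; the Ld:Lo intensity contrast defaults to 8,
reflecting the strong Ld partitioning of Texas-Red-like dyes and placing
the Lo baseline (1/8) safely below the 0.2 domain-calling threshold after
normalization. Noise is Poisson on the signal plus an additive Gaussian
background (level 10, σ configurable); the camera transfer function is not
modeled and intensities are arbitrary float units. Time lapses freeze all
parameters except actin thickness, which grows linearly at 0.1–0.3 µm/min
(the observed envelope).

What the generator does **not** emulate: point-spread-function blur beyond
the Gaussian ridge, photobleaching, z-structure, membrane nanotubes, focus
drift, or debris. Passing round-trip tests therefore demonstrates the
correctness of the measurement definitions and their noise robustness, not
performance on raw microscope data.

## Morphometry

Segmentation replaces manual wand-tool delineation: Otsu thresholding is
applied in the log-intensity domain (so the dim Lo membrane stays connected
to arcs that are ~8× brighter), small objects are removed, the component
containing the optional seed point (else the largest) is hole-filled and
its boundary traced; the contour is then snapped radially to the sub-pixel
membrane-ridge peak per degree, so the enclosed area measures the vesicle
rather than the thresholded halo. Diameter is the area-equivalent
2√(Area/π). Ellipticity uses the maximum pairwise (Feret) distance over
convex-hull vertices — ties broken toward the smallest angle to +x — and
the longest chord perpendicular to that axis, found by scanning 720
perpendicular section lines (verified against an independent
edge-interpolation oracle in the tests).

Actin thickness: for each of 360 rays from the contour centroid, the
membrane radius is the lipid-ridge peak, and the actin outer edge is the
outermost sample exceeding background + k·σ_background (k = 3; a 5%-of-peak
relative floor keeps the rule defined on noise-free data, with a tiny
absolute epsilon against interpolation round-off). Thickness is edge minus
membrane radius; the symmetry-breaking orientation is the circular mean of
the angles tied at the maximum within one radial sampling step, which
resolves the flat maxima produced by the 0.5 px radial quantization.
Structure classes use declared thresholds (a_sym = 0.3 on the relative
thickness modulation; comet when actin reaches 1.5 vesicle radii within a
< 90° sector): the experimental classification was by eye, so the
thresholds are configuration, echoed in outputs. Angles are 0° = +x,
counter-clockwise in physical (y-up) coordinates everywhere.

## Radial profiling

360 per-degree rays (bilinear interpolation, 0.5 px steps, out to 1.5
vesicle radii) yield per-ray peak values: the mean background-subtracted
intensity over the contiguous half-maximum run around the ray's global
peak — a parameter-free replacement for an unstated "on the peak" window;
for a Gaussian ridge of amplitude A the closed form of this statistic is
A·√(π/(2 ln 2))·erf(√(ln 2))/2 ≈ 0.81·A, which the tests verify. Background
is the per-channel median (robust σ from MAD) over pixels beyond 1.2× the
maximum contour radius; this region must remain majority-background, so
fields of view are sized generously when coronas grow large. Channels are
normalized by their own per-vesicle maximum. Ld domains are contiguous runs
with normalized lipid strictly above 0.2, wrap-merged across 0°/360°, and
runs narrower than the angle subtended by 1 µm at the vesicle radius (the
optical resolution floor) are discarded — this filter is logged and can be
disabled. The actin-on-Ld score is the mean normalized actin over Ld angles
divided by its maximum over Ld angles. Normalization is per frame; an
alternative (normalizing a whole series by its first frame) would couple
frames and is not used.

## Domain dynamics

Trajectories take N0/N10/N60 from the frames nearest 0/10/60 min within
±2 min (acquisition cadence is configuration). Time zero is the first
acquisition frame, taken one minute after the demixing quench — the
realistic latency of switching off the heater and refocusing; consequences
are discussed below. Ratios above 1 (counting noise splitting a domain) are
clipped to 1 with a warning, since the model forbids fission. Group
comparisons follow the study's policy: independent nonparametric →
Mann–Whitney U (exact when both groups ≤ 8 without ties, otherwise the
normal approximation with tie correction and no continuity correction, so
identical samples give p = 1); paired → Wilcoxon signed-rank; independent
normal → Welch's t; all two-sided with n.s./*/**/*** tiers at
0.05/0.01/0.001.

## Coalescence physics

D(r) = k_BT/(4π η_m)·ln(η_m/(η_f r)) with defaults k_BT = 4.1×10⁻²¹ J,
η_m = 10⁻⁸ Pa·m·s (Lo membrane), η_f = 10⁻³ Pa·s (water); valid for
r < η_m/η_f = 10 µm, and raising a validity error beyond. τ = R²/4D; the
corona overhang is v_gel·t (v_gel default 2.5 nm/s = 0.15 µm/min) and
blocks fusion strictly when it exceeds the mesh size ξ = 100 nm (an
overhang of exactly ξ does not block).

The simulator performs Euler–Maruyama Brownian steps of the domain centers
on the sphere surface (tangent-plane Gaussian steps of std √(2 D dt),
projected back; default dt = 0.05 s, with 0.2 s used for replicate sweeps —
the rms step of ≈ 0.25 µm stays well below the 1 µm domain radius, and a
stability error rejects steps larger than the radius). Each domain carries
its own D(r_i); spVCA mode multiplies D by f_spvca = 0.3, a hypothesized
(not measured) slow-down exposed in configuration. Domains merge when their
spherical caps overlap — deepest overlap first, iterated to exhaustion —
at the area-weighted centroid with radius √(r_i² + r_j²), conserving total
domain area to 10⁻⁹ relative. In actin mode, coronas start at the domain
edge at demixing (c_i = r_i at t = 0) and merging is blocked for all pairs
once v_gel·t > ξ (i.e. after ≈ 40 s at defaults) — blocking when *either*
partner's corona exceeds the mesh; requiring both would be equivalent here
since all coronas share one age. Ostwald ripening is omitted: coarsening is
coalescence-dominated in this regime. Merging runs freely down to a single
domain; "complete coalescence" is asserted as a final count ≤ 2, matching
an equatorial-plane count of a fully coarsened vesicle. The trace records
both whole-sphere counts and equatorial-great-circle arc counts (a cap of
angular radius α at latitude λ cuts the equator iff |λ| < α, in a
longitude arc of half-width arccos(cos α / cos λ)); image-facing outputs
use the equatorial projection.

Because coronas need ≈ 40 s to exceed the mesh size, merges occurring
before the first acquisition frame (at 60 s) are invisible to the
trajectories: actin-mode vesicles then hold their count for the remaining
hour (ratio_60 = 1), while bare vesicles coarsen to ≤ 2 domains and
spVCA-coated ones stall at small counts. The analytic τ is validated as a
first-passage statistic: the median time for a single (blocked, hence
unmerged) domain to first travel the 5 µm inter-domain distance is compared
with R²/4D within a factor of 2, reflecting the order-of-magnitude nature
of the estimate.

## Numerical choices and problem sizes

Radial sampling is 1° × 0.5 px bilinear everywhere. Replicate counts used
by the test suite — 50 matched-seed replicates for the 600 s mode-ordering
check, 12 paired replicates for the hour-long stabilization contrast, 40
replicates for the first-passage check, cohorts of 2–3 vesicles with
13-frame lapses for pipeline tests — were chosen as the smallest sizes at
which the qualitative claims are stable across seeds. The growth-rate
sweep sizes each field of view to the final corona (half-extent = vesicle
radius + final thickness + 8 µm) so the background annulus stays
uncontaminated.

## Known limitations

Segmentation assumes one dominant ring per field (a seed point selects
among several); heavily broken rings or out-of-focus vesicles fail loudly
and are skipped. The blocking criterion is binary and shared across pairs,
so partial stabilization arises only from pre-blocking merges, not from
per-pair corona heterogeneity. The simulator neglects hydrodynamic
domain–domain interactions, membrane tension, line-tension shape changes
and the logarithmic corrections of true 2D first-passage theory. The
actin-on-Ld score separates colocalized from spread actin only in the
presence of noise (both give 1.0 on noise-free renders by construction of
the within-Ld normalization).
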
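# Methods

This note documents the models and procedures implemented in
`chromotrack`, the defaults and why they were chosen, and what the
synthetic data generator does and does not emulate.

## The measurement model

A tracked cell contributes one video: a time series of paired spot
observations, each with a green and a red 3D position (nm, z along the
optical axis), a maximum intensity and a contrast value per channel.
Frames may be missing; every statistic uses actual time stamps, never
frame indices.

Because the two colours are imaged on separate cameras, red
coordinates carry a chromatic error relative to green. Alignment is
two-stage. The coarse stage is an affine map (translation, rotation,
magnification) whose parameters come from a calibration target;
`apply_affine` applies externally supplied parameters to coordinates —
estimating them from bead images is out of scope. The fine stage uses
a colocalising control in which a single operator array binds both
fluorophores, so the true inter-channel separation is zero: the
per-axis means of (red − green) over all control frames define a
constant translation that is subtracted from every red coordinate.
After this subtraction the per-axis mean residual on the control set
is identically zero (it is the same mean being removed), and the
remaining mean 3D distance is the *measurement error* of the workflow.

If each channel localises with isotropic per-axis Gaussian error of SD
`s`, the red−green difference vector is Gaussian with per-axis SD
`s·√2` and the 3D distance is Maxwell-distributed with

    mean = 4·s/√π,          variance = 2·s²·(3 − 8/π).

With `s = 27.9` nm the mean is ≈ 63 nm. These closed forms anchor the
test oracles. Note the Maxwell SD for `s = 27.9` is ≈ 26.6 nm; an
empirical error distribution with heavier tails would show a larger SD
at the same mean, so the generator's Gaussian noise reproduces the
mean, not necessarily the SD, of a real error distribution.

## Quality control

A frame is removed when any of the following holds, tested in the
fixed precedence order given (the first failing rule claims the frame,
making per-rule counts unambiguous; the counts always sum to the frame
total):

1. **z-margin** — either spot's z lies within `z_margin` (default
   1000 nm) of either bound of the imaging stack (default 0–5000 nm);
   near the stack boundary axial localisation degrades.
2. **contrast** — either channel's contrast is below its threshold
   (default 12 for both channels).
3. **intensity** — either channel's maximum intensity is below its
   threshold (default 25 red, 16 green).

Thresholds are taken as given configuration; deriving them from
error-vs-covariate curves is out of scope. Intensity and contrast are
treated as opaque per-spot covariates.

## Geometry and compaction

The effective genomic separation of a construct with intragenic spacer
`a` and operator arrays `x_p`, `x_q` (all bp) is
`z = a + 0.5·x_p + 0.5·x_q`, because each spot's fluorescence centres
on the midpoint of its array. The compaction ratio is `0.34·α/d`
(α in bp, d in nm; 0.34 nm per bp of B-DNA contour). Per strain the
package reports both the ratio at the pooled mean distance (the
single-number display) and the mean of per-frame ratios; the two
differ for broad distance distributions (Jensen), so both are emitted.
Distance histograms use half-open `[k·w, (k+1)·w)` bins with left edge
at 0 and default width 63 nm — one measurement-error length per bin.

## Anisotropy statistic D

Each frame's inter-locus vector (red − green; the sign convention is
pinned and documented, as D is not generally invariant under a global
flip) is mapped onto the unit square:

    u = (atan2(y, x) + π) / 2π   ∈ [0, 1)
    v = (|r| − z) / (2|r|)       ∈ [0, 1]

This is area-preserving: isotropic directions give (u, v) uniform on
the square. The printed one-argument arctangent form of the azimuth
has range (−¼, ¼) and cannot fill the square; only the two-argument
full-circle form makes the map measure-preserving, so that is what is
implemented. A vector with x = y = 0 gets u = 0.5; zero-length vectors
are skipped and counted.

D is the one-sample two-dimensional Kolmogorov–Smirnov statistic
against uniformity, evaluated at the data points: for each point and
each of the four quadrant orientations, the absolute difference
between the empirical fraction in the quadrant and the quadrant's
area; D is the maximum. Lower quadrants are closed (≤), complements
open. These conventions are pinned by an independent brute-force
enumeration oracle in the test suite, which the implementation must
match exactly. No p-value is attached to D; the statistic itself is
the anisotropy measure.

Two caveats established numerically: (i) D is only *approximately*
stable under rotation of all vectors about the optical axis — a
modular azimuth shift re-partitions the quadrants, moving D by up to
≈ 0.1 at n = 150 — though the isotropic/anisotropic ordering is
preserved; (ii) per-video D values computed on autocorrelated frames
are inflated relative to the same number of independent vectors, so D
should only be compared between videos of matched length and sampling.

## RV coefficient

For column-centred T×3 matrices X, Y,

    RV = tr(S_xy S_yx) / √(tr(S_xx²)·tr(S_yy²)),

the cosine similarity of the configuration matrices XX′ and YY′. It is
symmetric, lies in [0, 1], and is invariant to a rigid rotation of
either series alone. The default input is the per-frame displacement
vectors of each locus (motion coupling); a positions mode is also
available, as both readings of the underlying quantity are defensible.
The null value for independent trajectories is O(1/T), not 0.

## MSCD, baseline and plateau

Every ordered within-video time-point pair (t, t+τ) contributes
(d(t+τ) − d(t))²; pairs are pooled across the videos of a strain and
binned by τ into half-open bins (default width 6 s, labelled by
centre). Overlapping pairs are autocorrelated, so the per-bin standard
error (computed as if pairs were independent) understates the true
uncertainty; Monte Carlo comparisons in the tests therefore use
between-video spread instead.

For the stationary noiseless generator the distance variance is the
Maxwell variance σ²(3 − 8/π), and the MSCD plateau is twice that:
2σ²(3 − 8/π). The rise time is set by the relaxation time θ of the
inter-locus vector, but note the half-rise sits near **θ·ln2/2**, not
θ·ln2: the distance is an even function of the Gaussian vector, so its
autocorrelation decays as exp(−2τ/θ) to leading order (the odd Hermite
components vanish). This was verified numerically and is asserted in
the tests.

The bootstrap between-cell baseline draws a video uniformly, a time
point within it, then a different video and time point, and averages
the squared distance difference over `n_boot` draws (seeded). An
exclusion list supports recomputing the baseline without outlier
cells. For an ergodic homogeneous population the baseline coincides
with the within-cell plateau; cell-to-cell heterogeneity pushes it
above. The plateau estimate is the count-weighted mean of bins with
centre ≥ `t_min_s` (default 150 s).

MSD for a single locus uses the same pooling/binning machinery on
|p(t+τ) − p(t)|²; for the confined (OU) midpoint it follows
6σ_c²(1 − e^(−τ/θ_c)).

## Inheritance test

Per-video compaction is the mean of per-frame ratios (median
available). For a video pair, the statistic is log2(c_A/c_B), mother
in the numerator; within a strain the genomic separation cancels, so
the ratio compares distances only. Related pairs come from lineage
metadata; unrelated mother×daughter pairs are drawn with replacement,
excluding true lineage pairs, count matched to the related pairs by
default (mother/mother and daughter/daughter modes exist as controls).

The Mann–Whitney comparison is run on |log2 ratios| (primary —
inheritance would shrink the *magnitude* of related changes) and on
signed ratios (reported alongside; the signed distributions are
symmetric by construction). The p-value is exact — full enumeration of
rank arrangements — when the combined sample size is ≤ 12 with no
ties, and otherwise uses the normal approximation with tie and
continuity corrections; two identical constant samples return p = 1.
Because related and unrelated pairs reuse the same videos, the two
samples are weakly dependent and the test is mildly conservative;
calibration runs show near-uniform null p-values with a type-I error
slightly below nominal.

## Synthetic data generator

The inter-locus vector is a stationary 3-axis Ornstein–Uhlenbeck
process with stationary per-axis SD σ and relaxation time θ,
discretised with the exact conditional update
x′ = ρx + σ√(1−ρ²)·ξ, ρ = e^(−Δt/θ), and stationary initialisation,
so its statistics are exact at any frame interval. The pair midpoint
is an independent OU process (σ_c, θ_c) centred mid-stack — keeping
the two processes independent lets anisotropy and motion-coupling
properties be controlled separately. Green = midpoint − vector/2 +
noise; red = midpoint + vector/2 + noise + constant channel offset.
In `fixed-direction` mode the vector's direction is pinned per video
and its magnitude is the norm of the 3-axis OU process, preserving the
Maxwell marginal while making the orientation maximally anisotropic.
True z is always recorded; stack clipping is expressed through the QC
z-margin rule rather than by deleting frames, so QC is itself
testable.

Populations draw a cell-specific mean separation from a log-normal
between-cell law (the distribution is a config choice without any
claim of fidelity) with CV 0.4 — chosen so cell means span roughly a
2–3-fold range, the order of heterogeneity seen in per-cell
distributions of real locus-tracking data. A daughter's mean is
k·mother + (1−k)·fresh draw, with k the inheritance coefficient in
[0, 1]. Intensity and contrast covariates are truncated-normal draws
whose defaults pass QC for most frames. All randomness flows from one
seeded generator with deterministically spawned per-video sub-streams;
identical (config, seed) reproduce byte-identical tables.

Defaults: σ = 150 nm (mean separation 2σ√(2/π) ≈ 240 nm, the scale of
a ~70 kb reporter pair), θ = 20 s (distance fluctuations equilibrate
over tens of seconds to minutes, matching a rise-then-plateau MSCD on
a 30–150 s scale), frame interval 1 s, 60 frames per video, noise
27.9 nm/axis/channel (63 nm mean two-channel error), stack 0–5000 nm.

What the generator does **not** emulate: non-Gaussian localisation
error tails, intensity- or z-dependent error (QC covariates are
independent of the coordinates), photobleaching, tracking failures and
misassignments, cell-cycle or nuclear-geometry effects, and any
polymer-level coupling between midpoint and separation. Passing tests
therefore validate the statistical machinery under its stated
assumptions, not the biology of any particular dataset.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately modest sizes chosen for
stable statistics: 10⁵ frames for closed-form error checks (Monte
Carlo SE ≪ the 2% tolerances), 40 videos × 240 frames for MSCD
physics (between-video SE ~3% of the plateau), 100-seed comparisons
for calibration fractions, and 60–100 replicate populations of 100
mother/daughter pairs for inheritance calibration and power. Pinned
conventions: histogram and lag bins half-open with the left edge at 0;
bin labels at centres; Mann–Whitney U reported as the smaller of the
two U statistics; SDs use the n−1 denominator; rotation matrices must
be orthonormal to 1e−9; affine inverses restore coordinates to 1e−9 nm.

## Known limitations

* The bootstrap baseline samples videos uniformly, then time points —
  an alternative (uniform over pooled time points) would weight long
  videos more; the choice matters only for very unequal video lengths.
* MSCD/MSD standard errors treat overlapping pairs as independent.
* The long-dialect reader pairs channels by nearest time within half a
  frame interval; exports with systematically offset channel clocks
  need a pre-shift.
* D on short autocorrelated videos is upward-biased; compare only at
  matched video length.
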
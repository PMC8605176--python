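# Methods

This note documents the models, statistics, and design choices behind
`envshift`, in the spirit of a package methods appendix. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Session model and time conventions

A session is a position trace (nominal 30 Hz; seconds and cm, arena frame)
plus one sorted spike-timestamp list per cell. Sessions come in A-B-A'
triplets sharing a cell roster; only cells present in all three sessions
enter the change classifier (cells recorded in a subset of sessions are
loadable and are listed with the reason for exclusion). All analyses run on
the first 765 s of each session — the duration of the shortest recording in
the study design this emulates — and every interval in the package
(truncation window, 76.5 s blocks, 400 ms bins, speed bins except the top
edge) is **half-open** `[t0, t1)`. This makes counts deterministic: 765 s
yields exactly ten 76.5 s blocks and `floor(765/0.4) = 1912` complete
400 ms bins with the trailing 0.5 s discarded. Truncation is idempotent,
and a session shorter than the window fails inclusion rather than being
silently padded.

The arena note "1.25 m²" is read as a 1.25 m × 1.25 m square (side length,
not area): the companion expansion condition "moved outwards … to 1.5 m²"
only makes sense as a side length, and a 1.118 m side (the area reading)
is an implausible build dimension.

## MFR-change classifier

For each cell, block mean firing rates (spike count / 76.5 s) form three
groups of ten. The omnibus comparison is the tie-corrected Kruskal–Wallis
test (`scipy.stats.kruskal`). Pairwise session comparisons use a
**Scheffé-type contrast on pooled ranks**, the convention of MATLAB's
`multcompare` applied to `kruskalwallis` output: with pooled mean ranks
R̄ᵢ, group sizes nᵢ, N = Σnᵢ and tie-corrected rank variance
S² = N(N+1)/12 · (1 − Στ(τ³−τ)/(N³−N)), the standardised difference

    d = |R̄ᵢ − R̄ⱼ| / sqrt(S² (1/nᵢ + 1/nⱼ))

is referred to p = P(χ²₍k₋₁₎ ≥ d²), which controls the family-wise error
over all contrasts (Monte Carlo in the test suite confirms FWER ≤ α).
A literal "every block against every block" reading (100 pairwise tests per
session pair) is statistically incoherent and was not implemented.

A cell is labelled **increase** when manip-vs-pre *and* manip-vs-post are
both significant at α = 0.05 and Δ = MFR_manip − ½(MFR_pre + MFR_post) > 0;
**decrease** with Δ < 0; otherwise **none**. Pre-vs-post significance never
vetoes a label — it is surfaced as a `flankers_differ` quality flag. The
flanker mean is used as the reference for Δ because it is symmetric in the
two baseline sessions; the label criterion itself is likewise symmetric
under swapping pre and post (tested). α and the block count are
configurable; defaults are the study's printed parameters.

The whole-session MFR is reported alongside the block rates as descriptive
output only; it equals the mean of the ten block MFRs exactly (equal
blocks), which the population-vector module exploits as a cross-check.

## Spatial ratemaps

Occupancy bins are 3 cm squares covering the arena bounding box; each
tracking sample deposits one frame interval (1/30 s) into its bin, so
occupancy sums to the session duration exactly. A spike takes the spatial
bin of its *temporally nearest* tracking sample (sub-frame interpolation
adds complexity no downstream analysis uses). Raw rate = spike count /
occupancy per visited bin; unvisited bins are masked from every subsequent
computation, and a bin is "visited" at any occupancy > 0 (no minimum-dwell
filter). Conservation — Σ rate·occupancy over visited bins = assigned spike
count — holds exactly and is asserted in the tests.

Smoothing uses a Gaussian kernel under masked renormalisation
(`G*(rate·mask) / G*(mask)` on visited bins), which preserves constant
fields exactly and never bleeds rate into or out of unvisited pixels. The
kernel convention "spanning 7 cm" is ambiguous (σ? FWHM? support); the
package uses **σ = 7/3 cm ≈ 2.33 cm with the support truncated at 3σ =
7 cm half-width**, so the kernel's footprint spans ±7 cm. σ is an explicit
parameter, so σ = 7 cm (or any other reading) is one argument away.

For display, a cell's three smoothed session maps are divided by the 95th
percentile of their pooled visited-bin rates; values above that percentile
exceed 1 by design, and an all-zero triplet maps to zeros rather than NaN.

## Speed tuning

Speed is the finite difference of position at the frame rate with a
5-frame boxcar (both the smoothing width and "off" are configurable and
recorded on the series; the upstream tracking filter of the original
hardware is unknown, so the choice is surfaced rather than hidden).
Statistics use 25 half-open 2 cm/s bins spanning 5–55 cm/s; curves shown
to humans use 2.5 cm/s bins spanning 0–60 cm/s (the two conventions the
study itself used for its statistics and its figures, kept deliberately
distinct). Per-bin rate = spikes on frames in the bin / dwell time; empty
bins are undefined and excluded from fits; the occupancy-weighted mean of
the analysis curve equals the MFR restricted to in-range frames exactly.

The sensitivity test fits the defined bins with a uniform (1-parameter)
and a linear (2-parameter) unweighted least-squares model and compares
residuals: F = (RSS₀ − RSS₁) / (RSS₁/(n−2)) on (1, n−2) df. An exactly
linear curve (RSS₁ = 0) reports p = 0 with a `perfect_fit` flag; an exactly
constant curve reports F = 0, p = 1. Fits are unweighted (the stated
convention); occupancy-weighted fitting is available behind a flag. A cell
is *speed sensitive* if p < 0.05 in at least one of the three sessions —
note this any-of-three rule inflates the null detection rate to
1 − 0.95³ ≈ 14 %, which the recovery tests account for explicitly.

Shape categories are a qualitative convention of this package: the display
range is split into terciles, each tercile's mean rate over defined bins is
compared, and the winning tercile must exceed the far tercile(s) by a 10 %
margin — lowest tercile → *decreasing*, highest → *increasing*, middle (vs
both ends) → *preferred*, otherwise *unclassified*. Tercile means rather
than single peak bins are compared because the maximum of ~24 noisy bins
exceeds any single reference bin too easily; with means, >90 % of simulated
untuned cells stay unclassified while monotone tuned cells are recovered
essentially perfectly (measured in the test suite). Split-half curves
split the concatenated triplet at its temporal midpoint and pool counts
and dwell across session boundaries within each half.

## Population-vector correlations

For a fixed roster, the whole-session population vector (per-cell MFR over
765 s) of each session type is Pearson-correlated with each 400 ms binned
population vector of every session, pooling both directions of each
pairing into four labelled distributions (same-type, pre×manip, pre×post,
manip×post). Pearson is the field default for population-vector analyses;
a rank-correlation flag is available. Bins in which no roster cell fired
(or a zero-variance PV) have undefined correlations and are **excluded and
counted**, never imputed as zero. The four distributions are compared with
Kruskal–Wallis plus the same Scheffé rank post hoc; medians summarise
direction. Pooling across triplets is plain concatenation, matching a
pooled pseudo-population reading (correlations are permutation-invariant
within groups, which is tested).

## Synthetic data generator

The generator exists so every stage is testable with known ground truth;
its defaults *are* the study conditions.

**Rate model.** λ(t) = base_rate(session) · g(speed(t)) · s(x, y) · d(t),
piecewise constant per 33.3 ms video frame — far below every analysis bin
width, so frame discretisation cannot bias block, speed-bin, or 400 ms
statistics. The multiplicative form is the simplest model in which MFR
shifts and speed tuning vary independently. Speed gains g (flat, linear
increasing/decreasing, Gaussian-bump preferred) are renormalised to mean 1
over each session's frames, so the session MFR equals the baseline
regardless of tuning. Spikes are drawn by Poisson thinning at the
per-session envelope rate (the per-frame maximum, checked); thinning
correctness is verified by χ² goodness-of-fit of per-speed-bin counts
against the model expectation.

**Shift cells.** An increase cell adds +4.0 spikes/s to its baseline in the
middle session; for a decrease cell the *middle-session* rate is drawn from
the baseline distribution and the flankers sit 5.7 spikes/s above it.
The mirror construction is forced by arithmetic: baselines are lognormal
with mean 3.0 spikes/s (σ = 0.5), and 3.0 − 5.7 would be negative. Default
composition: 200 cells, 11.5 % increase, 7.5 % decrease (i.e. 23 and 15
cells), 60 % speed tuned (25 % increasing, 25 % decreasing, 10 %
preferred). Every cell's spikes come from an RNG stream keyed by
(seed, CRC32(cell id), session), so adding or removing cells never
perturbs the spike trains of existing ones.

**Trajectory.** Heading diffuses (1.6 rad/√s) and walls reflect the path;
running speed is an Ornstein–Uhlenbeck process (relaxation 1.5 s) mapped
through a Gaussian copula onto a 60·Beta(1.1, 1.2) cm/s stationary
marginal. The copula construction was chosen over a plain (clipped
Gaussian) OU because the per-bin rates of a tuning curve are Poisson with
variance 1/dwell: a speed marginal that concentrates dwell at one mode
makes the unweighted F-test's inputs strongly heteroscedastic and the test
anti-conservative. The broad Beta marginal keeps the dwell ratio across
the 5–55 cm/s analysis bins below ~2, where the F-test's measured null
rejection rate is ≈ 0.05 (asserted in the acceptance suite). Consequences
of the defaults, all measured rather than assumed: mean speed ≈ 29 cm/s,
essentially no samples above 60 cm/s, and ≥ 90 % (typically ≥ 96 %) of
3 cm bins of the 1.25 m square arena visited within 765 s.

**Drift.** Optional per-cell slow ramps d(t) = 1 + slope·(phase − ½),
phase ∈ [0, 1] spanning the concatenated triplet, slope ~ N(0, drift_sd).
The default is **no drift** (trajectory and rate statistics identical
across sessions); the drift-injection analyses use drift_sd = 1.5, large
enough that drift rather than the shifted subpopulation dominates the
cross-session PV gradient — which is the regime the original observation
(same-type highest, pre×post lowest) describes.

**What the generator does not emulate.** Object-directed investigation
bouts, reward seeking, or any behavioural reaction to the manipulation:
trajectory statistics are identical across sessions by design (an option
exists to perturb them for robustness checks). Real rat speed
distributions are more right-skewed than the broad Beta marginal used
here, bursting and refractoriness are absent (spikes are Poisson), and
baselines are stationary within sessions apart from injected drift.
Passing tests therefore demonstrate correctness of the *analyses* under a
known generative model, not robustness to every behaviour of real data —
in real recordings with little high-speed dwell, the upper speed bins will
be noisy and the unweighted F-test less calibrated than in simulation
(the occupancy-weighted flag exists for exactly that case).

## Problem sizes and numerical choices

The simulation scales used throughout (chosen as comfortable desk-scale
study conditions): 200-cell triplets for recovery and PV analyses,
3 × 334 cells for classifier specificity, 20 trajectories × 100 flat cells
(2000 session curves) for F-test calibration, 10 000 draws for
Kruskal–Wallis null calibration. Degenerate inputs are handled explicitly:
all-identical samples give H = 0, p = 1; silent cells are labelled `none`
with a flag; all-zero map triplets normalise to zeros; empty rosters warn
rather than raise. Ties in ranks use midranks with the standard tie
correction everywhere. Float block edges are computed as `duration/n`
exactly; no epsilon nudging is applied anywhere except a 1e-9 guard when
flooring `duration/bin` to count complete bins.

## Known limitations

* The Scheffé χ² post hoc is asymptotic in the group sizes; at n = 10
  blocks per session it is conservative (measured FWER well below α),
  which trades a little sensitivity for safety with no user-visible knob.
* Shape categories are display-range conventions, not inferential claims;
  preferred cells whose peak sits near a tercile boundary are regularly
  assigned to the neighbouring monotone category.
* The pooled pseudo-population reading of the PV analysis ignores
  within-animal correlation structure; per-animal pooling is a trivial
  caller-side change (pass each animal's triplets separately).
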
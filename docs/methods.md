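# Methods

This note documents the model, the numerical conventions, the synthetic-data
generators, and the design choices behind `shoalkit`, in the spirit of a
package methods appendix. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The agent-based model

**State.** Agent *i* carries position **c**ᵢ(t) (2-D, model length units),
unit direction **v̂**ᵢ(t), intrinsic speed |vᵢ| and goal-orientedness ωᵢ.
Speeds and ω are sampled once per simulation and held constant; they are the
model's representation of consistent inter-individual differences. Constant
speed is a deliberate simplification: agents still modulate their *effective*
speed through path tortuosity (a fast agent boxed in at the front weaves; a
slow trailer swims straight).

**Interaction rules.** Zones are concentric and non-overlapping:

1. *Repulsion*, d < r_r: s = −Σⱼ (cⱼ−cᵢ)/|cⱼ−cᵢ|. Takes absolute priority
   (collision avoidance) and is evaluated omnidirectionally — the blind area
   applies only to the orientation and attraction zones, which model vision.
2. *Orientation*, r_r ≤ d ≤ r_o: sum of neighbour unit headings.
3. *Attraction*, r_o < d ≤ r_a: sum of unit vectors toward neighbours.

Orientation and attraction each see only neighbours within the field of
perception (±(360−a)/2° of the current heading; a = 90°). The two zone sums
are normalised individually and added, i.e. the social vector is
s = ŝ_o + ŝ_a (each term a unit vector or zero). With any repulsion
neighbour present, s = s_r unnormalised and the other zones are ignored.

The printed forms of the orientation/attraction sums in the source
description carry leading minus signs; implemented literally they make
agents flee each other and groups disperse immediately, contradicting the
cohesive, ordered shoals the model is known to produce in its lineage. The
package therefore uses positive orientation/attraction sums (repulsion
negative); `SimConfig(literal_signs=True)` switches in the printed signs for
audit.

**Desired direction, noise, turning.** d = ŝ + ω·ĝ, then normalised. The
goal vector ĝ is the current direction (inertia) unless a food cue (patch
centre with items remaining) lies within r_c, in which case ĝ points at the
nearest such cue. Zero resultants keep the previous heading. The target
direction is rotated by ε ~ wrapped-Normal(0, e) and the agent turns from
its current heading toward the noisy target along the shorter arc, by at
most ψΔt per step; exact 180° ties resolve deterministically to the
counterclockwise arc. Whether noise precedes or follows the turn cap is not
fixed by the model description; noise-on-the-target-then-cap is used.
Displacement is **c** += **v̂**·|v|·Δt with a synchronous update of all
agents; RNG draws occur in agent index order, so runs are bit-reproducible.

**Arenas.** `unbounded` (free schooling; the attraction radius is infinite,
so groups cannot disperse), `periodic` (wrap at A with minimum-image
interactions; recorded trajectories stay unwrapped so that finite-difference
kinematics never see jump discontinuities), and `circular` (foraging;
radius A/2). In circular mode a narrow edge zone (width 4% of the radius —
the "narrow zone" is otherwise unquantified; configurable) replaces the
desired direction with the unit vector toward the arena centre before the
turn cap, and positions are clamped to the arena as a safety net.

**Feeding.** Three disc patches (radius 10) are placed at a common random
radius in the band 0.375–0.875 of the arena radius, 120° apart with a random
rotation — the experimental layout (patches between 5 cm from the wall and
15 cm from the centre of a 40-cm-radius tank) rescaled to model units. An
agent on a patch consumes one item with probability f per step while items
remain (at f = 0.001 a Bernoulli probability and a continuous rate are
numerically indistinguishable); agents are processed in index order so the
last item resolves deterministically. Food is conserved:
items remaining + items eaten = items provisioned, at every step.

**Parameters** (model units; defaults in `SimConfig`):

| parameter | symbol | default | notes |
|---|---|---|---|
| arena size | A | 500 | circular mode: radius A/2 |
| repulsion zone | r_r | 1 | ~1 body length; the unit of scale |
| orientation zone | r_o | 6 | |
| attraction zone | r_a | ∞ | small-arena assumption |
| field of perception | α | 270° | blind angle a = 90° behind |
| max turning rate | ψ | 60°/time | 6° per step at Δt = 0.1 |
| speed mean, spread | \|v\|, e_s | 1.0, 0.1 | explored range 0.1–2.0 |
| goal weight mean, spread | ω, e_ω | 0.05, 0.01 | explored range 0.01–0.1 |
| time step | Δt | 0.1 | |
| heading noise SD | e | 0.05 rad (≈2.86°) | unstated in the source; the standard value in this model lineage |
| cue radius | r_c | 30 | |
| patches × items, feed rate | —, f | 3 × 50, 0.001 | foraging mode |
| steps (free / foraging) | — | 2,000 / 10,000 | snapshots every 200 / 500 |

Negative Gaussian speed draws are resampled (floor 10⁻⁶); ω is floored at 0.
Initial positions are uniform in a disc of radius 5 at the arena centre
(groups are released from a small central cylinder in the experiments;
any clustered start coalesces identically under infinite attraction),
initial directions uniform.

**Gamma speeds.** The right-skew robustness mode draws speeds from a Gamma
distribution. The configured default is shape 0.4, scale 0.05 as printed in
the source description, but those values give mean 0.02 and variance 0.001 —
outside the explored speed range and an order of magnitude below the
Gaussian variance, and with shape < 1 most members are effectively
stationary, so groups do not travel and front/back position is undefined in
practice. The replication study (`studies.front_assortment_study`,
`speed_distribution="gamma"`) instead uses shape 4, scale 0.05: the unique
choice at that scale whose mean (0.2) lies inside the explored range and
whose variance (0.01) equals the Gaussian spread e_s² — the two properties
the skewed-speed robustness check was designed around. Both parameters stay
exposed on `SimConfig`.

## Kinematics conventions

* Coordinates: x right, y "north". Headings ψ = atan2(u, w) in degrees,
  clockwise from +y, in (−180°, 180°]; due east is +90°. Only relative
  angles and |turning speed| matter downstream, so results are invariant to
  the handedness choice.
* Velocity: forward difference, v(t) = (r(t+Δt) − r(t))/Δt; the final frame
  is masked. Acceleration: central difference; both edge frames masked.
  Turning speed: wrapped forward heading difference, folded to the shorter
  arc (a 179° → −179° step is +2°, never −358°).
* Undefined values are NaN with explicit validity masks; edge frames are
  masked, never extrapolated; heading is masked at zero speed.
* Smoothing: Savitzky–Golay, window 15 frames, polyorder 3 (the window
  matches the tracking pipeline the analysis was designed around; the order
  is the standard choice below that window and is exact on cubic paths).
  When smoothing is requested, all derivatives are taken from the smoothed
  positions — a single pipeline.
* On uniform circular motion at 24 fps the discretisation error of this
  scheme is below 1% for radii 50–200 mm and rates 0.2–1.0 rad/s (checked
  against the closed forms v = rω, |a| = rω², γ = ω).

## Group metrics

The centroid is the unweighted mean position; its kinematics come from the
same finite-difference pipeline. The group-frame transform maps fish
positions to (x′, y′) = CD·(sin σ, cos σ) with σ the centroid-relative
bearing minus the centroid heading, wrapped; the transform is an isometry
(hypot(x′, y′) = CD). "Front" is y′ > 0, strictly — y′ = 0 counts as
not-front (measure zero at float precision). Frames whose centroid speed is
below 10⁻⁶ mm/s have an undefined travel direction and are excluded from
front-fraction denominators. IID is the mean over unordered pairs (the
ordered-pair mean is identical; a unit test demonstrates the equality).
Polarization is the resultant length of the heading unit vectors, in [0, 1].
Centre-distance rank is 1 (most central) to n (most peripheral), mean ranks
on ties. Trial summaries report medians per fish for speed/NND/CD (the
frame-level distributions are right-skewed) and both group-speed senses —
median centroid speed, and mean of member median speeds — labelled
distinctly.

## Schooling classification

A frame schools when IID ≤ 160 mm, centroid speed ≥ 0.5 BL/s, ρ ≥ 0.6, and
the frame has no outlier or split; boundaries are inclusive, following the
printed ≤/≥. The outlier/split detector links fish closer than 4 BL and
inspects the connected components: one isolated fish = outlier, two or more
sub-groups of ≥ 2 = split (4 BL is the same proximity cut-off that gates the
leadership analysis; the original detector's parameters were tuned on raw
data distributions that are not published, so both the threshold and the
method tag are configurable). Frames with any undefined input are excluded
from the classified-frame denominator rather than scored false.
Classification is monotone: relaxing any threshold can only increase the
schooling proportion (property-tested).

The robustness scan evaluates every combination of ρ ∈ {0.4…0.8} (step 0.1),
speed ∈ {1.0…3.0} cm/s (step 0.5) and IID ∈ {100…220} mm (step 30) — 125
cells; the primary criteria map to the (0.6, 2.0 cm/s, 160 mm) cell
(0.5 BL/s = 2.03 cm/s at BL = 40.6 mm), leaving 124 alternatives. Speed
thresholds are specified in cm/s and converted internally through the body
length. Spearman p-values use the asymptotic approximation.

## Leadership

For each dyad, series are compared at every lag in ±72 frames (±3 s at
24 fps): Pearson correlation for speed (raw speed by default; a
first-difference switch is exposed), and the mean cosine of the heading
difference for direction — the heading-vector dot product is wrap-safe,
unlike Pearson on wrapped angles. Frames enter a dyad only when the pair is
closer than 4 BL and both fish move faster than 1 BL/s (strict
inequalities, following the printed "less than"/"faster than");
correlations use the jointly eligible overlap at each lag, with no padding,
and a dyad is undefined below 240 eligible frames (10 s) of overlap per lag.
The peak lag τ* (ties resolved toward zero, then positive) gives the delay;
positive τ* means the first fish leads. A sliding-window mode (30 s windows,
50% overlap — window length is not fixed by the source; whole-trial
single-window is the default) reports the mean of per-window peak lags.
Edges run leader → follower weighted by |τ*| seconds; τ* = 0 contributes no
edge. Per-fish summaries report out-degree, in-degree, net leading
(out − in) and mean lead delay.

The planted-lag oracle modulates a leader's speed with two incommensurate
sinusoids (ratio the golden ratio) so the correlogram peak is unique — a
single sinusoid is ambiguous at lags ± one period — and delays a copy by a
known lag. Recovery is within ±1 frame across delays 0–72 frames and
additive speed noise up to 20% of the signal SD; independent white-noise
pairs show no directional bias in peak lags and only small peak
correlations.

## Foraging metrics and behaviour scores

A fish is "at" a patch when over it or within 30 mm of its boundary (square
patches use the true distance-to-square; disc patches distance-to-circle).
The discoverer is the first arrival per patch per trial; simultaneous
arrivals within one frame are ordered by fish id (documented tie rule).
Depletion latencies are per-item consumption times from trial start, with
uneaten items censored at the trial length (eaten + censored = provisioned).
The experimental provisioning arithmetic — 3 patches × 5 items = 15 per
trial, 2 trials per day → a 30-item theoretical daily maximum per fish — is
exposed as `foraging.items_per_trial` / `foraging.max_daily_intake`.

Cover metrics treat the tracked point as the fish (the "at least half the
body out" criterion of tag-based tracking is not recoverable from point
data — a documented approximation): per-fish proportion of frames out of
the cover disc, proportion out alone, and mean leaving order across
excursions, where an excursion brackets a contiguous run of frames with the
group centroid outside the disc. Group level: mean count out and the
all-out proportion, optionally restricted to the food-available window.

Behaviour scores: exploration = mean across the two boldness-assay trials of
the proportion of time out of cover, min–max scaled to [0, 1] across the
cohort; social proximity = mean shoal-compartment distance, square-root
transformed, inverted (max − value), then min–max scaled, so higher = a
stronger proximity tendency (the chain is strictly monotone decreasing in
raw distance). Min–max is the only normalisation that guarantees the [0, 1]
bounds; the choice is flagged in the score object. Relative scores subtract
the mean of the focal fish's group-mates. Single-trial inputs set a warning
flag rather than failing.

## Replication studies and their sizes

`shoalkit.studies` re-runs the model claims end to end; the replicate counts
are sized so that the *sign* of each effect resolves on a single CPU.

* **Front assortment** (free schooling, n = 5, Gaussian speeds, 2,000
  steps): 100 replicates; within-group Spearman between intrinsic speed and
  front fraction, sign-consistency by one-sided binomial test.
* **Centroid distance**: same replicates, speed vs mean CD. At n = 5 the
  model produces a *U-shaped* centre-distance profile — the slowest member
  trails as peripherally as the fastest leads — so this correlation sits at
  chance; the package reports it as computed. Front-back asymmetry, not
  radial distance, is the robust signature of speed heterogeneity in this
  model at this group size.
* **Gamma robustness**: 100 replicates at shape 4 / scale 0.05 (above).
* **Depletion grid**: 5 × 5 grid over speed_mean ∈ [0.1, 2.0] and
  omega_mean ∈ [0.01, 0.1], 10 replicates per cell, foraging protocol with
  the experimental 5 items per patch (with the full 50 the horizon cannot
  express depletion at f = 0.001). Depletion speed is the mean per-item
  latency with censoring at the trial end — the survival-style statistic —
  and the claim tested is Spearman ρ < 0 pooled over cells, against each
  trait axis.
* **Schooling vs speed**: 10 replicates each at speed_mean 0.25 and 1.5,
  classifier thresholds rescaled to model units (body length 1, IID cut at
  8 units ≈ twice the typical schooling IID of the model).
* **Leadership**: 100 planted-lag fixtures (delays 0–72 frames × noise
  0–20%) and 100 white-noise null pairs of 4,000 frames.

## What the synthetic data does and does not emulate

The simulator and parametric fixtures stand in for tracked fish: group sizes
and release procedure, frame-rate-and-body-length bookkeeping, heterogeneous
per-individual speeds, foraging patches with per-item events, and cover
geometry all mirror the experimental design. They do **not** emulate
tracking noise, occlusions or identity swaps (the loader rejects gaps rather
than interpolating, because the reference tracks were manually completed),
body posture (point tracks only), wall-following behaviour of real fish, or
any fitted relationship between the assay scores and model traits. Passing
tests therefore demonstrate correctness of the computations and the model's
qualitative behaviour, not quantitative agreement with any particular
empirical dataset.

## Numerical details and degenerate inputs

* Coincident agents repel along a random direction and are counted.
* Zero social + zero goal resultant keeps the previous heading.
* NaN positions abort a simulation with the step index.
* The loader rejects missing frames, duplicate (frame, id) rows and
  non-numeric coordinates, naming the offending row; read ∘ write is the
  identity to ≤ 10⁻⁹ mm.
* Batch simulations give each replicate its own RNG stream in a fixed draw
  order, so a batch is bit-identical to the same seeds run singly.

## Known limitations

* 2-D only; no predator agents; no parameter fitting to empirical data.
* The centre-distance U-shape above means radial-position claims should be
  made with rank- or front-based statistics at small n.
* The outlier/split rule is a connectivity heuristic standing in for an
  unpublished detector; its threshold is configurable and should be
  re-examined for group sizes far from 5.
* Cover metrics approximate "half the body out" by the tracked point.
* The sliding-window delay aggregation ("mean time point of the maximum")
  exposes both whole-trial and windowed modes because the original
  aggregation granularity is ambiguous.
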
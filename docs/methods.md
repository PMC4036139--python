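# Methods

This note documents the models and procedures implemented in
`electrokin`, the choices made where the design was genuinely open, and
what the synthetic data can and cannot show.

## Egocentric kinematics

Frames are sampled at the animal's own EODs, so the time base is
irregular (gamma-like inter-pulse intervals, mean near 1/25 s). For the
interval between frames n and n+1 with head displacement **d** and
heading θ(n), the package computes

- thrust = (**d** · û)/Δt, with û the unit heading vector,
- slip = (**d** · n̂)/Δt, with n̂ the 90°-counterclockwise rotation of û
  (slip is positive to the animal's left, consistent with
  counterclockwise-positive yaw; mirror movements then oppose in both
  slip and yaw),
- yaw = wrap(θ(n+1) − θ(n))/Δt, wrapped into (−180°, 180°].

Velocities attach to the leading frame, so onset-triggered analyses can
index behavior starts; the last frame of a contiguous segment carries no
velocity, and no velocity ever spans a gap left by removed frames. All
interfaces use degrees, cm and seconds. Rotating the whole trajectory
leaves (thrust, slip, yaw) unchanged; mirroring it negates slip and yaw
only — both are property-tested.

Before clustering, thrust and slip are z-scored with one pooled
mean/SD (they are commensurate translational velocities) and yaw with
its own; this removes the unit mismatch between translational and
rotational channels without distorting the thrust/slip geometry.
Z-scoring is fitted on the pooled dataset; sample SDs use ddof = 1.

## Prototypical movements and the cluster-count scan

A Ward-linkage pre-scan on a seeded subsample (default 5 000 points)
brackets plausible cluster counts via the top decile of relative jumps
in merge cost. k-means (k-means++ seeding, Lloyd iterations, squared
Euclidean distance, tolerance 1e−8, ≤ 300 iterations) is then scanned
over k = 2..50. Per k, 20 replicate fits with seeds derived from the
master seed by fixed offsets (each keeping the better of two k-means++
starts) are scored:

- **stability**: mean pairwise adjusted Rand index between replicate
  partitions — a chance-corrected measure of whether the partition at
  this k is reproducible;
- **quality**: mean silhouette of the replicate partitions on one fixed
  seeded subsample (default 2 000, at most 20 000 points).

The selected k is the **largest** k whose stability is ≥ 0.9 and whose
quality lies within 5% of the running maximum: the finest partition
that is still reproducible and does not degrade separation. The
published evaluation this emulates does not state its exact formulas;
the concrete rule above is this package's own, is configurable, and its
trace (per-k stability/quality, eligibility) is retained and
serialized. When no k passes, the best-quality k is returned with a
warning rather than an error, since degenerate inputs (single blob)
have no defensible "largest stable k".

The final model is refit at the selected k (ten k-means++ restarts),
centroids are put in canonical order (lowest-thrust prototype first,
then increasing rotation amplitude, positive-yaw member of each pair
first), and mirror pairs are detected greedily with the score
|Δthrust|/σ_trans + |slip_i + slip_j|/σ_trans + |yaw_i + yaw_j|/σ_rot,
accepted below 0.5. The score deliberately uses mean-free scaled sums:
summing z-scored slip values would retain twice the scaler mean and
mask true mirrors. Assignment is nearest-centroid with ties going to
the lowest PM id.

## Homogeneous chains and triggered averages

Chains are maximal runs of one PM of at least 10 frames, never crossing
segment gaps. PM 01 chains split at mean thrust −2 cm/s into
"backwards swimming" (below) and "stationary behavior" (at or above;
the boundary is inclusive on the stationary side). Onset-triggered
averages resample each contributing signal onto a regular grid (0.04 s
step) by nearest-frame lookup within one step's tolerance — the time
base is irregular, so exact alignment is impossible; nearest-frame is
the least-committal choice. Per grid point the mean, sample SD and a
t-based 95% CI of the mean (n−1 df per bin) are reported; bins with
fewer than 2 contributions are masked. Note that a t-based CI
half-width only drops below one SD for n ≥ 7.

## Transition model and SPM mining

Consecutive equal labels collapse to single tokens (lossless,
round-trip tested), which removes self-transitions; transition counts
pool over contiguous segments and normalize row-wise into
P(next | current). Token stationary frequencies are the token counts
over the total. The probability of a sequence s₀…s₅ is
stationary(s₀)·∏ P(sᵢ₊₁|sᵢ) — the start token's stationary weight is
included so sequence probabilities are comparable across start states.
The top-100 five-transition sequences are found by best-first search:
since each extension multiplies by a factor ≤ 1, a prefix's probability
bounds all completions, so sequences leave the frontier in exact rank
order (verified against brute-force enumeration on small alphabets);
ties break lexicographically.

Reduction first maps each token to its mirror pool (discarding
left/right direction), then merges sequences with equal pooled token
multisets (same movements, different fine structure). Merging conserves
total probability. Occurrences are found by sliding a window over the
mirror-pooled token stream and matching the entry's canonical pooled
sequence; relative frequency per condition is occurrence frames over
total frames (frame counting; per-occurrence counting is available via
the occurrence lists themselves). Overlapping occurrences are kept and
flagged.

## Spatial and electromotor analytics

Frame n's instantaneous EOD frequency is the reciprocal of the
*preceding* inter-pulse interval (the first frame is masked). fEOD is
z-scored per recording night to absorb between-night shifts in basal
rate; a numerically constant night maps to z = 0. Object distance is
head-to-cube-center (a surface-referenced option subtracts the half
edge). Maps use 1 cm² bins; empty bins are masked, out-of-extent frames
dropped and counted. Distance profiles return both normalizations —
per-bin (flagged / all frames at that distance) and relative to the
whole dataset — because either can be wanted; mutually exclusive flags
partition every bin under the per-bin form.

The approach conditional keeps occurrences whose final frame lies
within 4 cm of the object and closer than their first frame; the
inverted filter (start < 4 cm, ending farther) defines departures, and
the two subsets are disjoint by construction. Post-chain transition
shifts compare PM frequencies in the 10 frames after chain ends against
a null of equally many uniformly placed windows (999 permutations,
add-one-corrected two-sided p, Holm across PMs). Group comparisons use
the two-sided Mann–Whitney rank-sum test (exact for small untied
samples) or Kruskal–Wallis with tie correction followed by Dunn's
pairwise z statistics under Holm adjustment; Dunn's test is implemented
directly from the rank statistics.

## The synthetic session generator

The generator emulates nocturnal object exploration in an 80×80 cm
arena imaged over a central 64×48 cm view, with the coordinate origin
at the arena center (= default object position), x rightward, heading
0° = +x, counterclockwise positive.

Sessions follow a script of macro-behaviors drawn from configurable
weights (defaults: cruise 0.50, approach 0.15, stationary 0.15,
backwards 0.10, departure 0.10) with log-normal durations (medians 2.0,
1.1, 0.6, 0.9, 1.1 s; σ = 0.35 log-units). Within a behavior, per-frame
PM labels follow a first-order Markov chain: cruising mixes the nine
forward PMs with a preference for intermediate amplitudes and a
persistence of 0.85; approach/departure alternate straight swimming
(PM 02) with the moderate-turn pool (PM 07/08) at persistence 0.7;
stationary and backwards behaviors hold PM 01. Approaches steer by
choosing the mirror-pair member whose yaw sign turns the animal toward
the object (departures away; shelter-biased cruising without an object
steers toward the nearest shelter when more than 10 cm away) and end on
arrival within 2.5 cm or after a timeout. Velocities are Gaussian
emissions around the prototype means (SDs 0.9 cm/s translational,
11 deg/s rotational; PM 01 thrust SD 1.5 cm/s); during stationary and
backwards behavior the PM 01 thrust mean shifts to −0.6 and −2.9 cm/s,
giving PM 01 a broad two-mode thrust interior inside a single cluster,
separable at the −2 cm/s chain threshold; during approach/departure the
thrust mean ramps linearly down inside 10 cm of the object (floor
0.85×). Inter-pulse intervals are gamma distributed (shape 10 — regular
but variable trains) with mean 1/rate, where the rate is a per-PM base
(22–33 Hz, low for slow translational PMs, high for high-amplitude
PMs) times a near-field gain (default 1.2 within 5 cm) when an object
is present. Position and heading integrate the body-frame velocities
over each realized interval using the leading frame's heading, so the
kinematics module recovers the emitted velocities exactly in the
noise-free case.

Trajectories that would leave the recorded view are reflected at its
walls (preserving determinism; counted in the session metadata), and
the landing frame after a boundary contact is removed from the track —
as frames with the animal not fully in view are removed in real
recordings — leaving a frame-index gap that downstream kinematics
never bridge. About 1% of frames are removed this way.

Defaults were calibrated once against the study conditions the
pipeline assumes — mean EOD rate within 10% of 25 Hz, mean swim speed
within 15% of 10 cm/s, ten recoverable prototypes with four mirror
pairs, a bimodal PM 01 thrust interior, approach slow-down inside 10 cm
and EOD-rate gain inside 5 cm — and are fixed. The numeric prototype
table is a free parameter of the generator (no published centroid
values exist); it is *not* ground truth about any animal.

### What the generator does not emulate

Real tracking noise (centroid jitter, heading estimation error from the
body-midline fit), body posture and bending, haptic chin contacts,
social/communication EOD patterns, habituation across nights, and any
electric-image physics. Passing the recovery tests therefore shows the
*analysis chain* is correct and calibrated on data with the assumed
statistical structure — not that real fish data would yield the same
catalog sizes or frequencies.

## Problem sizes

The test suite and the acceptance script run the cluster-count scan on
two sessions of 25 000 frames (≈ 50 000 kinematic triples, the scale at
which the selection is stable across seeds), with 20 replicates per k
over k = 2..50 and silhouette evaluated on a 2 000-point seeded
subsample; unit tests use sessions of 10–25 k frames. The end-to-end
pipeline default is three object and two no-object sessions of 10 000
frames.

## Known limitations

- The stability/quality selection rule is this package's concrete
  reading of a published but under-specified evaluation; other rules
  (gap statistic, BIC over Gaussian mixtures) could select differently
  on ambiguous data.
- Mirror-pair detection assumes pairs are exact mirrors up to noise; a
  handed behavioral asymmetry would leave PMs unpaired rather than
  discovering a biased pairing.
- The Markov/SPM layer is first-order by construction; longer-range
  dependencies in behavior fold into the transition probabilities.
- Permutation nulls for post-chain shifts place windows uniformly,
  ignoring any spatial inhomogeneity of chain ends.
- The CLI `report` stage emits tables (TSV/JSON) only; no plotting code
  ships with the package.
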
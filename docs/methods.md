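# Methods

## Model and procedure

Each user's trajectory is treated as a realization of a hidden Markov
model over K latent spatial contexts. The observation model is a
full-covariance bivariate Gaussian per context in raw (lon, lat) degree
space; no map projection is applied, matching the clustering stage, which
also works in "coordinate units". Timestamps order the events but carry
no other information into the HMM: the chain steps once per event, not
per unit time, so a user photographing daily and one photographing
monthly are modelled identically if their location sequences agree.

The pipeline per user is:

1. **Filters.** Events outside the study polygon are dropped (points at
   sea carry no residence information); then users whose remaining events
   all fall on one UTC calendar date are dropped entirely, since a
   single-day record cannot show movement between contexts. The single-day
   predicate is evaluated *after* the region filter, so a user whose only
   multi-day activity was at sea is removed. Both filters are idempotent
   and commute under this convention.
2. **DBSCAN** with ε = 0.5° and MinPts = max(2, round-half-up(2% · T)).
   The point itself counts toward its own neighbourhood (the standard
   |N_ε(p)| ≥ MinPts convention). The floor of 2 exists because
   MinPts ≤ 1 makes every point core. Cluster ids follow the input order
   of first core points, and border points go to the first cluster that
   reaches them, making labels deterministic.
3. **HMM initialization.** K = number of clusters (1 if all points are
   noise); means = cluster centroids; covariances = per-cluster sample
   covariances with noise points attributed to their nearest centroid for
   this statistic only (all events, including noise, enter the EM fit);
   transition matrix = 0.9 on the diagonal, uniform off-diagonal; initial
   distribution uniform. The strong diagonal encodes the prior that
   consecutive events usually stay in one context.
4. **Baum–Welch** with scaled forward–backward recursions; stop when the
   relative log-likelihood gain drops below 1e-4 or after 100 iterations.
   Covariance eigenvalues are floored at 1e-6 deg² at every M-step, which
   prevents collapse onto repeated coordinates; row-stochasticity and
   simplex invariants are asserted after every M-step and a violation
   raises rather than propagates. Note the log-likelihood is a density
   and routinely positive at degree scale.
5. **Viterbi decoding** in log space, ties broken toward the lower state
   index. The decoded path yields occupancy fractions and transition
   counts.

## Aggregation

User weights default to event-count-proportional (`photo_count`), with
`uniform` available; the choice is recorded in output metadata. The
per-user spatial density uses the Viterbi occupancy as mixture weights;
the stationary distribution of the fitted transition matrix is available
as an alternative (`mixture_weights="stationary"`). Occupancy is the
default because the aggregation follows the decoded path, and because it
remains defined when the chain is reducible.

The grid is an even lon/lat lattice (default 0.05°, UK-like bounding box
(−8.65, 49.84, 1.77, 60.86)); values are densities per square degree, and
the raster integrates to 1 ± 2% when the box covers every state's ±5σ
support — a logged warning signals leakage otherwise. The OD surface is
evaluated only at a finite list of named locations. Within-context pairs
(i = j) are excluded by default and the diagonal is zeroed: the target
quantity is between-place travel. Normalization rescales the matrix to
total mass 1 over ordered pairs.

## Peak detection and scoring

Windows are specified in km and converted to odd cell counts with
1° lat = 111.32 km and 1° lon = 111.32·cos(mid-latitude) km; the local
flat-earth conversion is adequate at country scale and keeps the filter a
pure raster operation. A cell is a peak iff it attains the maximum of its
centred window and exceeds φ; on plateaus only the lexicographically
smallest (lat, lon) cell survives, which matters only for degenerate
grids. Matching to the catalogue is greedy in ascending haversine
distance and one-to-one, so a single dense blob cannot claim two cities
nor two blobs one city; precision is defined as 0 when nothing is
detected. The default sweep interpolates 10 window sizes between
(18, 28) and (90, 140) km at fixed aspect ratio and 20 thresholds
log-spaced between 1e-3 and 1e-4, both overridable, since useful φ values
can fall outside that interval depending on grid normalization.

## Null-model comparison

Reference OD matrices are journey counts; estimates are probabilities.
Before the Frobenius comparison the estimate is rescaled so its total
matches the reference's (Kendall's τ needs no such alignment, being rank
based). The lognormal is fitted by maximum likelihood to the reference's
positive off-diagonal entries — zeros are excluded from the fit but kept
as zeros in all distances — and random matrices are drawn i.i.d. on the
reference's positive support with zero diagonal, asymmetric. The
exceedance is the fraction of 100 draws (default) lying farther from the
reference than the estimate. Calibration: when the estimate is itself a
draw from the fitted null, its distance is exchangeable with the trials'
and the exceedance is a uniform rank statistic with mean 0.5 and variance
≈ 1/12 — the calibration tests use this variance for their Monte-Carlo
error bars.

## Synthetic data generator

The generator realizes exactly the structure the inference assumes — the
minimal generative counterpart of the model, so parameter recovery is
well-posed. A world of weighted anchors (heavy-tailed lognormal weights,
mimicking city sizes) is placed by rejection sampling with a minimum
pairwise great-circle separation of 1° of arc, guaranteeing DBSCAN at
ε = 0.5° can separate contexts and density peaks are resolvable. Each
user picks k anchors (weight-proportional, k uniform on 2–6 by default —
the real distribution of per-user context counts is unknown, so k is an
exposed parameter), follows a symmetric Markov chain with self-transition
0.9, and emits isotropic Gaussian positions with σ = 0.1°. Event counts
are lognormal(ln 200, 1.0) per user and inter-event gaps lognormal with
median 24 h and log-sd 1.5 — heavy-tailed in a way that matches observed
upload-gap behaviour qualitatively while keeping closed-form quantiles
for tests. Timestamps are strictly increasing by construction.

What the generator does *not* emulate: spatially correlated emissions
(real cities are not isotropic Gaussians), bursts of photos at identical
coordinates, non-stationary behaviour (holidays, relocation), unequal
observation effort over time, and boundary effects of real coastlines.
Passing the recovery tests therefore shows the inference is correct when
its assumptions hold, not that real photo streams satisfy them.

A note on displacement statistics: the mixture of short within-context
steps and rare long jumps is heavier-tailed than Gaussian only in the far
tail. A single Gaussian fitted to all displacement lengths is inflated by
the jump mode and *over*-covers moderate distances (~100 km); the
empirical survival exceeds the Gaussian's from roughly 300 km outward,
which is where the tests assert the Lévy-flight-like signature.

## Problem sizes and determinism

The shipped test populations use 50 users (shared fixture) and 200 users
(full-pipeline recovery), 10-anchor worlds, and 20 users × 500 events for
parameter recovery; the acceptance script uses the same sizes. These
scales already give tight recovery (state-mean error ≈ 0.006°, decoding
accuracy 100%, all anchors found), so nothing is gained by simulating
larger populations. One master seed is expanded into per-stage
substreams (`numpy` SeedSequence spawning), so stages re-run in isolation
reproduce the pipeline's outputs byte-for-byte given the same inputs.

## Known limitations

- Degree-space metrics make ε and emission covariances anisotropic in km
  (1° lon ≈ 64 km at 55° N vs 111 km of lat); this mirrors the intended
  parameterization but means the same ε covers different ground at
  different latitudes.
- K is fixed by DBSCAN; there is no model-order selection, and a user
  whose contexts overlap within ε is fitted with too few states.
- EM is run from a single (cluster-derived) initialization; with
  well-separated contexts this is reliably near the global optimum, but
  no restarts are attempted.
- The OD surface evaluates Gaussian densities at city points; broad
  contexts contribute to several nearby cities, which is intended, but a
  context lying between two cities is split rather than assigned.
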
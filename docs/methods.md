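# Methods

## The plausibility model

The package treats an interpolation of a measured series as a
piecewise-linear path through the ordered measured points plus any
inserted points. The *inflexion count* of a path is the number of adjacent
sign alternations in its second differences, after differences of
magnitude ≤ `zero_tol` (default 1e-12) are dropped — a flat kink is
neither a positive nor a negative curvature event. A path is *plausible*
relative to a reference count k when its inflexion count is ≤ k. The
reference is the count of the measured points alone (or of the current
measurement realization under the error model). The biological reading:
each inflexion marks a change of regulatory regime, and no regime change
is assumed without evidence.

Two remarks on this choice:

* The constraint is purely combinatorial, so the piecewise-linear family
  loses nothing against smooth curves: any smooth curve through the
  points with c curvature-sign alternations witnesses a polyline with the
  same alternation pattern. Splines are deliberately not used in the
  core.
* The rule is ≤ rather than strict equality. Equality would declare a
  perfectly straight continuation of a curved series implausible, which
  is not a defensible biological position; the switch
  `acceptance="eq"` preserves the stricter variant for comparison.

## Plausible bounds

At an abscissa x between measurements, the plausible set
{y : insert (x, y) keeps the path plausible} is an interval (verified
empirically on randomized fixtures; the on-line value is always a
member). `pointwise_bounds` scans a 64-point grid over the clipped window
[y_min − c·R, y_max + c·R] (R the measured y-range, clip factor c = 1 by
default) and refines both edges by 60 bisection steps. The clipping is
needed because with two measured points, or in end intervals of
permissive references, single insertions are unconstrained; an unbounded
envelope would be useless downstream, and the clip factor is an explicit,
reported parameter rather than a hidden one.

Under measurement error, each measurement carries a t-based confidence
interval at level `conf` (default 0.99). The bounds become the union of
the pointwise bounds of every *corner path* — each measurement pinned to
its lower or upper confidence limit — plus the all-mean path, which
guarantees the union contains the mean path's bounds. Each corner uses
its own reference count, since corner assignments genuinely change the
curve's shape. Corners are enumerated exactly up to 2^12; beyond that a
seeded sample of 4096 corners is taken and a warning is logged.

## Likelihood distributions

Two routes compute the distribution of plausible interpolations over the
guide columns (two per interval, at the trisection points of the time
axis):

**Monte Carlo.** Guide y values are drawn independently and uniformly
within the bounds at each column; a configuration is accepted iff the
merged path is plausible. Accepted configurations are binned per column
into `bins` equal-width intervals of the envelope span (default 40,
matching the direct grid). The acceptance rate collapses roughly
exponentially with the number of measured points — by six points on a
typical single-peak series, a million draws no longer produce five
hundred acceptances — which is why the sampler is kept as a validation
oracle rather than the production route.

**Direct.** Each column's span [lo, hi] is divided into V equal-width
intervals (default V = 40) represented by their midpoints. The
left-conditional vector starts uniform at the leftmost column; sweeping
right, each midpoint's weight is the plausibility-masked sum over the
previous column's vector, then the column is normalised. The
right-conditional vector mirrors this from the right. The joint vector of
the first (last) guide column is its right- (left-) conditional vector;
interior columns sum the triple-insertion plausibility over the left
neighbour's left-conditional and right neighbour's right-conditional
mass. All plausibility checks insert the candidate points into the full
measured path, and all columns are normalised to sum to one. A column
whose weights vanish entirely is replaced by the uniform vector with a
warning; this happens when a directional chain concentrates mass on
midpoints that admit no continuation, and the fallback keeps the
computation defined without silently inventing precision.

An exhaustive enumeration oracle (`enumerate_joint_oracle`) computes the
exact marginals of the uniform distribution over plausible midpoint
combinations, up to a configurable cap (10^6 combinations by default). On
three-measurement fixtures the DP reproduces it exactly; in general the
DP is a local approximation.

### Numerical behaviour worth knowing

The column grid is anchored to the envelope, and the envelope *is* the
plausibility boundary. Consequently some grid rows lie exactly on the
constraint surface, where the transparent-zero rule decides membership.
Two visible consequences, both O(1/V):

* the midpoint rule biases coarse grids: at V = 8 the enumeration
  marginals differ from the continuous (Monte Carlo) distribution by a
  total-variation distance of ≈ 0.12 on generic three-point fixtures,
  falling to ≈ 0.035 at the default V = 40;
* the zero-error field is a discontinuity point of the estimator: fields
  of infinitesimally perturbed measurements differ from it by a
  density-TV of ≈ 1/V (the boundary rows are kept at zero error but lost
  for about half of the perturbed realizations).

Fixtures whose values form exact rational collinearities (round numbers
on integer times) put entire midpoint combinations on the constraint
surface and should be avoided when comparing fields across perturbations.

## Measurement-error model

`summarize_replicates` gives mean, sample sd and the CI half-width
t_{(1+conf)/2, n−1}·sd/√n. A single replicate requires an externally
supplied sd and uses the normal quantile (a t with zero degrees of
freedom does not exist). Identical replicates get exactly sd = 0.

The CI is divided into m sub-intervals of equal probability under the
scaled-t sampling distribution of the mean: boundaries at the inverse-t
quantiles of (1−conf)/2 + j·conf/m, j = 0…m, each sub-interval
represented by the arithmetic midpoint of its boundaries. m defaults
to 20 so that the default 20 Latin-Hypercube cycles use every stratum
exactly once; LHS permutes each measurement's midpoints independently
with a seeded Fisher–Yates shuffle and realization j takes every
measurement's j-th ranked midpoint. Each realization carries its own
reference count; its field is computed on the shared corner-union bounds,
and the per-realization joint vectors are averaged with equal weight —
equal-mass strata make every realization equally probable by
construction. Measured columns of the aggregated field pool the
realizations' representative values with uniform weights.

## Envelopes, coverage, PC1

The level-q envelope interval at a guide column is the central
(equal-tailed) interval of the discrete joint distribution, with linear
interpolation inside midpoint bins; at a measured column it is the
t-based central CI at level q. Vertices are connected by straight lines.
Highest-density intervals are available behind `hdi=True`; central
intervals are the default because the likelihood regions are defined by
their boundaries, and equal-tailed boundaries are monotone in q (which
guarantees nesting). Coverage of withheld measurements scores only their
means — the error of the new measurements is deliberately ignored — with
a relative tolerance of 1e-9 so that points lying exactly on a zero-width
boundary count as covered.

Genome-wide matrices are reduced by mean-centred PCA across the gene
dimension; every (time, replicate) sample is projected onto the first
component, the loading sign is fixed so its largest-magnitude entry is
positive, and the variance fraction of the component is reported
alongside the resulting univariate replicate series.

## Synthetic data

The generator produces the shape vocabulary the estimator targets:
logistic rises/falls, single Gaussian peaks, and damped oscillations,
sampled at a handful of time points (default 9 over [0, 8]) with
replicate noise that is normal by default (sd 0.1, 3 replicates) so the
t-interval machinery applies exactly; a Student-t(3) option exists for
robustness checks. What it does not emulate: platform-specific intensity
transforms, correlated replicate error, heteroscedasticity across the
dynamic range, or missing values. Passing tests therefore validate the
algorithmic contract, not robustness to microarray artefacts.

`simulate_truth_from_plausible_set` draws one accepted guide
configuration through a retained series and linearly interpolates it —
the exactly correct reference distribution for calibration, since the
estimator claims to describe precisely that plausible set.

## Calibration experiment

The calibration study runs 200 zero-noise series (7 time points; curve
families and shape parameters varied per series), withholds every other
time point, draws the truth from the plausible set of the retained
points, estimates envelopes with the direct method at V = 40, and pools
coverage over the 600 withheld points. Zero measurement noise is used
because it is the only setting in which the nominal level has an exact
referent. Measured coverage is consistently 2–6 points *above* nominal at
the interior levels (e.g. ≈ 24% at the 20% envelope, ≈ 79–81% at 75%).
This over-coverage is a geometric property of the straight-line envelope
construction: a withheld time lies midway between two guide columns, the
truth there is the average of two positively correlated guide values, and
averaging concentrates the truth relative to linearly connected marginal
quantile boundaries (under independence the effect would reach
1−(1−q)²). The envelopes therefore err on the conservative side between
columns; at the columns themselves they are calibrated up to the
discretisation effects above.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `conf` | 0.99 | confidence level of measurement CIs (dimensionless) |
| `V` (`--grid`) | 40 | intervals per guide column; cost of the joint pass is O(V³) per interior column |
| `m` (`--ci-bins`) | 20 | equal-probability strata per CI |
| `cycles` (`--lhs-cycles`) | 20 | LHS realizations (must be ≤ m) |
| `clip_factor` | 1.0 | search-window extension in units of the measured y-range |
| `acceptance` | `le` | plausibility rule (`le` or `eq`) |
| `levels` | 0.20, 0.75, 0.95 | envelope likelihood levels |
| `zero_tol` | 1e-12 | absolute flatness tolerance on second differences |

`zero_tol` is absolute: series whose values are far from unit scale
should be rescaled, or the tolerance adjusted, before counting
inflexions.

## Known limitations

* The plausibility constraint is an assumption, not an inference: widely
  spaced measurements make "no unobserved regulatory event" increasingly
  optimistic, and the envelopes inherit that optimism.
* The directional/joint passes condition only on adjacent columns; the
  enumeration oracle is exact but exponential, so global-constraint
  accuracy at scale is approximate by design.
* No extrapolation: all quantities are defined only inside the measured
  time range, and withholding patterns must retain both endpoints.
* Between columns, envelopes are conservative (see the calibration
  section); at coarse V, midpoint discretisation biases are material.
* 99% CIs with two or three replicates are extremely wide (t quantiles
  near 10), so corner-union bounds on noisy triplicate data can span
  several times the data range. That is a faithful statement of the
  uncertainty, but it makes dense replication valuable.
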
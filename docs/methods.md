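# Methods

## Estimation model

The survey records an ordinal visible-count class per morphospecies per
25 cm² scrape plate. Estimation replaces each class with a fixed
representative count (default 0/10/50/100 per plate) and proceeds in two
stages: plates admitted by the inclusion rule are averaged within host
(counts divided by plate area, so units are nematodes/cm²), and host
means are averaged **without weights** across hosts. The two-stage form
treats the host, not the plate, as the sampling unit: extra
pseudoreplicate plates sharpen a host's mean but do not let heavily
sampled hosts dominate the population mean. Flat pooling over plates
gives visibly different numbers (≈2.25/3.16/3.10 per cm² on the 2018
data instead of 2.26/3.19/2.76); only the two-stage form reproduces all
three published 2018 means, which is why it is the default and is
cross-checked against an independently coded double-loop oracle in the
tests.

Inclusion rules are explicit and configurable:

- `non_sequential` (default, behind the published 2018 means): drop only
  repeat passes over an already-scraped area (sequential resamples);
  first passes and pseudoreplicate plates stay in.
- `first_pass_only`: keep pass 1 of every area.
- `all_passes`: keep everything.
- An `exclude_hosts` list composes with any rule.

The published 2019 means (2.64/2.65/2.65 per cm²) could not be
reconciled with any single rule above, so the package produces a 2019
report but deliberately verifies nothing against those three numbers.

Composition is the per-species share of the summed mean densities;
fractions sum to 1 whenever any density is positive, and an all-zero
survey is flagged as undefined rather than silently reported as 0/0.
Prevalence treats a species as present on a host if any sample, at any
depth, scored above class 0. All rounding is a reporting-layer concern:
densities print at 2 decimals, composition at whole percent, loads as
whole counts, always half-up (ties away from zero), with unrounded
values retained internally.

## Ordinal scale

The scale's visible-count ranges are 0, 1–20, 21–99, ≥100. (Survey table
captions elsewhere print 1–15 / 15–99 for the middle classes; those
overlap at 15 and are kept only as metadata. The non-overlapping ranges
are the binning default because simulation requires a partition.) The
representative-count map must be strictly increasing with level and send
class 0 to exactly 0, which yields two useful monotonicity guarantees
checked as properties: raising any single plate's class never lowers any
density, and scaling the map by λ scales every density by λ while
leaving composition unchanged.

## Surface-area model

From umbilicus girth G and curvilinear total length L (both cm), the
tail dorsum is modelled as a circle of radius r = G/2π and the body
dorsum as an ellipse with semi-minor axis a = r and semi-major axis
b = L/2:

    A_tail = G²/4π,  A_body = π·a·b = G·L/4,  A_total = A_body + A_tail.

The full figures (not half) are used for "dorsal" area: the published
per-sex component/total means are additive and of the right magnitude
under that reading, and a `scale` factor is exposed for sensitivity
analysis of the alternative. Cohort summaries average per-individual
areas within sex (mean of areas, not area of mean measurements — the
formulas are nonlinear in G, and by Jensen's inequality the two orders
differ; a property test checks the convexity direction). Tail length is
carried in the data model but enters no formula. The packaged
morphometrics fixture stores the published per-sex **means** (length
262/310 cm female/male, tail length 64/66 cm, areas 15,320/3,730/19,050
and 16,136/3,435/19,571 cm²); per-individual measurements are not
published, so exact reproduction of those area means from raw
morphometrics is out of reach and the census consumes the printed means
directly.

## Loads and extrapolation ranges

Baseline load = total density × area, kept unrounded internally. The
published loads derive from area means rounded to the whole cm², so they
are matched to ±0.1 % rather than exactly. Headline ranges round the
baseline to a quantum (default 10,000 nematodes — this reproduces the
published endpoints) and multiply by the deeper-sampling factor range.
The default multiplier preset is (3, 4), from the observation that
sequentially rescraping the same patch yields roughly 3–4× the first
pass; a `conservative` preset (1, 4) keeps the unadjusted baseline as
the lower endpoint. The depth-yield statistic itself (cumulative mapped
count over all passes of a patch ÷ first pass, species pooled) is
summarized by median and range per host and treated as qualitative
context, not re-estimated into the multipliers: on the 2019 data two
hosts with near-empty superficial passes have ratios near 46, and a host
whose first pass maps to zero is reported as undefined rather than
folded into a summary.

## Synthetic surveys

The generator (`epicensus.simulate`) emulates the field design: hosts
with sex-specific correlated (length, girth) morphometrics anchored to
the published adult means (girth means back-solved from the published
tail areas via G = √(4π·A_tail), ≈216.5/207.8 cm); per-host latent
densities lognormal on the log scale with medians at the observed
per-species means and log-SD 0.7 (host means in the 2018 data span
roughly 0.7–4 per cm²); visible counts negative-binomial with variance
m + m²/k and k = 2 by default (epibionts are clustered; `None` gives
Poisson); counts binned at 1/21/100. Depth stratification is a
per-species availability fraction per pass; the 2019-shaped preset makes
one species fully unavailable at the superficial pass, reproducing the
qualitative field observation that it was absent from the biofilm layer
but present once dead skin was scraped. The availability values are
illustrative — the field data quantify none. Juvenile hosts attenuate
all latent densities by a factor (default 0.05, emulating the single
sparse juvenile observed); the default configuration is the 2018 shape
(7 adult hosts, 6 pseudoreplicate plates); `survey_2019_config()` gives
the sequential 4-pass design with one juvenile in seven.

What the simulator does **not** emulate: spatial autocorrelation across
the host surface, between-year dynamics, observer differences in class
assignment, and any dependence of plate area on sampling pressure.
Passing recovery tests therefore demonstrate estimator correctness under
the stated generative model, not field accuracy.

## Recovery ground truth

Binning counts into four classes and mapping back to fixed
representative values is inherently biased for the latent density, so
the recovery harness does not pretend otherwise: the target is the
estimator's **own expectation under the simulator**, computed
numerically — Gauss–Hermite quadrature (80 nodes) over the lognormal
latent density, exact class probabilities from the negative-binomial (or
Poisson) CDF at the bin boundaries, averaged over the plate/pass slots
the inclusion rule admits and mixed over the sequential-design and
juvenile fractions. Replicate means are compared to this expectation
within Monte-Carlo error (200 replicates of the 2018 shape in the
tests); the latent mean is reported alongside for context but never
asserted against.

## Numerical and design choices

- Half-up rounding throughout the reporting layer (Python's built-in
  banker's rounding would turn 2.5 % into 2 %).
- Depth-pass indices are stored explicitly in tables; a `-k` label
  suffix is only a fallback when the column is absent (sequential
  designs that label the first pass with a bare letter need the column,
  since `A-1` can mean pass 1 or pass 2 depending on the year's
  labelling convention).
- Sample tables are UTF-8 delimited text with the delimiter
  auto-detected between tab and comma; write/read round-trips are exact
  and tested field by field.
- Report JSON is key-sorted and timestamp-free, so identical inputs and
  configuration produce byte-identical reports.
- Degenerate inputs fail loudly: empty surveys, all-zero fauna
  (undefined composition), zero first-pass totals (undefined depth
  ratio), non-positive girths/lengths/areas, and girths above a
  configurable sanity ceiling that catches mm-for-cm unit errors.

## Problem sizes

The packaged fixtures are small (46 and 27 plates); the default
simulation studies use 7–1000 hosts and 200 recovery replicates, sizes
at which the full suite runs in seconds while leaving Monte-Carlo error
well below the effects being checked.

## Known limitations

No detection-probability / occupancy modelling, no interval estimation
beyond the multiplier range, no ventral-surface extrapolation, and no
claim about the 2019 published means (see above). Whether the published
"body only" area is the plain ellipse or an ellipse minus the tail-circle
overlap is not derivable from the source text; the plain ellipse is
used.
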
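# Methods

This note records the models, conventions and numerical choices behind
`heatpath`, in the order the pipeline applies them.

## Spatial frame

All distances, buffers and hexagon geometry are computed in a single metric
projected CRS: an ellipsoidal transverse Mercator (Krüger series on WGS84,
scale factor 1) centred on the study area. For study-area extents of tens
of kilometres the series truncation error is far below a millimetre, and
forward/inverse round-trips recover coordinates to better than 1e-6
degrees (asserted by test). Points more than 30° of longitude from the
central meridian are flagged as outside the projection's validity area
rather than silently projected.

Raster sampling is **nearest-cell**: a point takes the value of the cell
that contains it, with half-open containment ([west, east) × (south,
north]) so every in-bounds point belongs to exactly one cell. Bilinear
interpolation is deliberately not used — the indicator products are
cell-valued measurements, and smoothing across cells would invent spatial
structure the data do not assert. Temperatures are °C internally; grids
stored in Kelvin are converted on read (K − 273.15).

## Trajectory model

Pings are sorted in time per participant and aggregated to one per
calendar minute (first ping of the minute by default; a centroid rule is
available). The speed filter is a single forward pass over consecutive
retained pings: if the straight-line speed from a ping to the next
strictly exceeds 100 mph, the *origin* ping of the segment is excluded.
Which endpoint of an over-speed segment to drop is genuinely ambiguous;
excluding the origin matches the reading "exclude points with speeds from
that point to the next" and is configurable in one place. After any
exclusion the elapsed-time weights are recomputed from the surviving
pings, so excluded points never carry weight but never alter the
coordinates or timestamps of the points that remain.

The interval following a ping is wear time iff it lasts ≤ 1 minute.
A "day" is the local calendar date of the interval's starting ping, so an
overnight interval is attributed to the evening's date. The final ping of
follow-up carries zero weight (it has no next ping). Valid days require
≥ 10 h of wear; participants without one are excluded.

## Home inference

A flat-topped regular hexagon grid with side 62 m (cell area
(3√3/2)·62² ≈ 9 987 m²) tessellates the study bounding box. Hexagon
containment is computed as nearest-centre (a hexagon grid is the Voronoi
diagram of its centres) via cube rounding of fractional axial coordinates,
confirmed against the six neighbours; exact edge ties break to the lowest
cell index. Home is the centroid of the cell with maximal elapsed dwell
time over all hours, with ties broken to the earliest-visited cell. An
overnight (20:00–06:00) dwell argmax is computed as a cross-check —
intervals spanning a window boundary contribute only their clipped
within-window part — and classified as same / adjacent / disjoint relative
to the all-hours cell. The all-hours cell is authoritative: overnight
argmaxes can land on night-shift workplaces.

## Temporal interpolation

*Sparse single-valued series.* The value on index date t interpolates the
nearest scene on each side with weights span/(t − t_earlier) and
span/(t_later − t); algebraically this is linear interpolation in time.
When t coincides with a scene date, or falls before the first / after the
last scene, the nearest scene takes full weight. If one scene is nodata at
the sampled cell the other takes full weight; if both are, the interval is
dropped from the mean (its duration removed from the normaliser).

*Daily max/min series.* The clock-time weights use distances a (to 15:00
of the index date) and b (to the anchoring sunrise); the combination
(v_max·b + v_min·a)/(a+b) follows from the printed inverse-distance
weights. Anchor-day convention: between the day's sunrise and 15:00, b is
the time since that day's sunrise; after 15:00, the time until the *next*
day's sunrise; before the day's sunrise, the time since the *previous*
day's sunrise. Indicator values always come from the index date's grids.
Exact anchor times are handled as limits (full weight on the corresponding
extreme), avoiding the division by zero in the raw formulas.

Sunrise uses the NOAA solar-position chain (Julian century, equation of
time, declination, hour angle at zenith 90.833°) at a single fixed study
centroid — sunrise shifts by well under a minute across a metropolitan
area — with an explicit, configurable UTC offset (fixed offset by default;
no DST inference). An independently coded NOAA formulation in the test
suite agrees within 2 minutes year-round.

## Exposure summaries

Means are Σ v·Δt / Σ Δt over retained pings, with Δt the elapsed time to
the next retained ping, including overnight; a second mean excludes
non-wear intervals. Maxima average point values inside consecutive
10-minute bins anchored at each participant's first retained ping
(unweighted within the bin) and take the largest bin mean; bin anchoring
is a convention, and a whole-bin time shift leaves the maximum unchanged.
The residence-based method replays the participant's exact ping times at
the home centroid, so both methods share the temporal weighting and
differ only in space. For the sparse indicator the residence maximum is
the maximum day-level home value over follow-up dates (within a day the
interpolated home value is constant, so interval binning would be
redundant); for the daily pair it is the maximum 10-minute bin mean at
home.

## Synthetic world

The generator supplies the study conditions the pipeline is exercised
under; only its first and second moments are constrained by the emulated
products, the rest are explicit model choices.

*Heat surfaces.* Scenes are seasonal mean + smooth spatial field + optional
hot-zone disc. The spatial field is white noise low-pass filtered with a
Gaussian kernel (periodic boundaries) and standardised per scene, then
scaled to the target within-scene SD — 8.36 °C for the LST-like series,
3.75/3.02 °C for the air-temperature max/min. Correlation lengths (1 km
fine-scale, 8 km coarse) are model choices at neighbourhood/synoptic
scales. The LST-like schedule runs every 15 days from 30 days before to
30 days after the study window; each scheduled scene drops independently
with probability 0.49 (matching the fraction of scenes lost to cloud
cover), except the first and last, which are always kept so every study
date is bracketed. Seasonal means (31 °C LST, 25/12 °C air max/min with
amplitudes 12/8/6 °C peaking at day-of-year 200) follow the emulated
products' annual ranges. Daily minimum grids are clipped 0.2 °C below the
maximum where the two independent fields would cross.

*Cohort.* Defaults: 599 participants (tests and the acceptance run use
50), 14 days, 13.3 h daily wear, 59 km mean daily travel, 74 % of elapsed
time at home, on a 60 km domain with homes dispersed over the central
20 km so round trips rarely hit the boundary. Each day has round trips to
uniformly random bearings (distance set by the day's travel target, speed
30 km/h), destination dwell chosen so the away-from-home time budget
matches the time-at-home target, and a single overnight non-wear gap
(~10.7 h) bracketed by pings at home. Between-individual travel varies by
a mean-one lognormal multiplier (σ = 0.4), within-individual by a mean-one
gamma (shape 2). All waypoint times fall on whole minutes, so the
minute-sampled path length equals the scheduled distance exactly.
Randomness derives from `SeedSequence([seed, stream, participant])`
sub-streams, so adding a participant leaves the others bit-identical.
What the generator does **not** emulate: road networks, spatially
clustered destinations, multi-home arrangements, indoor/outdoor context,
or correlation between demographic labels and travel — covariate labels
are drawn independently from marginal frequencies. Passing tests
therefore certify the measurement machinery, not behavioural realism.

*Closed forms.* On a temporally constant, piecewise-constant surface
(background c, disc at +Δ) a deterministic block schedule spending a
weighted-time fraction f in the disc has mobility mean c + f·Δ and
residence mean c; the test suite recovers f·Δ to 1e-9 through the full
pipeline over a grid of (f, Δ) including f = 0.

## Comparison statistics

Differences are mobility − residence per participant. Cohort SDs use the
n−1 denominator. Pearson r is undefined (NaN, never 1.0) for n < 2 or
zero variance. Daily-distance tertiles cut at the empirical 33⅓ and 66⅔
percentiles using the lower order statistic, so printed boundaries are
observed values; the first interval is closed on both ends, later ones
half-open ("[lo, q1], (q1, q2], (q2, hi]"), with observed extremes as
outer bounds. Histogram bins are anchored at zero with configurable
width. No significance testing is attached to these descriptives.

## Problem sizes

The default acceptance run uses 50 participants × 14 days (≈ 560 000
minute pings) on the full-resolution surfaces (2000×2000 LST-like cells,
15×15 air-temperature cells); the unit-test worlds are 12 km domains with
coarser cells. These sizes give stable cohort statistics while keeping a
complete run in tens of seconds.

## Known limitations

Exposure misclassification sources the study itself names — indoor/outdoor
status, air conditioning, radiant heat — are out of scope. The hexagon
side default (62 m) follows the stated side length; the alternative
area-of-1000 m² reading (side ≈ 19.6 m) is available via configuration.
Which endpoint the original speed filter dropped, the 10-minute bin
anchor, and the diurnal anchor-day convention are documented choices, each
configurable at a single site.
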
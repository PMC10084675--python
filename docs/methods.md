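# Methods

## The comparison being made

The analysis asks how similar the microbial-community shift behind a rock
surface alteration at one location is to the shift at a reference location,
in a paired design: at each location, replicate swabs from the alteration
("dark zone") and from an adjacent unmarked control surface, profiled at
genus level for three marker domains (bacterial 16S, archaeal 16S, fungal
ITS2), plus qPCR marker-gene copies per ng of total DNA as a community-size
proxy. The default design is 9 locations × 2 conditions × 6 replicates.

## Δlog and its conventions

All condition contrasts are expressed as

    Δlog = log10(m̄_dz + c) − log10(m̄_ctrl + c)

with `m̄` the arithmetic mean over a condition's replicates (of a genus's
reads, of total archaeal reads, or of qPCR copies/ng) and pseudocount
`c = 1` (one read, or one copy/ng). Positive Δlog means enrichment in the
dark zone. The pseudocount makes zero means well defined and guarantees
Δlog is exactly 0 when the means are equal; its price is a saturation
floor: a genus with control mean `m̄` can never show Δlog below
`−log10(m̄ + 1)`, however complete its disappearance. Genus means are taken
on rarefied counts for bacteria and fungi and raw counts for archaea.

Reference criteria are the genera with `|Δlog| > 1` (strictly) at the
reference location — the threshold is a parameter, default 1, i.e. a
ten-fold change — plus the archaeal-reads Δlog, one Bray–Curtis criterion
per rarefied domain, and one qPCR Δlog per domain. With both Bray–Curtis
criteria included the criterion count is always
`n_bacterial + n_fungal + 6`.

## Banded similarity scoring

A location's Δlog is compared with the reference through the relative
deviation `r = |Δlog_local − Δlog_ref| / |Δlog_ref|`, which is scale-free
across criteria. Scores fall in eleven levels:

    r ∈ [k/10, (k+1)/10)  →  score 1 − k/10   (k = 0 … 9)
    r ≥ 1                 →  score 0

Band edges are closed below (`r = 0.1` exactly scores 0.9). A local
variation of opposite sign to the reference is flagged and scores 0
regardless of magnitude; `Δlog_local = 0` is not opposite — it lands at
`r = 1` and scores 0. Bray–Curtis criteria band the differential
`d = (β − α)/α` identically, where α is the Bray–Curtis distance between
the two locations' control centroids and β between their dark-zone
centroids; `d < 0` (dark zones more mutually similar than the controls) is
flagged opposite. A centroid is the mean of the replicates'
relative-abundance vectors. When α = 0 with β = 0 (self-comparison on
identical data) the criterion scores 1; α = 0 with β > 0 leaves the
differential undefined and is an error.

Per-location totals sum positive scores only (flagged cells contribute 0).
Percent similarity is `100 × total / n_criteria`, rounded half-away-from-zero
to one decimal **from the unrounded total**; ranks order locations by
descending percent with alphabetical tie-break. Rounding the totals first
can shift the percent by a tenth, which is why the package never does it.

## Alpha diversity and correlation

Per-sample indices follow the conventions of the PAST package: Shannon H′
with natural log, evenness `e^H / S_obs` (not Pielou's `H / ln S`), Simpson
reported as `1 − D`, and the bias-corrected Chao-1
`S_obs + F1(F1 − 1) / (2(F2 + 1))`, defined even without doubletons.
Computation is delegated to scikit-bio; Bray–Curtis and Kendall's tie-
corrected τ-b to scipy, with an exact permutation p-value for n ≤ 8 untied
observations and the normal approximation otherwise.

## Table conditioning

Genera whose total count over all samples falls strictly below a fixed
fraction (default 0.005%) of the table's grand total are removed; a genus
exactly at the threshold is kept (the conservative reading). Samples are
then rarefied — multivariate-hypergeometric subsampling without
replacement — to fixed depths, default 13,467 (bacteria) and 12,753
(fungi). Each sample's draw is seeded from (global seed, sample id), so
adding or removing samples never changes other samples' draws, and results
are bit-identical across runs. Samples below the depth are dropped with a
warning (an error only if all fall below). The archaeal table is never
rarefied — its read numbers are too low and uneven — and the pipeline
enforces this by domain tag.

## Synthetic data generator

The generator emulates the processed genus tables of the paired design, not
raw reads. For each domain, control communities at each location are
compositional: genus weights `10^(baseline + location effect)` with
baseline spread (log10 sd 1.0, truncated at two decades) and per-genus ×
location heterogeneity (log10 sd 0.3), normalized to proportions.

Dark-zone communities apply planted condition effects directly on the
proportion scale: an effect genus with target Δlog10 `e` has its control
proportion multiplied by `10^e`; dark-zone-specific genera (hard zeros on
every control surface) receive a fixed target proportion (default 0.5% of
reads, with a per-location log10 wobble in the preset); the remaining
genera share the leftover mass proportionally. This makes the planted Δlog
values exact in expectation at the reference location, so parameter
recovery is a sharp test rather than an inference exercise. Planted mass is
capped — no effect genus above 30% of a community, summed planted mass at
most 85% — with any capping recorded in the truth record as the realized
effect. Counts are multinomial at fixed depth; a depth-inflation flag (10%
in the preset) emits deeper samples so the rarefaction step is exercised
for real. Archaeal totals are deterministic per condition and location
(dark zones depleted ten-fold by default), and qPCR copies/ng are
log-normal (log10 sd 0.15) around per-condition means. All randomness flows
from one master seed through named substreams (per domain, per sample).

The `make_reference_scenario` preset plants 27 bacterial and 14 fungal
effect genera with `|Δlog| > 1` (four well-sampled "anchor" genera per
domain for tight recovery, five reference-only effects that vanish
elsewhere, the rest minor), 12 cosmopolitan genera, 6 dark-zone-specific
genera at all locations and 6 single-location endemics, and perturbs each
effect per location with log10 sd 2.2.

What the generator does **not** emulate: taxonomy mis-assignment, chimeras
and contaminant OTUs, library-size variation beyond the inflation flag,
genus-genus correlation structure, and overdispersion beyond multinomial
sampling. Passing tests therefore demonstrate that the pipeline's
arithmetic and classification logic recover known structure under the
stated sampling model — not that the statistic is robust to real-data
artifacts.

A property of the Δlog statistic worth knowing when reading the preset's
output: strongly counter-selected criteria saturate at the detection floor
`−log10(m̄_ctrl + 1)` at every location, so two locations that both lose a
genus entirely look alike on that criterion no matter how different their
planted effects were. The preset's percent similarities consequently
concentrate around 40–60% rather than spreading arbitrarily low.

## Numerical choices and degenerate inputs

* Band membership uses a searchsorted over the exact decimal edges
  0.1 … 1.0 rather than `floor(10r)`, avoiding spurious boundary flips from
  the multiplication; scores are produced as exact decimals `(10 − k)/10`.
* Percent rounding goes through `decimal` with ROUND_HALF_UP on the repr of
  the float, not banker's rounding.
* A reference Δlog of exactly 0 makes a criterion ill-defined and is an
  error, as is Kendall τ on a constant vector, Bray–Curtis between two
  all-zero vectors, diversity of an empty sample, and a missing condition
  at a scored location.
* A genus named by a criterion but absent from a target table contributes
  zero counts (Δlog 0 → score 0), which is the correct behavior for a
  taxon never observed at that location.
* Classification presence is count ≥ 1 in the processed table ("not
  detected" read literally as zero reads); the threshold is exposed as a
  parameter. Classification averages over whatever replicates survived
  normalization.

## Design choices that were genuinely open

* **Δlog sign.** The implementation defines Δlog = log10(dark zone) −
  log10(control), so that enrichment in the alteration is positive; this
  matches the sign of every worked value the method is calibrated against.
* **Condition aggregation for Bray–Curtis.** Distances are computed between
  condition centroids (mean relative-abundance profiles), which makes the α
  and β of the differential single-valued per location pair; averaging
  pairwise replicate distances is the plausible alternative and the choice
  is recorded in the run manifest.
* **Tie handling in the low-abundance filter** (keep at exactly the
  threshold) and **strictness of the |Δlog| > 1 cutoff** (exclusive) are
  both the conservative readings.
* **Endemicity** is generalized to "present in all dark-zone replicates of
  a proper subset of locations", with the location set reported, rather
  than a single-location category.

## Problem sizes

The test suite and the acceptance script run the full scenario — 9 locations
× 2 conditions × 6 replicates at depths 13,467 / 12,753 / 500, 197 genera
across domains — plus two constructed comparison locations; a complete
pipeline pass takes a few seconds on one CPU, and the whole suite well
under a minute. Monte-Carlo checks (rarefaction expectation) use 1,000
draws on small columns.
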
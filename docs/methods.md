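# Methods

## The trait model

phenokit models phenology data as observations of *presence traits*:
directly observable qualities of a plant, each measured by the count or
percentage of one plant structure (true leaves, breaking leaf buds, open
flowers, ...). Phenological "stages" or "phases" are deliberately not
modeled — records stay close to what an observer can actually see, and any
stage definition a study needs can be expressed as a query over traits.

Structures form a graph with two edge kinds:

* **subclass** (`dormant leaf bud ⊑ leaf bud`): the child is a special
  case of the parent;
* **visible parthood** (`breaking leaf bud has-visible-part unfolding true
  leaf`): every instance of the whole shows at least one instance of the
  part.

For each trait the package derives two qualitative *convenience classes*,
"Xs present" and "Xs absent", and the subsumption edges between them:

| structure edge | present classes | absent classes |
| --- | --- | --- |
| child ⊑ parent | present(child) ⊑ present(parent) | absent(parent) ⊑ absent(child) |
| whole has-part part | present(whole) ⊑ present(part) | absent(part) ⊑ absent(whole) |

The absent hierarchy is the exact mirror of the present one (every edge
reversed, polarity flipped); the test suite asserts this duality on the
shipped catalog and on random graphs. Both rules apply only between traits
of the same *modality* (attached vs abscised). The spec'd subclass rule
requires this; we extend the restriction to parthood edges as well, since
an abscised-leaf count describes leaves no longer on the plant and must not
imply anything about attached structures. Parthood propagation is
toggleable (`derive_presence_classes(..., include_parthood=False)`) for
catalogs whose parthood links are decorative rather than existential.

The shipped default catalog is a 19-structure / 21-trait subset (leaf buds
and their dormant/swelling/breaking variants, true leaves and their
unfolding/unfolded/expanding/senescing variants, flowers, fruits, cones,
plus two abscised traits). It is a working subset, not a complete
vocabulary: real deployments are expected to supply their own catalog TSV.

## Inference from measurement ranges

A measurement is a range `[lower, upper]`, count or percent, so observer
uncertainty is first-class. Classification:

* count `lower ≥ 1`, or percent `lower > 0` → **present**;
* `upper = 0` → **absent**;
* `lower = 0 < upper` → **indeterminate**: no assertion at all.

Indeterminate ranges yield nothing (rather than a disjunction) because only
a strictly positive lower bound or a zero upper bound licenses a
conclusion. The percent threshold is "> 0", mirroring the count rule "one
or more". An unbounded count `[k, +∞)` (serialized as an empty upper
field) encodes "at least k", the natural reading of a status-network "yes"
with no intensity; percent ranges cannot be unbounded. Counts are kept as
exact integers — fractional count bounds are rejected, never coerced.

Materialization is eager: each observation's full superclass closure is
stored, so the exported table is self-contained and queries need no
reasoning at read time. Observations entailing nothing still appear (with
an empty class set). An observation whose duplicate measurements of one
trait classify both present and absent is flagged inconsistent, excluded
from harmonized output, and counted in the pipeline report — conflicting
sources are surfaced, not silently dropped.

## The harmonization pipeline

Stage 1 parses each dialect CSV, collecting unparseable rows as rejects
with line numbers (a bad row never aborts a run). Stage 2 maps
`(dialect, source code)` pairs to traits through a user-supplied mapping
table; the shipped default covers the simulator's vocabulary only, since
real network mappings are deployment-specific. Status semantics: "yes"
with intensity → that range; "yes" without → `[1, +∞)`; "no" → `[0, 0]`;
"unknown" → skip. Event records assert presence on the event date only —
no persistence to later dates is inferred, which is all the earliest-onset
analyses need. Agricultural codes map to an explicit skip rule. Stage 3
materializes inferred classes; stage 4 writes one row per observation with
a pipe-delimited sorted class list.

Invariants maintained on every run: input rows = harmonized + rejects +
skips + conflicts (conflicts are structurally zero when each source row is
its own observation), and output bytes are a pure function of input bytes
(rows ordered by source, then record id).

Subject identity follows the source: status `plant_id` and event
`plant_or_station_id` become subject ids unchanged, with ids prefixed
`station:` treated as populations. Whether two records without explicit
plant ids refer to the same plant is unknowable downstream, so the package
surfaces the id rather than guessing. Coordinates are carried through
unrounded; gridding happens only at analysis time.

## Onset analysis

* **Selection**: keep rows whose inferred classes contain a required class
  and not an excluded one (e.g. leaves present but not yet senescing);
  genus filter is case-insensitive exact.
* **Gridding**: coordinates round to one decimal degree, ties half away
  from zero (implemented via decimal arithmetic on the shortest float
  representation, so `0.05 → 0.1` and `−0.05 → −0.1`). The tie-break and
  quantile/median conventions below are package choices; they are
  documented here precisely because several equally defensible variants
  exist.
* **Earliest per cell-year**: one estimate per occupied (cell, year), the
  minimum day of year, ties broken by observation id. Applying the filter
  to its own output is the identity.
* **Decade filter**: decades are `floor(year/10)·10`; decades with fewer
  records than a caller-chosen threshold (1,000 for well-sampled genera,
  400 for sparser ones, in the analyses this package reproduces) are
  dropped entirely.
* **Summaries**: per-decade n, median day of year (midpoint convention for
  even n), and a Gaussian KDE with bandwidth
  `h = 0.9 · min(sd, IQR/1.34) · n^(−1/5)`, where sd is the n−1 sample
  standard deviation and the IQR uses linear-interpolation quantiles. If
  the IQR is zero but the data have spread, sd alone is used; fewer than
  two values or zero spread raise typed errors. The KDE grid spans the
  data range ±4h (512 points by default), which bounds the lost tail mass
  near 3×10⁻⁵ per side, so the trapezoidal integral is 1 within 10⁻³.
* Day of year is taken from the real calendar (Feb 29 exists); no leap
  adjustment is applied afterwards.

## The simulator

The generator emulates exactly the structure the analyses assume — and no
more. Each of `n_plants` plants gets a fixed uniform location; its onset
in each year is `Normal(a + b·lat, σ²)` rounded to whole days and clipped
to `[1, 366 − season_length]` (with defaults the window is >12σ wide, so
clipping and true truncation coincide). The structure stays visible for
`season_length` days. Defaults describe a weekly-visited deciduous-leafing
campaign: `a = 20`, `b = 2.5` d/° (onset ≈ day 120 at 40°N — a
Hopkins-style latitudinal gradient), `σ = 5` d, `season_length = 120` d,
`status_cadence = 7` d, 10 years × 200 plants, 5% agricultural
contamination in the event dialect only (where such records occur in real
networks).

Status visits fall on days 1, 1+cadence, ... of each year for every plant,
so the first "yes" lags true onset by up to one cadence — the recovery
tests assert the resulting median bias lies in `[0, cadence]`, while the
lossless event dialect recovers the true median to within 2 days.
Intensity ranges are deterministic `(k, k+10)` windows with k growing
through the season, exercising the range-inference path without adding a
second noise source.

What the simulator does *not* emulate — and therefore what passing tests
do not show about real data: between-year autocorrelation within plants,
climate drivers, spatial clustering of observers, taxonomic misnaming,
heterogeneous visit schedules, and observer error beyond visit cadence.
Results on simulated data validate the machinery, not ecological
conclusions.

Problem sizes in the shipped tests and the acceptance script (≈200 random
catalogs of ≤50 structures, ≈54,000 pipeline rows, 1,000 plant-years for
onset recovery, n = 5,000 for KDE accuracy) were chosen as the smallest
scales at which each property is comfortably away from its noise floor.

## Numerical and degenerate-input choices

* Closure order: breadth-first from the query class, lexicographic
  tie-break — reproducible serialization.
* Catalog loading is a pure function of file content; row order never
  matters, and duplicate ids, dangling references and subclass cycles are
  typed errors (or report entries, via `validate_catalog`, when collecting
  is preferred to raising).
* All randomness flows from explicit integer seeds; identical
  configuration yields byte-identical CSV and JSON artifacts (reports
  store paths relative to the output directory for this reason).

## Known limitations

* The propagation rules are exactly the two stated above; this is not a
  description-logic reasoner (no role chains, no disjunctions, no
  nominals), and it makes no attempt to reproduce a full OWL reasoner's
  behavior beyond them.
* Taxonomic name reconciliation is out of scope; genus/species strings are
  matched literally.
* Percent semantics differ between individuals (fraction of structures)
  and populations (fraction of member plants) but share one inference
  rule; downstream analyses must not mix the two interpretations blindly.
* The default mapping table is illustrative; real BBCH/phenophase
  mappings must be authored per deployment.
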
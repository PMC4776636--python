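# Methods

## Problem and model

The tool evaluates scalar dose/volume points on cumulative dose–volume
histograms (DVHs). A cumulative DVH for a structure is a non-increasing
curve V(d): the absolute volume (cc) receiving at least dose d (Gy),
sampled on a strictly increasing dose grid as exported by a DVH reviewer.
The model assumption throughout is that the exported curve is exactly
piecewise linear between grid points; every metric is then evaluated in
closed form on that piecewise-linear curve, with no smoothing or
resampling.

### Forward query: volume at dose

`V(d)` by linear interpolation on the grid. Below the grid start the whole
structure is covered (total volume, defined as the first cumulative-volume
entry); above the grid end the last exported volume is returned.

### Inverse query: dose at volume

`D(v) = sup{d : V(d) ≥ v}` — the largest dose still covering the requested
volume. The supremum convention decides flat segments: on a curve with
doses [0, 10, 20] Gy and volumes [50, 50, 0] cc, the dose covering 50 cc is
10 Gy, the *end* of the flat segment. This matches the "dose that covers"
reading of the metric and keeps the RTOG near-maximum well-defined when the
curve tail is flat. Consequences: `D(total_volume)` is the first grid dose
and `D(0)` the last. A query volume above the total volume returns 0 Gy
with an `out_of_range` flag rather than raising, so a single bad request
line cannot abort a cohort batch; the flag surfaces in the report
annotations.

### Mean dose

`Dmean = ∫ V(d) dd / V(0)` by the trapezoid rule on the grid — exact under
the piecewise-linear assumption and equal to the mean of the implied
differential DVH (the tests verify this equivalence against an independent
differential-route computation). The differential-DVH route is deliberately
not used in the implementation.

### RTOG near-extremes

`Dmax = D(0.03 cc)` and `Dmin = D(total_volume − 0.03 cc)`: the
near-maximum and near-minimum are read 0.03 cc in from the ends of the
volume, avoiding single-voxel extremes. `Dmax` is implemented as *the same
call* as `D(Gy)0.03(cc)`, so the identity holds bitwise. Structures smaller
than 0.03 cc raise a degenerate-structure error.

### Truncated exports

Some exports stop before the curve reaches zero volume. The curve is
treated as dropping to zero immediately after the last grid dose; any
result that touches the region beyond the export carries a
`structure_truncated` flag.

## Expression language

The grammar (see the package README for the full roster) admits exactly the
eight D/V unit pairings — D outputs Gy or %, with a volume argument in cc
or %; V outputs cc or %, with a dose argument in Gy or % — plus the three
named metrics Dmax, Dmin, Dmean. Keywords and metric names are
case-sensitive to keep the language unambiguous; a lenient mode is
deliberately not provided. Numbers are positive decimals without scientific
notation. The `/Rx` suffix (optionally `× 100`) is accepted after any
metric whose value is an absolute dose in Gy — `D(Gy)…`, `Dmax`, `Dmin`,
`Dmean` — and rejected after volumes and percent doses, where it would
double-normalize. `×`, `x`, `X` and `*` are interchangeable multiplication
signs so request files can stay ASCII. Parsing and formatting are exact
inverses: `parse(format(p)) == p` for every valid AST, and `format ∘ parse`
canonicalizes whitespace idempotently.

## Reference doses

Percent-dose units need a 100% reference. Two modes exist:

* **prescription** — a global prescription dose may be set for the run; a
  per-case value stored in the DVH file header (cell C1) overrides it.
* **maximum** — the per-plan maximum dose from the file header (cell D1),
  required per case because plans do not share a maximum dose.

`/Rx` always divides by the *prescription* dose, even under reference mode
"maximum": the ratio is defined against the prescription, and the reference
mode governs only percent-dose unit conversions. A case whose needed
reference cannot be resolved still has all its reference-free points
computed; only the dependent cells are marked `evaluation_error`.

## Batch semantics

The batch loop runs cases outer, request rows inner, points innermost,
resolving the reference dose once per case. Errors are data at this level:
every (case, structure, point) triple yields exactly one cell, holding
either a value or an absence with its reason (`structure_missing` or
`evaluation_error` with detail), so a QA batch always completes. Structure
matching is exact after whitespace trimming, with a case-insensitive
fallback that attaches a naming-deviation warning (structure names are
expected to follow the trial network's naming convention; the fallback
catches capitalization slips without hiding them). Request files use an
invented but documented plain-text format, `Name: expr1, expr2, ...`, with
`#` comments; colons delimit names so names may contain spaces but not `:`
or `,`. Per-arm processing of a protocol is achieved by running the tool
once per arm with its own request file — no arm logic lives in the tool.

## Cohort statistics and report

For each (structure, expression) column the report computes the 1, 2, 5,
10, 15, 85, 90, 95, 98 and 99% quantiles — the tails relevant for judging
plan-quality spread — plus the count of contributing cases. The quantile is
the linear order-statistic interpolation: on sorted values with 1-based
ranks, h = (n−1)·p/100 + 1 and Q = x⌊h⌋ + (h−⌊h⌋)(x⌊h⌋+1 − x⌊h⌋). The
formula is stated (rather than delegated) so any implementation reproduces
it bit-for-bit; it coincides with the common "linear" convention, and the
tests cross-check it against numpy's independent implementation. Absent
cells are excluded from the statistics and counted — imputation would
fabricate plan quality.

The report mirrors a three-region spreadsheet layout: the request echoed at
the top, values case-per-row, statistics at the bottom, with one sheet per
requested structure plus an overview of all columns. CSV output renders
numbers with 2 decimals ('.' decimal separator, no thousands separators)
for locale-independent diffability, with optional full-precision sidecar
files; CSV regeneration from the same result table is byte-identical. XLSX
output puts one worksheet per sheet in a single workbook. Absence reasons
and naming warnings appear in a trailing annotations column of each row.

## Synthetic data

The generator emulates the DVH CSV export exactly (header variants
included) from three analytic profiles with known metrics:

* **uniform(d₀)** — whole structure at one dose; the step is realised as a
  symmetric ramp of half-width 1e-6 Gy so the trapezoidal mean is exactly
  d₀ and near-max/min sit within 2e-6 Gy of d₀;
* **linear(D₀)** — V(d) = V₀(1 − d/D₀)₊ with D₀ inserted into the grid, so
  all metrics have exact closed forms (Dmean = D₀/2, etc.);
* **sigmoid(d₅₀, slope)** — a logistic fall-off resembling a realistic
  target-coverage curve; its truths come from an independent 10⁵-point
  dense-grid numeric oracle and are grid-resolution-limited (≈1e-3
  relative at the default 0.1 Gy step).

Cohorts multiply each structure's volume and dose-scale parameter by
independent lognormal factors (median-preserving, positive by
construction) with a stated sigma, fully deterministic per seed. Default
grid: 0.1 Gy steps to 1.2 × the largest profile dose. Defaults used in the
acceptance rehearsal: 20 cases, 6 structures / 14 points in a
lung-protocol-scale request, 7% jitter, 60 Gy prescription — a realistic
mid-size trial-QA workload that runs in seconds.

What the synthetic cohorts do **not** emulate: anatomically realistic
per-organ DVH shapes, correlated doses between organs, dose-calculation
noise, or export quirks beyond the documented dialect. Passing tests
therefore demonstrate correctness of parsing, interpolation, batch and
statistics logic on well-formed exports — not robustness to every
real-world vendor file.

## Numerical choices and limitations

* Doses are taken as Gy; cGy grids are not auto-detected (documented
  limitation — a cGy file would simply yield values 100× off).
* Differential DVHs are out of scope; so are DICOM-RT parsing, computing
  DVHs from dose grids, biological indices (gEUD/NTCP/TCP), and encoding
  protocol pass/fail limits — the tool extracts and tabulates, adjudication
  stays with the reviewer.
* CSV dialect: RFC 4180, UTF-8 with BOM tolerated, '.' decimal regardless
  of locale; trailing empty rows/columns stripped; the cell above the dose
  column may hold any label and is ignored.
* File round-trips preserve 10 significant digits (≤ 1e-9 relative).
* Oracle tolerances in the tests: 1e-9 relative for interpolation queries
  against a knot-refined dense grid, 1e-6 for the acceptance rehearsal,
  1e-3 for sigmoid truths (grid-resolution-limited).
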
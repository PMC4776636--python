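# dvhpoints

Batch extraction of dose/volume-point statistics from cumulative dose–volume
histogram (DVH) exports, for radiotherapy clinical-trial plan-quality review.

Dosimetry compliance review — checking that a submitted treatment plan's
dose/volume points satisfy the limits stated in a trial protocol — typically
means reading 10–20 points per case off DVH curves for each of dozens to
hundreds of enrolled patients. `dvhpoints` automates that: it parses a
standard expression syntax for dose/volume points, evaluates the points
against cumulative DVHs exported as CSV, and tabulates per-structure reports
with cohort quantile statistics, so reviewers and protocol developers can see
the distribution of plan quality across enrolling institutions at a glance.

## The metrics

A cumulative DVH gives, for each structure, the absolute volume V(d) in cc
receiving at least dose d in Gy. Points are written in a compact
case-sensitive syntax:

| Expression | Meaning |
|---|---|
| `D(Gy)40(cc)` | dose in Gy covering 40 cc of the structure |
| `D(Gy)40(%)` | dose in Gy covering 40% of the structure |
| `D(%)40(cc)` | dose as % of the reference dose covering 40 cc |
| `D(%)40(%)` | dose as % of the reference dose covering 40% of the structure |
| `V(cc)40(Gy)` | volume in cc receiving ≥ 40 Gy |
| `V(cc)40(%)` | volume in cc receiving ≥ 40% of the reference dose |
| `V(%)40(Gy)` | volume as % of the structure receiving ≥ 40 Gy |
| `V(%)40(%)` | volume % receiving ≥ 40% of the reference dose |
| `Dmax` | RTOG near-maximum dose: identical to `D(Gy)0.03(cc)` |
| `Dmin` | RTOG near-minimum dose: dose at total volume − 0.03 cc |
| `Dmean` | mean structure dose (trapezoidal integral of V(d) / V(0)) |
| `Dmean/Rx` | mean dose divided by the prescription dose |
| `Dmean/Rx × 100` | the same ratio in percent |

`/Rx` (optionally `× 100`; `x`, `X` and `*` are accepted spellings) may
follow any metric whose value is an absolute dose — e.g. `D(Gy)1(%)/Rx` and
`D(Gy)0.03(cc)` are alternative near-maximum formats that can be tabulated
side by side. The reference dose for percent-dose units is either a
prescription dose (a global run setting, overridden per case by a value in
the DVH file header) or the per-plan maximum dose (always per case). All
queries interpolate the exported curve linearly; the inverse query takes the
largest dose still covering the requested volume on flat segments.

## DVH CSV dialect

Row 1: patient/site ID, with optional per-case prescription dose in the
third cell (`Rx = 60 Gy` or just `60`) and per-case maximum dose in the
fourth (`Dmax = 80 Gy` or `80`). Row 2: structure names. Rows 3+: the dose
column in Gy followed by one absolute-volume column (cc) per structure.

## Worked example

Generate a 5-case synthetic cohort, check a review request, and run it:

```sh
dvhpoints gen --spec spec.yaml --n 5 --seed 11 --out dvh/
dvhpoints validate --request request.txt
dvhpoints run --request request.txt --dvh-dir dvh/ --out report/ --rx 60
```

with `request.txt`:

```text
PTV: D(%)95(%), Dmax, Dmean/Rx × 100
Lungs: V(%)20(Gy), Dmean
```

prints `5 cases x 5 points: 25/25 cells evaluated -> report/` and writes
`report/PTV.csv`, `report/Lungs.csv` and `report/overview.csv`. The overview
echoes the request, lists one row per case, and ends with the statistics
block (the 1, 2, 5, 10, 15, 85, 90, 95, 98 and 99% quantiles of every
column, plus the count of contributing cases):

```text
case,PTV | D(%)95(%),PTV | Dmax,PTV | Dmean/Rx × 100,Lungs | V(%)20(Gy),Lungs | Dmean,annotations
SYN-001,110.20,86.39,118.38,69.05,32.31,
SYN-002,89.85,74.12,98.02,70.42,33.81,
...
quantile,,,,,
1%,78.21,67.30,86.39,69.10,32.36
...
99%,109.55,86.00,117.73,72.51,36.38
n,5,5,5,5,5
```

Reading `SYN-001`: 95% of the PTV is covered by 110.2% of the 60 Gy
prescription, its near-maximum dose is 86.4 Gy, the mean PTV dose is 118.4%
of the prescription, 69.1% of the lungs receive ≥ 20 Gy, and the mean lung
dose is 32.3 Gy. The tail quantiles at the bottom show the spread of those
points across the cohort — the numbers a protocol developer looks at when
deciding whether a dose limit needs amending. Cases that lack a requested
structure are excluded from the statistics, counted in `n`, and flagged in
the annotations column.

The same works from Python:

```python
from pathlib import Path
from dvhpoints import (read_dvh_file, load_request, run_batch,
                       RunSettings, build_report, write_report)

cases = [read_dvh_file(p) for p in sorted(Path("dvh").glob("SYN-*.csv"))]
table = run_batch(cases, load_request("request.txt"),
                  RunSettings("prescription", global_rx_dose=60.0))
write_report(build_report(table, load_request("request.txt")), "report")
```

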
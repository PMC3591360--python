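# Methods

## The screening model

The package analyses plate-based screens of stimulated B-cell/PBMC
co-cultures in which each agent is run at 4 or more doses with a single
well per readout per concentration. Because there are no per-dose
replicates, no per-dose variance exists; statistical context comes from
two plate-external sources instead: fixed log10-ratio thresholds for
calling, and an empirical significance envelope estimated from
accumulated historical control wells. Reports convey significance only
through that envelope band, mirroring the assay's presentation
conventions.

### Ratios

Every measurement is normalised per plate as
`L(d, r) = log10(x_treated / mean x_control_stim)`. The denominator is
the arithmetic mean of the plate's control stimulated wells ("average
values"); a geometric-mean alternative is available as
`profile_agent(..., control_stat="geometric")` for users who prefer
averaging multiplicative quantities on the log scale. The viability
readout is ratioed against the same stimulated-no-drug baseline as every
other readout. Raw zeros (below detection) are floored at half the
smallest positive value of that readout on the plate before the log is
taken, and flagged; this keeps profiles finite without pretending the
measurement was informative. Missing readouts stay missing (NaN cells)
and propagate as "no call" — nothing is imputed.

### Envelope

The 95% band per readout is the empirical ((1−c)/2, 1−(1−c)/2) quantile
pair of the archived null ratios, with numpy's default linear (type-7)
interpolation. An empirical construction was chosen over a parametric
normal band because it is assumption-free and monotone in the coverage
parameter by construction; a minimum archive size (default 50 per
readout) guards against bands estimated from too little history. This
construction is this package's own; prediction-envelope procedures in
the literature differ in detail and no claim of equivalence is made.

### Gating and calling

A dose is excluded when its viability log10 ratio is strictly below
−0.2 (a decrease greater than 0.2 log units); exactly −0.2 is kept. A
dose whose viability measurement is missing cannot be cleared and is
excluded the same way. Exclusion applies to all readouts at that dose.

Calling uses strict inequalities at −0.2 (inhibition) and +0.15
(stimulation), each requiring ≥ 2 non-cytotoxic active doses. The
asymmetry of the thresholds is deliberate and matches the tabulated
rules of the assay format this package implements. For a non-monotone
agent satisfying both patterns on one readout, the pattern with more
active doses wins and an exact tie is reported as none with a warning;
this majority rule is an artifact decision (the underlying rules do not
define the case) and is flagged in output rather than silently applied.

### Selectivity

"X over Y" selectivity is operationalised as an explicit cut-point
search over the sorted dose series: there must exist a cut with ≥ 2
doses below it active for one cytokine alone and ≥ 2 doses above it
active for both. This formalises "selective at 2 or more relatively low
doses, both at 2 or more higher doses" as *all* solo-selective doses
sitting strictly below all dual-active doses at some cut. Agents with
opposing directions on IL-17A and IL-17F (PGE2-like) get category
`none` with `divergent=True` and stand as two independent hit calls.
Single-cytokine hits are `A_only`/`F_only`.

Class aggregation counts an agent as active when it has any IL-17A or
IL-17F hit; a class is included only above a strict 50% majority, and
the modal selectivity of the active agents breaks ties toward the most
inclusive category (`A_and_F` first). Totals are computed over the
agents actually present in the supplied calls; class-map entries for
unscreened agents are ignored.

Whether the original analysis gated hits on the envelope or on the
fixed thresholds is not fully determinable; this package exposes both
(the envelope via reports and `Envelope.contains`, the thresholds via
`Thresholds`) and defaults to the fixed thresholds for calling.

## Expression statistics

Fold change is stimulated mean over control mean, full precision
internally and rounded to 2 decimals only at the reporting layer. The
paired t is the classical statistic (mean difference over its standard
error, df = n−1, two-sided p, reported as |t|), implemented directly so
the zero-variance degenerate case can return an explicit sentinel
(t = +inf, p = 0, with a warning; identical rows give t = 0, p = 1);
it is cross-checked against an independent library implementation in
the tests. FDR adjustment is Benjamini–Hochberg step-up (the upstream
software behind published FDR columns is not specified, so the standard
procedure is adopted and documented; printed FDR columns are therefore
not reproduction targets). The qRT-PCR path computes per pool
2^−(Ct_gene − Ct_ref) per condition, takes the stim/ctrl ratio, and
summarises mean ± sd (ddof = 1) across pools; it is invariant to
condition-wide Ct shifts by construction.

Reproduction of printed worked examples is limited by input rounding:
fold-change columns recompute exactly from printed means for most rows,
but where the printed 1-decimal means round differently from the
unpublished full-precision data a 0.01 discrepancy at the second
decimal can remain, and the acceptance checks keep such rows faithful
rather than loosened.

## Synthetic-data generator

The generator emulates the study conditions, not arbitrary data:

* **Plates** carry ≥ 2 control stimulated wells, ≥ 6 DMSO non-stimulated
  wells (the assay's stated 6–12 range), one colchicine control
  stimulation well at 1.11 µM, and one well per (agent, dose). Well
  values are `baseline × planted multiplier × 10^N(0, sd)`.
* **Baselines** use the measured stimulated supernatant levels where
  reported — IL-17A 261 pg/ml, IL-17F 1549 pg/ml — with the remaining
  panel members set to plausible stimulated levels (IgG 1800 ng/ml,
  IL-2 310, IL-6 2400, TNFα 920 pg/ml, AlamarBlue absorbance ~1 AU).
  Default log10 sds are calibrated so control CVs match the reported
  mean ± sd pairs (73/261 for IL-17A, 206/1549 for IL-17F); this is a
  calibration choice, not a claim about assay error structure.
* **DMSO wells** sit one stimulation window (default 1.0 log10, i.e.
  10×) below baseline.
* **Truth patterns** cycle through the seven qualitative behaviours the
  screen observed: dual inhibitor, IL-17A-selective dose-stratified
  (active on A at all doses, on F at the top two), IL-17F-selective,
  dual stimulator, divergent (A up / F down), cytotoxic-at-top-dose,
  and null. Ground truth is serialised beside the plate so tests never
  re-derive it.
* **Historical archives** draw null log10 ratios directly from the
  per-readout noise model; **paired expression** draws control values
  lognormally around per-gene baselines and multiplies the same pool's
  control value by the planted fold (pairing preserved).

What the generator does **not** emulate: donor-to-donor biology,
between-plate batch effects, correlated readouts, heteroscedastic
assay error, plate-position effects, or the actual 144-agent compound
set. Passing recovery tests therefore demonstrates correctness of the
analysis rules under the stated noise model, not performance on real
plates.

## Problem sizes and numerical choices

The recovery experiment uses 200 agents × 4 doses on one plate with 4
control stimulated wells (a realistic positive-control complement that
keeps the control-mean noise at sd/√4), planted effect |log10| = 0.5
and uniform noise sd 0.05; envelope coverage uses a 10,000-value
archive against 10,000 fresh null draws; null-p uniformity uses 2,000
genes at 3 pools. Null p-value uniformity is assessed on the log10
scale, where the generator's paired differences are exactly normal and
the t reference distribution is exact; on raw lognormal values at
n = 3 pools it would only be approximate. Plate and archive round-trip
I/O serialises floats via `repr` and parses with round-trip precision,
so raw values survive bit-exactly.

## Known limitations

* Potency (EC50/IC50) estimation is out of scope by design — the
  calling rules are threshold-based, not curve-fit-based.
* Dose units are opaque strings; nothing converts between µM, nM,
  ng/ml or U/ml, and doses are only ever compared within one agent's
  series.
* Plate geometry (row/column positions) is not modelled; the schema has
  no physical-layout concept.
* The behaviour of an agent that inhibits at low doses and stimulates
  at high doses on the *same* readout is resolved by the majority rule
  described above; users with such agents should inspect the warning
  and the per-dose calls rather than the summary direction alone.
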
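# Methods

## Scoring model

Each specimen's percent of immunopositive tumor cells (per marker, read
in five random ×400 fields) is averaged arithmetically and binned onto
an 11-point decile scale. The published scale is stated over integer
percent ranges ("1–10 %" → 10, "11–20 %" → 20, …), which leaves
fractional five-field averages (e.g. 35.2 %) formally unassigned. We
read the bins as half-open intervals: score = 0 iff pct = 0, otherwise
10·⌈pct/10⌉. This is the only reading consistent with both "no
staining → 0" and "1–10 % → 10", it is monotone, idempotent on decile
inputs, and assigns every value in [0, 100].

Marker staining compartments (nuclear for p53/p16/p27, membrane for
c-erbB2) are validated as metadata; no computation depends on them.

## D-value model and decision rule

For a lesion pair, per-marker D-values are absolute decile-score
differences and the total is their unweighted four-marker sum, in
{0, 10, …, 400}. The source formula writes the differences as
"T1 − T2" without absolute-value bars; we read them as absolute
differences because every published control D-value is non-negative and
the total is otherwise unbounded below. The sum is therefore symmetric
in the two lesions and satisfies a per-marker triangle inequality (both
property-tested).

The decision rule calls a pair metastatic when the total **does not
exceed** 90 and MPLC when it does. The boundary convention matters:
the calibration data contain a known-metastasis pair with total exactly
90, which fixes "≤ 90 → metastatic" as the default; the alternative
strict rule (`lt_is_metastatic`) is available as a configuration
option, as is the threshold itself. Because totals are multiples of 10,
the smallest total called MPLC under the defaults is 100 — verified by
exhaustive enumeration of all 11⁴ per-marker combinations rather than
by formula.

Patients with three lesions are handled as (primary, other) pairs with
one report per pair; no patient-level call is synthesized from
conflicting pairwise calls, since no aggregation rule was ever
published.

## Packaged control data

Three published tables are compiled in verbatim: the 30
lymph-node-metastasis control pairs (the negative-control group), the
2×2 reclassification counts against the Martini–Melamed diagnosis
(29/6/7/14 over 56 patients), and the five cohort group sizes
(20/11/30/36/14). One control row is internally inconsistent: case 13's
printed total (30) disagrees with the sum of its printed per-marker
values (50). Both numbers are stored verbatim; `validate_totals`
reports the discrepancy, and all downstream statistics use recomputed
sums. Printed percentages (e.g. the two inconsistent figures quoted for
the same 29/36 fraction) are never stored — fractions are always
recomputed from counts.

The raw per-specimen scores behind the control table were never
published, so the CSV export of the controls uses a score-preserving
embedding (primary lesion carries the D-value, the paired lesion
carries 0); it reproduces every per-marker and total D-value exactly
when pushed through the scoring pipeline, but the individual specimen
scores are synthetic.

Per-case D-values for the distant-metastasis group, the
different-histology MPLC group and the two reclassified cohorts were
shown only graphically in the source; they are not transcribed. Only
their printed ranges (10–60, 100–220) and counts enter tests.

## Agreement statistics

`agreement` computes percent agreement, per-clinical-group concordant
fractions, and Cohen's κ = (p₀ − p_e)/(1 − p_e) on the 2×2 table.
Percent agreement and κ are standard derived summaries added by this
package — the source reports only raw counts and per-group fractions —
and are labeled as such. A degenerate table with p_e = 1 is assigned
κ = 1 under perfect agreement and 0 otherwise; the implementation is
cross-checked against scikit-learn's independent κ on random tables.

`threshold_sweep` evaluates the rule over thresholds 0–400 in steps of
10 (intermediate thresholds are redundant because all achievable totals
are multiples of 10), with "metastatic" as the positive class:
sensitivity = fraction of known-metastatic control pairs called
metastatic, specificity = fraction of known-independent pairs called
MPLC. Both curves are monotone in the threshold by construction.

## Synthetic pair generator

The generator emulates the two mechanisms the model presupposes.
Per-marker percent positivity follows a zero-inflated Beta law: fully
negative with probability `zero_inflation`, otherwise
100·Beta(α, β). **Clonal** (metastasis-like) pairs share one draw; the
second lesion adds Gaussian drift N(0, drift_sd) on the percent scale,
clipped to [0, 100]. **Independent** (MPLC-like) pairs draw the two
lesions separately. Drift is Gaussian rather than a correlated-Beta
construction because only the binned decile scale feeds the model and
the simpler noise law is transparent.

Defaults (units: zero-inflation is a probability, drift_sd is percent):

| parameter | default | rationale |
|---|---|---|
| p53 zero-inflation | 0.50 | p53 positive in ~50 % of NSCLC |
| p16 zero-inflation | 0.50 | p16 inactivated in roughly half |
| p27 zero-inflation | 0.75 | p27 expression retained in only ~20–30 % |
| c-erbB2 zero-inflation | 0.63 | overexpressed in ~37 % |
| positive part | Beta(0.8, 0.8) | dispersed, U-shaped staining fractions |
| drift_sd | 5.0 | modest within-clone drift, below one bin width |

These are loose translations of reported marker prevalences, not a fit:
the raw per-specimen scores behind the published cohorts are
unavailable, so the generator is a test harness whose defaults cannot
be validated against real staining data. It also omits features of real
IHC: inter-observer variation, within-specimen field heterogeneity
(each synthetic specimen's five fields are identical), marker–marker
correlation, and histology effects. Passing the synthetic-recovery
tests therefore shows the pipeline is internally coherent and that the
rule separates the two generative mechanisms at the stated parameters —
not that the threshold is clinically optimal.

A single integer seed drives one `numpy.random.Generator`; repeated
runs produce byte-identical cohort tables.

## Problem sizes and numerical choices

Boundary properties are established by exhaustive enumeration (11⁴ =
14 641 combinations). Monte-Carlo property tests use 200–300 pairs per
condition with pinned seeds; label-recovery is tested on 200 pairs
(100 clonal / 100 independent, drift 5 %, dispersed Beta(0.5, 0.5)
positivity) with a one-sided binomial test against chance at p < 0.01.
All statistics are exact integer/rational arithmetic except the
agreement ratios and κ, which are plain floating point; no tolerance
tighter than 10⁻¹² is asserted anywhere.

## Known limitations

- The model is pairwise only; multi-lesion patients get per-pair calls.
- The decile scale discards within-bin information by design.
- The packaged reclassification table fixes model calls at threshold
  90; counterfactual thresholds cannot be evaluated on the real
  reclassified cohorts because their per-case D-values were never
  published, only on controls and synthetic data.
- Reader-disagreement reconciliation is not modeled; the pipeline takes
  a single percent stream per specimen.
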
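# Methods

This note documents the models, parameters and design choices behind
`claimsbmi`: what the pipeline computes, what the synthetic data does and
does not emulate, and where the genuinely open decisions were made.

## Code dictionaries and BMI scales

The granular dictionaries are the adult BMI range codes of both eras:
ICD-9-CM `V85.0`, `V85.1`, `V85.21–25`, `V85.30–39`, `V85.41–45` and
ICD-10-CM `Z68.1`, `Z68.20–45`, each mapped to one of ten ordered levels
(≤19.9, 20.0–24.9, 25.0–29.9, 30.0–34.9, 35.0–39.9, 40.0–44.9,
45.0–49.9, 50.0–59.9, 60.0–69.9, ≥70.0 kg/m²). Category intervals are
half-open `[lower, upper)`, so "30.0–34.9" means 30.0 ≤ BMI < 35.0 and a
measured 34.95 falls in it; this removes the gap between printed labels
(34.9 vs 35.0). The nonspecific set is the six obesity-status pairs
`278.00`/`E66.9`, `278.01`/`E66.01`, `278.03`/`E66.2`, `E66.09`, `E66.1`
and `E66.8`; whether additional codes (e.g. `278.02`) belong there is a
judgement call, so the dictionary ships as a plain-text TSV users can
audit and extend. Pediatric percentile codes (`V85.5x`/`Z68.5x`) are out
of scope. Codes are accepted dotted or dotless, case-insensitive, since
both dialects occur in claims extracts.

Coarsening merges the ten levels into five (≤29.9, 30.0–39.9, 40.0–49.9,
50.0–59.9, ≥60.0) or four (underweight/normal/overweight/obese ≥30.0);
both are order-preserving partitions whose coarse bounds are the min/max
of the merged fine bounds.

## Temporal design

All windows are fixed-day, not calendar-month: "6 months" = 182 days,
"1 year" = 365 days. The preoperative window `[index − 182 d, index]`
includes the index day (stated explicitly only for the tier-2 definition
in the source design; applied uniformly here); the postoperative window
`(index, index + 365 d]` excludes it. The proximity restriction is
±30 days, inclusive. Ties are resolved deterministically: among same-day
weight codes, granular beats nonspecific and then the higher category
wins (up-coding practice suggests the higher code drives authorization);
among equidistant measurements, the earlier one wins. The proximate
measurement for tiers 2 and 3 must lie *inside* the corresponding window
**and** within the proximity bound — both constraints, applied to both
tiers for symmetry.

Tier-1 exclusions, in fixed order (each excluded patient carries the
first reason that applied): conflicting same-day bariatric procedure
codes; age < 18; lack of continuous enrollment over the preoperative
window (administrative gap allowance 0 days by default, configurable);
any bariatric/revisional operation in the 182 days before index; GI
malignancy diagnosis in the lookback (prefixes 150–159 / C15–C26); an
emergency-department encounter on the index day; a GI ulcer diagnosis on
the index day (531–534 / K25–K28). Real CPT-4/HCPCS procedure lists are
licensed, so the schema carries an explicit operation-type column
instead; a code-list hook would slot in for real data.

## Reference-standard asymmetry

Preoperative comparisons pair the last available code with its most
proximate measurement; postoperative comparisons pair the last available
code with the *last available* in-window measurement. This asymmetry is
part of the validation design being implemented, and it matters: after
surgery BMI falls ~15–30% over the first year, so the last measurement
can post-date the last code by weeks and sit one category lower. This is
the main reason default-configuration postoperative kappas (~0.65) run
below preoperative ones (~0.85) even though the coding kernel is
identical in both windows — a genuine property of the last-available
outcome definition under weight loss, not a bug.

With the expanded (nonspecific-included) algorithm, a nonspecific last
code is assignable only under the four-level scheme (obese ≥30.0); under
the 10- and 5-level schemes there is no principled level assignment, so
the patient is flagged `nonspecific_last_code` and drops out of that
comparison with an auditable denominator.

EHR values outside 10–120 kg/m² are flagged non-physiologic and excluded
from comparisons. Patients with no reference data never enter validation
denominators (they cannot reach tiers 2/3); they are never counted as
negatives.

## Synthetic world

Per patient: one index operation (AGB/RYGB/SG, default mix
0.100/0.322/0.578), an index date uniform over 2011-01-01..2018-06-30,
baseline BMI log-normal matched to mean 46.1, SD 9.0 kg/m² — the
preoperative distribution of a large US bariatric cohort — and a linear
postoperative trajectory reaching `(1 − L)·baseline` at day 365 (plateau
after), with per-patient loss fraction L ~ Normal(mean by operation:
AGB 0.15, RYGB 0.30, SG 0.25; SD 0.05) clipped to [0, 0.6]; these are
typical one-year total-weight-loss figures by operation. Encounters
arrive at Poisson rates (preop 1.0, postop 0.7 per 30 days) on distinct
days, plus the index day.

The coding process is the contribution-bearing part. At each encounter a
weight code is emitted with a per-window probability; if granular, its
category is drawn from a row-stochastic 10×10 **fidelity kernel** applied
to the true category (default: 0.85 on-diagonal, remainder split over
adjacent categories), except that a true 30.0–34.9 preoperative
encounter is up-coded to 35.0–39.9 with probability `upcode_at_35`
(default 0.60, chosen from the observed pattern that ~70% of
preoperative patients measured 30.0–34.9 carry a code indicating ≥35 —
insurance-threshold up-coding; 0.60 direct plus the kernel's adjacent
mass lands near that). Nonspecific emissions use the morbid-obesity pair
when true BMI ≥ 35 and the unspecified-obesity pair otherwise. The code
string is era-appropriate (ICD-9-CM before 2015-10-01, ICD-10-CM after).
Per-encounter emission defaults (`p_any_code` 0.53/0.185,
`p_granular_given_code` 0.70/0.38 for preop/postop) were derived once by
inverting the Poisson-encounter presence formula so that *window-level*
availability lands at the canonical bariatric pattern — roughly
93/5/2% granular/nonspecific-only/none preoperatively and 45/34/21%
postoperatively.

EHR linkage covers 15% of patients by default; a linked patient's
encounter records a BMI vital with probability 0.70 (so the proximity
restriction actually binds) with Gaussian measurement noise (SD
0.5 kg/m²). Determinism: one master seed; per-patient substreams are
spawned from it, so increasing `n_patients` leaves earlier patients
bit-identical.

What the generator does **not** emulate: comorbidity structure and its
correlation with postoperative coding (the differential-coding concern in
real data), preoperative supervised weight loss, enrollment churn
(everyone is continuously enrolled unless a fixture says otherwise),
care-seeking intensity varying with BMI, and calendar trends in coding
quality. Passing tests therefore demonstrate that the *pipeline* is
correct under a known coding process — not that real claims achieve any
particular accuracy.

## Analytic oracle

`expected_agreement_matrix(config, window)` returns the exact joint
distribution of (coded category, measured category) at a random
encounter, conditional on a granular code and a measurement being
present: a deterministic quantile-grid integration over baseline BMI
(100,000 nodes preoperatively; 1,000 × 16 × 24 nodes over baseline ×
loss × time, per operation type, postoperatively), composed with the
kernel, up-coding and the Gaussian noise CDF. Cells are resolved to about
1/nodes, i.e. ~1e-5 preoperatively. For the preoperative window this
per-encounter joint equals the per-*pair* (last code vs proximate
measurement) distribution exactly, because the preoperative trajectory is
flat and all coding/measurement draws are i.i.d. across encounters —
which is why the kappa-recovery check (empirical kappa at n = 50,000
versus the kappa implied by the matrix, within 3 Monte-Carlo SEs over
5 replicate seeds) is run preoperatively.

## Metrics

Weighted kappa is computed from the k×k observed table with linear
(Cicchetti–Allison) weights by default — the common default for ordinal
scales, with quadratic (Fleiss–Cohen) selectable; for k = 2 both reduce
to unweighted Cohen's kappa. The asymptotic variance is the
Fleiss–Cohen–Everitt large-sample form (clamped at zero; it can go
negative on near-perfect tables), with a normal interval truncated to
[−1, 1]; a seeded multinomial bootstrap percentile interval is the
cross-check, and samples under N = 30 carry a warning flag.
Interpretation bands are the conventional 0.40/0.75 cutpoints. Zero
marginals keep their rows/columns (k is scheme-fixed); undefined metrics
are flagged, never reported as 0 or 1.

Small-cell suppression is reporting-only: counts ≤ 10 become a mask, and
a percentage whose numerator (complement) is masked is shown as an upper
(lower) one-sided bound computed by substituting the threshold for the
hidden count — e.g. TP = 90 with FN ≤ 10 reports sensitivity as ">90".

## Problem sizes

Default runs use 20,000 patients (availability, validation, acceptance
reporting); the perfect-coder identity checks use 5,000–10,000; the
kappa-recovery experiment uses 5 replicates of 50,000; property suites
use 1,000 random tables. These sizes put Monte-Carlo noise well inside
the tolerances being asserted while keeping any single run in the
minutes range on one CPU.

## Known limitations

* Postoperative per-encounter coding is homogeneous; real data show
  coding differential on age/comorbidity, which this package can only
  represent through a user-supplied kernel, not emulate by default.
* The expanded-algorithm mapping for nonspecific codes is this package's
  documented rule (four-level only), not a reconstruction of any
  specific published rule.
* The asymptotic kappa CI assumes independent pairs; cohort pairs are
  one-per-patient, so this holds, but bootstrap resampling is of table
  cells, not patients with covariates.
* Era assignment uses the service date alone; claims submitted across
  the ICD switch with lagged dates are not modelled.
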
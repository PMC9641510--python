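# Methods

## The score

Life Age is a risk-communication metric, not a survival prediction.  For a
participant of chronological age *t*:

    life_age = t + L + P,        delta = L + P

where *L* is the lifestyle effective-age component and *P* the psychosocial
component.  The decomposition is exact by construction and asserted on every
result; *delta* does not depend on *t* (no age-specific tables are shipped).

### Lifestyle component *L*

Five modifiable all-cause-mortality factors — BMI band, smoking status,
alcohol, Mediterranean-diet adherence and physical activity — each map to a
signed year offset, summed without interaction terms.  The conversion from
risk to years follows the effective-age idea: adult all-cause mortality is
well approximated by a Gompertz hazard *a·e^{bt}*, under which a hazard
ratio RR equals an age shift of `ln(RR)/b` years.  The default slope is
`b = 0.0866 /year` (hazard doubling every 8 years; `ln 2 / 8`).  Users can
supply published RRs per category and have offsets derived; the shipped
default is instead a **years table calibrated to the published extremes**:
the best-possible profile must total −6 years and the worst +28.

| factor   | categories (healthiest → worst) | years |
| -------- | ------------------------------- | ----- |
| BMI      | <23, 23–24.9, 25–29.9, 30–39.9, ≥40 | −1, 0, +2, +4, +8 |
| smoking  | never, ex, current              | −2, 0, +8 |
| alcohol  | none/low, moderate, binge       | −1, 0, +4 |
| diet     | optimal (≥10), average (7–9), poor (≤6) | −1, 0, +4 |
| activity | high, moderate, low, sedentary  | −1, 0, +2, +4 |

No per-factor RRs for this exact banding were published, so these values are
a calibration choice, versioned (`default-calibrated-1`) and embedded in
every result; they are *not* sourced estimates, and overriding them with
published RRs plus a Gompertz slope is the intended production path.  Each
factor has a zero-offset reference category (the "typical" category, not a
population average — a documented, configurable convention).

Banding choices where the anchors left gaps: the 14-unit weekly alcohol
boundary separates no/low from moderate; "binge" is any self-reported binge
episode in a typical week and overrides the unit banding; activity bands are
in MET·hours/week with 0 = sedentary, ≥10 (the guideline-equivalent of 150
moderate minutes at 4 MET) = moderate, ≥20 = high, and anything in between =
low.  Moderate/vigorous minutes convert to MET·hours at 4.0/8.0 MET
(configurable).

### Psychosocial component *P*

Four domains: life satisfaction, combined mood (`positive − negative`
affect), perceived stress, and sleep.  The first three are norm-referenced:

    years = clip( −dir · (score − μ)/σ · k , −2, +2 )

with `dir = +1` for satisfaction and mood (higher is healthier), `−1` for
stress, and slope `k = 1 year/SD` by default.  The ±2-year clip is the
defining contract of the component; the 1 year/SD slope is a design choice
(only the range, not the slope, is pinned by the concept) and is
configurable per domain.  Sleep is mapped by absolute deviation from a 7-h
optimum, `min(2, |hours − 7|)` years — a U-shaped penalty that is never
negative, reflecting that both short and long sleep carry excess risk.  The
four domains sum to *P* ∈ [−6, +8] under defaults.

The shipped norms (satisfaction 24 ± 6, combined mood 15 ± 10, stress
16 ± 7) are **placeholders**: the reference-population statistics behind the
original tool were not published.  They are versioned and should be replaced
with local normative data; every result records the norms version used.

An open ambiguity, documented rather than resolved: the ±2-year range could
be read per domain or for the whole psychosocial block.  We implement it per
domain (giving the block a −6…+8 range, comparable in magnitude to the
lifestyle component) with per-domain slopes configurable down if a
block-level reading is preferred.

### Questionnaire instruments

Diet is the 14-item Mediterranean adherence screener, one point per
criterion, banded low (≤7) / high (≥8); a score of exactly 7 is not assigned
by the published bands ("<7" low, "≥8" high) and we classify it low,
matching the convention of the trial that introduced the score.  Mood is
10 positive + 10 negative items on 1–5 scales (sums 10–50 each).  The life
satisfaction and stress instruments were not named by the study; we adopt a
5-item 1–7 satisfaction scale (total 5–35, the only range consistent with
the published mean 30.6, SD 6.3) and a 10-item 0–4 stress scale with items
4, 5, 7, 8 reverse-coded (total 0–40, consistent with the published median
15 and range 5–27).  All scorers reject out-of-range ratings rather than
clipping, and no missing items are imputed.

## Evaluation statistics

The single-arm pre/post design is analysed on complete cases.  The fixed
variable→test assignment mirrors the study's analysis: paired t-test for
diet score, life satisfaction and combined mood; Wilcoxon signed-rank for
the Life Age delta, BMI, weight, activity, stress and sleep.  Significance
is `p ≤ 0.05`, two-sided throughout (sidedness was unstated; two-sided is
conservative).  No multiplicity adjustment is applied, matching the design.

**Wilcoxon policy** (implemented in-package because no library offers this
combination): zero differences are dropped; tied |d| get mid-ranks; with
m ≤ 12 nonzero differences the exact two-sided p is computed from the full
2^m sign-flip null of W⁺ (built by convolution; tests cross-check it against
literal enumeration), as `min(1, 2·min(P(W⁺≤obs), P(W⁺≥obs)))`; beyond m=12
a normal approximation with tie correction (−Σ(t³−t)/48 on the variance) and
a 0.5 continuity correction is used.  All differences zero is a defined
degenerate case (p = 1), as is a zero-variance paired t (t = 0, p = 1 at
zero mean; p = 0 otherwise).

**Sample size** uses normal quantiles,
`n = ⌈((z_{1−α/2}+z_{power})·σ/δ)²⌉`, then `⌈n/(1−dropout)⌉`.  At δ = 0.5 y,
σ = 0.75, α = .05, power .90, dropout 20% this reproduces the published
30-participant design (24 complete pairs).  The normal-quantile form is
deliberate — it is the version consistent with that published figure — but
it overstates the power of the actual t-test: the exact noncentral-t power
at n = 24 is 0.878, and our Monte-Carlo simulator reports ~0.88 accordingly.
The honest discrepancy is reported, not patched; n = 26 would be needed for
a true ≥90% t-test power at this effect size.

Cohort summaries report mean (SD), median, IQR **and** full range for every
numeric variable — the original table's "(IQR)" columns actually display
min–max ranges, so both are computed and labelled explicitly — plus counts
with integer half-up percentages (10/16 → 63%) for categories.

## Synthetic cohorts

The generator emulates the study conditions: n participants (default
enrolment 27 in the observed study; 30 in the planned design) with baseline
marginals calibrated to the published baseline column — diet 7.1 (1.8),
satisfaction 30.6 (6.3), positive mood 35.7 (6.4), negative mood ~17, stress
~15 (7), sleep ~6.5 (1.0) h, BMI ~24.2, activity ~13.3 MET·h — drawn from
truncated normals on each instrument's legal range (integer-rounded for
questionnaire scores).  Follow-up = baseline + N(change mean, change SD),
hard-clipped to the legal range.  Change means default to the published
pre/post differences (diet +1.4, satisfaction +3.6, sleep +0.5, stress −1,
BMI −1.4, activity +3.4, mood +1.8/−1.5); change SDs were never published
and are free calibration parameters chosen so effects of that size are
detectable at ~18 completers (diet 1.5, satisfaction 4.5, sleep 0.75, etc.).
Dropout is missing-completely-at-random at 1/3 (the observed 18-of-27
completion), weight tracks BMI exactly through a fixed per-person height,
and raw questionnaire items can be back-filled deterministically to match
the generated scores.  A single integer seed drives independent per-variable
substreams (`numpy` `SeedSequence.spawn`), so cohorts are bit-reproducible.

What the generator does **not** emulate: the real joint distribution across
variables (everything but weight/BMI is independent), informative dropout,
learning/reactivity effects, or the study's exact p-values (individual data
were never deposited).  Passing tests therefore demonstrate that the
*machinery* is calibrated and mutually consistent, not that real cohorts
behave this way.

**A numerical consequence of range clipping**: variables whose baseline mass
sits near an instrument bound (life satisfaction near its 35 ceiling,
negative mood near its 10 floor, activity near 0) acquire a small bias in
their change scores even under zero change effects, slightly inflating
their type-I rate above the nominal 5% (to roughly 6–9% at n = 18 for the
worst case).  The type-I calibration tests therefore use a per-variable
band of [0.01, 0.12] and a pooled band of [0.03, 0.08] around the nominal
rate; the clean 0.05 ± 0.01 calibration of both tests is asserted separately
on unclipped null differences.

## Problem sizes used in the test suite

Deterministic checks run on single profiles or 10,000-profile cohorts;
power and type-I calibrations use 10,000 Monte-Carlo replicates; generator
recovery uses 1,000 cohorts of 18 completers; exact-Wilcoxon oracle
equivalence enumerates 200 random instances with up to 12 nonzero
differences.  These sizes give Monte-Carlo standard errors well inside the
asserted tolerances.

## Known limitations

- Default offset tables and psychosocial norms are calibrations and
  placeholders, not estimates; outputs should not be interpreted clinically
  without replacing them with sourced values.
- No sex- or age-stratified tables (none were published); sex and waist are
  carried for reporting only.
- Offsets are additive with no interactions; the effective-age conversion
  assumes a shared Gompertz slope across factors.
- Complete-case analysis only; no imputation or mixed models for dropouts.
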
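# cvcsurv

Fully-automated, rule-based surveillance of **central venous catheter-related
bloodstream infection (CVC-BSI)** from tabular electronic health record
extracts, together with the diagnostic-accuracy statistics used to validate
such algorithms against manual record review, and a synthetic cohort
generator with implanted ground truth.

It is written for infection-prevention and clinical-epidemiology teams who
want to replace manual CVC-BSI chart review with continuous automated
surveillance, and for methodologists validating such algorithms.

## The surveillance rules

The unit of surveillance is the *potential CVC-BSI episode*: every blood
culture (BCx) drawn during an admission is one potential episode, and every
admission without any BCx counts as one potential episode. Two algorithm
variants label each episode:

1. **with symptoms** — microbiological findings in BCx and CVC cultures
   combined with BSI symptoms;
2. **microbiology only** — microbiological findings alone.

An episode anchored on a positive BCx is CVC-BSI when both of the following
hold.

**BSI confirmation.** A recognised pathogen requires one positive BCx. A
common commensal (per an editable CDC-style organism classification list)
requires a second distinct BCx growing the same species within 48 h; under
variant 1 it additionally requires a BSI symptom — fever (> 38 °C), systolic
blood pressure < 90 mmHg, or diastolic blood pressure ≤ 60 mmHg — within
three days before or after the draw.

**CVC attribution.** Either a quantitative CVC-tip culture ≥ 10³ CFU/ml
growing the same species within 48 h *after* the BCx, or a central/peripheral
BCx pair drawn ≤ 15 min apart, positive for the same species, with a
differential time to positivity ≥ 2 h (central flagging first).

Within one admission, later positives falling inside the 14-day **repeat
infection timeframe (RIT)** opened by an episode's first positive BCx are
suppressed into that episode. A CVC-BSI is **healthcare-associated (HA)**
when anchored on admission day ≥ 3 (admission day = day 1), or on day 1–2
with a previous admission discharged within 48 h.

Validation statistics: sensitivity, specificity, PPV, NPV with Wilson score
95% CIs; Cohen's κ; AUROC of the binary rule (= balanced accuracy);
stratified extrapolation of 2×2 counts from a validation sample to a target
cohort with percentile-bootstrap CIs (resampling within stratum *before*
extrapolation, 10,000 replicates); rate tables against several denominators;
and a monthly incidence series per 1000 in-patient hospital-days.

## Worked example

```sh
mkdir -p demo
cvcsurv simulate --out-dir demo/cohort --seed 11
cvcsurv detect   --cohort-dir demo/cohort --out-dir demo/det --variant 2
cvcsurv evaluate --predicted demo/det/episode_labels.csv \
                 --reference demo/cohort/reference_labels.csv --out-dir demo/eval
cvcsurv incidence --labels demo/det/episode_labels.csv \
                  --cohort-dir demo/cohort --out-dir demo/inc
```

which logs

```
INFO cvcsurv: wrote cohort with 1500 admissions, 4813 draws to demo/cohort
INFO cvcsurv: 5098 potential episodes, 53 CVC-BSI (22 HA)
INFO cvcsurv: wrote metrics.csv and rates.csv to demo/eval
INFO cvcsurv: overall rate 3.21 per 1000 hospital-days (53 cases / 16521 days)
```

Reading: the simulated cohort contains 5098 potential CVC-BSI episodes, of
which the microbiology-only algorithm flags 53 as CVC-BSI (22 of them
healthcare-associated) — exactly the implanted ground truth, so
`demo/eval/metrics.csv` shows sensitivity, PPV and κ of 1.0, and
`demo/eval/rates.csv` reports 53/5098 = 1.04% of potential episodes. The
incidence command bins the same labels by month against hospital-days
contributed by overlapping stays.

The same functionality is available as a library (`cvcsurv.run_surveillance`,
`cvcsurv.metrics_with_wilson`, `cvcsurv.generate_cohort`, …).

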
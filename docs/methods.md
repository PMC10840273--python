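# Methods

## Surveillance model

The package labels *potential CVC-BSI episodes* — one per blood-culture (BCx)
draw, one per culture-free admission — with a deterministic rule cascade:
BSI confirmation, CVC attribution, repeat-infection-timeframe (RIT)
deduplication, and healthcare-associated (HA) classification. The rules
operationalise an ECDC-style microbiologically confirmed CVC-BSI definition
using only structured data: organism identities and classes, quantitative
tip cultures, blood-culture time to positivity (TTP), draw sites and
timestamps, and vital-sign observations. Criteria that require free text
(chills, pus at the insertion site) or device tables (explicit CVC presence)
are deliberately out of scope; the culture-based attribution criteria serve
as proxy for catheter presence.

Timestamps are timezone-naive clock times at minute resolution. All windows
are exact clock intervals except where noted; all interval bounds are
closed (inclusive) unless stated otherwise.

### Rule parameters

| parameter | default | unit | role |
|---|---|---|---|
| `fever_threshold` | 38.0 | °C | symptom if strictly greater |
| `sbp_threshold` | 90 | mmHg | symptom if strictly less |
| `dbp_threshold` | 60 | mmHg | symptom if less-or-equal |
| `symptom_window_days` | 3 | days | closed window before *and* after the draw |
| `contaminant_pair_window_hours` | 48 | h | second draw for commensal confirmation |
| `tip_window_hours` | 48 | h | tip culture after the BCx; lower bound at the draw |
| `tip_cfu_threshold` | 1000 | CFU/ml | greater-or-equal |
| `paired_draw_max_minutes` | 15 | min | central/peripheral pair |
| `dtp_min_hours` | 2 | h | peripheral TTP − central TTP, greater-or-equal |
| `rit_days` | 14 | days | calendar days; index day counts as day 1 |
| `ha_min_day` | 3 | day | admission day of onset; admission day = day 1 |
| `ha_readmission_window_hours` | 48 | h | previous discharge before current admit |

### Design choices where the definition is open

* **Symptom gate.** The symptom requirement of the symptom variant applies
  only in the commensal pathway, mirroring BSI case definitions in which
  pathogens need one culture while commensals need two cultures plus signs.
  The alternative reading — symptoms gating every episode — is available as
  the config toggle `require_symptoms_for_pathogens` but is off by default.
* **"Two different BCx"** means two distinct draw events; multiple bottles
  of one draw collapse to one draw at ingestion. Only the *same* commensal
  species in both draws qualifies.
* **Symptom window** is clock arithmetic (± 3×24 h), not calendar days:
  vitals carry clock times and no rounding rule is prescribed.
* **Tip window** is `[draw, draw + 48 h]`; tips collected before the BCx
  never match.
* **DTP** requires both TTP values recorded; a missing TTP fails the
  criterion (no imputation). Draws with unspecified site can anchor a BSI
  but never participate in a DTP pair.
* **RIT** is anchored on the index episode's first positive BCx date and is
  never rolled forward by suppressed positives; it applies to calendar
  dates, suppresses only rule-positive episodes, and ties at identical
  timestamps are broken by draw id. A suppressed positive does not
  re-anchor the HA classification of its index episode.
* **HA arithmetic** uses calendar dates for the admission day and clock
  times for the 48-h readmission look-back.
* Both attribution tags are recorded when a draw satisfies tip *and* DTP
  criteria; the episode counts once. Every label carries the full evidence
  trail (`pathogen_bsi`, `commensal_pair`, `symptoms`, `tip_match`,
  `dtp_match`, `ha_day3`, `ha_readmission`) for rule-level audit.

## Validation statistics

* **Wilson score intervals** for sensitivity/specificity/PPV/NPV
  (delegated to `statsmodels.stats.proportion.proportion_confint`).
* **Cohen's κ** from the 2×2 cells, implemented directly so it also applies
  to real-valued extrapolated cells; cross-checked against scikit-learn in
  the test suite.
* **AUROC of a binary rule** is defined as balanced accuracy,
  (sensitivity + specificity)/2 — the trapezoidal area through the single
  operating point. The κ CI method for extrapolated tables is percentile
  bootstrap; an analytic alternative is deliberately not offered.
* **Stratified extrapolation** scales each stratum's cells by the
  target/sampled episode ratio and sums; extrapolated cells stay
  real-valued (no rounding before metric computation).
* **Bootstrap before extrapolation.** Per replicate, episodes are resampled
  with replacement within each stratum at the sampled size. Because every
  metric is a function of the 2×2 cells alone, the resampled cells are drawn
  directly as a multinomial over the observed cell proportions — the exact
  distribution of cell counts under episode resampling — which vectorises
  10,000 replicates into a single array operation. Replicates with an
  undefined metric (zero marginal) are dropped and counted, not imputed.
  The CI is the empirical 2.5th/97.5th percentile pair; the interval is
  clamped to contain the analytic point estimate. Deterministic under a
  fixed seed (default 20240205).
* **Rounding** for reporting is half-up at the printed precision (3 decimals
  for metrics, 2 for rates); all internal computation is full precision.
* **Hospital-days** per admission are whole days (discharge date − admit
  date), minimum 1; the incidence series splits a stay's days across
  calendar bins day by day, so bin rates conserve the total case count.
  Whether admission and discharge days are counted inclusively is a
  convention choice; this one reproduces the order of magnitude of typical
  published denominators.

## Synthetic cohorts

The generator emulates the tabular substrate the rules consume: admissions
with log-normal length of stay (median ≈ 8 days), blood-culture draws
(≈ 3.9 per cultured admission, ≈ 36% positive), background organisms split
pathogen/commensal, TTP values, quantitative tip cultures, and vitals every
4–8 h. Defaults mirror a hospital-wide validation cohort: 1500 admissions of
which 5/6 have BCx, episode-level CVC-BSI prevalence ≈ 1.2% among draws,
≈ 63% of infections HA. They are illustrative study conditions, chosen once,
not fitted parameters.

Ground truth is exact **by construction**: implanted positives satisfy every
conjunct of the rule set; everything else violates at least one named
conjunct. This is enforced structurally — background positive draws use
organism pools disjoint from implant pools and unspecified sites, tips are
emitted only for implants, and at most one infection is implanted per
admission. The peripheral member of an implanted DTP pair is itself
rule-positive and is recorded in the truth as RIT-suppressed. Truth rows
carry per-variant expected labels, so cohorts with deliberately unrecorded
symptoms (`symptom_recording_rate < 1`) remain exactly checkable: they
degrade the symptom variant against the reference while the expected labels
still match.

`implant_edge_cases` appends one admission per rule boundary (pair gap
exactly 48 h, ΔTTP exactly 2 h, draw gap exactly 15 min, tip at exactly
+48 h and exactly 10³ CFU/ml, temperature exactly 38.0 °C, DBP exactly
60 mmHg, RIT day 13 vs day 14, readmission gap exactly 48 h vs 72 h), each
with its intended label.

**What passing does and does not show.** Exact truth recovery on these
cohorts demonstrates that the implementation applies the stated rules
correctly, including at every boundary. It does not estimate real-world
accuracy: real EHR data contain near-miss configurations, missing and
erroneous entries, free-text-only evidence and annotation disagreement,
none of which the generator models (ambiguity is opt-in via the edge-case
fixtures and the symptom-recording rate). Real-data validation metrics are
therefore reproduced from published 2×2 counts, not simulated.

## Problem sizes and numerics

The test suite uses cohorts of 120–5800 admissions; the large truth-recovery
check runs at ≈ 20,000 potential episodes, and bootstrap coverage is
assessed over 60 simulated label sets at 10,000 replicates each (fast due to
the multinomial vectorisation). Acceptance replays run at the published
validation sizes (4326–181,354 episodes) since they operate on counts.
Degenerate inputs fail loudly: zero marginals raise an undefined-metric
error rather than returning 0, infeasible simulation configs are rejected,
and referential-integrity violations in a cohort bundle are fatal at read
time.

## Known limitations

* The shipped commensal list is a representative subset; surveillance
  programmes should substitute their governed list.
* Only microbiologically confirmed CVC-BSI is detected — no local/general
  catheter infection, no peripheral-venous-catheter BSI, no
  semi-quantitative tip methods, no central-to-peripheral quantitative
  culture ratios.
* Catheter-days are not modelled; incidence uses in-patient hospital-days.
* The exact branch ordering of clinical flow diagrams that inspired the rule
  cascade can differ between implementations in how evidence is *recorded*;
  the accept/reject decision for every episode is invariant to that order.
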
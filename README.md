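# aoekit

Retrospective adjudication of arterial occlusive events (AOEs) in a
clinical-trial safety database, as a reusable, tested pipeline:

1. **Term screening** (`aoekit.screening`) — match adverse-event preferred
   terms against a packaged 604-term occlusive-event list plus a
   cardiac-failure list (exact matching on normalized strings), and pull
   non-progression deaths for fatal review.
2. **Event grouping** (`aoekit.grouping`) — cluster a patient's screened
   records into candidate clinical events with a 48-hour single-linkage
   window, pooling the clinical evidence of each cluster.
3. **Endpoint rules** (`aoekit.rules`) — deterministically classify each
   candidate event against charter definitions (MI types 1/2/4a/4b/4c/5,
   heart-failure hospitalization/urgent visit with AOE attribution,
   hospitalization for unstable angina, stroke subtypes, SVT/DVT/PE,
   peripheral vascular disease, and the cause-of-death hierarchy), with a
   criteria trace on every outcome (ids documented in
   `criteria_catalog.md`). Unknown evidence never auto-classifies; cases
   blocked only by unknowns are flagged for panel review.
4. **Committee workflow** (`aoekit.workflow`) — two independent reviewers,
   third-cardiologist escalation, panel meetings with specialty quorum,
   and consensus for fatal events; reviewers are the rule engine,
   optionally perturbed with a seeded per-criterion flip probability.
5. **Incidence analytics** (`aoekit.analytics`) — patient-level rates,
   exposure-adjusted incidence per 100 patient-years with yearly
   intervals that exclude prior-event patients, time-to-onset summaries,
   risk-factor strata, relative risk with log-normal CI, dose-modification
   (worst action per patient) and resolution summaries. Printed percents
   round half-away-from-zero.
6. **Synthetic data** (`aoekit.synthetic`) — a seeded generator
   (per-patient random streams, multiplicative hazards with yearly decay,
   symptom noise, configurable evidence completeness) and a constructive
   **calibrated fixture**: a 449-patient dataset laid out so that running
   the real pipeline reproduces the published marginal counts exactly.
   The fixture validates aggregation logic; it makes no claim of
   patient-level fidelity to the original trial.

## CLI

```bash
aoe simulate --seed 42 --n-patients 200 --out data/   # synthetic trial
aoe simulate --calibrated --out data/                 # calibrated fixture
aoe screen     --data data/ --out out/
aoe group      --data data/ --window-hours 48 --out out/
aoe adjudicate --data data/ --flip-prob 0.0 --seed 7 --out out/
aoe analyze    --data data/ --out out/
aoe validate   --data data/
```

Input layout (UTF-8 delimited, RFC-4180 quoting): `patients.csv`,
`adverse_events.csv`, `deaths.csv`, and `evidence.jsonl` (one JSON object
per record key). A YAML config (`--config run.yaml`) can override the term
lists, grouping window and generator parameters. Structured per-stage
record counts are logged to stderr.

## Notes

- Clinical evidence is tri-state: documented value / explicitly absent /
  unknown. Pooling takes set unions, extremes that favor criterion
  satisfaction, and known-beats-unknown.
- The cardiac-failure term list is an editable stand-in for the
  proprietary SMQ; its packaged default holds the heart-failure preferred
  terms the screen must cover.
- Reviewers are blind to dose actions and investigator causality: the
  review view exposes only a pre-abstracted "medication changed" boolean.
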
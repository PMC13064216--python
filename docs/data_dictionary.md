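# Data dictionary

## Synthetic panel CSV (`*_panel.csv`, long format, one row per person-wave)

| column | type | description |
|---|---|---|
| person_id | int | person key; never missing |
| wave | int | survey year (2009-2022 by default) |
| sex | str | `female` / `male`, sex assigned at birth; never missing |
| age | int | age in years at the wave; increments by 1 per wave |
| immigration | str | `none` / `indirect` / `direct` immigration history |
| east | 0/1 | residence in East German states |
| partner | 0/1 | living with a partner in the household |
| children | str | `none` / `single` / `multiple` underaged children in household |
| sexual_orientation | str | `probably heterosexual` / `probably bi- or homosexual` |
| housework | float | daily housework hours index (gender indicator) |
| childcare | float | daily childcare hours index (gender indicator) |
| parental_leave | 0/1 | currently on maternity/parental leave (thresholded) |
| wage | float | gross hourly wage index (gender indicator) |
| income | float | gross monthly labor income index (gender indicator) |
| education | float | highest educational degree index |
| employment | 0-3 | employment status (ordinal, thresholded) |
| risk_taking | float | risk-taking scale index |
| political_interest | 0-3 | political interest (ordinal, thresholded) |
| physician_visits | float | physician-visits index |
| smoking | 0/1 | smoking reported at or before this wave |
| hypertension | 0/1 | hypertension reported at or before this wave |
| diabetes | 0/1 | diabetes reported at or before this wave |
| migraine | 0/1/NaN | diagnosis response; present only on health waves before carry-forward |
| stroke | 0/1/NaN | diagnosis response; present only on health waves before carry-forward |
| weight | float >= 0 | wave-specific cross-sectional weight (0 for the zero-weight fraction) |

## Truth sidecar JSON (`*_truth.json`)

`config`: the generating configuration (tuple-keyed effect maps serialized
as `a->b`). `persons`: per person — `gender_true` (latent value),
`<outcome>_prob` (cumulative incidence probability), `<outcome>_prevalent`,
`<outcome>_incident_wave` (-1 for never), `<risk>_flag`, `<risk>_onset`.
The truth table is never part of the panel itself.

## Analysis table (per outcome, one row per person)

`person_id`, `sex`, `sex_binary` (1 = female), `age` (baseline years),
`age10` (age/10), `age_group` (18-34 / 35-49 / 50-64 / 65+), `immigration`
plus dummies `imm_indirect`, `imm_direct`, `east`, `partner`, `children`
(0/1/2), `sexual_orientation` (0/1), the ten indicator columns collapsed to
baseline, `smoke_before_<outcome>`, `hypertension_before_<outcome>`,
`diabetes_before_<outcome>`, `<outcome>_incident` (0/1), `weight` (baseline
wave).
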
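# Cohort table schema

TSV, one row per subject.  Missing values are empty fields (never imputed).

| column | type | units | notes |
|---|---|---|---|
| `subject_id` | str | — | `W…`/`P…`/`E…` prefix by group |
| `group` | str | — | `WELDER`, `IPD` or `ET` |
| `age` | float | years | |
| `sex` | str | — | `M`/`F` |
| `age_at_onset` | float | years | always < `age` |
| `years_exposure` | float | years | welders only, empty otherwise |
| `years_since_exposure` | float | years | welders only, empty otherwise |
| `sign_<name>` | int {0,1} | — | one column per clinical sign (see `tremorlab.archetypes.SIGN_NAMES`) |
| `<condition>_<side>_target_intensity` | float | m/s² | realized simulation target; conditions `rest`/`postural`, sides `R`/`L` |
| `<condition>_<side>_target_cf` | float | Hz | realized simulation target |

# Metrics tables

`metrics.tsv` (long, one row per record): `subject_id`, `condition`,
`side`, then `intensity` (m/s²), `cf`, `median_freq`, `dispersion` (Hz),
`low_frac`, `high_frac`, `hi` (unitless).

`metrics_wide.tsv` (one row per subject): the cohort columns above joined
with `<condition>_<side>_<metric>` columns for every estimated metric.

# Signal files

Tab-delimited text: `#`-prefixed header lines
(`# sampling_rate_hz=…`, `# subject=… condition=… side=…`), a column header
`t  ax  [ay]`, then one row per sample (seconds, m/s²).
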
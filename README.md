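# tremorlab

Quantitative hand-tremor accelerometry for a three-group clinical contrast:
workers chronically exposed to manganese in welding fumes can develop an
extrapyramidal syndrome ("manganism") whose tremor resembles both idiopathic
Parkinson's disease (IPD) and essential tremor (ET).  `tremorlab` provides
the full analysis chain used to ask whether spectral tremor parameters
separate the three groups: a generative simulator of rest/postural hand
acceleration signals, the five classical tremor parameters, the cohort
statistics, and an explicit rule-based classifier.  It is aimed at
movement-disorder and occupational-health researchers who want a tested,
reproducible reference implementation of this design — no proprietary
device software required.

## The measurements

From each acceleration record `a(t)` (biaxial, m/s²), a Welch power
spectral density `P(f)` restricted to the 0.9–15 Hz band yields

* **tremor intensity** = RMS acceleration in band, `sqrt(∫ P df)` (m/s²),
* **center frequency** `Cf = Σ f·P(f) / Σ P(f)` (Hz),
* **frequency dispersion** = width of the narrowest window centered on the
  median frequency holding 68% of band power (Hz; small = regular tremor),
* **energy distribution** = power shares of the 3–6.5 Hz and 6.6–10 Hz
  sub-bands,
* **harmonic index** = power concentration within ±0.5 Hz of the spectral
  peak (1.00 for a single harmonic oscillation).

The group-level contrast: welder and ET tremor intensifies with the arms
extended (2-fold and more) while IPD tremor does not, and welders keep a
fast (~7 Hz) rest tremor whereas ET rests slow (~5.9 Hz) — which the
package condenses into a three-branch decision rule (see
`docs/methods.md`).

## Worked example

```sh
python analysis/01_simulate_cohort.py   # 37 welders, 20 IPD, 20 ET
python analysis/02_compute_metrics.py
python analysis/03_group_statistics.py
```

The simulator writes 308 signal files (77 subjects × 2 conditions × 2
sides) under `scratch/cohort/signals/` and the metrics stage prints the
group means it recovered:

```
  WELDER rest-R intensity 0.780 m/s^2, rest-R Cf 6.90 Hz, postural-R intensity 1.302 m/s^2
  IPD    rest-R intensity 1.318 m/s^2, rest-R Cf 6.68 Hz, postural-R intensity 1.397 m/s^2
  ET     rest-R intensity 0.198 m/s^2, rest-R Cf 6.42 Hz, postural-R intensity 0.546 m/s^2
```

i.e. at n = 37/20/20 the sample means scatter around the archetype targets
(welders 0.774 → 1.61 m/s², ET 0.241 → 0.588 m/s², IPD flat).  The
statistics stage then reports the fold changes and the variance
decomposition:

```
  WELDER R: 0.780 -> 1.302 m/s^2, x1.67 (paired t p=0.00953)
  IPD    R: 1.318 -> 1.397 m/s^2, x1.06 (paired t p=0.755)
  ET     L: 0.111 -> 0.556 m/s^2, x4.99 (paired t p=2.1e-05)
  WELDER: position 2.37% (p=0.061), side 1.19% (p=0.18), ...
```

— welders and ET intensify posturally, IPD does not, and arm position
explains a small percentage of welder intensity variance.  The clinical
sign panel is reproduced from the published counts alone:

```sh
$ python analysis/04_symptom_panel.py
initial_limb_cramping           7/32     0/17    0.0798
resting_tremor                 19/31     9/16    0.7631
action_tremor                  27/31     3/16    0.0000
```

(exact two-sided Fisher tests; `0.0000` is p < 0.0001).  The classifier
stage (`analysis/05_classify_cohort.py`) separates the archetype means
perfectly but reaches only ~0.55 per-subject accuracy — an honest
consequence of the heavy between-subject overlap implied by the published
SEMs (`docs/methods.md` quantifies this).

The same stages are available as a CLI for external data
(`tremorlab simulate|analyze|stats|classify|report|reproduce-table2`);
signal and table formats are documented in `docs/cohort_schema.md`.

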
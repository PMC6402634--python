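# File formats

All formats are plain text (CSV / YAML), versioned, and round-trip
bit-exactly: writing, reading and re-writing a file reproduces it byte for
byte.

## Event log CSV (canonical, format version 1)

One row per executed trial, header fixed:

```
timestamp_s,animal_id,task_id,trial_idx,valence,combo_index,lick_mask,response,outcome,reward_ul,iti_s
```

- `timestamp_s` — trial start, float seconds since experiment epoch (3 dp)
- `trial_idx` — 0-based, contiguous per animal
- `valence` — `+` (S+) or `-` (S-)
- `combo_index` — ordinal of the valve combination used
- `lick_mask` — 4-character binary string, Q1 leftmost (e.g. `1101`)
- `response` — `1` positive (≥ 3 quarters licked), `0` negative
- `outcome` — `H`, `M`, `CR` or `FA`
- `reward_ul` — microlitres delivered (> 0 iff `H`; 2 dp)
- `iti_s` — imposed inter-trial interval, seconds (3 dp; > 4 iff `FA`)

Example:

```
timestamp_s,animal_id,task_id,trial_idx,valence,combo_index,lick_mask,response,outcome,reward_ul,iti_s
74424.871,RFID001,initial,0,-,2,0100,0,CR,0.00,4.000
74430.871,RFID001,initial,1,+,1,1111,1,H,15.00,4.000
```

Parsing is header-keyed (column order is free); malformed rows are reported
with line number and field name, all diagnostics collected unless
`fail_fast` is set. Read/write via `gonogo.io.read_event_log` /
`write_event_log`.

## Schedule CSV

One row per planned trial:

```
animal_id,task_id,trial_idx,valence,odour_labels,mixture_ratio,combo_index,valve_ids,reward_ul,lick_requirement,response_window_s
```

`odour_labels` and `valve_ids` are `|`-joined; `mixture_ratio` is `60:40`
style or empty; `lick_requirement` is the required licking fraction of the
trial length (pre-training stage 3 ramp; 0 elsewhere).

Example:

```
animal_id,task_id,trial_idx,valence,odour_labels,mixture_ratio,combo_index,valve_ids,reward_ul,lick_requirement,response_window_s
m1,initial,0,+,ethyl_butyrate|ethyl_butyrate,,3,L1V2|L2V2,15.00,0.0000,2.00
```

## Experiment config YAML

```yaml
version: 1            # mandatory
seed: 7
days: 30
odours: [ethyl_butyrate, amyl_acetate, cineol, eugenol]
cohort:
  n_animals: 8        # or an explicit animals: [{animal_id: ..., weight_g: ...}] list
  weight_mean_g: 25.0
  weight_sd_g: 3.0
olfactometer:         # optional; omitted -> standard 2-line config per task
  splus_odour: ethyl_butyrate
  sminus_odour: amyl_acetate
  n_sources_per_odour: 2
battery:
  - task_id: initial
    task_type: initial
    odour_pair: [ethyl_butyrate, amyl_acetate]
    n_trials: 500
    reward_volume: 15.0
  - lesion: {all: XXL}          # lesion presets: sham, S, M, L, XL, XXL
  - task_id: post_familiar
    task_type: familiar
    odour_pair: [ethyl_butyrate, amyl_acetate]
    n_trials: 300
```

Unknown keys are rejected by name; all diagnostics are reported at once;
battery odours must appear in `odours` (when declared). Validation via
`gonogo.io.validate_config`.

## Stimulus trace CSV

Two columns, `time_s,concentration` (relative units, full-strength plateau
= 1), written by `StimulusTrace.to_csv`.

## CLI exit codes

0 success, 1 validation failure (config or log), 2 runtime error.
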
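# File formats

All configuration files are YAML or JSON (chosen by extension); all
outputs are CSV or JSON with a commented metadata header.

## Parameter sets

A mapping whose keys are the `ParameterSet` field names; omitted keys
take the calibrated defaults, unknown keys are rejected by name.
`examples/default_params.yaml` is a complete instance. Reporters are a
nested mapping:

```yaml
q1: 0.465
n_sos_sites: 4
reporters:
  EKAR3: {k_ph: 0.5, k_deph: 0.15, total: 0.01}
  ERKTR: {k_ph: 5.0, k_deph: 1.5, total: 0.01}
```

## Stimulation protocols

```yaml
segments:                 # non-overlapping, ordered; dose in pg/ml
- {t_start: 0.0, t_end: 20.0, dose: 3.0}
- {t_start: 60.0, t_end: inf, dose: 10.0}   # "inf" = sustained
inhibitors:               # EGFR-kinase inhibition from `time` onward
- {time: 900.0, target: EGFR}
```

Washout is implicit: the dose is zero outside all segments.

## Run configs (`mapkosc` CLI)

```yaml
params: {...}             # ParameterSet mapping (or {} for defaults)
protocol: {...}           # as above
t_end: 3000.0             # minutes
seed: 0
output: traj.csv          # optional
```

## Trajectory CSV

Line 1: `# {json metadata}` — package version, parameter digest, seed,
and the full parameter set (making the file self-describing; reading it
back rebuilds the network). Line 2: header `time,<species...>,
active_erk_fraction,complex_total,reporter_*_fraction`. Values are
written with 17 significant digits (lossless round trip).

## Other outputs

* `bifurcate` CSV: `axis_value,n_states,n_stable,erk_fractions`
  (semicolon-joined branch values), fold locations in the metadata line.
* `population` CSV: long format `dose,cell,time,active_erk_fraction`.
* `spatial` output directory: one `frame_*.csv` per stored time
  (`node,egf_dose_pgml,ras_gtp_fraction,active_erk_fraction`) plus
  `sources.json` (the sampled EGF release events and the seed).
* SBML: Level 3 Version 2, one compartment, mass-action kinetic laws,
  the EGF dose as a constant parameter `egf_dose`.
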
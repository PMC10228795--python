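# woundfield

Reaction-diffusion modelling of the bistable spatial separation between a
stress-signalling pathway (JNK/AP-1, driven by a diffusible wound signal,
"EIG") and a pro-proliferative cytokine pathway (JAK/STAT, driven by the
diffusible "UPD" ligands) on a 1D wound-centre-to-periphery axis.

The package simulates two network topologies to steady state —
*unidirectional* repression (JAK inhibits JNK) and *mutual* repression (each
pathway also cell-autonomously inhibits the other) — scans a 21-dimensional
log-uniform parameter space, classifies every steady state as a bistable
spatial pattern or not, and computes the model-comparison and
parameter-dependence analyses that distinguish the two topologies.

## Layout

| module | contents |
| --- | --- |
| `woundfield.model` | domain types, dimensional→dimensionless parameter map, nondimensional equations, zero-flux Laplacian |
| `woundfield.simulate` | stiff time integration to steady state (LSODA, banded Jacobian), kymographs, damped-Newton root-finding oracle |
| `woundfield.explore` | log-uniform ensemble sampling, "simple"/"observed" bistable classifiers, gradient geometry (half-max width, curve intersection), paired-topology scans, model comparison, parameter-density analysis |
| `woundfield.profiles` | reporter-track aggregation (mean ± SEM, max-scaled), LOESS smoothing with confidence band, region masking |
| `woundfield.synthetic_data` | deterministic generators: noisy reporter tracks, parametric reference profile pairs, analytically labelled classifier fixtures |
| `woundfield.cli_io` | config loading/validation, CSV/npz round-trips, seed derivation, run manifests |
| `woundfield.cli` | the `woundfield` command |

## CLI

```sh
woundfield scan --n 2000 --seed 3 --out scan_out          # sample + simulate + classify both topologies
woundfield compare scan_out/records.csv --out cmp_out     # per-topology bistable counts, paired contingency
woundfield density scan_out/records.csv --parameter k_act_JNK --out dens_out
woundfield geometry scan_out/records.csv --out geo_out    # gradient-width vs intersection Spearman analysis
woundfield simulate --seed 1 --topology mutual --out sim_out   # one steady state + kymograph
woundfield make-tracks --seed 3 --out tracks_out          # synthetic noisy reporter tracks
woundfield profile tracks_out/tracks.csv --out prof_out   # aggregate + LOESS
woundfield make-reference --out ref_out                   # parametric reference profile pair
woundfield make-fixtures --out fx_out                     # labelled classifier fixtures
```

Every command accepts `--config` (YAML/JSON; unknown keys rejected) and
writes a `manifest.json` capturing the config snapshot, seeds, timings and
output digests. All randomness flows from the `--seed` argument; rerunning a
seeded command reproduces byte-identical CSV outputs.

Example config:

```yaml
model:
  topology: mutual
  n_compartments: 100
  wound: [0.0, 0.05]
  tolerance: 1.0e-6
  horizon: 1000.0
sampling:
  n_sets: 2000
  hill_scheme: continuous   # or integer
  diffusion: faster         # faster | slower | equal (UPD vs EIG diffusivity)
  ranges:
    gamma: [0.01, 10000.0]
```

## Classification rules

A converged steady state is a **simple** bistable pattern when JAK rises and
JNK falls from centre (x = 0) to periphery (x = 1), each with a relative
difference |u(1) − u(0)| / max(u(0), u(1)) strictly above 10%. It is an
**observed** bistable pattern when both the JNK and JAK curves have Pearson
r strictly above 0.7 against reference reporter profiles (by default the
parametric logistic pair from `synthetic_data`; override with
`woundfield scan --reference <prefix>` pointing at `<prefix>_jnk.csv` /
`<prefix>_jak.csv`).
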
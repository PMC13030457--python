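# otk

Optical-trap signal simulation and binding-kinetics inference.

`otk` models an optically trapped microsphere whose effective drag grows as
a ligand monolayer forms on its surface, and implements the full analysis
chain for recovering binding kinetics from detector signals:

1. **synthetic** — overdamped Ornstein–Uhlenbeck simulation of the trapped
   bead (exact one-step update, Euler–Maruyama cross-check), Stokes drag,
   a pseudo-first-order surface-binding schedule, and a phenomenological
   quadrant-photodiode detector model producing `X`, `Y`, `SUM` channels
   whose total-intensity gain can shift with surface coverage.
2. **spectral** — SUM-normalisation, initial-transient discard, splitting
   into 1-s segments, per-segment one-sided PSDs, and Lorentzian fits
   `P(f) = D / (2π²(fc² + f²))` yielding a corner frequency and an
   effective (scaled) friction coefficient `γ* = kBT / D` per segment.
3. **kinetics** — per-particle max normalisation, 20-segment moving
   averages, time-windowed kernel-density summaries, sigmoid fitting of
   `γ(t) = b / (c + exp(−Kobs(t − t0)))` to extract the observed rate
   `Kobs`, and the pseudo-first-order conversion `kon = (Kobs − koff)/[L]`.
4. **stoichiometry** — surface-saturation dosing `S = 6C/(ρd)` (mixed
   mg/m², g/cm³, µm convention with strict unit plausibility checks) and
   mass→molar concentration conversion.
5. **sec** — size-exclusion-chromatography calibration: least-squares line
   of log10(hydrodynamic radius) vs elution, with interpolation of
   unknowns and extrapolation flagging.
6. **tsio / pipeline / cli** — delimited-text and HDF5 record I/O, a YAML
   run configuration with one master seed fanning out to all stochastic
   stages, and the `otk` command-line entry point.

## CLI

```sh
# simulate a detector record from a YAML config (or the built-in demo)
otk simulate --seed 1 --out record.csv

# per-segment Lorentzian fits (gamma* trajectory)
otk analyze record.csv --discard 30 --segment-length 1 --out segments.csv

# sigmoid fit of the gamma* trajectory and kon
otk fit segments.csv --ligand-conc 5e-9 --out fit.json

# moving-average + KDE summaries
otk report segments.csv --out summary.json

# full chain: simulate -> analyze -> fit -> report bundle
otk pipeline --seed 1 --out run1/

# monolayer dosing plan and SEC calibration utilities
otk plan-coating --capacity 3 --density 1.19 --diameter 4.8 --excess 10
otk sec-calibrate standards.csv --elution 11.161
```

A run configuration can be written with
`python -c "import otk; otk.default_demo_config().to_yaml('run.yaml')"`
and edited; every output file carries the config hash and master seed in
its header.

## Notes on conventions

- The Lorentzian model is the *two-sided* spectral density; one-sided
  periodogram estimates are halved before fitting so that `D = kBT/γ` in
  physical units.
- The default fit performs unweighted least squares on log-power and
  corrects the known `digamma` bias of log-periodogram ordinates; a
  weighted linear fit on the rearranged Lorentzian is available as a
  cross-check (`fit_space="weighted_linear"`).
- The default fit band tops out at `fs/8`: the sampled process has an
  aliased (AR(1)) spectrum that departs from a Lorentzian above that and
  biases the corner frequency when included.
- `γ*` blends hydrodynamic drag with detection-gain changes and is only
  meaningful as a relative (per-particle max-normalised) quantity.
- The sigmoid has an exact gauge freedom (rescaling `b`, `c` with a shift
  of `t0`); the default fit pins `c = 1`, which leaves `Kobs`, the fit
  quality and the predicted curve unchanged.
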
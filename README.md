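# aerotax

Analysis toolkit for oxygen-gradient navigation ("aerotaxis") of swimming
microorganism colonies in a PDMS microfluidic device. The package covers the
full pipeline from raw bright-field video to population-model fits:

- **`aerotax.oxygen_sim`** — finite-volume solver for the oxygen diffusion
  equation on the 2D device cross-section (PDMS slab, water-filled sample
  channel, two flanking gas channels with time-dependent air/nitrogen
  Dirichlet conditions, no-flux glass boundaries), plus extraction of 1D
  chamber concentration profiles.
- **`aerotax.keller_segel`** — 1D Keller–Segel population solver (implicit
  diffusion + upwind advection, mass-conserving, positivity-preserving) with
  pluggable gradient-response functionals (`constant`, `linear`, `tanh_abs`,
  `tanh_linear`, and the relative-gradient / Weber-law `tanh_log`), and
  multi-start least-squares fitting of (D, α, v_drift) to density kymographs.
- **`aerotax.navigation`** — deterministic-steering and stochastic
  (modulated-rotational-diffusion, Itō) heading SDEs, their analytic
  Fokker–Planck steady states, turn-angle (Δϕ) densities by Gauss–Legendre
  quadrature, the drift-velocity closed form, and maximum-likelihood fits
  for model comparison.
- **`aerotax.trajectory_stats`** — boundary-corrected kernel density
  estimates, running ensemble velocity/alignment statistics, and pooled
  heading/turn-angle samples from track tables.
- **`aerotax.tracking`** — running-median background estimation, band-pass +
  local-maxima colony detection with sub-pixel refinement, and greedy
  proximity linking with gap bridging.
- **`aerotax.synthetic_data`** — canned gas protocols solved into oxygen
  fields, biased-swimmer trajectory ensembles coupled to the field through
  the response functional, and noisy toy videos with ground truth.

## Command-line tools

```bash
# solve the device diffusion equation for a gas protocol
oxygen-sim --protocol protocol.yaml --tend 5400 --out field.npz \
           --profile-csv profile.csv

# solve / fit the population model on a stored chamber profile
ks-solve --field profile.csv --model tanh_log --D 865 --alpha 1850 \
         --vdrift 5.2 --out rho.csv
ks-fit --observed rho.csv --field profile.csv --model tanh_log

# simulate heading ensembles
nav-sim --model stochastic --eps 0.55 --dr 0.33 --n 1000 --T 60 \
        --seed 1 --out angles.csv

# detect + link colonies in a TIFF stack
track --stack stack.tif --px-um 0.645 --out tracks.csv

# synthetic scenarios
synth tracks --scenario flip --n 150 --seed 7 --out tracks.csv
synth video --tracks tracks.csv --snr 5 --out stack.tif
```

A gas protocol file is a YAML/JSON list of segments:

```yaml
- {t: 0,    left: air,      right: nitrogen}
- {t: 1200, left: nitrogen, right: air}
```

Geometry configs accept `slab_width`, `slab_height`, `channel_thickness`,
`sample_width`, `gas_width`, `gas_gap`, `dy`, `dz` (µm; defaults documented
in `aerotax.oxygen_sim.DeviceGeometry`).

## Conventions

Concentrations are % O₂, lengths µm, times s. The chamber gradient axis is
y (0 at the chamber center), z is height above the bottom glass, and heading
θ = π/2 points up the oxygen gradient. The turn angle over a lag Δt is
positive for turns toward the gradient. Every stochastic entry point takes
an explicit seed.
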
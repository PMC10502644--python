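# fluidmre

Viscoelastic *fluidity* and *stiffness* analysis for multifrequency MR
elastography (MRE), from scalar rheology up to a biomechanical tumor
growth-pattern classification. The package provides:

- **`fluidmre.rheology`** — complex shear modulus algebra: phase angle
  `phi = arctan(G''/G')`, normalized fluidity `(phi - pi/4)/(pi/4)`
  (−1 pure solid … +1 pure fluid), the speed/magnitude conversion
  `|G*| = c^2 rho (1 + cos phi)/2`, the two-parameter springpot model
  `G* = mu^(1-alpha) eta^alpha (i 2 pi f)^alpha` (eta = 1 Pa s), and a
  joint relative least-squares fit of (mu, alpha) to dispersion tables of
  shear-wave speed `c(f)` and penetration rate `a(f)`.
- **`fluidmre.cylinder`** — the tabletop-MRE stage: the Bessel forward model
  `u(r) = U0 J0(k* r)/J0(k* R)` for axial shear waves in a z-infinite
  cylinder, per-frequency complex-wavenumber fitting, and a pipeline from
  radial profiles to a 500 Hz springpot summary (fit band 200–800 Hz).
- **`fluidmre.inversion`** — a desk-scale 2D heterogeneous Helmholtz forward
  solver (sparse finite differences, Dirichlet drive edge, absorbing sponge)
  and a multifrequency magnitude inversion recovering `|G*|`, `phi`,
  fluidity and wave-speed maps, plus a phase-gradient wave-speed surrogate.
- **`fluidmre.maps`** — fluidity-map features: solid/transitional/fluid
  regime labeling (default thresholds ±0.1, configurable), regime-occupancy
  entropy as a spatial heterogeneity score, tumor-front texture
  (isoperimetric roughness + boundary-normal gradient width), and the
  Saffman–Taylor boundary-instability criterion
  `sin(phi_t)/sin(phi_c) < G_c/G_t`.
- **`fluidmre.classify`** — the five-input growth-pattern decision tree
  (stiffness ratio, tumor regime, control regime, heterogeneity, front
  texture → types 1–4 via `type = 1 + displacing + 2·infiltrative`), its
  full 72-combination enumeration, a Welch's-t "stiffer than control" test
  from summary statistics, the packaged per-entity meta-analysis fixture,
  and the retrospective per-entity classification reproduction.
- **`fluidmre.tracks`** — 3D cell-trajectory displacement analysis with the
  one-cell-radius unjamming threshold and Wilson-interval unjammed
  fractions.
- **`fluidmre.synthetic`** — seeded generators for every consumed input:
  springpot dispersion tables, cylinder profiles, heterogeneous 2D phantoms
  (fluid islands, blurred or fingered boundaries) with simulated wave
  fields, and jammed/unjammed track mixtures.

## CLI

```sh
fluidmre classify --entity "Liver - CCA"
fluidmre classify --stiffer --tumor-regime fluid --heterogeneous --front sharp
fluidmre simulate spec.yaml --seed 3 --out sim_out      # kind: dispersion|profiles|phantom|tracks
fluidmre fit-dispersion sim_out/dispersion.csv
fluidmre fit-cylinder sim_out/profile_*.csv
fluidmre invert sim_out/fields --out maps
fluidmre tracks-report sim_out/tracks.tsv
```

Example simulation spec:

```yaml
kind: dispersion
scenario: rat-tail        # or mu/alpha explicitly
freqs: [200, 300, 400, 500, 600, 700, 800]
noise: 0.05
```

## File formats

- Dispersion tables: CSV with `freq_hz,k_re,k_im` or `freq_hz,c_mps,a_mps`.
- Cylinder profiles: CSV `r_m,u_re,u_im` plus a JSON sidecar
  `{"radius_m": ..., "freq_hz": ...}`.
- Wave fields / parameter maps: `.npz` archive plus JSON manifest
  (`fluidmre.io`).
- Cell tracks: TSV `cell_id,t_min,x_um,y_um,z_um,region`.
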
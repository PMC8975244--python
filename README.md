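# memprobe

Membrane mechanics from single-nanorod orientation tracking.

A gold nanorod adhered to a lipid bilayer is a local probe of the
membrane's thermal physics: its position reports lateral diffusion, its
in-plane rotation reports membrane viscosity, and the wobble of the local
membrane normal — reconstructed from the rod's rapidly rotating orientation
— reports the bending undulation spectrum. `memprobe` implements the full
computational chain for such experiments on giant unilamellar vesicles
(GUVs) and cell plasma membranes:

- **Fluctuation model** (`memprobe.model`): the out-of-plane mean-squared
  angular displacement (MSAD) of the membrane normal over the wavenumber
  band q ∈ [π/R, 2π/l] set by the vesicle radius R and rod length l,

      ⟨Δθ²(τ)⟩ = (kBT/π) ∫ q dq/(κc q² + σ)
                 × [1 − (κc/κ̃c) e^{−ω₂τ} − (1 − κc/κ̃c) e^{−ω₁τ}]
                 + ⟨Δθ²⟩_static ,

  with bending rigidity κc, tension σ, renormalized rigidity
  κ̃c = κc + 2εd² (monolayer compressibility ε, leaflet offset d), and the
  two per-mode relaxation rates ω₁, ω₂ of the coupled height /
  monolayer-density dynamics (intermonolayer friction b, bulk viscosity η).
  Its τ→∞ plateau is the closed form
  ⟨Δθ∞²⟩ = (kBT/2πκc) ln[(κc q_max² + σ)/(κc q_min² + σ)].
- **Estimators** (`memprobe.estimators`): MSD/MSAD with overlapping lags,
  the raw→physical MSAD correction that undoes the octant folding of
  polarimetric orientation data, membrane-normal estimation by windowed SVD
  plane fits, out-of-plane angle series, and angle covariance
  A(τ) = ⟨θ⊥(t+τ)θ⊥(t)⟩.
- **Inference** (`memprobe.inference`): 4Dτ diffusivity fits, the
  simultaneous MSAD-curve + asymptote fit for (κc, σ, b), χ² sensitivity
  profiles, rod-length uncertainty propagation, inversion of (D_t, D_r) to
  membrane viscosity η_m and effective rod length via Saffman–Delbrück
  drag, and the cell-membrane corral/covariance analysis
  A(τ) = (kBT/2πκc)(δq/q) e^{−ωτ}.
- **Synthetic data** (`memprobe.synthetic`): seeded generators for every
  input — sphere diffusion, prone-rod rotation with octant folding and 1°
  instrument noise, band-mode normal tilt with the exact two-exponential
  per-mode correlation, corral-caged cell walks, and noisy model curves.
- **Membrane Monte Carlo** (`memprobe.dtmc`): a dynamically triangulated
  simulation of a closed vesicle (Canham–Helfrich energy discretized with a
  per-vertex shape operator, vertex moves + edge flips, tether and
  self-avoidance constraints, volume/area windows for tense vs floppy
  states) with a Lennard-Jones-bound rigid rod, reproducing the
  tension-dependent caging of rod rotation and validating the
  normal-inference procedure.
- **IO & CLI** (`memprobe.io`, `memprobe.cli`): '#'-headered CSV trajectory
  files, JSON result documents with config hashes and seeds, and
  `memprobe simulate-guv / analyze-guv / fit-msad / simulate-cell /
  analyze-cell / simulate-dtmc` subcommands.

## Worked example

Simulate a 4-second vesicle recording (R = 7 µm, octant-folded orientations
with 1° noise) and analyze it back:

```
memprobe simulate-guv --config guv.json --out sim
memprobe analyze-guv --config analyze.json --out out
```

with `guv.json`:

```json
{"mode": "simulate-guv", "seed": 5,
 "params": {"R": 7e-6, "rod_l": 2e-6, "Dt": 0.52e-12, "Dr": 27.7,
            "dt": 2e-4, "n_steps": 20000,
            "kappa_c_kbt": 7.3, "sigma": 1.1e-6, "b": 6.9e8}}
```

and `analyze.json` pointing at `sim/trajectory.csv`. The analysis stage
prints/stores (`out/diffusivities.json`):

```
D_t = 5.19e-13 m²/s    (generated at 5.2e-13)
D_r = 28.2 rad²/s      (generated at 27.7)
eta_m = 1.21e-9 Pa·s·m, l_m = 1.21 µm
```

i.e. the translational and rotational diffusivities are recovered from the
folded, noisy orientation data, and inverting them through the rod drag
model gives the membrane surface viscosity and the Saffman–Delbrück length
l_m = η_m/η (the scale below which membrane, not bulk, drag dominates).

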
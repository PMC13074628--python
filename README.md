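# swirsr

Two-wavelength, two-separation SWIR diffuse-reflectance hydration pipeline
for gelatin–Intralipid phantoms.

A compact contact probe measures diffuse reflectance at 1450 nm and 1650 nm
at two source–detector separations (0.45 cm and 0.70 cm) through a 4 mm
collection aperture.  This package implements the full analysis chain:

1. **Phantom recipes** (`swirsr.recipes`) — recipe-defined true water
   fractions from component masses, with the Intralipid-stock water content
   (default 80% by mass) as an explicit parameter.
2. **Monte Carlo transport** (`swirsr.mc`) — a numba-accelerated photon
   transport kernel for a homogeneous slab with a finite-area generalized
   Lambertian LED source, Fresnel boundary at the top surface, an absorbing
   mask with circular aperture, acceptance-cone-limited detection,
   continuous absorption weighting, Henyey–Greenstein scattering, and
   Russian roulette.  Deterministic per seed; full weight-conservation
   bookkeeping.
3. **Lookup tables** (`swirsr.lut`) — per-wavelength far/close ratio curves
   versus reduced scattering μs′ at a fixed assigned absorption, with
   starvation flagging, a noise-tolerant monotonicity check (isotonic
   projection within 2 standard errors), and log-domain interpolation
   inversion of measured ratios (no extrapolation).
4. **Diffusion dipole model** (`swirsr.diffusion`) — semi-infinite
   extrapolated-boundary dipole fluence proxy whose far/close ratio is
   independent of coupling constants; used for the water-fraction sweep.
5. **Signal pipeline** (`swirsr.signals`) — dark subtraction, PTFE
   reference normalization (applied exactly once), corrected ratio
   formation, low-SNR exclusion; per-channel gains and dark offsets cancel
   by construction.
6. **Water-fraction inversion** (`swirsr.inversion`) — bounded dense-grid
   sweep of the log-domain squared ratio error, agreement metrics
   (per-pair absolute percent error, group means, bias/MAE/RMSE).
7. **Synthetic data** (`swirsr.synthetic`) — measurement-frame generator
   with known ground truth (gains, offsets, noise, reference mismatch) and
   the packaged recipe/validation fixtures.

Water absorption constants at the two bands are packaged
(`swirsr/data/water_absorption.csv`, Hale–Querry-derived center-wavelength
values); lookups are exact, never interpolated.

## CLI

```sh
swirsr simulate --mu-a 1.0 --mu-sp 10 --rho 0.45 --n-photons 1000000 --seed 1
swirsr build-lut --fw 0.78 --grid-points 12 --grid-lo 1 --grid-hi 10 \
    --n-photons 1000000 --seed 1 --out lut.csv
swirsr synth --fw 0.83 --mu-sp-1450 2.0 --mu-sp-1650 1.8 --noise 0.02 \
    --seed 7 --out frames.csv
swirsr ratios --measurements frames.csv
swirsr forward --fw 0.83 --mu-sp 2.0 --wavelength 1450
swirsr invert --measurements frames.csv --lut lut.csv
swirsr report --pairs pairs.csv
```

Outputs embed a config hash, seed, and package version for provenance.

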
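# llstorm

Analysis pipeline for whole-cell 3D single-molecule localization microscopy
on a lattice light-sheet (LLS) instrument — for microscopists and image
analysts who acquire dSTORM-style blinking movies of membrane receptors
while stage-scanning the sample through a thin light sheet, and who need
quantitative receptor densities, mobilities and localization precisions over
the *entire* cell surface rather than just the coverslip-contacting membrane.

The package covers the full chain:

- **Astigmatic 3D localization** — difference-of-Gaussians detection,
  elliptical-Gaussian maximum-likelihood fitting under Poisson noise, and
  axial assignment by inverting a bead-stack calibration of the defocus
  curves σx(z), σy(z).
- **Scan correction and deskew** — the sample is scanned in a sawtooth
  (s = frame·Δs, resetting each stack) with the camera plane inclined by α
  to the coverslip; localizations are mapped into biological coordinates by
  x′ = x, y′ = s + y·cos α − z·sin α, z′ = y·sin α + z·cos α.
- **Membrane densities** — sliding-window counts (2 µm × 2 µm window,
  0.2 µm step) over region masks, summarized as median ± MAD with boxplot
  statistics, for basal / apical / cell–cell-interface membranes.
- **Single-particle tracking** — Crocker–Grier-style linking and
  per-dimension ensemble MSD with the linear fit ⟨Δr²⟩(τ) = o + 2Dτ on the
  first five lag points (o reflects the squared localization precision).
- **FRAP** — trace normalization and single-exponential recovery fits
  (τ, mobile fraction).
- **Precision estimation** — per-axis pooled within-event standard
  deviations over repeated localizations of single blinking events.
- **Synthetic data** — a two-cell membrane scene with blinking emitters,
  sheet-limited sawtooth-scanned image formation, Brownian trajectories and
  FRAP traces, so the whole pipeline is testable end-to-end without raw
  data.

## Worked example

Estimate per-dimension diffusion constants from simulated membrane-receptor
trajectories (anisotropic D, 20 ms frames, 20/70 nm lateral/axial
localization noise), via the full link → ensemble-MSD → fit pipeline:

```python
from llstorm import (simulate_trajectories, trajectories_to_table,
                     link_localizations, ensemble_msd, fit_diffusion)

D_true = (0.058, 0.059, 0.023)        # µm²/s, x/y/z
_, noisy = simulate_trajectories(
    n=300, D=D_true, dt=0.02, n_frames=50, noise=(20, 20, 70), seed=7)
trajs = link_localizations(trajectories_to_table(noisy), max_disp=500, dt=0.02)
msd = ensemble_msd(trajs, min_track_len=20, dt=0.02)
fit = fit_diffusion(msd, n_fit_points=5)
for axis, d, o in zip("xyz", fit.D, fit.offset):
    print(f"D_{axis} = {d:.4f} um^2/s   offset_{axis} = {o:.0f} nm^2")
```

prints

```
D_x = 0.0583 um^2/s   offset_x = 762 nm^2
D_y = 0.0607 um^2/s   offset_y = 750 nm^2
D_z = 0.0246 um^2/s   offset_z = 9656 nm^2
```

The fitted D match the simulation inputs within Monte-Carlo error, and the
offsets sit near 2σ² of the injected localization noise (2·20² = 800 nm²
laterally, 2·70² = 9800 nm² axially) — the static-error interpretation of
the MSD intercept.

The end-to-end membrane-density study (simulate a scanned two-cell
acquisition, localize every frame, filter, deskew, measure region
densities) runs in a few minutes:

```python
from llstorm.pipeline import run_density_study

res = run_density_study(seed=0)
for name, s in res["summaries"].items():
    print(f"{name:10s} {s.median:6.1f} ± {s.mad:.1f} loc/µm²  (n={s.n_windows})")
print("interface : apical ratio =", round(res["interface_apical_ratio"], 3))
```

prints

```
apical       18.0 ± 1.2 loc/µm²  (n=289)
basal        10.8 ± 2.2 loc/µm²  (n=289)
interface    32.8 ± 2.0 loc/µm²  (n=100)
interface : apical ratio = 1.819
```

Two membranes are apposed at the cell–cell wall, so the interface density is
about twice the apical one at equal per-membrane labeling — the geometric
signature of receptor accumulation measurements at cell contacts.

A CLI mirrors the library (`llstorm simulate | calibrate | localize |
deskew | density | track | frap | precision`); stages read and write TIFF /
CSV / YAML so they chain via files.

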
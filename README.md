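# myxoquant

Quantitative analysis of type-IVa-pilus / exopolysaccharide (T4aP–EPS)
driven surface motility in *Myxococcus xanthus* — and of the binding
measurements that accompany such studies.

*M. xanthus* cells twitch across surfaces by extending and retracting
type IVa pili that grip secreted exopolysaccharide. Experiments on this
system produce three kinds of quantitative data, and this package covers
the measurement layer for all of them:

* **Time-lapse motility movies** → cell detection (threshold +
  connected components + second-moment ellipse), globally optimal
  frame-to-frame track linking (Hungarian assignment), instantaneous
  velocity profiles (µm/min), cumulative surface coverage (union of
  per-detection disc footprints with radius = minor semi-axis), and
  Gaussian-smoothed positional density heatmaps.
* **Two-channel fluorescence images** → colocalization statistics:
  Pearson's correlation coefficient (PCC ∈ [−1, 1]), Manders overlap
  coefficients (M1, M2 ∈ [0, 1]) and the intensity correlation quotient
  (ICQ ∈ [−0.5, 0.5]).
* **Equilibrium binding data** → SPR steady-state affinity fits
  (`R_eq = R_max·C/(K_D + C)`) and ITC one-set-of-sites thermogram fits
  (parameters n, K_D, ΔH, with perfusion-displacement concentration
  bookkeeping and dilution-heat subtraction).

Every pipeline input has a matching synthetic-data generator
(agent-based rod-cell motility simulator with persistent random walk,
Poisson reversals and optional EPS-trail following; capsule renderer;
two-channel object placer; Langmuir and Wiseman-isotherm samplers), so
each analysis is validated by parameter recovery against known ground
truth. See `docs/methods.md` for the models and their assumptions.

## Worked example

```python
import myxoquant as mq
from myxoquant.tracking import segment_stack, link_tracks

# simulate a wild-type-like population, render, track, and quantify
cfg = mq.MotilitySimConfig(n_cells=20, duration=1000.0, arena_width=120.0,
                           arena_height=120.0, speed_mean=10.36,
                           speed_sd=5.03, seed=1)
truth = mq.simulate_trajectories(cfg)
stack = mq.render_frames(truth, pixel_size=0.25, psf_sigma=0.2,
                         noise_sd=0.02, seed=1)
tracked = link_tracks(segment_stack(stack), frame_interval=10.0)
prof = mq.instantaneous_velocities(tracked)
cov = mq.cumulative_coverage(truth, grid_pixel_size=0.4)
print(f"tracks: {tracked.n_tracks}")
print(f"mean speed: {prof.mean:.2f} ± {prof.sd:.2f} µm/min over {prof.n_steps} steps")
print(f"coverage fraction: {cov.coverage_fraction:.3f}")

# fit synthetic binding data generated at known constants
spr = mq.generate_spr_dataset(mq.SPRSimConfig(
    Rmax=100.0, K_D=1.055e-3,
    concentrations=[31.25e-6 * 2**k for k in range(7)], noise_sd=2.0, seed=1))
fit = mq.fit_spr_steady_state(spr)
print(f"SPR: K_D = {fit.K_D:.3e} M, Rmax = {fit.Rmax:.1f} RU")

itc = mq.generate_itc_dataset(mq.ITCSimConfig(
    n=1.47, K_D=3.00e-4, dH=-5.0, cell_conc=1e-3, syringe_conc=2.2e-2,
    noise_sd=0.1, seed=1))
ifit = mq.fit_itc_one_site(itc)
print(f"ITC: n = {ifit.n:.2f}, K_D = {ifit.K_D:.2e} M, "
      f"dH = {ifit.dH:.2f} kcal/mol (c = {ifit.c_value:.1f})")
```

Output:

```
tracks: 24
mean speed: 10.08 ± 5.14 µm/min over 1984 steps
coverage fraction: 0.063
SPR: K_D = 9.805e-04 M, Rmax = 96.7 RU
ITC: n = 1.44, K_D = 2.70e-04 M, dH = -4.75 kcal/mol (c = 5.3)
```

The tracker finds 24 tracks for 20 cells (brief occlusions split a few),
and the pooled instantaneous speed 10.08 ± 5.14 µm/min recovers the
generating 10.36 ± 5.03 µm/min within ~3%. The single noisy SPR series
(2 RU noise) returns K_D within 7% of the generating 1.055 mM, and the
single noisy titration (2% heat noise) recovers stoichiometry,
affinity and enthalpy within a few percent — at a Wiseman c ≈ 5, inside
the well-conditioned 1–1000 window.

## Command line

The same stages are available as a `myxoquant` console script:

```bash
myxoquant simulate-movie --n-cells 20 --duration 1000 --seed 1 --out sim/
myxoquant track --movie sim/movie.tif --out trk/
myxoquant quantify-motility --tracks trk/tracks.csv \
    --arena-width 200 --arena-height 200 --out motility/
myxoquant simulate-itc --n 1.47 --k-d 3e-4 --dh -5 --out itc/
myxoquant fit-itc --data itc/itc.csv --out itcfit/
myxoquant demo --seed 1 --out demo/   # scaled run of every stage
```

Each run directory receives the resolved configuration, the seed, a
`run.log`, and a machine-readable `summary.json`; movie TIFFs carry a
JSON metadata sidecar (pixel size, frame interval, seed), and rerunning
with the same config and seed reproduces outputs bit for bit.

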
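# spheroflow

Quantitative analysis of tumour-spheroid rolling adhesion in microfluidic
flow chambers.

Ovarian cancer disseminates through the peritoneal cavity, where ascitic
flow exerts wall shear stresses of only ~0.03–0.15 dyn cm⁻² — an order of
magnitude below vascular shear.  A standard assay for studying this step
perfuses fluorescently labelled cancer-stem-cell spheroids (70–100 μm
diameter) over a mesothelial monolayer in a parallel-plate microchannel,
records 30 s time-lapse videos at 1 frame s⁻¹, and scores each spheroid as
**tethering** (transient capture), **rolling** (sustained translation below
the hydrodynamic velocity over more than one spheroid diameter), **firm
adhesion** (stationary for more than one frame, through the end of the
recording) or non-interacting.  `spheroflow` implements that analysis as a
tested, reusable pipeline, for experimentalists who have trajectory tables
or TIFF stacks from such assays and for modellers who need a calibrated
synthetic benchmark.

## What is inside

| Module | Role |
| --- | --- |
| `flow_geometry` | Plate-channel hydrodynamics: τ = 6μQ/(wh²), near-wall spheroid velocity u_h = k·(τ/μ)·(d/2), shear-ramp schedules |
| `synthetic_data` | Catch-slip bond Markov simulator (k_off(τ) = a·e^(−τ/f_c) + b·e^(τ/f_s)), trajectory/image rendering, detachment ramps, an exact dynamic-programming oracle |
| `detection_tracking` | Blob detection with a 70–100 μm size gate, watershed splitting, greedy flow-aware linking |
| `motion_classification` | The tether/roll/arrest rules, reference-velocity estimation, cohort percentages |
| `cohort_stats` | Pearson chi-square, one-tailed Student's t, median fold changes, significance stars |
| `cli_io` | Shared trajectory CSV schema, JSON/YAML configs, sidecars, `spheroflow` CLI |

Because the spheroid–substrate bond behaves as a catch bond, capture
efficiency is not monotone in shear: it peaks at an intermediate threshold
shear (0.05 dyn cm⁻² under the calibrated defaults) and collapses on both
sides.  The synthetic module reproduces this structure with two built-in
conditions — a high-avidity cohort (`M-CSC`, generative firm-arrest
probability 0.40 at the optimum) and a low-avidity one (`NM-CSC`, 0.17) —
so every stage of the pipeline can be validated against known ground truth.

## Worked example

```python
import spheroflow as sf
from spheroflow.synthetic_data import study_config, simulate_trajectories

cfg = study_config("M-CSC", wall_shear_dyn_cm2=0.05, seed=1, n_fields=4)
traj, truth = simulate_trajectories(cfg)

classified, u_ref = sf.classify_cohort(traj, cfg.flow)
s = sf.summarize_cohort(classified, "M-CSC", 0.05)
print(f"reference velocity u_ref = {u_ref:.1f} um/s")
print(f"{s.n_total} spheroids: {s.pct_tethering:.1f}% tethering, "
      f"{s.pct_rolling:.1f}% rolling, {s.pct_adhesion:.1f}% adhesion")
print(f"median rolling velocity = {s.median_rolling_velocity_um_s:.1f} um/s")
```

prints

```
reference velocity u_ref = 129.8 um/s
47 spheroids: 44.7% tethering, 6.4% rolling, 38.3% adhesion
median rolling velocity = 16.9 um/s
```

`u_ref` is the analytic near-wall transport velocity of a free spheroid at
the cohort's median diameter; every track slower than `0.5·u_ref` over a
long enough path counts as rolling.  The percentages divide class counts by
all 47 spheroids that transited the four fields during the 30 s recordings,
the assay's standard denominator.  38.3% firm adhesion is consistent with
the condition's generative arrest probability of 0.40.

The same analysis runs from the shell, stage by stage:

```bash
spheroflow simulate --condition M-CSC --shear 0.05 --seed 1 --out traj.csv
spheroflow classify traj.csv --out-tracks classes.csv --out-summary summary.csv
spheroflow sweep --seed 1 --out-summary sweep.csv --out-stats stats.csv
spheroflow detach --seed 1 --out detach.csv
```

`simulate --render-dir` additionally writes 16-bit multi-page TIFF stacks,
and `spheroflow track *.tif --out traj.csv` recovers trajectories from
them, interchangeable with simulated ones.

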
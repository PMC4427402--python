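# neutrotax

Quantification of neutrophil chemotaxis in co-flow microfluidic gradient
channels, for labs evaluating patient-derived chemoattractant sources (such
as COPD sputum) at the level of single-cell migration. The package
implements the full analysis chain — gradient modeling, cell detection and
linking, trajectory statistics, ellipse morphometry, and cohort-level
tests — together with a ground-truthed synthetic assay simulator, so every
stage is testable end to end without experimental image data.

## The statistics at the core

For a cell track with positions $x_0 \dots x_n$ sampled at a fixed frame
interval, with $\hat{g}$ the unit vector pointing up the gradient:

- **Chemotactic index**
  $\mathrm{C.I.} = \dfrac{(x_n - x_0)\cdot\hat{g}}{\sum_i \lVert x_{i+1}-x_i\rVert} \in [-1, 1]$ —
  signed net displacement along the gradient over total path length
  (negative: net migration toward the opposite source).
- **Migration speed** $V = \text{path length} / (t_n - t_0)$ in µm/s.
- **Aspect ratio** of the moment-equivalent ellipse of a segmented cell,
  $\sqrt{\lambda_1/\lambda_2}$ from the eigenvalues of the second-order
  central image moments (1 = round, >1 = polarized/elongated).

The simulator draws step directions from a von Mises law with
concentration $\kappa$ and direction-independent Gamma step speeds, so the
asymptotic C.I. has the closed form $I_1(\kappa)/I_0(\kappa)$; inverting it
(`calibrate_kappa`) pins any simulated condition to a chosen target C.I.
Cohort analysis provides pooled-variance Student's t / one-way ANOVA group
tests and OLS of per-subject C.I. on spirometry (FEV1/FVC) with an
exhaustive leave-one-out scan. A per-subject clinical table (5 COPD, 5
control: age, sex, FVC, FEV1, FEV1/FVC, C.I.±SEM, speed±SEM) ships as a
packaged fixture.

## Worked example

```python
import neutrotax as nt

# pin the simulator to the strongest clinical responder's C.I. (0.533)
copd = [r for r in nt.load_table1() if r.group == "COPD"]
kappa = nt.calibrate_kappa(copd[0].ci_mean)          # -> 1.2668
mot = nt.MotilityParams(kappa=kappa, mean_step_speed=copd[0].speed_mean)

cfg = nt.AssayConfig()                               # 350 µm channel, 10 s, 120 frames
tracks = nt.simulate_tracks(500, mot, cfg, seed=1)
s = nt.summarize_condition(tracks, cfg.gradient_axis)
print(f"C.I. {s.mean_ci:.3f} ± {s.sem_ci:.3f}, speed {s.mean_speed:.3f} µm/s")

scan = nt.leave_one_out_scan(copd)
best = scan[0]
print(f"exclude {best.excluded_id}: slope {best.slope:+.5f}, r² {best.r_squared:.3f}")
```

prints

```
C.I. 0.536 ± 0.003, speed 0.129 µm/s
exclude COPD3: slope -0.00595, r² 0.948
```

— the 500-track mean C.I. recovers the 0.533 calibration target (the
±0.003 is the SEM over tracks; the small excess is the known finite-track
ratio bias), the mean speed matches the subject's 0.129 µm/s, and the
leave-one-out scan finds that dropping the youngest subject leaves four
patients whose C.I. falls steeply with FEV1/FVC (r² = 0.948), while all
five together give only r² = 0.341.

## Analysis drivers

Numbered scripts under `analysis/` run the study end to end and write
tables to `results/`:

1. `01_gradient_profile.py` — cross-channel profiles and establishment times
2. `02_condition_metrics.py` — single/competing/uniform attractant panel
3. `03_morphology_conditions.py` — closed-loop aspect-ratio recovery
4. `04_tracking_validation.py` — render → detect → link vs ground truth
5. `05_cohort_stats.py` — clinical-table and synthetic-cohort statistics

A thin CLI wraps the same library: `neutrotax simulate | analyze | stats |
run-all`.

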
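"""Simulate the chemoattractant-condition panel and quantify migration.

Builds the single, competing, and uniform attractant layouts (fMLP-type
terminal peptide vs IL-8-type intermediate chemokine vs sputum), derives
each condition's effective directional bias from the dominance rules,
simulates 100 tracks per condition, and summarizes C.I. and speed.
Writes results/condition_metrics.tsv.
"""

from pathlib import Path

import pandas as pd

from neutrotax import (
    AssayConfig,
    Attractant,
    ConditionSpec,
    MotilityParams,
    simulate_tracks,
    summarize_condition,
)

# relative potencies (kappa each attractant would induce alone)
FMLP10 = Attractant("fMLP-10nM", family="terminal", potency=1.1)
FMLP100 = Attractant("fMLP-100nM", family="terminal", potency=2.0)
IL8 = Attractant("IL-8-10nM", family="intermediate", potency=1.0)
COPD_SPUTUM = Attractant("COPD-sputum", family="intermediate", potency=0.9)
CTRL_SPUTUM = Attractant("control-sputum", family="intermediate", potency=0.5)

CONDITIONS = [
    ConditionSpec("il8_gradient", top_attractant=IL8),
    ConditionSpec("fmlp10_gradient", top_attractant=FMLP10),
    ConditionSpec("fmlp100_gradient", top_attractant=FMLP100),
    ConditionSpec("il8_top_vs_fmlp10_bottom", top_attractant=IL8, bottom_attractant=FMLP10),
    ConditionSpec("il8_top_vs_fmlp100_bottom", top_attractant=IL8, bottom_attractant=FMLP100),
    ConditionSpec("copd_sputum_gradient", top_attractant=COPD_SPUTUM),
    ConditionSpec("control_sputum_gradient", top_attractant=CTRL_SPUTUM),
    ConditionSpec("copd_sputum_vs_fmlp10", top_attractant=COPD_SPUTUM,
                  bottom_attractant=FMLP10),
    ConditionSpec("uniform_il8", top_attractant=IL8, bottom_attractant=IL8),
    ConditionSpec("medium"),
]

out = Path("results")
out.mkdir(exist_ok=True)
cfg = AssayConfig()
rows = []
for i, cond in enumerate(CONDITIONS):
    mot = MotilityParams(kappa=cond.effective_kappa, mean_step_speed=0.17)
    axis = tuple(cond.bias_sign * a for a in cfg.gradient_axis) if cond.bias_sign else None
    # seed on the side the cells will migrate away from, so wall reflections
    # do not clip the drift
    w = cfg.geometry.width
    y_region = (0.05 * w, 0.5 * w) if cond.bias_sign < 0 else (0.5 * w, 0.95 * w)
    tracks = simulate_tracks(100, mot, cfg, seed=200 + i, bias_direction=axis,
                             start_region=((100.0, 900.0), y_region),
                             condition_label=cond.label)
    # C.I. is measured along the up-gradient (toward-top) axis, so a
    # bottom-dominated condition shows up as a negative mean C.I.
    s = summarize_condition(tracks, cfg.gradient_axis, label=cond.label)
    rows.append(dict(condition=cond.label, bias_sign=cond.bias_sign,
                     effective_kappa=round(cond.effective_kappa, 3),
                     mean_ci=round(s.mean_ci, 4), sem_ci=round(s.sem_ci, 4),
                     mean_speed=round(s.mean_speed, 4), sem_speed=round(s.sem_speed, 4),
                     n_tracks=s.n_tracks))
    print(f"{cond.label:32s} sign {cond.bias_sign:+d} kappa {cond.effective_kappa:5.2f} "
          f"C.I. {s.mean_ci:+.3f} ± {s.sem_ci:.3f}  v {s.mean_speed:.3f} µm/s")

pd.DataFrame(rows).to_csv(out / "condition_metrics.tsv", sep="\t", index=False)
print("\nSingle gradients produce strong positive C.I.; competing layouts are "
      "dominated by the terminal peptide (sign follows fMLP, dose-dependently "
      "weakened by the competitor); uniform fields and plain medium give "
      "C.I. near zero at unchanged speed.")
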
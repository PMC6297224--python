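# rpospulse

Single-cell simulation and trace analysis of pulsatile RpoS stress-response
dynamics in *E. coli*.

Exponentially growing bacterial populations keep a minority of cells in a
transient, slow-growing, high-RpoS state.  Because the general-stress sigma
factor σ^S (RpoS) represses growth while growth dilutes RpoS, the two form
a mutual-inhibition loop whose molecular noise produces rare,
multi-generation RpoS pulses — a bet-hedging mechanism that lets those
cells survive sudden insults such as an H₂O₂ pulse.  This package provides,
for people studying such dynamics in mother-machine or time-lapse data:

* **`rpospulse.cellsim`** — a hybrid simulator: exact Gillespie SSA for
  RpoS (*r*) and a growth factor (*γ*) inside a deterministically growing,
  adder-dividing cell, with growth rate read out from concentrations via

      g = g_max · [1/(1+(h_γ/[γ])^{n_γ})] · [(1−f)/(1+(h_r/[r])^{n_r}) + f],

  n_γ > 0, n_r < 0, plus in-silico knockout and g_max sweeps under
  constant- or reduced-efficacy models (f·g_max held constant).
* **`rpospulse.traces`** — the per-lineage estimators: relative growth rate
  g ~ (l_{t+1}−l_t)/(Δt·l_t) with artefact correction and 5-frame
  smoothing; promoter activity A = M(g+p) + dM/dt (dilution- and
  bleaching-corrected reporter production per unit length); pulse detection
  (smoothed local maxima, 7-frame unsmoothed window heights); normalized
  cross-correlation; the cycle-time mixture solver Σ n_i 2^{t_D/c_i} = 2;
  low-growth events below a threshold and their duration distribution.
* **`rpospulse.synthetic`** — a forward observation model (reporter ODE,
  frame downsampling, lognormal measurement noise, survival cohorts, OD
  series, CFU plate counts) so every estimator is testable against known
  ground truth.
* **`rpospulse.survival`** — ROC/AUC/optimal-threshold survival
  classification, CFU survival fractions with the 30–300 colony filter,
  OD growth fits, and the simulation-to-data scaling fit.
* **`rpospulse.io` / the `rpospulse` CLI** — delimited-text schemas for all
  tables, YAML configs, run manifests, and subcommands
  `simulate | ensemble | sweep | synth | analyze | roc | cfu | scalefit`.

The numbered scripts under `analysis/` run the study end-to-end:
simulate ensembles with/without feedback, pulse and low-growth-event
statistics, the efficacy sweep, the synthetic survival/ROC assay, and the
bulk assays.

## Worked example

```python
import numpy as np
from rpospulse import SimParams, knockout_params
from rpospulse.pipelines import ensemble_stats

p = SimParams()                    # calibrated fast-growth condition
wt = ensemble_stats(p, 100, master_seed := 42)
ko = ensemble_stats(knockout_params(p), 100, master_seed)
print(f"WT : mean g {wt.mean_growth:.2f}/h, lag-0 corr {wt.lag0_corr_mean:+.2f}, "
      f"events/h {wt.events_per_hour:.2f}")
print(f"KO : mean g {ko.mean_growth:.2f}/h, lag-0 corr {ko.lag0_corr_mean:+.2f}, "
      f"events/h {ko.events_per_hour:.2f}")
print(f"P(event >= 2 h): WT {np.mean(wt.event_durations_h >= 2):.3f}, "
      f"KO {np.mean(ko.event_durations_h >= 2):.3f}")
```

prints

```
WT : mean g 0.91/h, lag-0 corr -0.81, events/h 0.59
KO : mean g 1.15/h, lag-0 corr -0.05, events/h 0.24
P(event >= 2 h): WT 0.061, KO 0.000
```

With the feedback intact, growth and RpoS concentration are strongly
anti-correlated, the mean growth rate drops, and episodes of growth below
the survival-predictive threshold (0.71/h) are both more frequent and far
longer-lived; removing the feedback (the in-silico ΔrpoS) erases the
correlation and the long-duration tail.  That long tail is the mechanistic
link between RpoS pulses and stress survival: slow cells are the ones that
live through an insult, as the ROC analysis on synthetic cohorts shows
(growth rate before stress classifies survival with AUC ≈ 0.9).

Or from the shell:

```sh
rpospulse simulate --config configs/fast_growth.yaml --out lineage.tsv
rpospulse synth --config configs/fast_growth.yaml -n 20 --out frames.tsv
rpospulse analyze frames.tsv --threshold 0.71 --out-dir out/
```

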
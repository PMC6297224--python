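# Methods

## The model

`rpospulse` simulates one rod-shaped *E. coli* cell tracked over many
generations, as in a mother-machine microfluidic experiment where a single
daughter is kept at each division.  Two molecular species live inside the
cell:

* **r** — RpoS (σ^S), the general-stress sigma factor;
* **γ** — a "growth factor" standing in for σ^70-driven growth capacity.

Both follow zeroth-order production and first-order degradation,

    0 →(k_rp) r,   r →(k_rd) 0,   0 →(k_γp) γ,   γ →(k_γd) 0,

simulated with an exact Gillespie SSA between deterministic growth steps.
Because the reactions are zeroth/first order their propensities do not
depend on cell volume.  Cell length follows the discrete recursion

    Δl_i = g_{i−1} · Δt · l_{i−1},

and division obeys the **adder rule**: once the length added since the last
division reaches ΔL, the length is halved and both molecule counts are
floor-halved (`⌊n/2⌋`; for odd counts one molecule is lost, never gained).
Concentrations are counts divided by the previous step's length, and the
growth rate is read out from them through a product of Hill functions:

    g = g_max · [ 1 / (1 + (h_γ/[γ])^{n_γ}) ]
              · [ (1−f) / (1 + (h_r/[r])^{n_r}) + f ],

with n_γ > 0 (activation) and n_r < 0 (repression).  This closes a
mutual-inhibition loop: growth dilutes RpoS, RpoS represses growth.  An
upward RpoS fluctuation slows growth, which slows dilution and lets RpoS
stay high — producing rare, multi-generation RpoS pulses accompanied by
low-growth episodes, while the knockout (repressive factor pinned to 1)
shows neither.

### Step ordering and conventions

The printed formulas do not fix a unique within-step sequence; we use
SSA → concentrations (with the previous length) → growth rate → length
update (with the previous step's growth rate) → adder check.  The adder
comparison includes the current step's increment, so division fires at the
first step the accumulator reaches ΔL and overshoot is at most one
increment.  Zero concentrations are handled by limits (activating factor
→ 0, repressing factor → 1), so the Hill readout is defined everywhere and
bounded in [0, g_max].  Normalizing concentration by the *previous* length
is kept as printed in the source model even though it looks like an index
quirk; at Δt = 0.1 h the difference is O(gΔt) ≈ 1–2 %.

### Parameters

| parameter | default | meaning |
|---|---|---|
| k_rp, k_rd | 3 /h, 0.3 /h | RpoS production/degradation; the slow turnover (τ ≈ 3 h intrinsic) makes pulses span generations |
| k_γp, k_γd | 16 /h, 1 /h | growth-factor turnover; the low copy number (~10) makes growth intrinsically noisy, as seen in the knockout |
| g_max | 1.6 /h | maximum growth rate, fast-growth (37 °C-like) reference |
| f | 0.35 | residual growth fraction at saturating RpoS |
| h_γ, n_γ | 3, +2 | activation midpoint/steepness |
| h_r, n_r | 2, −4 | repression midpoint/steepness |
| Δt | 0.1 h | deterministic growth step |
| ΔL, l0 | 1, 1 | adder increment and initial length (lengths live in [1, 2]) |
| t_total, t_burnin | 500 h, 250 h | run length; the first half is discarded from analyses |

The published study tabulates its simulation constants in supplementary
material not distributed with the article text, so the defaults here were
calibrated once, by hand, against the *described* behaviour: a broad
wild-type growth distribution (sampled mean ≈ 0.9/h, SD ≈ 0.29) with a
pronounced low-growth tail that vanishes in the knockout (mean ≈ 1.15/h);
strongly negative lag-0 growth↔[RpoS] correlation (≈ −0.8) with feedback
and |corr| < 0.1 without; and the efficacy-sweep trends below.  Absolute
pulse/event counts were never calibration targets, so the totals this
package computes differ from the published ones while reproducing every
ordering and trend.  f = 0.35 is higher than a naive reading of "residual
growth" might suggest; it is needed for the reduced-efficacy gap to close
monotonically from the fast-growth reference (with small f, the rising
Hill occupancy at lower g_max initially outweighs the flattening of the
repressive curve).

Initial counts default to the no-dilution stationary means (r0 = k_rp/k_rd,
γ0 = k_γp/k_γd) and l0 = ΔL; the mandatory burn-in makes initial conditions
irrelevant to every analysis path.  Per-lineage RNG seeds derive from the
master seed by a counter-based scheme (`SeedSequence(master, spawn_key)`),
so ensembles are bit-reproducible and order-independent.

## Efficacy modes

Growth-rate perturbations (poorer media, lower temperature) are modelled by
lowering g_max.  Two hypotheses about RpoS's potency at slow growth:

* **constant** efficacy — f fixed; RpoS's maximal repressive effect scales
  with g_max;
* **reduced** efficacy — f raised to keep f·g_max at its fast-growth value
  (capped at 1), flattening the repressive Hill curve.

Under reduced efficacy the wild-type/knockout mean-growth gap shrinks
monotonically as g_max falls (vanishing near g_max ≈ f_ref·g_ref/1);
under constant efficacy it persists or widens.  Mean [RpoS] rises as
growth slows in both modes (less dilution).

## Trace analysis

All estimators operate on per-frame observables (time, length *l*, mean
fluorescence *M*) at a uniform frame interval (10 min for experimental-style
data; the simulation grid for simulated traces).

* **Growth rate**: g ~ (l_{t+1} − l_t)/(Δt·l_t).  Frame pairs spanning a
  division are excluded (mother-cell halving is physiology, not shrinkage)
  and, like negative raw values from segmentation-style artefacts, replaced
  by the mean of the nearest non-negative valid frames; the series is then
  smoothed with a centered 5-frame moving average (shrinking symmetric
  windows at the ends, MATLAB-`smooth` style).
* **Promoter activity**: A = M_s(g + p) + dM_s/dt with M_s the 5-frame
  smoothed mean fluorescence, dM_s/dt its forward difference, g the
  unsmoothed corrected growth rate, and p = 0.1/h the lumped
  bleaching/degradation constant.  `activity_p_sensitivity` recomputes A at
  p ∈ {0.05, 0.2}; conclusions must not depend on the choice.
* **Pulses**: local maxima of the 5-frame-smoothed activity (strictly
  greater than neighbours; a plateau's first frame wins; endpoints never
  qualify), each scored by the maximum of the *unsmoothed* series in a
  7-frame window centered on it.  Heights are absolute values — no baseline
  subtraction, no prominence filter.
* **Cross-correlation**: mean-subtracted cross-covariance normalized by
  √(c_xx(0)·c_yy(0)) (the `xcov 'coeff'` convention); positive lag means
  growth shifted later than activity.  Across lineages, per-lineage curves
  are averaged and reported with their SD.
* **Population growth rate**: the cycle-time mixture equation
  Σ_i n_i·2^{t_D/c_i} = 2 is solved for t_D by Brent's method on [0, max c]
  (the left side is strictly increasing, 1 at t=0 and ≥2 at max c, so the
  root is bracketed); g_pop = ln2/t_D, solved to 1e-14 tolerance.
* **Low-growth events**: maximal runs of frames with g < 0.71/h (the
  ROC-optimal survival threshold); runs touching a trace boundary are kept
  but flagged censored.  The duration distribution is reported as the
  complementary cumulative fraction P(duration ≥ d) — chosen so "more long
  events" reads as a heavier tail — with the orientation switchable.

An extra display-only smoothing pass exists (`display_smooth`) and is never
used by any statistic.

## Synthetic observations

The generator turns ground-truth histories into the observables above, so
every estimator can be tested against known answers.  The reporter obeys
dF/dt = a·l − p·F with a the *per-length* activity (total production is
extensive in cell size), integrated by forward Euler on the lineage grid —
deliberately the same discretization the estimator's forward differences
assume, which makes the inverse exact at discrete steady state and O(Δt)
for slowly varying activity.  At divisions F halves with the length, so M
is continuous.  Frames are downsampled (the frame interval must be a whole
number of simulation steps) and length and M receive independent
multiplicative lognormal noise; the study's measurement-noise model is not
stated, so lognormal (scale-free, positive) was chosen.  Survival cohorts
draw Bernoulli labels from a rule (logistic/step/constant) evaluated on
pre-stress observables; OD series are exponentials with lognormal noise;
CFU plates draw Poisson counts from density × plated volume / dilution.

What the generator does **not** emulate: segmentation/tracking failures
beyond simple noise, cell-to-cell parameter variation, reporter maturation
delays, or stress-induced RpoS activation during the insult itself.
Passing tests therefore validate the estimators' correctness and the
model's internal logic, not quantitative agreement with any particular
experimental dataset.

## Survival statistics

ROC curves sweep all distinct classifier values plus ±∞ sentinels; a cell
passes a threshold when its value is strictly below it (growth) or strictly
above it (activity) — the strict/non-strict choice is not dictated by the
source definitions and is fixed and documented here.  TPR and FPR are the
fractions of surviving/non-surviving cells past the threshold; AUC is the
trapezoidal integral; the optimal threshold maximizes TPR − FPR with ties
broken toward the less permissive threshold.  CFU survival fractions
average cells/mL over plates with 30–300 colonies (inclusive) per arm and
divide stressed by control.  Bulk growth rates are log-linear least-squares
fits to OD.  The simulation-to-data scaling fit fits y = a·e^{b·g} to each
(g_pop, value) set and minimizes the RMS difference between s·sim_fit and
exp_fit over 1000 uniform grid points on [0.29, 1.6]/h; the minimizer is
the closed-form projection ⟨exp·sim⟩/⟨sim²⟩, so the grid only sets the
integration measure.

## Problem sizes and numerics

The SSA inner loop is numba-compiled; a full 1000-lineage, 500 h ensemble
reduces in ~5 s, so the acceptance script runs the complete protocol.
Unit and property tests use shorter lineages (30–200 h) and ensembles of
15–150, with statistical assertions at 3–4 SE.  The ensemble comparison
tests extrapolate 150-lineage totals to the 1000-lineage protocol using
per-lineage SEs.  Hypothesis-based property tests (ROC vs pairwise
Mann–Whitney oracle, cross-correlation vs brute-force summation, moving
average vs windowed means, mixture solver vs plain bisection) are bounded
to small n and run in seconds.

## Known limitations

* The simulation constants are this package's own calibration, not the
  published table; absolute pulse/event counts are therefore
  package-specific, while orderings and trends are reproduced.
* Concentration normalization by the previous length and the post-division
  concentration bookkeeping follow the printed model; at division steps the
  recorded concentration precedes the halving of counts.
* The activity estimator carries an O((gΔt)²) discretization bias at coarse
  frame intervals; at 10-min frames and g = 1.4/h this is ~5 %, inherent to
  the forward-difference definition rather than to this implementation.
* Only one daughter is followed; population-tree statistics and mechanistic
  sigma-factor competition are out of scope.
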
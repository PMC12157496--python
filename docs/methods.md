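# Model and methods

## The model

`astroabm` simulates the growth of a breast-cancer brain metastasis on a
2-D square lattice in which the decisive microenvironmental actors are
astrocytes. Each lattice site (nominally 25 µm across) holds at most one
agent: a tumor cell, an astrocyte, or an inert neutral filler. One timestep
represents about 17 hours — half the assumed 34-hour tumor doubling time —
so an unimpeded tumor cell divides with probability 0.5 per step. A run
starts from a single tumor cell at the grid center, astrocytes placed by a
configurable spatial layout, and no drug; the default run is a 300×300 grid
for 150 steps (~3.5 months).

### Influence kernel

All cell–cell interactions are local and distance-decayed. An agent at
Euclidean lattice distance *d* contributes the weight

    w(d) = 1 / (1 + exp(S·(d − d_half)))

with steepness `S = 3` and half-maximal distance `d_half = 1.5`, summed
over the 7×7 neighborhood (48 non-center sites, a 3-cell radius). The
kernel's unit-magnitude sum `I_max ≈ 7.2348` is computed from the kernel
itself, never hard-coded, so non-default `S`/`d_half` stay consistent.
Neighborhoods are truncated at grid edges while the normalizer keeps its
full-neighborhood value: edge cells simply experience less influence, since
the normalizer is defined as a single theoretical maximum.

### Astrocyte reprogramming

Astrocytes start anti-metastatic. Each step, every anti-astrocyte
accumulates tumor influence `I = Σ κ·w(d_i)` over tumor cells in its
neighborhood, normalized by `κ·I_max` to `I_norm ∈ [0, 1]`, and switches
irreversibly to the pro-metastatic state with probability

    P_switch = 1 / (1 + exp(−S_A·(I_norm − θ)))

`θ` (conversion threshold) is the normalized influence at which switching
is a coin flip; `S_A ∈ {8, 16, 32}` sets the sharpness. The switch is
evaluated with one uniform draw per astrocyte in a freshly shuffled order
from the run's single RNG stream. Because only tumor cells contribute
influence, switches within a pass cannot affect one another, and the
vectorized evaluation used internally is exactly equivalent to the
sequential scheme. Note `P_switch > 0` even at zero influence, which is why
"no reprogramming" is a hard configuration flag rather than an extreme
parameter value.

### Tumor division

Each tumor cell sums signed astrocyte influence: `−α·w(d)` per
anti-astrocyte and `+β·w(d)` per pro-astrocyte, same kernel for both signs.
The sum is normalized by `max(α, β)·I_max` — the largest achievable
single-sign magnitude, which guarantees `I_norm ∈ [−1, 1]`; when
`α = β = 0` the normalized influence is 0 by contract. (An alternative
normalizer, `(α + β)·I_max`, would also bound the range; the max
convention is isolated in `normalize_tumor_influence` for easy revision.)
Division fires when a uniform draw falls below

    P_div = 1 / (1 + exp(−S_T·I_norm))

which is exactly 0.5 at zero influence. The daughter occupies a uniformly
random empty site of the parent's 3×3 Moore neighborhood; with no empty
neighbor the division silently fails (contact inhibition). The probability
draw is consumed before the crowding check, keeping the RNG stream
independent of occupancy. Astrocyte-mediated suppression acts only through
reduced proliferation — there is no astrocyte-induced death channel.

### Update scheme

Per step: (1) drug-field update if treatment is active; (2) one shuffled
pass over anti-astrocytes (switching); (3) one shuffled pass over tumor
cells, each cell checked for chemotherapy death *before* its division
attempt (a cell killed this step cannot divide this step, since the drug
acts on current exposure). Passes read the live grid: a daughter placed
earlier in the pass blocks later placements, the standard sequential-update
convention. The division-probability field is evaluated once per step by
convolution because astrocyte states are frozen during the tumor pass.

### Chemotherapy

The drug obeys `∂C/∂t = D_c∇²C − decay`, advanced by a Peaceman–Rachford
ADI step (unconditionally stable; one step per timestep, with an optional
substep size for convergence studies). The discrete decay/uptake update is
authoritative: after diffusion, every site is multiplied by the retention
factor λ, and tumor-occupied sites lose a further fixed fraction of the
post-decay value (the order diffuse → decay → uptake is a deliberate
choice, isolated in one function). During dosing the boundary ring is held
at `C_b` (Dirichlet influx); between doses the boundary is zero-flux, using
a copied-ghost stencil that conserves mass to solver precision, and
outflowed drug never re-enters.

Treatment triggers the first time the tumor count *reaches* the threshold
(default 3,000 cells, ~1–1.5 mm lesion) and then cycles forever: 14 dosing
steps, 7 rest steps. Cycles are counted in timesteps exactly as specified
even though a timestep is 17 h rather than a day; the "21-day cycle" is
therefore a 21-step cycle in model time.

A tumor cell with `N_pro` pro-metastatic astrocytes among its 8 Moore
neighbors senses the gap-junction-modulated concentration
`C_eff = C·(1 − G_f·N_pro/8)` and dies with probability
`1/(1 + exp(−k·(C_eff − T)))`. With `G_f = 1` and a fully pro-metastatic
Moore ring the blockade is complete and the kill probability drops to the
drug-independent floor `1/(1 + e^{kT})`. Astrocytes and neutral agents are
never affected by drug. Kill probability is memoryless in dose — uptake
does not accumulate into the kill decision.

### Density control and layouts

The non-tumor compartment (astrocytes + neutrals) is fixed at
`non_tumor_total` sites (45,000 = 50% of the default grid) at every
astrocyte density, so density effects are not confounded by crowding;
neutral agents are inert placeholders that block placement but enter no
probability. Six layouts are provided: uniform (even lattice, trimmed or
topped up to the exact count), random, clustered (Gaussian aggregates of
spread 8 sites around 25 uniformly placed seeds — both exposed in
`LayoutParams`), radial and inverse-radial (linear ramp in normalized
distance to center, decreasing resp. increasing), and gradient (linear
horizontal ramp). Weighted placements sample without replacement via
Efraimidis–Spirakis keys; every layout places the exact requested count and
reserves the central site for the initial tumor cell. Radial profile shape
(linear rather than exponential) is a design choice; a small floor weight
(0.01) keeps every site reachable.

### Morphometrics

The tumor *front* is every tumor cell with at least one EMPTY site in its
3×3 Moore neighborhood (off-grid is not empty; a cell walled in by
astrocytes or neutrals is interior). Fractal dimension and lacunarity are
computed on the bounding-box-cropped front; eccentricity on the bulk tumor.

* **Fractal dimension**: box counting over non-overlapping grids anchored
  at the bounding-box origin, box sizes in powers of two from 2 up to half
  the bounding-box side, requiring at least three scales (otherwise the
  metric is reported as missing, NaN, never as 0). The dimension is minus
  the least-squares slope of log N(ε) on log ε. Partial boxes at the far
  edges count if occupied.
* **Lacunarity**: for each window size ε, the region is partitioned into
  non-overlapping ε×ε windows (partial edge windows included) and
  Λ(ε) = σ²/μ² of the per-window occupied counts — the ratio form exactly
  as defined, not the `1 + σ²/μ²` variant found elsewhere in the
  literature, so a fully occupied region has Λ = 0. The reported scalar is
  the arithmetic mean of Λ(ε) over the scale set; per-scale values are
  exported so the aggregation convention can be revisited.
* **Eccentricity**: `E = 1 − λ₂/λ₁` of the population-normalized coordinate
  covariance eigenvalues (λ₁ ≥ λ₂); 0 for round masses, 1 for collinear
  ones; a degenerate single-cell mass reports 0 by contract.
* **Residualization**: for replicate ensembles, each metric can be
  residualized on tumor count per time step by ordinary least squares
  (≥3 replicates), separating shape effects from size effects.

### Sensitivity harness

Parameter sets are drawn from a scrambled Sobol sequence (scipy's
implementation) over α, β, θ, κ ∈ [0, 1] and the discrete sensitivities
S_A ∈ {8, 16, 32}, S_T ∈ {4, 8, 16} mapped by equal-probability binning.
PRCC is computed as the Pearson correlation of rank residuals: all columns
rank-transformed, each parameter and the output regressed on the remaining
parameters, residuals correlated. Regime stratification ranks parameter
sets by mean final tumor count and splits them into tertiles — Inhibitory,
Neutral, Promoting — with ties broken by stable sample index; labels are
meant to transfer unchanged when the same sets are re-run under other
densities or layouts. Replicate seeds derive from one master seed through
`numpy` SeedSequence spawn keys `(sample, replicate)` and are recorded for
exact replay.

Five experiment designs are packaged: switching comparison, global
sensitivity, density sweep (0, 12.5, 25, 37.5, 50%), layout sweep (six
layouts at 30%), and chemotherapy comparison (G_f ∈ {0, 0.5, 1} ×
switching on/off). Group statistics (Mann–Whitney, Kruskal–Wallis) come
from scipy as supporting output. The full-scale design is n = 1000 samples
× 10 replicates on the 300×300 grid; the default `ci` scale is n = 64 × 3
on a 100×100 grid for 60 steps, chosen as a faithful desk-scale rendition
of the same designs.

## Parameter defaults and stand-ins

The interaction ranges (Table-style bounds 0–1 for α, β, θ, κ; discrete
S_A, S_T levels) and the structural constants (S = 3, d_half = 1.5, 7×7
neighborhood, 45,000 non-tumor agents, threshold 3,000, 14/7 schedule) are
fixed by the model definition. The *numeric* chemotherapy constants and the
fixed "pro-metastatic regime" parameter set are not part of the model
definition available here; the shipped defaults are documented stand-ins
chosen once for qualitative realism:

| parameter | default | rationale |
|---|---|---|
| α (effect_anti_met) | 0.5 | moderate suppression |
| β (effect_pro_met) | 0.9 | strong promotion (pro-metastatic regime) |
| θ (conversion_threshold) | 0.2 | reprogramming achievable at a growing front |
| κ (effect_per_tumor_cell) | 0.8 | strong per-cell signal |
| S_A, S_T | 16, 8 | middle discrete levels |
| D_c | 100 lattice²/step | boundary-to-core penetration on the 300×300 grid within a treatment cycle |
| λ (retention) | 0.98/step | slow decay; drug persists across the rest phase |
| C_b | 1.0 | concentration unit definition |
| uptake fraction | 0.02 | small per-cell sink |
| k, T | 10, 0.5 | near-certain kill at full dose, negligible (~7·10⁻³/step) at zero |
| G_f | 0.5 | midpoint of the explored {0, 0.5, 1} |

`experiments.scaled_chemo_params` rescales the trigger threshold with grid
area and the diffusion coefficient with squared linear size so the same
qualitative treatment scenario holds on smaller lattices.

Under these stand-ins the simulator reproduces the model's directional
findings — reprogramming raises final burden, higher G_f raises
post-treatment survival, θ and α carry negative PRCC on burden,
inverse-radial layouts grow the largest and radial the smallest tumors —
but the absolute headline numbers tied to the original constants are not
expected to match, and the test suite asserts directions, not those
magnitudes.

## Numerical and degenerate-input choices

* RNG: one `numpy` PCG64 generator per run, seeded from the config;
  identical config + seed gives bit-identical trajectories.
* ADI: half-step diffusion number r = D·dt/2 with dx = 1; Dirichlet solves
  operate on the interior with the boundary ring clamped; Neumann solves
  use the first-order copied-ghost operator whose column sums vanish,
  making zero-flux mass conservation exact. Negative undershoot is clamped
  at 0; non-finite fields raise.
* Influence normalization clamps tiny floating overshoot into [0, 1] /
  [−1, 1] but raises if raw influence exceeds the theoretical maximum
  beyond tolerance (an internal-consistency guard).
* Empty morphometric masks report NaN ("missing"), never 0; tiny masks
  with fewer than three box-counting scales likewise.
* Treatment trigger uses ≥ (the count *reaching* the threshold starts
  therapy).

## What the desk-scale conditions do and do not show

Desk-scale runs (50–100-site grids, 20–80 steps, 3–5 replicates) preserve
the model's mechanisms — the kernel, both sigmoidal laws, the scheduler,
the crowding control — and its directional behavior, and the acceptance
tests assert exactly that. They do not reproduce quantities that depend on
the full 300×300/150-step scale (absolute final counts, lacunarity
magnitudes), and none of the synthetic conditions include vasculature,
immune cells, tumor migration or death channels other than chemotherapy,
3-D structure, or pharmacokinetics beyond the single diffusing species —
all outside the model's scope.

## Known limitations

* The chemotherapy constants are stand-ins (above); absolute treated-run
  magnitudes are parameterization-dependent.
* Lacunarity with partial edge windows slightly inflates variance for
  regions not divisible by the window size; the per-scale export allows
  any alternative aggregation.
* The discrete "day = timestep" schedule convention understates cycle
  duration in wall-clock terms (17 h per step).
* Pro-metastatic astrocytes influence tumor cells but not other
  astrocytes' switching; only tumor cells drive reprogramming.
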
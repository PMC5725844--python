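# Methods

## Model overview

`scratchsim` is an agent-based (rule-based) model of a 2-D scratch assay:
a near-confluent monolayer of tumor cells is "scratched", and the cells at
the freshly cut edge — the cells a tracking experiment follows — shed a
stimulatory ligand (the L1CAM ectodomain) that frees them from
intercellular adhesion and stimulates their own motility and proliferation
through two receptor pathways (integrin, FGFR) converging at FAK.

The model's core assumptions, mirrored from the in-vitro system it
emulates (T98G glioblastoma cells):

* no cell death; all cells are identical in size/shape and express the
  ligand precursor constitutively;
* monolayer cells are confined by crowding (and optionally by explicit
  adhesion springs) and do not pile up;
* edge cells shed the ligand; cells that migrate past the scratch line
  start shedding (blue → red) and keep shedding while they have open space
  ahead;
* shed ligand saturates the shedding cell's own receptors: stimulation is
  binary per pathway and cells do **not** chemotax up ligand gradients —
  the ligand agents are visual/accounting entities only;
* migration is directed toward open space near the monolayer and becomes
  random in the open field.

Space is a bounded, non-wrapping 65×33 patch grid; 1 patch = 20 μm
(≈ one cell diameter; both configurable). Time: 1 tick = 1 simulated
minute, 60 ticks = 1 h. Runs are fully determined by the parameter set
including its RNG seed.

## Signaling and motility

Each pathway is linearly inhibitable by a user fraction i ∈ [0, 1]. The
deliverable rate of the integrin arm interpolates from the uninhibited
rate u (default 0.23 μm/min) down to `base_motility_A` (0.15) as the
*FGFR* arm is inhibited — `base_motility_A` is by definition the motility
observed with pathway B fully blocked — and symmetrically for the FGFR
arm (`base_motility_B` = 0.13). The FAK cap interpolates with its own
inhibition down to `base_motility_C`. The converged motility is the
minimum of the three deliverable rates, which reproduces all four
endpoint behaviors: 0.23 uninhibited, 0.15 with B blocked, 0.13 with A
blocked, and `base_motility_C` with C blocked regardless of the upstream
arms. (The `pct_decrease_*` controls are an equivalent parameterization,
`base = u·(1 − pct/100)`; exactly one form is active per pathway.)

Per-cell variability: each cell carries two arm deviations, redrawn with
probability 1/2 per tick uniformly from ±`deviation_from_avg` (default
0.3 μm/min, chosen to match the visual spread of experimental velocity
traces). The cell's motility is the converged center plus the mean of its
two arm deviations — symmetric about the center, so the population mean
equals the configured rate exactly, which is what makes the reported
average recover the configured value at any sampling interval. The
signaling value may dip below zero when the deviation is large relative to
an inhibited center (the reported average then shows occasional negative
excursions once the deviation exceeds ≈ 0.5 under full inhibition);
the kinematic step length is floored at zero separately, and the
`motility_check` switch clamps the *reported* value at zero.

## Movement

Per cell per tick, in order: (1) if the patch behind (west) holds more
than two cells, step east; (2) else with probability `randomness`
(default 0.1) step in a uniformly random direction; (3) else step toward
the least-crowded open Moore-neighbor patch (counts below the crowding
threshold of 2 cells/patch; ties broken uniformly at random); with no
open neighbor the cell is stationary. Step length is √2·μ·dt patch units;
the default dt = 1/(√2·`patch_scale`) makes the physical per-tick
displacement equal μ μm, i.e. speeds are honest μm/min. Walls are
impassable on three sides; a cell reaching the rightmost column ends the
run early.

## Cell cycle and proliferation

The uninhibited cycle spans the doubling time (default 24 h = 1440
ticks): M is fixed at 5% of it (a typical mitosis fraction; the source
interface does not specify one), S occupies `pct_S_base`% (default 28),
and the remainder splits evenly between G1 and G2 (rounding remainder to
G1). Inhibition stretches the whole cycle by the proliferation factor
1/max(1 − ī, 0.05) (ī = mean inhibition; the 0.05 floor avoids division
by zero and makes full inhibition a 20× longer cycle rather than an
infinite one). The S-phase share interpolates linearly to
`pct_S_max_inhibition`% (default 8) of the stretched cycle; the S change
is absorbed by G1 when `s_phase_to_g1` is on (default), else by G2, the
other phase keeping its proportionally stretched length. Phase boundaries
are computed in real ticks and rounded half-up; durations always sum
exactly to the cycle length.

Cells start at a uniform-random point of the cycle, so expected phase
occupancy is proportional to phase duration (hence ≈ 28% in S uninhibited,
≈ 8% fully inhibited). On completing M a cell divides: the daughter lands
on a uniformly chosen open neighbor patch (division is skipped if none is
open), inherits the parent's released state, takes the lighter color
variant of the parent's lineage, is never added to the tracked cohort,
and both cells restart the cycle at zero.

## Ligand agents and adhesion

Newly released cells hatch 4 ligand molecules; released cells past the
line with a clear path ahead add 1–4 more with 5% probability per tick.
Ligands never decay (an optional `ligand_cap` guards memory in
pathological settings). Each tick a ligand steps randomly with probability
`l_randomness` (default 0.5 — the source gives no default; mid-scale
keeps both behaviors visible) or toward the neighbor patch with most
cells, at `ligand_speed` = 0.25 patch units/tick, which keeps molecules
clustered around the cells that shed them.

With `cellular_adhesion` on, unreleased cells within 1.5 patches are
linked by springs (rest length 1 patch, spring constant 0.2 per tick —
the source names the layout-spring mechanism but no constants). Springs
displace cells along their net Hooke restoring vectors, capped at the
cell's per-tick step; link displacements are pairwise equal and opposite.
Red cells that run into a crowded path ahead while adhesion is on revert
to blue and regain links on the next rebuild; green-lineage cells never
revert.

## Monitors

The reported average motility is the mean signaling motility μ of the
tracked cohort (the original scratch-edge cells; daughters excluded), not
a realized displacement — matching how the original interface plots it
and why its long-run mean equals the configured rate exactly. A separate
`realized_speed` column reports the cohort's mean per-tick displacement
in μm/min for users who want kinematic ground truth. `% in S-phase`
counts all cells. Frames (one per tick, tick 0 included), cohort trails
and the resolved parameter set export as CSV.

## Numerical and implementation choices

* All randomness flows through one seeded PCG64 generator in a fixed call
  order; frame series are bitwise reproducible.
* Patch membership is round-half-up of continuous coordinates; positions
  are clamped so they always round into the grid.
* All per-tick cell rules read the patch densities computed at the start
  of the tick, so per-cell updates are order-independent; they are applied
  simultaneously (vectorized). Mitosis placements, which interact through
  occupancy, are resolved sequentially in RNG-shuffled order against a
  live grid. Daughters participate in movement from their birth tick.
* Ties (least/most dense neighbor) are broken by adding a uniform [0, 1)
  key to integer counts — uniform among tied patches, order-preserving
  otherwise.
* Degenerate inputs: a cycle of ≤ 4 ticks or any phase under one tick is
  rejected; a scratch line at the left wall yields a valid zero-cell run
  (with a warning) that halts immediately via the extinction guard — the
  guard is defensive, since no rule removes cells.

## What the generator does and does not emulate

Synthetic runs reproduce the *rule-driven* statistics of the assay:
cohort motility means and their interval invariance, inhibition-scaled
S-phase occupancy, monotone migration suppression under FAK inhibition,
and adhesion confinement. They do not emulate measurement artifacts of
real tracking (segmentation error, lost tracks), heterogeneous cell sizes
or speeds, chemotactic gradients, 3-D invasion, or cell death — so
passing tests validate the model's internal consistency and its published
endpoint behaviors, not biological generality beyond them.

## Test problem sizes

The slower checks run the full default scenario (24 h, ≈ 950 → 1900
cells). The inhibition-monotonicity test uses ten seed-matched triplets
of 6 h runs (the displacement ordering is already unambiguous at 6 h),
and the adhesion comparison uses 120-tick seed-matched runs with the
scratch line at −20 (a smaller monolayer, as recommended for adhesion
runs). These sizes are the package's own choices for routine testing;
all scenarios scale up by raising `time_scale_hours`.

## Known limitations

* Strictly 2-D, single cell type, no death or senescence.
* Ligand agents are bookkeeping only; no concentration field or
  receptor-occupancy kinetics (inhibition enters as a linear scale).
* The min-convergence form is one consistent reading of a source that
  describes the convergence both as a maximum of upstream responses and
  as a minimum across pathways; the chosen form is the one that
  reproduces every quantitative endpoint.
* Adhesion-on runs with a large monolayer are markedly slower (link
  rebuilding dominates); shift the scratch line left to shrink the
  monolayer.
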
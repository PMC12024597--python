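# Methods

This note documents the models implemented in `rehabgait`, their
assumptions, the defaults and why they were chosen, and the limits of what
the synthetic-data experiments can show.

## 1. The rehabilitation network

### Structure

The network is layered by construction:

* **Observation roots** (binary, state 0 = good, 1 = poor): the 15 measured
  joint motions — hip flexion/extension (`B11`, `B12`),
  abduction/adduction (`B21`, `B22`), external/internal rotation
  (`B31`, `B32`); knee flexion (`B41`) and external/internal rotation
  (`B51`, `B52`); ankle flexion/extension (`B61`, `B62`),
  abduction/adduction (`B71`, `B72`), external/internal rotation
  (`B81`, `B82`).
* **Intermediates** (binary, recovered/injured): one per joint plane,
  `B1..B8`, each the child of its plane's motion pair; knee sagittal (`B4`)
  has the single parent `B41` because the knee is modelled as a
  one-degree-of-freedom sagittal joint.
* **Goals** (ternary): `P1` (hip: gait improvement / strength enhancement /
  flexibility restoration), `P2` (knee: coordination / strength /
  flexibility), `P3` (ankle: balance / motor ability / physical fitness),
  each conditioned directly on its joint's motion roots — the layout of the
  published tables.
* **Target** `E` (ternary: mild / moderate / severe repair), child of all
  eight intermediates.

The goal nodes do not feed `E` by default.  The source material lists the
goals among the observation layer but publishes no table for `E` given the
goals, so adding such edges would require inventing a CPT shape with no
anchor; the builder accepts `add_edges` overrides for users who want that
variant (the target CPT is then rebuilt over the extended parent set).

### Published vs default tables

The three goal CPTs are packaged verbatim (64, 8 and 64 rows; every row
sums to exactly 1.00 as printed).  The intermediate and target CPTs are not
published, so the defaults are deliberately simple and fully overridable:

* **Intermediates — leaky noisy-OR.**  Each poor parent independently
  drives its plane to "injured" with activation 0.8; a leak of 0.05 injures
  it regardless.  Noisy-OR is the canonical low-parameter choice for
  "any of these failures suffices" causal structure, and two numbers per
  node are easy to elicit or re-fit.
* **Target — weighted injured-count kernel.**  With
  `s = Σ w(Bi)·1[Bi = injured]` and `S = Σ w(Bi)`, the target distribution
  is a softmax of `−((s − c_k)/τ)²` over stage centers `c = (0, S/2, S)`
  with temperature `τ = S/4`.  An all-recovered configuration points to the
  mild scenario, an all-injured one to severe, with a smooth, monotone
  hand-over in between; centers and temperature are config keys.

Functional-impact weights default to 5 for the core sagittal planes (hip
`B1`, knee `B4`), 3 for the remaining planes (the secondary tier, e.g.
ankle coronal `B7`), and 1 for motion-level observation nodes (auxiliary
tier, e.g. hip abduction `B21`).  Only the three tier examples are fixed by
the source; the assignment of the unnamed planes to the middle tier is this
package's choice and is config-overridable.  Stage priority coefficients
are 0.8 / 0.6 / 0.4 for mild / moderate / severe.

### Inference

`query_posterior` is exact variable elimination over dense factors.  The
elimination order is min-fill with a lexicographic tie-break, so runs and
logs are bit-reproducible.  Evidence is applied by slicing factors before
elimination; a normalization constant of zero raises an inconsistency
error naming the evidence.  `enumerate_posterior` multiplies all node
factors into the full joint array and marginalizes — an independent oracle
capped at 10^7 joint states, used throughout the tests to cross-check the
elimination engine to 1e-12.

### Goal scoring

The source names the ingredients (weights, priorities, favourable-state
posteriors) but not their combination, so the score is a documented toolkit
convention:

    score(g) = priority(stage) × Σ_{n ∈ {g} ∪ parents(g)} w(n) · P(n = favourable)

with favourable = state index 0 (good / recovered / the first-listed goal
state).  Rankings sort descending with node-id tie-breaks.  Any alternative
combination can be computed directly from the returned posteriors.

### Dynamic updating

Beliefs are tracked per node across time slices of one training cycle
(20 min).  The transition matrix is re-estimated from consecutive pairs in
a FIFO window of discretized observations with additive smoothing
(`T[i,j] ∝ c_ij + α`), then the belief advances as `T'b` and hard evidence
for the new slice collapses it.  Defaults: window 5 slices, pseudocount
α = 1.  The window length trades responsiveness against estimator variance;
five cycles keeps the estimate reactive within a single session, and the
unit pseudocount guarantees a defined estimate from the first slice.  An
empty window with α = 0 raises a degenerate-estimate error rather than
guessing.  The recovery test (200 slices from a known 2-state chain,
full-length window) bounds the estimation error at 0.05 per entry.

## 2. Mechanism kinematics

### Frames, units, conventions

Millimetres throughout; angles elsewhere in the toolkit are degrees.  The
fixed frame has Z up, X along the fixed platform's horizontal bar, Y
right-handed.  The device hangs below its rails: working poses have
`Pz < 0`, and the forward solver always takes the negative Pz root.

### Closed forms

Solving the three right-triangle constraints `|MiCi|² + |CiBi|² = |MiBi|²`
gives the passive coupling `d1 = d2 = Py`, `d3 = Px` and the push-rod
lengths of the README.  The inverse solver keeps the `(Py − d1)`- and
`(Px − d3)`-terms in the computation (they vanish identically through the
coupling) so the code follows the constraint structure rather than a
simplified shortcut.  Forward kinematics inverts the closed form:

* `Px = (L1² − L2²)/(4m)` — singular at `m = 0`, which is rejected;
* `Pz = −√(L1² − (Px + m)²)` — radicands are computed in factored
  difference-of-squares form to avoid cancellation (round-trip error on the
  sampled workspace is below 1e-9 mm; the naive form loses an order of
  magnitude);
* `Py = q ± √(L3² − Pz²)` — the length model is symmetric about `Py = q`,
  so both roots are geometrically valid.  The root inside a configurable
  workspace box is returned (lower root preferred when both qualify),
  defaulting to `Py ∈ [0, q]`.  The packaged vertical verification motion
  operates at `Py = 485 > q ≈ 440`, i.e. on the other side of the symmetry
  plane; round-tripping such poses requires passing an explicit box, which
  the trajectory tests do.

Radicands more than 1e-6 mm² negative raise an infeasibility error;
smaller negatives are clipped as rounding.

### Geometry and calibration

Individual link dimensions `a, b, c, L` enter the length model only through
`m = L/2 − a − c` and `q = b + c`, so they are unidentifiable from lengths
alone.  Geometry is therefore accepted lumped; full mode exists for the
branch-point construction and constraint residuals.

Calibration fits each lumped offset to measured pose/length rows.  Each
observation admits two algebraic sign roots; every root seeds a 1-D least
squares polish against all observations, the refined estimates are scored
by their inlier sets (residual within 1 mm), and the estimate covering the
most observations with the smallest RMS wins, followed by a refit on its
inliers.  The report lists all distinct solutions, per-row residuals, and
excluded outliers, and flags ambiguity when a rival solution with the same
inlier count fits within a factor of two of the best — the single-row
branch-3 case, where both roots fit exactly, is the canonical ambiguous
input.  A fit is rejected when no estimate explains a majority of the
observations or the inlier RMS exceeds 0.5 mm (the print-precision
tolerance: inputs and outputs are 2-decimal values).

Of the three packaged verification rows, branches 1–2 of all rows are
mutually consistent (`m ≈ 340.0`), and the branch-3 cells of rows 2–3 agree
(`q ≈ 440.0`); row 1's branch-3 cell implies `q ≈ 640` or `160` and cannot
be reconciled with any single offset.  It is excluded by the default
calibration and flagged as an outlier — whether it is a typo in the source
is recorded as an open question, not resolved.

### Trajectories and workspace

`trajectory_commands` runs the inverse solver per sample and reports the
rod axis components.  Branches 1–2 are structurally parallel to the XZ
plane and branch 3 to the YZ plane; the zero components are computed from
the passive coupling, not hard-coded, so they double as a consistency
check.  The packaged vertical verification motion starts at
`(0, 485, −1225)`, rises 300 mm in Z at constant speed over 5 s, and is
sampled every 0.5 s — ten points, excluding t = 0 by convention.
`workspace_sample` grid-samples a pose box and marks a pose reachable iff
all three rod lengths lie within their stroke intervals; the reachable
fraction is monotone in stroke inclusion by construction.

## 3. Range-of-motion checks

The ROM table stores physiological and normal-gait limits per (joint,
plane, direction) as `(0, max)` magnitudes in degrees.  The knee coronal
plane is marked not-applicable rather than zero.  One transcription
decision: the hip horizontal physiological pair is printed ambiguously in
the source ("0–90/070") and is stored as external 0–90, internal 0–70,
noted in the fixture metadata.  Classification is three-valued with
inclusive boundaries; series discretization maps a recording to the binary
network state by thresholding the fraction of samples inside the gait range
(default τ = 0.8, inclusive).  τ is a named default because no
discretization threshold is published; it is the single knob linking angle
recordings to network evidence, and raising it can only flip states from
good to poor (monotonicity is tested).

## 4. Synthetic data

The generators produce every input the toolkit consumes, at desk scale,
from explicit seeds (one `numpy` generator per call; no hidden state):

* **Cohorts** — ancestral sampling of the network root-to-leaf.  Default
  root priors are P(poor) = 0.5 per motion node, since the surveyed
  cohort's marginals are not published; the cohort emulates the *mechanism*
  of a patient survey (discretized joint states consistent with the CPTs),
  not any real cohort's statistics.  At n = 10,000 with parents clamped,
  empirical child frequencies sit within 3 binomial standard deviations of
  the table rows.
* **Angle recordings** — rectified sinusoids per channel with Gaussian
  noise and per-cycle out-of-range episodes.  These reproduce the features
  the ROM pipeline consumes (magnitudes, gait-range excursions) but none of
  the temporal structure of real gait (stance/swing asymmetry,
  inter-stride correlation), so passing tests say nothing about real
  recordings beyond the classification logic.
* **Trajectories** — the vertical verification motion (exact defaults
  above), a circle in the XZ plane, and a gait-like ellipse with optional
  seeded jitter.
* **Calibration rows** — closed-form lengths plus i.i.d. Gaussian noise.
  Noise-free rows recover the generating offsets to machine precision by
  construction; at σ = 0.1 mm with 50 rows the m estimate lands within
  0.05 mm.  The q estimate sees half as many observations (one branch-3
  cell per row versus two branch-1/2 cells) at lower geometric sensitivity,
  so its recovery bound in the tests is set at three times its standard
  error (≈0.18 mm) rather than m's band.

## 5. Problem sizes and determinism

All experiments are desk-scale by design: inference cross-checks use
randomized networks of at most ~10 nodes (the enumeration oracle is capped
at 10^7 joint states), kinematic round-trips use 1000 sampled poses,
calibration recovery 50 rows, and cohort checks 10,000 subjects.  Every
randomized test and generator takes a fixed seed, and both inference
engines, the calibration pipeline, and the workspace sampler are
deterministic given their inputs.

## 6. Known limitations

* The intermediate and target CPTs are package defaults, not published
  values; posteriors that depend on them (e.g. the `E` marginal) are
  illustrative of the machinery, not reproductions.
* No mapping from platform poses to anatomical joint angles is provided —
  the source device's shoe/limb linkage is not specified mathematically —
  so ROM checks and workspace analysis remain separate views.
* Dynamics, forces, and the asserted "dynamic load" reduction are out of
  scope: no mathematical definition exists to implement.
* The calibration consensus procedure assumes at most a minority of
  inconsistent rows; with systematically corrupted data it will error out
  rather than recover.
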
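# Methods

## Model and assumptions

The detector operates on one frame at a time.  Its input is the
proxemic state of each person — ground-plane position `(x, y)` and
head orientation `θ` (radians, counter-clockwise from +x) — in a
consistent length unit (centimetres for the shipped defaults, pixels
for image-plane datasets).  Tracking and head-pose estimation are
assumed done upstream; temporal smoothing across frames is out of
scope.

A person's transactional segment is an isotropic Gaussian with mean
one stride `D` ahead along the facing direction and scale `σ`.  An
F-formation is a set of people whose transactional segments overlap on
a shared o-space centre; lone individuals are treated internally as
spurious one-member formations and reported as singletons.  The
negative log posterior of a joint assignment is, up to constants,

    J′ = Σᵢ ‖μᵢ − O_{Gᵢ}‖² + σ²·|O_G| + Σᵢ Σ_{j≠i} R_{i,j}(Gᵢ)

Three modelling notes:

- **MDL weight.**  The per-group penalty is `σ²` — the price, in
  squared residual units, that a group must amortise to justify its
  existence.  Taking the exponent `‖·‖²/σ²` of the Gaussian likelihood
  together with a unit penalty per model and multiplying through by
  `σ²` yields exactly this weight.  It is exposed as `mdl_weight` for
  experimentation, but the default couples it to `σ` so that noisier
  settings (larger `σ`) merge more aggressively, consistent with the
  shipped per-dataset presets.
- **Gaussian exponent.**  The likelihood uses `exp(−‖·‖²/σ²)` (no
  factor 2 in the denominator); a factor 2 is absorbable into `σ` and
  the presets are calibrated for this form.
- **Occlusion term.**  `R_{i,j}(g)` is non-zero only when *j* is
  strictly closer to the centre than *i* *and* the angle the two
  subtend at the centre is below the window `θ̂` — i.e. *j* stands
  between *i* and the centre.  Equidistant pairs (a circular formation)
  are never mutually occluding.  The term depends only on `i` and the
  candidate centre, so it is folded into the unary costs.  `θ̂` and
  `K` have no canonical published values; the defaults `θ̂ = π/6`,
  `K = 1` penalise near-collinear blocking geometry and are
  configurable.  If a candidate centre coincides exactly with an
  occluding person the exact penalty diverges; the solver substitutes
  a large finite cost (1e12), which simply forbids that pairing.

## Optimisation

Given a candidate set of centres, every person term is unary, so the
assignment step is an uncapacitated facility-location problem: choose
the subset of candidates minimising total service cost plus `σ²` per
open centre.  Two backends satisfy the same contract:

- exact, vectorised enumeration of all candidate subsets for up to 16
  candidates (every scene the generator produces stays within this);
- greedy drop/add/swap local search for larger candidate sets, seeded
  both from all-open and from the incumbent solution so it can never
  return a labelling worse than the previous iteration's.

Ties are broken deterministically: among equal-cost subsets the one
with more open centres wins (so a merge must be *strictly*
profitable), and a person equidistant between open centres takes the
lowest label id.  The outer loop starts from one candidate per person
(their own transactional-segment centre), and alternates assignment
with centre updates at the members' mean TS centre.  Alongside each
new mean, the previous centre is kept as a proposal (so a centre move
that triggers a large occlusion penalty can be rejected), plus the
pooled mean of every pair of groups whose centres lie within `3σ`
(merges only ever pay within ~`σ√2`, so the gate is generous).  These
merge proposals are what make the two-person merge boundary exact:
from the one-centre-per-person initialisation alone, coordinate
descent would only merge a pair when one person's own TS centre is
cheap enough for both (`r < σ/2`), not at the true boundary
`r = σ/√2` where the *midpoint* centre becomes profitable.

When the alternation converges, a deterministic polish refines the
labelling in partition space: every group, and every pair of groups
whose centres lie within `4σ`, is exactly re-partitioned (full
set-partition enumeration up to 8 members, bipartitions up to 14) with
centres at member TS means, applying the best strictly improving move
until none remains, then resuming the alternation.  This covers the
correlated moves coordinate descent cannot make — splitting one group
into two sub-pairs, or exchanging members between adjacent groups —
and brings the solver to the exhaustive all-partitions optimum on
essentially all small frames while preserving monotone descent.
Distant group pairs are skipped because any profitable single-member
move between far-apart groups is already unary and handled optimally
by the assignment step.

Convergence: the energy never increases (the incumbent labelling
remains feasible at every step), and the loop stops when the relative
decrease falls below `cost_tol` (default 1e−9, a floating-point-robust
stand-in for the strict-decrease test) or after `max_iters` (default
100) iterations.  The procedure contains no randomness; re-running on
the same input reproduces the identical labelling bit for bit.

## Parameters

| parameter | unit | default | role |
|---|---|---|---|
| `stride_D` | length | 30 | distance to the transactional-segment centre; circular groups have diameter ≈ 2D |
| `sigma` | length | 80 | tolerated deviation from the shared centre; also sets the MDL weight σ² |
| `vis_theta_hat` | rad | π/6 | angular half-width of the occlusion window |
| `vis_K` | — | 1 | gain of the angular occlusion factor `exp(K cos θ)` |
| `mdl_weight` | length² | σ² | per-group penalty (override to decouple from σ) |
| `cost_tol` | — | 1e−9 | relative-decrease stopping threshold |
| `max_iters` | — | 100 | iteration cap |

Shipped presets (stride `D`, scale `σ`) for the five public
benchmarks: synthetic (30, 80), idiap (20, 45), cocktail (70, 170),
coffeebreak (30, 85), gdet (30, 200) — units follow each dataset
(cm or px).

## Evaluation metrics

A truth group `G` is correctly detected by `D` at tolerance
`T ∈ [1/2, 1]` when `|G ∩ D| ≥ ⌈T·|G|⌉` and `|D \ G| ≤ ⌈(1−T)·|G|⌉`.
The false-subject bound is stated in the literature in a form that is
negative for any real group; the implementation uses the only
non-negative reading, which reproduces the customary `T = 2/3` regime
("at least two thirds found, no more than one third false") and
collapses to exact set equality at `T = 1`.  Matching is one-to-one,
greedy by descending intersection (ties to the lexicographically
smallest truth group).  Detected singletons never count as groups.

Dataset scores micro-average the TP/FP/FN counts over frames before
forming precision, recall and F1, so every group weighs equally and
empty frames are neutral; the alternative (per-frame macro-averaging)
is not provided.  The Global Tolerant Matching score is the area under
the dataset F1-vs-T curve on the grid `T ∈ {1/2, 2/3, 5/6, 1}`
(trapezoidal, normalised by the interval length 1/2), so a detector
with constant F1 = c scores exactly c; the 1/6 step resolves every
cardinality up to 6.  Cardinality-stratified F1 restricts truth groups
to size k, counts detected size-k groups left unmatched by the
*global* matching as the stratum's false positives, and summarises
across strata by mean ± population std.

## Synthetic scenes

The generator emulates a hand-authored benchmark of diverse social
situations: 10 archetype layouts totalling 90 people and 30 groups
(mean 9 individuals and 3 groups per frame), each repeated 10 times
with re-randomised placement, giving the default 100-frame batch.
Group members are placed so their transactional-segment centres
coincide exactly at the group centre — circle of radius `D` facing
inward (circular, cardinalities 2–6), two people `2D` apart facing
each other (vis-à-vis), two people at right angles each `D` from the
shared centre (L-shape) — except side-by-side, where both face the
same way with a shoulder gap of `D/2` (not dimensioned in the
literature; this keeps both TS centres within half a stride of the
shared centre).  Group centres are rejection-sampled (capped retries,
explicit failure) at pairwise separation ≥ `min_group_separation`
(default 180 cm > 4D, ensuring unambiguous ground truth); singletons
keep that separation from every group centre *and* from each other's
TS centres, and face away from the groups.  The pairwise singleton
constraint matters: two independently placed bystanders who happen to
stand within `σ√2` of each other form a genuine F-formation under the
model, which would make "perfect recovery" unattainable for any
correct detector rather than reveal a defect.

What the generator deliberately does **not** emulate: detector/tracker
noise structure (quantised head orientations, missed or hallucinated
people), non-circular o-spaces, people in transit, and groups closer
than the separation floor.  Passing the recovery tests therefore shows
the optimiser finds the model's optimum on well-separated scenes — not
that the model resolves ambiguous real-world crowding, which the
public benchmarks probe instead.

Noise protocol: each person's state receives independent additive
Gaussian perturbations with standard deviations `L·σ_x`, `L·σ_y`,
`L·σ_θ` at integer level `L = 0..10` (defaults 20 cm, 20 cm, 0.1 rad —
`N(0, s)` is read as standard deviation `s`, i.e. levels scale the
spread linearly).  Position-only, orientation-only and combined modes
are supported; the same per-replicate seed is reused across levels
(common random numbers), so level curves are coupled and the monotone
degradation trend is not masked by resampling noise.  Ground truth is
never perturbed.

## Numerical and design notes

- Angles are normalised to `(−π, π]` on construction; degree input is
  converted once at the I/O layer only.
- Distance ties in the occlusion test (`dᵢ = dⱼ`) count as "closer":
  no penalty, matching the strict inequality of the model and keeping
  circular formations penalty-free.
- Energies are plain float64 sums; the assignment step's subset
  enumeration uses an exact min-reduction per subset, so assignment
  energies are reproducible to the last ulp.
- Labels are re-indexed `0..g−1` after every assignment; group
  identity is not tracked across iterations (single-frame method).
- The `.mat` reader targets the published per-frame cell-array layout
  (`features` with columns id, x, y, θ; `GTgroups` with member-id
  vectors) and logs any variables or columns it cannot map; all tests
  run on JSON/CSV fixtures generated at test time.

## Known limitations

- The optimiser is exact only for ≤ 16 candidate centres per
  assignment step; beyond that the local-search backend inherits a
  (tested, bounded) local-optimum allowance.
- The polish enumerates partitions of at most ~14 pooled members per
  move; pathological scenes with very large tight clusters could in
  principle retain suboptimal labellings.
- `θ̂` and `K` defaults are plausible rather than calibrated; datasets
  with heavy occlusion may warrant tuning.
- Image-plane inputs (pixels) are handled only as a unit choice; no
  camera geometry or projection is modelled.
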
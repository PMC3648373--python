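# Methods

## Activity from expression (3-sigma thresholds)

Each gene's expression vector over one cycle (length `n ≥ 2`; a matrix
covering several successive cycles is first averaged column-wise down to
one cycle) yields a per-gene threshold
`Active_TH = u·F + (u+3σ)(1−F)` with `F = 1/(1+σ²)`. Two conventions
matter and are fixed deliberately:

- **Population variance** (denominator `n`, not `n−1`). The variance here
  weighs the curve's own fluctuation, not an estimate of a sampling
  distribution.
- **Inclusive comparison**: time point `i` is active when `EVᵢ ≥
  Active_TH`. A flat curve therefore has every point active (threshold
  equals the mean), which is the sensible reading for constitutively
  expressed proteins.

When the threshold exceeds the curve's maximum, no active point can be
inferred; the protein is assigned the wildcard set `{0}`. The same
wildcard is used for proteins with no expression row at all. The two
cases are tallied separately (`uninferred` vs `missing`) but treated
identically downstream. Empty-active-set is our operational definition of
"activity cannot be inferred"; a fluctuating curve whose threshold lands
above all values (e.g. `[0]*10 + [10,10]`, threshold ≈ 12.1) is the
canonical example. No smoothing, detrending or log transform is applied.

## Formation model

`FC(C, S, K)` is evaluated literally: condition 1 checks that each step's
`AP` intersects the running union (read as "intersection non-empty");
condition 2 that the union over the interval equals `C`. `K = 0` reduces
to `AP_S = C`. Time is linear within the cycle — no wrap-around; `S ≥ 1`
and `S + K ≤ n`.

**Wildcard semantics** default to *strict*: a protein with `Active = {0}`
never appears in `AP_i` for `i ≥ 1`, so a complex containing one is not
formable. A *permissive* mode treats wildcard proteins as active at every
real time point. Strict is the conservative literal reading; the switch
exists because curated catalogs do contain proteins whose activity a
single expression experiment cannot resolve.

The co-active rate `OL` of an interval averages the per-step overlaps; a
single-point interval has no merge steps and is assigned `OL = 1.0` by
convention (used only in reporting). `find_formation` enumerates all
`O(n²)` intervals (n = 12 gives 78) and reports the maximum `OL`,
breaking ties toward the smallest `K`, then the smallest `S`, so results
are deterministic. Catalog statistics assess complexes of size ≥ 2 and
report the formable fraction and the mean best `OL` over formable
complexes; a catalog with **no** formable complex reports mean `OL = 0.0`
rather than an undefined value, so clean/contaminated comparisons remain
total.

## Refinement

**Splitting** takes, for each time point `t` of the complex's active time
set, the members active at `t` (for `t = 0`: the wildcard members) and
emits each connected component of the complex's induced subgraph as a
sub-cluster. The induced subgraph is taken from the full network
restricted to the complex's members; members absent from the network are
isolated vertices and yield singletons. Singletons are kept at this
stage — they can still be absorbed, since `OV(singleton, superset) = 1`.

**Assembling** runs three phases over the sub-clusters, which are always
processed in canonical order (time ascending, then sorted member list):

1. *Wildcard phase.* Every time-0 sub-cluster is unioned into each
   sub-cluster at a real time point it overlaps at `≥ T`; time-0
   sub-clusters that combined at least once are then deleted, unmerged
   ones survive as candidates. Note that under the member-overlap
   definition a wildcard sub-cluster and a real-time sub-cluster have
   disjoint member sets (a protein is either wildcard or has real active
   points), so their `OV` is 0 and this phase only fires at `T = 0`.
   This is the literal consequence of defining the merge criterion on
   `OV`; we implement it as specified rather than invent a different
   wildcard-merge rule.
2. *Temporal sweep.* For each real time `i` ascending, each sub-cluster
   at `i` is unioned into **all** sub-clusters at `i + 1` it overlaps at
   `≥ T` (union-into-all plus final deduplication makes the outcome
   independent of within-time ordering in the common cases); after time
   `i` is processed its combined sub-clusters are deleted. Unions land at
   `i + 1` before `i + 1` is processed, so chains cascade in a single
   ascending pass — no fixpoint iteration. Only numerically adjacent time
   points merge directly; time `n` is not adjacent to time 1.
3. *Output.* Surviving sub-clusters become candidate complexes; those
   below `min_output_size` (default 2 — reference complexes consist of
   two or more proteins, and singleton outputs would distort predicted
   counts) are dropped, and identical sets deduplicate to the first
   occurrence.

Complexes smaller than `min_refine_size` (default 3) pass through
unchanged: a size-2 complex could only re-emerge unchanged or as two
singletons. The refined catalog is globally deduplicated by set equality.

Because merges at `T > 0` require a shared member and each sub-cluster is
connected, every refined complex (after removing wildcard members) is
connected in the network restricted to its source complex, and contains
no protein outside its source complex.

## Evaluation

`OS(Pc, Kc) = |∩|²/(|Pc|·|Kc|)` — equivalently the product of the two
containment fractions. Matching uses `OS ≥ 0.2` by default; a complex may
match several on the other side (no assignment problem is solved). The
counts TP (= MPC) and FP live on the predicted side, FN (= #known − MKC)
on the known side; `Sn = TP/(TP+FN)` and `Sp = TP/(TP+FP)` are computed
literally from those counts even though `Sn` mixes the two universes, and
the purely known-side rate `MKC/#known` is reported alongside as
`sn_known`. The f-measure is the harmonic mean of Sn and Sp, defined as 0
when both are 0.

## Synthetic benchmarks

The generator produces the three inputs with known ground truth.

*Expression curves* are spike-plus-baseline (baseline 5.0 arbitrary
linear units): for a target active set of size `k`, a grid search picks
the spike amplitude placing the 3-sigma threshold strictly between
`baseline + 3·noise_sd` and `spike − 3·noise_sd`; the full-cycle target
is a constant curve, and the wildcard target is a two-point spike tall
enough that its own threshold exceeds the maximum. Curves are tiled over
the requested cycles with additive Gaussian noise. At `noise_sd = 0` the
round trip through the activity module reproduces the targets exactly.
Spikes were chosen over periodic shapes because their activity set is
analytically controllable; consequently the curves do not emulate real
metabolic-cycle dynamics (autocorrelation, drift, probe-level noise
structure), so passing tests demonstrate correctness of the machinery,
not robustness to real-array noise.

*Planted complexes* are cliques whose members follow a just-in-time
schedule over a contiguous interval: with overlap floor `ov_min > 0` the
schedule keeps a window of `s` co-active members, dropping the
longest-present member and adding one new member per step, so consecutive
`AP`s of size `s` overlap at `(s−1)/s ≥ ov_min` (window size
`s ≥ ⌈1/(1−ov_min)⌉`; interval length capped at `min(4, n−2)` so decoys
always have out-of-interval time points available). `ov_min = 0` instead
splits the membership into two disjoint consecutive halves, which
violates formation condition 1 — a negative control. Complexes share no
proteins. Each complex also receives three decoy neighbours — attached to
a random member but active only outside the complex's interval — plus
unattached background proteins as distractors. Defaults (n = 12 time
points, 3 cycles, sizes 3–8, `ov_min = 0.7`) mirror a 12-point metabolic
cycle averaged over three repeats and curated-complex size scales.

*Contamination* adds to each complex `k` proteins adjacent to a member
(so the induced subgraph stays connected and splitting, not mere
membership, must remove them) whose active points are disjoint from all
members'. Contaminated complexes are never formable — any interval
covering both the members' and a contaminant's active times has an empty
docking intersection at the boundary — which reproduces, in exaggerated
form, the direction of the clean-vs-predicted gap in formability and
co-active rate.

## Numerical choices and limitations

- All set quantities are exact integer arithmetic; only the final ratios
  are floats, so formula tests can compare against `fractions.Fraction`
  oracles at machine precision.
- Determinism: canonical ordering everywhere plus seeded `numpy`
  generators makes every pipeline output byte-identical across runs.
- Problem sizes in tests and in the acceptance script (60 planted
  complexes, 200 random formation instances, 1000 formula cases) were
  chosen as comfortably sufficient for the properties being checked while
  keeping the default suite quick.
- The refiner consumes any complex file; it does not re-implement the
  upstream clustering algorithms, weighted/directed networks, or
  GO-based evaluation metrics.
- A single expression experiment cannot resolve proteins active only
  under other conditions; the wildcard mechanism acknowledges this but
  (at `T > 0`) effectively excludes such proteins from refined complexes
  — a known conservative bias of the strict reading.
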
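# Methods

## Problem and scope

The package answers, exactly, three questions about an n-input 1-output
Boolean function f (n = 2..4):

1. What are the simplest combinational designs for f over genetic AND, OR
   and NOT gates?
2. How few logic-operating cells and chemical wires does an admissible
   distribution of such a design need?
3. How do those costs compare with the Standard NOR/NAND and Modular Cells
   methodologies?

Only functions that depend on every declared input are considered
throughout ("dependence-filtered"); for n = 3 this universe has 218 of the
256 functions. A separate steady-state model covers the two-cell XOR
consortium (below).

## Simplest-logic synthesis

**Selection rules.** A design is *simplest* when it has the fewest total
units; among those, designs with the minimum number of AND gates are kept
(NOT and OR are cheap in cells — an AND gate needs the two-component
T7ptag/supD device, while OR is just two promoters and NOT a repressor).
The implementation returns *all* optimal designs, deduplicated up to gate
relabeling, because the later distribution stage is free to pick the
best-distributing one.

**Tree engine (default).** Gate outputs feed exactly one consumer;
environmental inputs fan out freely. Minimal sizes come from a fixpoint
dynamic program over all 2^(2^n) functions
(`size[g op h] ≤ size[g]+size[h]+1`, `size[¬g] ≤ size[g]+1`); all optimal
formulas are reconstructed by enumerating the decompositions that achieve
the optimum. For n = 4 the same program runs in a leveled, budget-bounded
form.

**DAG engine.** Gate outputs may fan out (a diffusible molecule can be
sensed by many promoters). Exact minimal Boolean-chain sizes come from a
breadth-first search over *sets of computed functions*, canonicalized under
input permutation — the search that exhausts combinations of logic units
level by level. A state at level k containing f, where k is f's minimal
size, is exactly a minimal design's node-set (an unused gate would
contradict minimality), so every minimal DAG design is harvested from the
frontier and completed by enumerating acyclic decomposition covers.

**Which engine feeds the survey, and why.** Tree mode is the default for
the comparison statistics. Three anchors decide this: (i) the 2-input sweep
(only XOR and EQUALS need two cells) holds in both modes; (ii) the count of
zero-wire 3-input functions (52) and the 4-cell worst case are reproduced
only by tree designs; (iii) under DAG designs, sharing is so effective
(worst case 8 units instead of 11–12) that with NOT-absorption every
3-input function fits two cells, flattening the histogram the comparison is
about. DAG mode remains available everywhere for sensitivity analysis.

**Cross-checking.** An independent pairwise-composition dynamic program
(`oracle_min_units`) recomputes minimal formula sizes over arbitrary bases
({AND,OR,NOT}, {NOR}, {NAND}, mixed) and is tested against both engines.
One costing convention is shared by all engines: a gate may read the same
signal on both of its input ports at no extra cost (`NOR(g,g)` is one gate
plus one copy of g), because a cell can wire one molecule to two promoters;
this is what makes OR two NOR-cells (gate + inverter) rather than three.

## Distribution into cells

**Hard rules per cell.**

* *Unit budget:* at most 3 gates per cell, and tandem depth at most 3
  (stacked stages amplify intrinsic noise and leakage; regulatory cascades
  in E. coli rarely exceed three layers). The unit-budget reading is the
  one that reproduces the published zero-wire count — exactly the 52
  functions with ≤3-unit designs fit a single cell; the depth-only reading
  would admit 64. Both limits are independently configurable.
* *No shared inputs:* two gates in one cell must not read the same signal
  (environmental molecule, internal gate product, or wire) — their
  promoters would compete for the same regulator pool. This rule is hard
  by default; it is precisely what forces XOR's four-unit design (whose OR
  and AND both read both inputs) into two cells despite its depth of 3. A
  relaxed mode turns it into a reported count (`n_parallel`).

**Wires and NOT absorption.** Every producer gate whose output is consumed
across a cell boundary contributes one wire (one quorum-sensing molecule,
merged across consumers). A non-output NOT whose source is a gate may be
*absorbed*: it is assigned to no cell, its consumers sense the producer's
molecule through a repressive promoter, and it contributes no units or
depth to any cell. Absorption requires every consumer to sit in a
different cell from the producer. Environmental inputs reach any number of
cells for free and never count as wires. Ties between plans equal in
(cells, wires) break toward more absorption — the repressive wire is the
preferred device. If one producer's molecule is consumed both plainly and
through an absorbed NOT, it still counts once (one species, two sensing
modes); the plan lists the two senses as separate wire records.

**Exact search.** Branch and bound: for increasing cell count k, all
absorption subsets × backtracking assignments of the remaining gates to k
cells (with symmetry breaking), feasibility-checked against the rules,
minimizing wires at the first feasible k. Results are cached by the
design's canonical form under input permutation. Designs up to ~12 gates
are practical; the full 3-input survey (218 functions, 672 pooled designs,
orbit-level reuse) runs in a few seconds.

**Greedy heuristic.** The documented fast path: open a cell at the gate
nearest the output, grow it backwards along tandem chains while the unit
budget and the shared-input rule allow, repeat on the remaining gates, then
absorb every NOT whose input arrives on a wire. The suite asserts greedy
never beats exact and matches it on all minimal 2-input designs.

## Baseline methodologies

* **Standard NOR/NAND** — one 2-input NOR (or NAND) gate per cell, wired by
  quorum molecules; cells equal minimal gate count, wires equal cells − 1
  (in a minimal tree every internal output is consumed once). The default
  is a homogeneous NOR basis with tree composition: that convention uniquely
  reproduces the published "3 functions within two cells" (the three
  `NOR(NOR(x,y),z)` variants); mixed bases and exact DAG composition are
  available (`basis=`, `structure=`).
* **Modular Cells** — each cell computes an arbitrary Boolean function of
  at most two signals (all 16 two-input operators over any signal pair,
  degenerate tables giving 1-input behavior); composition search by the
  same leveled dynamic program over the function space.

## Survey conventions and known departures from printed values

The exhaustive 3-input survey under the default conventions gives:

| quantity | this package (exact) | previously printed |
|---|---|---|
| functions in universe | 218 | 218 |
| rules: within 2 cells | 194 | 191 |
| rules: worst case | 4 cells | 4 cells |
| rules: zero wires / one wire | 52 / 130 | 52 / 123 |
| NOR/NAND: within 2 cells / worst | 3 / 14 | 3 / 15 |
| modular: within 2 cells / worst | 114 / 4 | 43 / 8 |

The departures are systematic, not noise:

* The original rules-method statistics came from a greedy divider applied
  to search output. Our exact optima bound them from above
  (194 ≥ 191 ≥ 188; 130 ≥ 123 ≥ 127-ish for plausible greedies), and the
  printed 191 = 188 + 3 can only arise by resolving half of a size-6
  input-permutation orbit — i.e. from a heuristic that is not
  permutation-invariant. No deterministic convention in the swept space
  (tree/DAG designs, depth vs unit budget, absorption accounting, wire
  merging, greedy orderings) lands exactly on 191/123, so the package
  reports the exact optima and documents the gap.
* The NOR worst case of 15 matches the natural compositional construction
  of 3-input parity (a 5-gate NOR formula for XOR2 with the inner result
  duplicated: 5 + 2×5), while the exhaustive optimum is 14.
* The Modular Cells numbers (43 within two cells, worst 8, 75 zero-wire,
  88 one-wire) are not reproduced by any faithful reading of "each cell
  computes an arbitrary ≤2-input function" — the exact optimum reaches 114
  functions with a two-cell chain `g2(g1(xi,xj),xk)` and never needs more
  than 4 cells, and no 3-input function can occupy a single ≤2-input cell,
  so the zero-wire count is 0. Shared-readout variants (consortium output
  as an OR over reporter cells) and restricted operator libraries were
  examined and none reproduce the printed quadruple; rather than fit an
  arbitrary operator subset to the numbers, the package keeps the declared
  model.

The 4-input sweep is bounded by construction (synthesis budget per
function, plus cell/wire caps), streams the 64 594-function universe at
orbit level, and reports functions exceeding the bounds as `unresolved`.

## Consortium model

Steady-state algebraic composition of lumped Hill stages (the repressive
lux promoter responds much faster than the co-culture grows, which is what
licenses the quasi-steady-state treatment):

* activation: `act(x) = l + (1−l)·x^h/(K^h+x^h)` for P_BAD (arabinose) and
  P_Sal (salicylate);
* the AND device: `β·(u·v)/(K_T + u·v)` in the product of its two parts
  (T7ptag and supD);
* the OR device: `u + v − u·v` (two independent promoters on one gene; an
  additive-saturating alternative was considered and rejected as unbounded);
* the wire: `AHL = σ·φ/(1−φ)·LuxI` — AHL scales with the USC:DSC odds by
  default (`ahl_scaling="fraction"` switches to φ alone);
* repression: `t7(x) = l + (1−l)/(1+(x/K_ahl)^h_ahl)`;
* the downstream output: AND of the repression stage and the OR stage.

**Parameters** (defaults in `data/default_params.yaml`, loaded as data):
binding constants K in molar on the experimental concentration ladders
(arabinose 10⁻⁸..10⁻¹ M, salicylate 10⁻¹⁰..10⁻³ M, AHL 10⁻¹¹..10⁻⁵ M);
Hill coefficients h ≥ 1 (the repressive stage uses a lumped h = 4,
absorbing LuxR dimerization and the downstream T7 amplification into one
effective cooperativity); leakage fractions l ≪ 1; the RBS attenuation
factor f ≥ 1 (fold-reduction of luxI translation relative to BBa_B0034);
the USC fraction φ ∈ (0,1).

**Calibration.** The original fitted parameter values are not available,
so the defaults are anchored to the system's reported qualitative
behaviour: upstream on/off ratio > 100; XOR signal-background ratio ≥ 10
at f = 10 across USC:DSC from 1:20 to 1:1; a rise-then-fall attenuation
scan with an interior optimum (at f = 1 the leaky wire silences the ON
states; as f → ∞ the wire dies and the consortium degenerates to OR with
ratio → 1); and the optimum shifting to larger f as leakage grows. The
test suite asserts exactly these properties; numeric outputs of the model
are therefore comparable to the original system in shape, not in absolute
value.

**Parameter recovery.** As a self-consistency stand-in for fitting
experimental transfer functions, the characterization grids are simulated,
corrupted with multiplicative log-normal noise (CV 10%), and the three
binding constants are re-fit by log-space least squares; recovery is within
2-fold (typically within 1.5-fold).

**What the model does not cover.** Growth dynamics are summarized by the
static fraction φ (final proportions are set by inoculation); no spatial
AHL diffusion; no stochastic gene expression; no second (rhl) wire.

## Synthetic fixtures

Test fixtures are generated, not stored: truth tables drawn uniformly from
the dependence-filtered universe and paired with a seeded choice among
their rule-optimal designs, so every fixture circuit realizes its table by
construction. They exercise serialization round-trips, evaluator
cross-checks and distribution invariants; they do not emulate any
biological data set.

## Numerical and degenerate-input choices

Constants (functions depending on no input) are excluded everywhere by the
dependence filter; bare projections realize but do not distribute. Bounded
searches fail loudly (`BoundExceededError` carrying the bound) rather than
truncating. All combinatorial results are integer-exact; the simulator
works in double precision with outputs bounded in [0, β] by construction.
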
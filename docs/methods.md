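# Methods

This note documents the model behind the package: the cycle state machine
and its acceptance rules, the score-driven pruning rules, the density
operations, the evaluation metrics, the synthetic fixtures the tests run
on, and the numerical choices made where the design was genuinely open.

## The cycle engine

A run is a sequence of at most `max_cycles` (default 25) cycles over a
current model, a current map and the observed reflection data. Each cycle
executes, in order: pruning, density modification, dummy-atom addition,
protein building, post-building chain pruning, nucleic-acid building and
water addition. The guiding principle is cross-validation: any step that
adds parameters the data could overfit (dummy atoms, waters, the final
side-chain rebuild) is refined and then kept only if its R_free is
*strictly lower* than that of the previous refinement. Strictness is
deliberate — a tie means the extra parameters bought nothing, so the
simpler model wins.

Bookkeeping per cycle is the (R_work, R_free) of the last accepted
refinement plus per-step outcomes. The stall counter is the number of
cycles since the best R_free; the run stops when it reaches
`stop_after_no_improvement` (default 4) or at the cycle cap. The output is
the model of the lowest-R_free cycle (earliest on ties). When the data
extend beyond 2.5 Å and that cycle's R_work is below 30%, side chains that
are missing atoms or predicted incorrect are rebuilt once, again gated on
R_free.

Decisions taken where the behaviour was open:

- **Acceptance baseline for dummy atoms** is the most recent refinement
  R_free within the same run (normally the post-pruning refinement of the
  same cycle). On rejection, the density-modified map is used for building
  and the model is untouched; on acceptance the refined hybrid, stripped
  of its dummies, becomes the current model. Either way dummy atoms and
  carried-over waters are discarded before building — they exist only to
  improve phases, never for map interpretation.
- **Water gate**: water picking is only attempted once R_work is below
  40% (configurable); a noisy early map would otherwise fill solvent with
  junk that refinement then defends.
- **Experimental phases** (when provided) drive refinement only until
  R_work first reaches 35%; the switch latches off because by then the
  model phases are better than the starting experimental ones, and
  re-enabling them on a transient R_work rise would re-inject stale
  information.
- **Skipped refinements**: when a pruning step removes nothing, its
  follow-up refinement is skipped (a no-op refinement would only consume
  cycles); the nucleic-acid step runs only when a nucleic sequence is
  supplied.
- **Backends are contracts.** The engine never inspects the engines it
  orchestrates; `craft.synthetic.ScriptedBackends` implements the contract
  with a pre-scripted (R_work, R_free) trajectory and a
  copy-of-reference-with-deletions builder, which is sufficient to
  exercise every control path deterministically.

## Pruning and selection rules

All correctness thresholds are *relative to the median over the whole
structure* (not per chain), which makes them scale-free in the typical
case where the score distribution is bimodal (mostly right + a wrong
minority). Parameters, with defaults:

| rule | threshold | cap / scope |
| --- | --- | --- |
| chain pruning | mean main-chain correctness < 0.2 × median | chains ≤ 20 residues |
| residue pruning | main-chain correctness < 0.5 × median | ≤ 20% of scored residues |
| side-chain truncation | side-chain correctness < 0.5 × median | ≤ 20% of residues with side chains |
| rebuild selection | side chain < 0.25 × median and main chain > 0.25 × median, or atoms missing | GLY/ALA excluded |
| seed filter | LLK ≥ mean − 2 sd, then every 3rd survivor | sample (n−1) sd |

Residue/side-chain pruning is skipped in the first cycle (scores of a
freshly placed model are not yet meaningful) and when the data do not
extend beyond 2.3 Å (strict d_min > 2.3), where density is too weak to
judge individual residues. The 20% caps remove the worst scores first,
ties broken by (chain, residue number); the cap population is all scored
residues (respectively all residues with side chains), not just the
sub-threshold ones. The caps do not apply to chain pruning. The
every-third seed selection starts at the first survivor.

## Density operations

Maps are periodic grids; all statistics are population statistics over
all voxels (the map-grid convention), and "σ" always means
(value − mean)/sd. A *peak* is a voxel strictly greater than its 26
periodic neighbours at ≥ 2σ; its position is refined by per-axis parabolic
interpolation and its *volume* is the 6-connected periodic region above
the picking level times the voxel volume. Plateau maxima (exact value
ties) are not peaks; they occur only on degenerate synthetic input.

Dummy-atom flooding keeps peaks whose symmetry-expanded distance to the
model is within [1.9, 10] Å and accepts them greedily in descending height
subject to ≥ 1.4 Å pairwise separation. Water picking runs three passes;
a peak becomes a water when its volume is < 15 Å³, it is > 2.4 Å from all
current atoms and ≤ 3.2 Å from an N or O. Waters accepted in earlier
passes join the model as O atoms *between* passes, so second-shell waters
hydrogen-bonded only to other waters appear from pass 2; within a pass the
2.4 Å exclusion is applied live against the pass's own accepts, while the
hydrogen-bond check uses the pass-start model (otherwise the multi-pass
structure would collapse into one pass). Distance checks are
symmetry-expanded by default — crystal contacts are real contacts — with a
flag to disable for P1 toys.

Structure factors are computed by direct summation over atoms and
space-group operators, F(h) = Σ occ·f(s)·exp(−B s²/4)·exp(2πi h·x), with a
*single-Gaussian* form factor per element (amplitude = electron count,
bundled width table). This is a deliberate simplification of the usual
four-Gaussian fits: every consumer in the package (F-map correlation,
R factors) is a ratio or correlation, insensitive to the radial form
factor shape. The synthetic map generator uses the exact Fourier mates of
these form factors, so FFT-based oracles agree with the direct summation
to rounding error on band-limited fixtures.

## Evaluation metrics

**Completeness.** A reference protein residue is matched when some built
residue lands its N, Cα and C all within 1 Å. Each built chain
independently searches all space-group operators and allowed origin shifts
for the transform matching the most residues; matching is greedy
one-to-one in reference order (nearest Cα first). Distances use the
minimum-image convention, which grants whole-lattice translations for
free. Allowed origin shifts are enumerated by the group-invariance test
(conjugating every operator by the shift must permute the group); axes
fixed by every rotation are polar and admit continuous shifts. Continuous
components are resolved by candidate translations derived from built-Cα ×
reference-Cα pairings (seeded at zero), then refined by the mean matched
offset — the candidate set provably contains the exact alignment whenever
any residue truly matches, which is both faster and more reliable than a
fixed-step 1-D scan and extends to the 3-D continuous case of P1.

**F-map correlation** is Σ F₁F₂ cos Δφ / √(Σ F₁² Σ F₂²) over unique
reflections to d_min, F(000) excluded — algebraically the real-space
correlation coefficient of the two zero-mean maps, computed in reciprocal
space. **R factors** use a least-squares amplitude scale fitted on all
reflections and partition by the free flag (0 = free, CCP4 convention).
The **quality gate** fails on R_free > 0.06·d_min + 0.17, data
completeness < 90% or F-map correlation < 0.2, reporting every failed
clause. **Superposed similarity** truncates a predicted model to the
residues of a chain, Kabsch-superposes on the common Cα and reports the
percentage of chain Cα within 1 Å; "best chain" maximizes that percentage.
pLDDT truncation reads the per-residue confidence from the B-factor field,
as predicted models conventionally store it.

Free-flag hygiene: a flag column is usable iff its zero fraction is in
(0, 0.5]; otherwise a fresh 5% free set is generated reproducibly from the
run seed. The map used for building excludes the free reflections
entirely and is truncated at 2 Å — higher-resolution terms add noise
faster than signal for chain tracing, and the free set must never leak
into building.

## Synthetic fixtures and their limits

`craft.synthetic` generates everything the tests consume: ideal
poly-alanine α-helices (rise 1.5 Å, 100°/residue, radius 2.28 Å, N/CA/C/O/CB
with chord-interpolated backbone positions), exact-RMSD random
perturbations, uniform residue deletions, bimodal correctness/LLK scores
(correct ≈ U(0.7, 0.95), incorrect ≈ U(0.01, 0.2); LLK ≈ N(±5, 1)), noisy
amplitude sets (5% multiplicative noise, 5% free set) and the scripted
backend suite. Default toy conditions: P1 (density tests) or P2₁
(symmetry tests) cells of 20 × 20 × 30 Å, 10-residue helices, data to
2.0–2.6 Å. Everything is a pure function of (parameters, seed).

What the fixtures do *not* emulate: real scattering (solvent, anisotropy,
experimental error structure), real refinement convergence (trajectories
are scripted), rotamer chemistry, or disorder. Passing tests therefore
demonstrate that the *control logic and metrics* are correct — the rules
fire exactly when their stated conditions hold — not that the pipeline
will reach any particular completeness on real data; that depends on the
external engines behind the backend contract.

Problem sizes in the test suite and acceptance script (10-residue
helices, 16³ random grids, 50-fixture batches, 200 random score sets)
were chosen as the smallest cases that exercise every code path with
non-trivial symmetry.

## Numerical choices and degenerate inputs

- Constant maps (σ = 0) are flagged degenerate; peak search on them is an
  error rather than an empty answer, since a 2σ threshold is meaningless.
- Parabolic peak interpolation clamps offsets to half a voxel; axes with
  non-negative curvature keep the integer position.
- Sub-voxel ties in greedy acceptance are broken by flat grid index order,
  making pick lists deterministic.
- The symmetry expansion covers the 27 neighbouring cells, valid for
  contact distances well below the cell edge (all rules in scope are
  ≤ 10 Å against ≥ 20 Å cells).
- `generate_free_flags` uses `round(fraction · N)` zeros exactly;
  determinism comes from a single explicitly-seeded generator (no global
  random state anywhere in the package).
- Cell equality in model-vs-model metrics is relative 10⁻³; reflection
  d_min is computed from the cell metric, not trusted from file headers.

## Known limitations

- PDB writing is best-effort for ≤ 62 chains (single-character chain ids);
  mmCIF is the canonical format.
- Single-Gaussian form factors make absolute amplitudes unrealistic;
  only ratios/correlations of amplitudes should be interpreted.
- Anisotropic B-factors, alternate conformers beyond the first, TLS and
  binary MTZ are out of scope.
- The completeness matcher assigns at most one built residue per reference
  residue; heavily NCS-overlapped cases could in principle differ from
  tools that allow many-to-one matches.
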
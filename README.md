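# craft

An engine for automated macromolecular model building in X-ray
crystallography: the iterative cycle logic that wraps external building and
refinement programs, plus the evaluation metrics used to judge the models
it produces.

Automated pipelines alternate model building against an electron-density
map with reciprocal-space refinement, and the hard part is not any single
step but the control logic: when to prune a partly wrong model, when to
accept a risky modification, when to stop, and which cycle's model to keep.
This package implements that logic as a tested library with a small CLI,
for developers of building pipelines and for anyone who needs its
evaluation metrics (symmetry-aware model completeness, F-map correlation,
R factors) standalone.

## What it does

**Cycle state machine** (`craft.pipeline`). Each cycle runs seven steps in
order: (i) chain/residue/side-chain pruning, (ii) density modification,
(iii) dummy-atom addition, (iv) protein building, (v) chain pruning,
(vi) nucleic-acid building, (vii) water addition. Risky steps are gated by
the cross-validation residual: a modification is kept only when the
refined hybrid's R_free is *strictly* better than the previous
refinement's. The run stops once R_free has not improved on its best value
for 4 cycles (cap 25), and the output is the model from the cycle with the
lowest R_free, with an optional side-chain rebuild when the resolution is
better than 2.5 Å and R_work is better than 30%. External engines
(refinement, shift-field refinement, density modification, chain tracing,
scoring) enter only through the `BackendSuite` contract; scripted
deterministic mocks live in `craft.synthetic`.

**Pruning rules** (`craft.scoring`). Driven by per-residue main-chain /
side-chain correctness scores and log-likelihood (LLK) fit scores, all
thresholds relative to the whole-structure median: chains of ≤ 20 residues
are removed when their mean main-chain correctness is below 0.2× the
median; residues (side chains) below 0.5× the median are deleted
(truncated to Cβ), each class capped at 20% per stage; seed residues for
the finding step are every third residue after dropping LLK outliers below
mean − 2σ; side chains with correctness < 0.25× the median but a sound
main chain (> 0.25× median) are queued for rebuilding.

**Density operations** (`craft.density`). σ-level peak search with
periodic connectivity, dummy-atom flooding (peaks ≥ 2σ within 1.9–10 Å of
the model, pairwise ≥ 1.4 Å), three-pass water picking (volume < 15 Å³,
further than 2.4 Å from everything, within 3.2 Å of an N/O hydrogen-bond
partner, earlier waters counting as O in later passes), Gaussian-atom map
synthesis, and direct-summation structure factors with single-Gaussian
form factors.

**Evaluation metrics** (`craft.metrics`). Model completeness — the
percentage of reference protein residues whose N, Cα and C are all matched
within 1 Å by the built model after searching space-group operators,
allowed origin shifts (continuous along polar axes) and lattice
translations; the F-map correlation
Σ F₁F₂ cos(φ₁−φ₂) / √(Σ F₁² Σ F₂²); R factors with a least-squares scale;
a data quality gate (R_free ≤ 0.06·d_min + 0.17, completeness ≥ 90%,
F-map correlation ≥ 0.2); Kabsch-superposed Cα similarity and pLDDT
truncation for predicted models.

## Worked example

```python
from craft.model_io import UnitCell
from craft.pipeline import PipelineConfig, run
from craft.metrics import completeness
from craft.synthetic import (ScenarioSpec, make_helix_model,
                             make_observed_reflections, scripted_backends)

cell = UnitCell(20, 20, 30)
reference = make_helix_model(10, cell, seed=0)        # 10-residue poly-Ala helix
data = make_observed_reflections(reference, d_min=2.6, seed=1)
spec = ScenarioSpec(seed=1, trajectory=(0.40, 0.38, 0.36, 0.35,
                                        0.35, 0.35, 0.35, 0.35))
model, report = run(None, data, PipelineConfig(),
                    scripted_backends(spec, reference), sequence="A" * 10)
print(report["n_cycles"], report["best_cycle"], report["best_r_free"])
print(completeness(model, reference).completeness)
```

prints

```
8 4 0.35
100.0
```

The scripted refinement trajectory reaches its best R_free (0.35) in cycle
4; cycles 5–8 bring no improvement, so the stall counter reaches 4 and the
engine stops after cycle 8 and returns the cycle-4 model, which rebuilds
the reference completely (completeness 100%).

The same run is available from the shell:

```sh
craft simulate --preset helix --seed 1 --out fixtures/
craft run --data fixtures/reflections.cif --sequence fixtures/sequence.fasta \
      --backends mock --seed 1 --out out/
craft completeness --built out/final.cif --reference fixtures/reference.cif
```

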
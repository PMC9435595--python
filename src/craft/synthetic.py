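"""Synthetic fixtures: toy models, maps, scores and scripted backends.

Everything here is a pure function of its arguments and an explicit seed,
so fixtures are byte-reproducible.  The models are idealized poly-alanine
alpha-helices (rise 1.5 Å, 100 degrees per residue) with N, CA, C, O and
CB atoms — enough backbone for the completeness metric, the pruning rules
and Gaussian map synthesis, with no pretence of real rotamer chemistry.

The scripted backends exercise the pipeline control logic without any
external building or refinement engine: refinement returns a pre-scripted
(R_work, R_free) trajectory, building returns progressively larger subsets
of a reference model, and density modification returns a map synthesized
from the current model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .density import map_from_model
from .model_io import (AtomRecord, Chain, CraftError, DensityGrid,
                       ReflectionSet, Residue, SpaceGroup, StructureModel,
                       UnitCell, generate_free_flags)
from .scoring import ResidueScores
from . import density as _density

__all__ = [
    "ScenarioSpec",
    "make_helix_model",
    "perturb_model",
    "delete_residues",
    "make_scores",
    "make_observed_reflections",
    "scripted_backends",
    "ScriptedBackends",
]


@dataclass
class ScenarioSpec:
    """Parameters fully defining a synthetic pipeline scenario."""

    seed: int = 0
    cell: UnitCell = field(default_factory=lambda: UnitCell(20.0, 20.0, 30.0))
    spacegroup: str = "P 1"
    n_residues: int = 10
    perturbation_rmsd: float = 0.0
    deletion_fraction: float = 0.0
    trajectory: tuple = (0.40, 0.38, 0.36, 0.35, 0.35, 0.35, 0.35, 0.35)
    build_recovery_per_cycle: float = 0.5  # fraction of deleted residues restored per cycle

    def __post_init__(self) -> None:
        if not all(0.0 < r < 1.0 for r in self.trajectory):
            raise ValueError("trajectory values must lie in (0, 1)")


def make_helix_model(n_res: int, cell: UnitCell, spacegroup: str = "P 1",
                     seed: int = 0, chain_id: str = "A",
                     b_iso: float = 20.0) -> StructureModel:
    """Ideal poly-alanine alpha-helix placed along c at the cell centre."""
    if n_res < 3:
        raise ValueError("a helix needs at least 3 residues")
    rise, twist, radius = 1.5, math.radians(100.0), 2.28
    length = (n_res + 1) * rise
    if length > cell.c - 4.0:
        raise CraftError(
            f"helix of {n_res} residues ({length:.0f} Å) does not fit cell "
            f"c={cell.c:.0f} Å; use a larger cell")

    centre = cell.orthogonalize([0.5, 0.5, 0.5])
    z0 = centre[2] - n_res * rise / 2.0

    def ca(i: float) -> np.ndarray:
        ang = twist * i
        return np.array([centre[0] + radius * math.cos(ang),
                         centre[1] + radius * math.sin(ang),
                         z0 + rise * i])

    chain = Chain(chain_id)
    for i in range(n_res):
        p = ca(i)
        prev_dir = ca(i - 1) - p
        next_dir = ca(i + 1) - p
        radial = p - np.array([centre[0], centre[1], p[2]])
        radial /= np.linalg.norm(radial)
        n_pos = p + 0.39 * prev_dir
        c_pos = p + 0.39 * next_dir
        o_pos = c_pos + 1.23 * radial
        cb_pos = p + 1.53 * radial
        res = Residue(chain_id, i + 1, "ALA", "", [
            AtomRecord("N", "N", n_pos, 1.0, b_iso),
            AtomRecord("CA", "C", p, 1.0, b_iso),
            AtomRecord("C", "C", c_pos, 1.0, b_iso),
            AtomRecord("O", "O", o_pos, 1.0, b_iso),
            AtomRecord("CB", "C", cb_pos, 1.0, b_iso),
        ])
        chain.residues.append(res)
    return StructureModel(cell, SpaceGroup.from_symbol(spacegroup), [chain])


def perturb_model(model: StructureModel, rmsd_target: float,
                  seed: int = 0) -> StructureModel:
    """Copy with random displacements scaled to an exact all-atom RMSD."""
    if rmsd_target < 0:
        raise ValueError("rmsd target must be non-negative")
    out = model.copy()
    if rmsd_target == 0:
        return out
    rng = np.random.default_rng(seed)
    atoms = [a for a in out.atoms()]
    disp = rng.normal(size=(len(atoms), 3))
    disp *= rmsd_target / math.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
    for a, d in zip(atoms, disp):
        a.pos = a.pos + d
    return out


def delete_residues(model: StructureModel, fraction: float,
                    seed: int = 0) -> StructureModel:
    """Copy with a uniformly random ``round(fraction * n)`` residues removed."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    out = model.copy()
    keys = [r.key for r in out.residues()]
    n_del = int(round(fraction * len(keys)))
    if n_del == 0:
        return out
    rng = np.random.default_rng(seed)
    drop = rng.choice(len(keys), size=n_del, replace=False)
    out.remove_residues([keys[i] for i in drop])
    return out


def make_scores(model: StructureModel, correct_keys: Optional[set] = None,
                seed: int = 0) -> ResidueScores:
    """Correctness/LLK scores: high band for correct residues, low otherwise."""
    rng = np.random.default_rng(seed)
    scores = ResidueScores()
    for res in model.residues():
        if res.category != "protein":
            continue
        correct = correct_keys is None or res.key in correct_keys
        if correct:
            mc = rng.uniform(0.7, 0.95)
            sc = rng.uniform(0.7, 0.95)
            llk = rng.normal(5.0, 1.0)
        else:
            mc = rng.uniform(0.01, 0.2)
            sc = rng.uniform(0.01, 0.2)
            llk = rng.normal(-5.0, 1.0)
        scores.set(res.key, main_chain=float(mc), side_chain=float(sc),
                   llk=float(llk))
    return scores


def make_observed_reflections(model: StructureModel, d_min: float = 2.0,
                              noise_fraction: float = 0.05,
                              free_fraction: float = 0.05,
                              seed: int = 0) -> ReflectionSet:
    """Noisy amplitudes from a model, with a generated free set."""
    rs = _density.structure_factors(model, d_min)
    rng = np.random.default_rng(seed)
    noisy = np.abs(rs.f * (1.0 + noise_fraction * rng.normal(size=len(rs))))
    out = ReflectionSet(rs.cell, rs.hkl, noisy, noise_fraction * rs.f,
                        phase=rs.phase)
    return generate_free_flags(out, free_fraction, seed=seed + 1)


# ---------------------------------------------------------------------------
# scripted backends


class ScriptedBackends:
    """Deterministic stand-ins for the external engines.

    ``refine`` walks a pre-scripted (R_work, R_free) trajectory (one entry
    per call); ``build_protein`` returns the scenario's reference model
    with the scripted deletion shrinking every call; ``density_modify``
    synthesizes a map from the current model.  A test must size the
    trajectory to the number of refinements it expects; walking off the
    end raises.
    """

    def __init__(self, spec: ScenarioSpec,
                 reference: Optional[StructureModel] = None,
                 rich_maps: bool = False) -> None:
        if not spec.trajectory:
            raise ValueError("scripted trajectory must be non-empty")
        self.spec = spec
        self.reference = reference if reference is not None else make_helix_model(
            spec.n_residues, spec.cell, spec.spacegroup, seed=spec.seed)
        self.rich_maps = rich_maps
        self._call = 0
        self.calls: list[str] = []
        self._build_count = 0

    # -- contract methods -------------------------------------------------
    def refine(self, model, reflections, n_cycles, use_phases=False):
        self.calls.append(f"refine({n_cycles},phases={use_phases})")
        if self._call >= len(self.spec.trajectory):
            raise CraftError("scripted refinement trajectory exhausted")
        r_free = self.spec.trajectory[self._call]
        r_work = max(0.01, r_free - 0.03)
        self._call += 1
        return model, r_work, r_free

    def shift_field_refine(self, model, reflections, n_cycles, resolution_schedule):
        self.calls.append(f"shift_field_refine({n_cycles},{resolution_schedule})")
        return model

    def density_modify(self, reflections, phases, model_for_ncs):
        self.calls.append("density_modify")
        src = model_for_ncs if model_for_ncs is not None and model_for_ncs.n_atoms() \
            else self.reference
        if self.rich_maps:
            return map_from_model(src, grid_spacing=1.0)
        # one blob centred on an existing atom: a valid, non-degenerate map
        # that yields no pickable peaks away from the model, so the cycle
        # engine performs exactly one refinement per cycle
        first = next(iter(src.atoms()))
        tiny = StructureModel(src.cell, src.spacegroup, [Chain("z", [
            Residue("z", 1, "HOH", "", [AtomRecord("O", "O", first.pos.copy())])])])
        return map_from_model(tiny, grid_spacing=1.0)

    def build_protein(self, grid, reflections, sequence, prior_model, seeds,
                      n_cycles):
        self.calls.append(f"build_protein({n_cycles})")
        frac = self.spec.deletion_fraction * max(
            0.0, 1.0 - self.spec.build_recovery_per_cycle * self._build_count)
        self._build_count += 1
        model = delete_residues(self.reference, frac, seed=self.spec.seed + 7)
        if self.spec.perturbation_rmsd > 0:
            model = perturb_model(model, self.spec.perturbation_rmsd,
                                  seed=self.spec.seed + 11)
        return model

    def build_nucleic(self, grid, reflections, sequence, prior_model, n_cycles):
        self.calls.append(f"build_nucleic({n_cycles})")
        return prior_model

    def rebuild_side_chain(self, model, residue_key):
        self.calls.append(f"rebuild_side_chain{residue_key}")
        return model

    def score_residues(self, model, grid):
        self.calls.append("score_residues")
        return make_scores(model, seed=self.spec.seed + 13)


def scripted_backends(spec: ScenarioSpec,
                      reference: Optional[StructureModel] = None) -> ScriptedBackends:
    """Factory for the scripted backend suite (see :class:`ScriptedBackends`)."""
    return ScriptedBackends(spec, reference)
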
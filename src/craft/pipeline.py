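"""The model-building cycle state machine.

A run is a sequence of cycles, each executing seven steps in a fixed
order — pruning, density modification, dummy-atom addition, protein
building, chain pruning, nucleic-acid building, water addition — with
every risky step gated on R_free: the result of refining a modified model
is only accepted when its R_free is strictly better than the previous
refinement's.  The run stops when R_free has not improved on its best
value for a set number of cycles (or at the cycle cap), and the output is
the model from the cycle with the lowest R_free, optionally followed by a
side-chain rebuild at high resolution.

The external engines (shift-field refinement, conventional refinement,
density modification, chain tracing, nucleic-acid building, side-chain
rebuilding, per-residue scoring) enter only through the
:class:`BackendSuite` contract; the engine never looks inside them.
Scripted implementations live in :mod:`craft.synthetic`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Protocol, Sequence

import numpy as np

from . import scoring
from .density import flood_dummy_atoms, pick_waters, positions_to_residues
from .model_io import (CraftError, DensityGrid, ReflectionSet, StructureModel,
                       filter_reflections_for_building, generate_free_flags,
                       validate_free_flags)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "CycleRecord",
    "PipelineState",
    "BackendSuite",
    "initialize",
    "run_cycle",
    "should_stop",
    "accept_if_improved",
    "use_experimental_phases",
    "finalize",
    "run",
]


@dataclass
class PipelineConfig:
    """Tunable parameters of the cycle engine (defaults are the paperless
    production settings of the pipeline family this engine models)."""

    max_cycles: int = 25
    stop_after_no_improvement: int = 4
    buccaneer_cycles_first: int = 3
    buccaneer_cycles_later: int = 2
    nautilus_cycles: int = 3
    refmac_cycles_building: int = 10
    refmac_cycles_pruning: int = 5
    sheetbend_cycles: int = 12
    sheetbend_resolution_schedule: tuple = (6.0, 3.0)
    build_map_dmin_cap: float = 2.0
    phases_off_rwork: float = 0.35
    water_rwork_threshold: float = 0.40
    rebuild_dmin: float = 2.5
    rebuild_rwork: float = 0.30
    prune_skip_dmin: float = 2.3
    prune_chain_len: int = 20
    prune_chain_factor: float = 0.2
    prune_residue_factor: float = 0.5
    prune_cap: float = 0.2
    rebuild_sc_factor: float = 0.25
    rebuild_mc_factor: float = 0.25
    free_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_cycles", "stop_after_no_improvement",
                     "buccaneer_cycles_first", "buccaneer_cycles_later",
                     "nautilus_cycles", "refmac_cycles_building",
                     "refmac_cycles_pruning", "sheetbend_cycles"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("phases_off_rwork", "water_rwork_threshold",
                     "rebuild_rwork", "prune_chain_factor",
                     "prune_residue_factor", "prune_cap",
                     "rebuild_sc_factor", "rebuild_mc_factor"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(open(path).read()))


class BackendSuite(Protocol):
    """Contract for the external engines; each call is treated as pure."""

    def refine(self, model: StructureModel, reflections: ReflectionSet,
               n_cycles: int, use_phases: bool = False): ...

    def shift_field_refine(self, model: StructureModel,
                           reflections: ReflectionSet, n_cycles: int,
                           resolution_schedule: tuple): ...

    def density_modify(self, reflections: ReflectionSet, phases,
                       model_for_ncs: Optional[StructureModel]): ...

    def build_protein(self, grid: DensityGrid, reflections: ReflectionSet,
                      sequence: str, prior_model: Optional[StructureModel],
                      seeds: Sequence, n_cycles: int): ...

    def build_nucleic(self, grid: DensityGrid, reflections: ReflectionSet,
                      sequence: str, prior_model: Optional[StructureModel],
                      n_cycles: int): ...

    def rebuild_side_chain(self, model: StructureModel, residue_key): ...

    def score_residues(self, model: StructureModel,
                       grid: Optional[DensityGrid]): ...


@dataclass
class StepOutcome:
    name: str
    accepted: Optional[bool] = None
    detail: str = ""
    r_work: Optional[float] = None
    r_free: Optional[float] = None


@dataclass
class CycleRecord:
    index: int
    steps: list
    r_work: float
    r_free: float
    n_residues: int


@dataclass
class PipelineState:
    model: StructureModel
    reflections: ReflectionSet
    config: PipelineConfig
    sequence: str = ""
    nucleic_sequence: str = ""
    grid: Optional[DensityGrid] = None
    has_phases: bool = False
    phases_latched_off: bool = False
    seeds: list = field(default_factory=list)
    history: list = field(default_factory=list)
    best_r_free: float = float("inf")
    best_cycle: int = 0
    best_model: Optional[StructureModel] = None
    cycles_since_best: int = 0
    last_r_work: Optional[float] = None
    last_r_free: Optional[float] = None

    @property
    def d_min(self) -> float:
        return self.reflections.d_min


def accept_if_improved(candidate_r_free: float, reference_r_free: float) -> bool:
    """Strictly-better R_free acceptance (ties are rejections)."""
    if not (np.isfinite(candidate_r_free) and np.isfinite(reference_r_free)):
        raise ValueError("R_free values must be finite")
    return candidate_r_free < reference_r_free


def use_experimental_phases(state: PipelineState) -> bool:
    """Latching switch: phases are used until R_work first reaches 35%."""
    return state.has_phases and not state.phases_latched_off


def _observe_r(state: PipelineState, r_work: float, r_free: float) -> None:
    state.last_r_work, state.last_r_free = r_work, r_free
    if r_work <= state.config.phases_off_rwork:
        state.phases_latched_off = True


def _refine(state: PipelineState, backends: BackendSuite,
            model: StructureModel, n_cycles: int, step: str):
    try:
        refined, r_work, r_free = backends.refine(
            model, state.reflections, n_cycles,
            use_phases=use_experimental_phases(state))
    except CraftError:
        raise
    except Exception as exc:
        raise CraftError(f"backend failure in refine ({step}): {exc}") from exc
    return refined, float(r_work), float(r_free)


def initialize(
    starting_model: Optional[StructureModel],
    reflections: ReflectionSet,
    config: PipelineConfig,
    backends: BackendSuite,
    sequence: str = "",
    nucleic_sequence: str = "",
    has_phases: bool = False,
) -> PipelineState:
    """Validate inputs and (when a starting model exists) refine it.

    An unusable free set (no zeros or more than half zeros) is regenerated.
    A starting model receives shift-field refinement over the configured
    resolution schedule followed by conventional refinement, and its
    R_free becomes the baseline the first cycle must beat.
    """
    if not sequence and not nucleic_sequence:
        raise CraftError("a sequence is required")
    if reflections.free_flag is None or not validate_free_flags(reflections):
        logger.warning("free-R flags absent or unusable; regenerating")
        reflections = generate_free_flags(reflections, config.free_fraction,
                                          seed=config.seed)
    if starting_model is None:
        empty = StructureModel(reflections.cell,
                               _sg_from(reflections, backends), [])
        return PipelineState(empty, reflections, config, sequence,
                             nucleic_sequence, has_phases=has_phases)
    state = PipelineState(starting_model, reflections, config, sequence,
                          nucleic_sequence, has_phases=has_phases)
    try:
        model = backends.shift_field_refine(
            starting_model, reflections, config.sheetbend_cycles,
            config.sheetbend_resolution_schedule)
    except Exception as exc:
        raise CraftError(f"backend failure in shift_field_refine: {exc}") from exc
    model, r_work, r_free = _refine(state, backends, model,
                                    config.refmac_cycles_building, "initial")
    state.model = model
    _observe_r(state, r_work, r_free)
    # seed residues for the finding step come from the starting model
    scores = backends.score_residues(model, None)
    state.seeds = scoring.select_seed_residues(model, scores)
    return state


def _sg_from(reflections, backends):
    # reflection sets carry no symmetry; default to P1 for model-free starts
    from .model_io import SpaceGroup
    return SpaceGroup.from_symbol("P 1")


def _strip_transient(model: StructureModel) -> StructureModel:
    out = model.copy()
    out.remove_category("dummy")
    out.remove_category("water")
    return out


def run_cycle(state: PipelineState, backends: BackendSuite) -> PipelineState:
    """Execute one full cycle (steps i–vii) and append its record."""
    cfg = state.config
    index = len(state.history) + 1
    steps: list[StepOutcome] = []

    # (i) chain, residue and side-chain pruning
    if state.model.n_atoms():
        scores = backends.score_residues(state.model, state.grid)
        model, removed_chains = scoring.prune_chains(
            state.model, scores, cfg.prune_chain_len, cfg.prune_chain_factor)
        model, removed_res, removed_sc = scoring.prune_residues_and_sidechains(
            model, scores, index, state.d_min, cfg.prune_residue_factor,
            cfg.prune_cap, cfg.prune_skip_dmin)
        pruned = bool(removed_chains or removed_res or removed_sc)
        if pruned:
            model, rw, rf = _refine(state, backends, model,
                                    cfg.refmac_cycles_pruning, "pruning")
            _observe_r(state, rw, rf)
        state.model = model
        steps.append(StepOutcome(
            "prune", pruned,
            f"chains={len(removed_chains)} residues={len(removed_res)} "
            f"sidechains={len(removed_sc)}",
            state.last_r_work, state.last_r_free))
    else:
        steps.append(StepOutcome("prune", False, "empty model"))

    # (ii) density modification
    try:
        grid = backends.density_modify(state.reflections, None,
                                       state.model if state.model.n_atoms() else None)
    except Exception as exc:
        raise CraftError(f"backend failure in density_modify: {exc}") from exc
    state.grid = grid
    steps.append(StepOutcome("density_modify", True))

    # (iii) dummy-atom addition (phase improvement only)
    build_grid = grid
    if state.model.n_atoms() and state.last_r_free is not None:
        try:
            dummies = flood_dummy_atoms(grid, state.model)
        except CraftError:
            dummies = []
        if dummies:
            hybrid = state.model.copy()
            ch = positions_to_residues(dummies, hybrid.free_chain_id(),
                                       residue_name="DUM")
            hybrid.add_chain(ch)
            baseline = state.last_r_free
            refined, rw, rf = _refine(state, backends, hybrid,
                                      cfg.refmac_cycles_building, "dummy_atoms")
            accepted = accept_if_improved(rf, baseline)
            if accepted:
                state.model = _strip_transient(refined)
                _observe_r(state, rw, rf)
            steps.append(StepOutcome("dummy_atoms", accepted,
                                     f"n={len(dummies)}", rw, rf))
        else:
            steps.append(StepOutcome("dummy_atoms", None, "no peaks"))
    else:
        steps.append(StepOutcome("dummy_atoms", None, "skipped"))

    # waters from the previous cycle were only kept for phase improvement
    state.model = _strip_transient(state.model)

    # (iv) protein building
    n_bucc = cfg.buccaneer_cycles_first if index == 1 else cfg.buccaneer_cycles_later
    build_rs = filter_reflections_for_building(state.reflections,
                                               cfg.build_map_dmin_cap)
    try:
        built = backends.build_protein(build_grid, build_rs, state.sequence,
                                       state.model if state.model.n_atoms() else None,
                                       state.seeds, n_bucc)
    except Exception as exc:
        raise CraftError(f"backend failure in build_protein: {exc}") from exc
    built, rw, rf = _refine(state, backends, built,
                            cfg.refmac_cycles_building, "build_protein")
    _observe_r(state, rw, rf)
    state.model = built
    steps.append(StepOutcome("build_protein", True,
                             f"cycles={n_bucc}", rw, rf))

    # (v) post-building chain pruning
    scores = backends.score_residues(state.model, state.grid)
    model, removed_chains = scoring.prune_chains(
        state.model, scores, cfg.prune_chain_len, cfg.prune_chain_factor)
    if removed_chains:
        model, rw, rf = _refine(state, backends, model,
                                cfg.refmac_cycles_pruning, "chain_prune")
        _observe_r(state, rw, rf)
    state.model = model
    steps.append(StepOutcome("chain_prune", bool(removed_chains),
                             f"chains={len(removed_chains)}",
                             state.last_r_work, state.last_r_free))

    # (vi) nucleic-acid building (skipped without a nucleic sequence)
    if state.nucleic_sequence:
        try:
            built = backends.build_nucleic(state.grid, state.reflections,
                                           state.nucleic_sequence, state.model,
                                           cfg.nautilus_cycles)
        except Exception as exc:
            raise CraftError(f"backend failure in build_nucleic: {exc}") from exc
        built, rw, rf = _refine(state, backends, built,
                                cfg.refmac_cycles_building, "build_nucleic")
        _observe_r(state, rw, rf)
        state.model = built
        steps.append(StepOutcome("build_nucleic", True, "", rw, rf))
    else:
        steps.append(StepOutcome("build_nucleic", None, "no nucleic sequence"))

    # (vii) water addition, gated on R_work
    if (state.last_r_work is not None
            and state.last_r_work < cfg.water_rwork_threshold
            and state.grid is not None and state.model.n_atoms()):
        try:
            waters = pick_waters(state.grid, state.model)
        except CraftError:
            waters = []
        if waters:
            hybrid = state.model.copy()
            hybrid.add_chain(positions_to_residues(waters,
                                                   hybrid.free_chain_id()))
            baseline = state.last_r_free
            refined, rw, rf = _refine(state, backends, hybrid,
                                      cfg.refmac_cycles_building, "waters")
            accepted = accept_if_improved(rf, baseline)
            if accepted:
                state.model = refined
                _observe_r(state, rw, rf)
            steps.append(StepOutcome("waters", accepted,
                                     f"n={len(waters)}", rw, rf))
        else:
            steps.append(StepOutcome("waters", None, "no peaks"))
    else:
        steps.append(StepOutcome("waters", None, "r_work gate"))

    if state.last_r_free is None:
        raise CraftError("cycle completed without any refinement result")

    record = CycleRecord(index, steps, state.last_r_work, state.last_r_free,
                         state.model.n_residues())
    state.history.append(record)
    if record.r_free < state.best_r_free:
        state.best_r_free = record.r_free
        state.best_cycle = index
        state.best_model = state.model.copy()
        state.cycles_since_best = 0
    else:
        state.cycles_since_best += 1
    return state


def should_stop(state: PipelineState) -> bool:
    """Stop when R_free has stalled for the configured count, or at the cap."""
    if not state.history:
        return False
    cfg = state.config
    return (state.cycles_since_best >= cfg.stop_after_no_improvement
            or len(state.history) >= cfg.max_cycles)


def finalize(state: PipelineState, backends: BackendSuite) -> tuple[StructureModel, dict]:
    """Select the lowest-R_free cycle's model and optionally rebuild side chains.

    The rebuild runs only when the data resolution is better than 2.5 Å and
    the selected cycle's R_work is better than 30%; its refined result is
    accepted only on an R_free improvement.
    """
    if not state.history:
        raise CraftError("no completed cycles to finalize")
    cfg = state.config
    best = min(state.history, key=lambda rec: (rec.r_free, rec.index))
    model = state.best_model.copy() if state.best_model is not None else state.model.copy()
    final_r_work, final_r_free = best.r_work, best.r_free
    rebuild_info = {"attempted": False, "accepted": None, "n_selected": 0}
    if state.d_min < cfg.rebuild_dmin and best.r_work < cfg.rebuild_rwork:
        scores = backends.score_residues(model, state.grid)
        keys = scoring.select_sidechain_rebuilds(model, scores,
                                                 cfg.rebuild_sc_factor,
                                                 cfg.rebuild_mc_factor)
        rebuild_info.update(attempted=True, n_selected=len(keys))
        if keys:
            rebuilt = model
            for key in keys:
                try:
                    rebuilt = backends.rebuild_side_chain(rebuilt, key)
                except Exception as exc:
                    raise CraftError(
                        f"backend failure in rebuild_side_chain: {exc}") from exc
            rebuilt, rw, rf = _refine(state, backends, rebuilt,
                                      cfg.refmac_cycles_pruning, "rebuild")
            accepted = accept_if_improved(rf, best.r_free)
            rebuild_info["accepted"] = accepted
            if accepted:
                model = rebuilt
                final_r_work, final_r_free = rw, rf

    report = {
        "cycles": [
            {
                "index": rec.index,
                "r_work": rec.r_work,
                "r_free": rec.r_free,
                "n_residues": rec.n_residues,
                "steps": [asdict(s) for s in rec.steps],
            }
            for rec in state.history
        ],
        "best_cycle": best.index,
        "best_r_free": best.r_free,
        "final_r_work": final_r_work,
        "final_r_free": final_r_free,
        "sidechain_rebuild": rebuild_info,
        "n_cycles": len(state.history),
    }
    return model, report


def run(
    starting_model: Optional[StructureModel],
    reflections: ReflectionSet,
    config: PipelineConfig,
    backends: BackendSuite,
    sequence: str = "",
    nucleic_sequence: str = "",
    has_phases: bool = False,
) -> tuple[StructureModel, dict]:
    """Initialize, cycle until the stop rule fires, and finalize."""
    state = initialize(starting_model, reflections, config, backends,
                       sequence, nucleic_sequence, has_phases)
    while not should_stop(state):
        run_cycle(state, backends)
    return finalize(state, backends)
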
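"""Pruning and selection rules driven by per-residue scores.

Two kinds of per-residue inputs drive these rules: correctness predictions
in [0, 1] for the main chain and side chain (produced upstream by trained
classifiers; here they are simply inputs), and real-valued log-likelihood
(LLK) fit scores from the building engine.

All thresholds are relative: a residue is judged against a factor times the
median score over the whole structure, which makes the rules scale-free.
The residue/side-chain pruning stage is additionally capped so that no more
than a fixed fraction of the structure can be removed at once.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .model_io import CraftError, Residue, StructureModel

__all__ = [
    "ResidueScore",
    "ResidueScores",
    "median_score",
    "prune_chains",
    "prune_residues_and_sidechains",
    "select_sidechain_rebuilds",
    "select_seed_residues",
    "SIDECHAIN_ATOMS",
]

# heavy side-chain atoms beyond C-beta for the standard amino acids
SIDECHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": (),
    "GLY": (),
    "SER": ("OG",),
    "CYS": ("SG",),
    "THR": ("OG1", "CG2"),
    "VAL": ("CG1", "CG2"),
    "LEU": ("CG", "CD1", "CD2"),
    "ILE": ("CG1", "CG2", "CD1"),
    "MET": ("CG", "SD", "CE"),
    "PRO": ("CG", "CD"),
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "ASP": ("CG", "OD1", "OD2"),
    "ASN": ("CG", "OD1", "ND2"),
    "GLU": ("CG", "CD", "OE1", "OE2"),
    "GLN": ("CG", "CD", "OE1", "NE2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "LYS": ("CG", "CD", "CE", "NZ"),
    "ARG": ("CG", "CD", "NE", "CZ", "NH1", "NH2"),
}

_BACKBONE_AND_CB = ("N", "CA", "C", "O", "CB")


@dataclass
class ResidueScore:
    main_chain: Optional[float] = None
    side_chain: Optional[float] = None
    llk: Optional[float] = None


@dataclass
class ResidueScores:
    """Scores keyed by residue identity (chain id, seq number, insertion code)."""

    scores: dict = field(default_factory=dict)

    def get(self, key: tuple) -> ResidueScore:
        return self.scores.get(key, ResidueScore())

    def set(self, key: tuple, **kwargs) -> None:
        sc = self.scores.setdefault(key, ResidueScore())
        for k, v in kwargs.items():
            setattr(sc, k, v)

    def values(self, fieldname: str) -> list[float]:
        out = []
        for sc in self.scores.values():
            v = getattr(sc, fieldname)
            if v is not None:
                out.append(float(v))
        return out

    # JSON records: {"chain", "seqnum", "icode", "main_chain", "side_chain", "llk"}
    @classmethod
    def from_json(cls, path) -> "ResidueScores":
        records = json.loads(Path(path).read_text())
        obj = cls()
        for rec in records:
            key = (rec["chain"], int(rec["seqnum"]), rec.get("icode", ""))
            obj.set(key,
                    main_chain=rec.get("main_chain"),
                    side_chain=rec.get("side_chain"),
                    llk=rec.get("llk"))
        return obj

    def to_json(self, path) -> None:
        records = []
        for (chain, seqnum, icode), sc in self.scores.items():
            rec = {"chain": chain, "seqnum": seqnum, "icode": icode}
            for f in ("main_chain", "side_chain", "llk"):
                v = getattr(sc, f)
                if v is not None:
                    rec[f] = v
            records.append(rec)
        Path(path).write_text(json.dumps(records, indent=1))


def median_score(scores: ResidueScores, fieldname: str) -> float:
    """Median of a score field over all scored residues.

    An even count returns the mean of the two middle values.
    """
    vals = scores.values(fieldname)
    if not vals:
        raise CraftError(f"no residues carry a {fieldname!r} score")
    return float(statistics.median(vals))


def prune_chains(
    model: StructureModel,
    scores: ResidueScores,
    max_chain_len: int = 20,
    factor: float = 0.2,
) -> tuple[StructureModel, list[str]]:
    """Remove short, badly scoring protein chains.

    A protein chain of at most ``max_chain_len`` residues is removed when
    its mean main-chain correctness is below ``factor`` times the median
    main-chain correctness of the whole structure.  Returns the pruned
    model (a copy) and the removed chain ids.
    """
    med = median_score(scores, "main_chain")
    threshold = factor * med
    removed = []
    for ch in model.chains:
        prot = ch.protein_residues()
        if not prot or len(prot) > max_chain_len:
            continue
        vals = [scores.get(r.key).main_chain for r in prot]
        vals = [v for v in vals if v is not None]
        if vals and float(np.mean(vals)) < threshold:
            removed.append(ch.chain_id)
    out = model.copy()
    out.remove_chains(removed)
    return out, removed


def _capped_worst(eligible: list[tuple[float, tuple]], cap_count: int) -> list[tuple]:
    """Lowest-scoring keys first, at most cap_count, ties by residue id."""
    eligible.sort(key=lambda t: (t[0], t[1]))
    return [key for _, key in eligible[:cap_count]]


def prune_residues_and_sidechains(
    model: StructureModel,
    scores: ResidueScores,
    cycle_index: int,
    d_min: float,
    factor: float = 0.5,
    cap: float = 0.2,
    skip_d_min: float = 2.3,
) -> tuple[StructureModel, list[tuple], list[tuple]]:
    """Remove individual residues and truncate side chains by correctness.

    Residues with main-chain correctness below ``factor`` times the median
    are deleted; side chains (atoms beyond C-beta) with side-chain
    correctness below ``factor`` times their median are truncated.  Each
    class is capped at ``cap`` times its population, removing the worst
    first.  The stage is skipped entirely in the first cycle and when the
    data do not extend beyond ``skip_d_min`` resolution.
    """
    if cycle_index <= 1 or d_min > skip_d_min:
        return model.copy(), [], []

    out = model.copy()
    protein = [r for r in out.residues() if r.category == "protein"]

    mc_scored = [(scores.get(r.key).main_chain, r.key) for r in protein
                 if scores.get(r.key).main_chain is not None]
    removed_res: list[tuple] = []
    if mc_scored:
        mc_med = median_score(scores, "main_chain")
        eligible = [(v, k) for v, k in mc_scored if v < factor * mc_med]
        cap_count = int(cap * len(mc_scored))
        removed_res = _capped_worst(eligible, cap_count)
        out.remove_residues(removed_res)

    with_sc = [r for r in out.residues() if r.category == "protein"
               and SIDECHAIN_ATOMS.get(r.name)]
    sc_scored = [(scores.get(r.key).side_chain, r.key) for r in with_sc
                 if scores.get(r.key).side_chain is not None]
    removed_sc: list[tuple] = []
    if sc_scored:
        sc_med = median_score(scores, "side_chain")
        eligible = [(v, k) for v, k in sc_scored if v < factor * sc_med]
        cap_count = int(cap * len(sc_scored))
        removed_sc = _capped_worst(eligible, cap_count)
        for key in removed_sc:
            res = out.get_residue(key)
            res.atoms = [a for a in res.atoms if a.name in _BACKBONE_AND_CB]
    return out, removed_res, removed_sc


def select_sidechain_rebuilds(
    model: StructureModel,
    scores: ResidueScores,
    sc_factor: float = 0.25,
    mc_factor: float = 0.25,
) -> list[tuple]:
    """Residues whose side chain should be rebuilt.

    Selected when the side chain is predicted incorrect (side-chain
    correctness below ``sc_factor`` times the median) while the main chain
    is sound (above ``mc_factor`` times the median), or when side-chain
    atoms are missing relative to the canonical dictionary.  GLY and ALA
    have no rebuildable side chain and are never selected.
    """
    sc_vals = scores.values("side_chain")
    mc_vals = scores.values("main_chain")
    sc_med = float(statistics.median(sc_vals)) if sc_vals else None
    mc_med = float(statistics.median(mc_vals)) if mc_vals else None
    selected = []
    for res in model.residues():
        if res.category != "protein" or res.name in ("GLY", "ALA"):
            continue
        expected = SIDECHAIN_ATOMS.get(res.name)
        if expected is None:
            continue
        sc = scores.get(res.key)
        predicted_bad = (
            sc.side_chain is not None and sc.main_chain is not None
            and sc_med is not None and mc_med is not None
            and sc.side_chain < sc_factor * sc_med
            and sc.main_chain > mc_factor * mc_med
        )
        missing = not res.has_atoms(expected)
        if predicted_bad or missing:
            selected.append(res.key)
    return selected


def select_seed_residues(model: StructureModel, scores: ResidueScores) -> list[tuple]:
    """Every third well-fitting residue, to seed the chain-finding step.

    Residues with an LLK score lower than two (sample) standard deviations
    below the mean are dropped; of the survivors in model order, the 1st,
    4th, 7th, ... are kept.
    """
    seq = [(r.key, scores.get(r.key).llk) for r in model.residues()
           if scores.get(r.key).llk is not None]
    if not seq:
        return []
    llks = np.array([v for _, v in seq], dtype=float)
    mean = float(llks.mean())
    sd = float(llks.std(ddof=1)) if len(llks) > 1 else 0.0
    cutoff = mean - 2.0 * sd
    survivors = [key for (key, v) in seq if v >= cutoff]
    return survivors[::3]
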
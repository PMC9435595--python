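"""Model-vs-reference evaluation metrics.

The headline metric is *model completeness*: the percentage of protein
residues in a reference model that have a matching residue in the built
model, where a residue matches when its N, C-alpha and C atoms are all
within 1 Å.  Because a built model may sit in any symmetry-equivalent
frame, each built chain is first moved over the reference by searching the
space-group operators, the allowed origin shifts (continuous along polar
axes) and lattice translations for the transform that matches the most
residues.

Also here: the F-map correlation (reciprocal-space map correlation:
amplitude products weighted by the cosine of the phase difference),
R factors with a least-squares amplitude scale, the data-quality gate used
to vet test cases, and C-alpha similarity of a predicted model after
least-squares superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .density import structure_factor_values, unique_reflections
from .model_io import (Chain, CraftError, ReflectionSet, StructureModel)
from .symmetry import OriginShift, SymOp, candidate_origin_shifts, polar_axes

__all__ = [
    "ChainMatch",
    "MatchResult",
    "completeness",
    "fmap_correlation",
    "fmap_correlation_from_sf",
    "r_factor",
    "data_completeness",
    "quality_gate",
    "GateResult",
    "superposed_similarity",
    "best_chain_similarity",
    "truncate_by_plddt",
    "mr_score",
    "kabsch_superpose",
]


@dataclass
class ChainMatch:
    chain_id: str
    op: SymOp
    shift: np.ndarray  # resolved fractional origin shift (polar components fitted)
    matched: int


@dataclass
class MatchResult:
    per_chain: list
    matched: int
    reference_total: int

    @property
    def completeness(self) -> float:
        return 100.0 * self.matched / self.reference_total


def _backbone_arrays(residues) -> tuple[np.ndarray, list]:
    """(n, 3, 3) array of N / CA / C positions for complete backbones."""
    coords, keys = [], []
    for res in residues:
        trio = [res.atom(n) for n in ("N", "CA", "C")]
        if all(a is not None for a in trio):
            coords.append([a.pos for a in trio])
            keys.append(res.key)
    return (np.array(coords) if coords else np.empty((0, 3, 3))), keys


def _match_count(built_frac: np.ndarray, ref_frac: np.ndarray,
                 orth: np.ndarray, cutoff: float) -> tuple[np.ndarray, float]:
    """Greedy one-to-one matching of residues by backbone triplets.

    Both inputs are (n, 3, 3) fractional coordinates; distances use the
    minimum-image convention, so whole-lattice translations are free.
    Returns (matched reference indices, mean matched CA distance).
    """
    empty = (np.empty(0, dtype=int), np.empty(0, dtype=int), np.inf)
    if len(built_frac) == 0 or len(ref_frac) == 0:
        return empty
    diff = ref_frac[:, None, :, :] - built_frac[None, :, :, :]  # (R, B, 3, 3)
    diff -= np.round(diff)
    orthd = np.einsum("rbaj,ij->rbai", diff, orth)
    dist = np.linalg.norm(orthd, axis=-1)  # (R, B, 3) per-atom distances
    ok = np.all(dist <= cutoff, axis=-1)  # (R, B)
    ca = dist[:, :, 1]
    used_built: set[int] = set()
    matched_r, matched_b = [], []
    ca_dists = []
    for r in range(len(ref_frac)):
        cands = [b for b in np.nonzero(ok[r])[0] if b not in used_built]
        if not cands:
            continue
        best = min(cands, key=lambda b: ca[r, b])
        used_built.add(best)
        matched_r.append(r)
        matched_b.append(best)
        ca_dists.append(ca[r, best])
    if not matched_r:
        return empty
    return (np.array(matched_r, dtype=int), np.array(matched_b, dtype=int),
            float(np.mean(ca_dists)))


def completeness(built: StructureModel, reference: StructureModel,
                 cutoff: float = 1.0) -> MatchResult:
    """Symmetry- and origin-aware model completeness versus a reference.

    Each built chain independently picks the space-group operator, origin
    shift and lattice translation that match the most reference protein
    residues (N, CA, C all within ``cutoff``); polar origin components are
    resolved by candidate translations derived from CA pairings, refined
    by the mean matched offset.  Reference residues are counted at most
    once globally.
    """
    if not built.cell.approx_equal(reference.cell):
        raise CraftError("built and reference models have different unit cells")
    ref_bb, ref_keys = _backbone_arrays(reference.protein_residues())
    if len(ref_bb) == 0:
        raise CraftError("reference model has no complete protein residues")
    cell = reference.cell
    orth = cell.orth_matrix
    ref_frac = ref_bb @ cell.frac_matrix.T

    sg = reference.spacegroup
    shifts = candidate_origin_shifts(sg)
    polar = polar_axes(sg.ops)

    per_chain = []
    globally_matched: set[int] = set()
    for chain in built.chains:
        bb, _ = _backbone_arrays(chain.protein_residues())
        if len(bb) == 0:
            continue
        frac = bb @ cell.frac_matrix.T
        best = None  # (count, meandist, op, shift, matched_idx)
        for op in sg.ops:
            tf = frac @ op.rot.T + op.tran
            for oshift in shifts:
                base = tf + oshift.shift
                # candidate polar translations from CA pairings (plus zero)
                cands = [np.zeros(3)]
                if polar.any():
                    built_ca = base[: min(3, len(base)), 1, :]
                    for bca in built_ca:
                        delta = ref_frac[:, 1, :] - bca  # (R, 3)
                        delta = np.where(polar, delta, 0.0)
                        cands.extend(delta)
                for cand in cands:
                    shifted = base + cand
                    ridx, bidx, meand = _match_count(shifted, ref_frac, orth, cutoff)
                    if len(ridx) and polar.any():
                        # refine polar components by the mean matched CA offset
                        d = ref_frac[ridx, 1, :] - shifted[bidx, 1, :]
                        d -= np.round(d)
                        fine = np.where(polar, d.mean(axis=0), 0.0)
                        r2, b2, m2 = _match_count(shifted + fine, ref_frac, orth, cutoff)
                        if (len(r2), -m2) > (len(ridx), -meand):
                            ridx, bidx, meand = r2, b2, m2
                            cand = cand + fine
                    score = (len(ridx), -meand)
                    if best is None or score > best[0]:
                        best = (score, op, oshift.shift + cand, ridx)
        if best is None:
            continue
        _, op, shift, idx = best
        per_chain.append(ChainMatch(chain.chain_id, op, shift % 1.0, len(idx)))
        globally_matched.update(int(i) for i in idx)
    return MatchResult(per_chain, len(globally_matched), len(ref_keys))


# ---------------------------------------------------------------------------
# F-map correlation


def fmap_correlation_from_sf(rs_a: ReflectionSet, rs_b: ReflectionSet) -> float:
    """Correlation of two maps from their structure factors.

    ``sum(Fa Fb cos(phi_a - phi_b)) / sqrt(sum Fa^2 * sum Fb^2)`` over the
    common reflections; equals the real-space correlation of the two
    zero-mean maps.
    """
    if rs_a.phase is None or rs_b.phase is None:
        raise CraftError("both reflection sets need phases for F-map correlation")
    index = {tuple(h): i for i, h in enumerate(rs_a.hkl)}
    rows_a, rows_b = [], []
    for j, h in enumerate(rs_b.hkl):
        i = index.get(tuple(h))
        if i is not None:
            rows_a.append(i)
            rows_b.append(j)
    if not rows_a:
        raise CraftError("no common reflections")
    fa, fb = rs_a.f[rows_a], rs_b.f[rows_b]
    dphi = np.radians(rs_a.phase[rows_a] - rs_b.phase[rows_b])
    denom = np.sqrt(np.sum(fa ** 2) * np.sum(fb ** 2))
    if denom == 0:
        raise CraftError("zero amplitudes; correlation undefined")
    return float(np.sum(fa * fb * np.cos(dphi)) / denom)


def fmap_correlation(model_a: StructureModel, model_b: StructureModel,
                     d_min: float) -> float:
    """F-map correlation between the maps of two models, to ``d_min``."""
    if not model_a.cell.approx_equal(model_b.cell):
        raise CraftError("models have different unit cells")
    hkl = unique_reflections(model_a.cell, model_a.spacegroup, d_min)
    fa = structure_factor_values(model_a, hkl)
    fb = structure_factor_values(model_b, hkl)
    denom = np.sqrt(np.sum(np.abs(fa) ** 2) * np.sum(np.abs(fb) ** 2))
    return float(np.sum(np.abs(fa) * np.abs(fb)
                        * np.cos(np.angle(fa) - np.angle(fb))) / denom)


# ---------------------------------------------------------------------------
# R factors


def r_factor(rs_obs: ReflectionSet, model: StructureModel) -> tuple[float, float, float]:
    """(R_all, R_work, R_free) of a model against observed amplitudes.

    ``R = sum| |F_obs| - k |F_calc| | / sum |F_obs|`` with ``k`` the
    least-squares scale fitted on all reflections; the work/free partition
    follows the free-R flag (0 = free).
    """
    if rs_obs.free_flag is None:
        raise CraftError("observed reflections need free-R flags for R_work/R_free")
    fc = np.abs(structure_factor_values(model, rs_obs.hkl))
    fo = rs_obs.f
    if np.sum(fc ** 2) == 0 or np.sum(fo) == 0:
        raise CraftError("degenerate amplitudes; R factor undefined")
    k = float(np.sum(fo * fc) / np.sum(fc ** 2))

    def r(mask):
        if not mask.any():
            return float("nan")
        return float(np.sum(np.abs(fo[mask] - k * fc[mask])) / np.sum(fo[mask]))

    all_mask = np.ones(len(fo), dtype=bool)
    free = rs_obs.free_flag == 0
    return r(all_mask), r(~free), r(free)


def data_completeness(rs: ReflectionSet, spacegroup, d_min: Optional[float] = None) -> float:
    """Observed fraction (%) of the theoretically measurable unique reflections."""
    d_min = rs.d_min if d_min is None else d_min
    theory = unique_reflections(rs.cell, spacegroup, d_min)
    have = {tuple(h) for h in rs.hkl}
    count = sum(1 for h in theory if tuple(h) in have)
    return 100.0 * count / len(theory)


# ---------------------------------------------------------------------------
# quality gate


@dataclass
class GateResult:
    passed: bool
    reasons: list


def quality_gate(d_min: float, r_free: float, data_completeness: float,
                 fmap_corr: float) -> GateResult:
    """Data/model vetting gate.

    Fails when R_free exceeds ``0.06 * d_min + 0.17`` (a resolution-
    dependent ceiling), when the data completeness is below 90%, or when
    the F-map correlation is below 0.2.  All failed clauses are reported.
    """
    reasons = []
    if r_free > 0.06 * d_min + 0.17:
        reasons.append("r_free")
    if data_completeness < 90.0:
        reasons.append("data_completeness")
    if fmap_corr < 0.2:
        reasons.append("fmap_correlation")
    return GateResult(not reasons, reasons)


# ---------------------------------------------------------------------------
# superposition similarity (predicted models)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto target."""
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, ct - rot @ cm


def superposed_similarity(predicted: StructureModel, chain: Chain,
                          cutoff: float = 1.0) -> float:
    """Percentage of chain CA atoms near a predicted CA after superposition.

    The predicted model is truncated to the residues present in the chain
    (matched by residue number), superposed on the common CA atoms, and the
    fraction of chain CA atoms within ``cutoff`` of any predicted CA is
    returned as a percentage.
    """
    chain_ca = {}
    for res in chain.protein_residues():
        a = res.atom("CA")
        if a is not None:
            chain_ca[(res.seqnum, res.icode)] = a.pos
    pred_ca = {}
    for res in predicted.protein_residues():
        a = res.atom("CA")
        if a is not None:
            pred_ca[(res.seqnum, res.icode)] = a.pos
    common = sorted(set(chain_ca) & set(pred_ca))
    if len(common) < 3:
        raise CraftError("fewer than 3 common CA atoms; cannot superpose")
    mobile = np.array([pred_ca[k] for k in common])
    target = np.array([chain_ca[k] for k in common])
    rot, tr = kabsch_superpose(mobile, target)
    moved = np.array([pred_ca[k] for k in common]) @ rot.T + tr
    tree = cKDTree(moved)
    chain_pts = np.array(list(chain_ca.values()))
    d, _ = tree.query(chain_pts)
    return 100.0 * float(np.mean(d <= cutoff))


def best_chain_similarity(predicted: StructureModel,
                          reference: StructureModel) -> tuple[str, float]:
    """Superposed similarity against the best-matching reference chain."""
    best: tuple[str, float] | None = None
    for ch in reference.chains:
        try:
            sim = superposed_similarity(predicted, ch)
        except CraftError:
            continue
        if best is None or sim > best[1]:
            best = (ch.chain_id, sim)
    if best is None:
        raise CraftError("no reference chain shares enough CA atoms")
    return best


def truncate_by_plddt(model: StructureModel, cutoff: float) -> StructureModel:
    """Remove residues whose pLDDT (stored in the B-factor field) is below cutoff."""
    out = model.copy()
    drop = []
    for res in out.residues():
        if not res.atoms:
            continue
        plddt = float(np.mean([a.b_iso for a in res.atoms]))
        if plddt < cutoff:
            drop.append(res.key)
    out.remove_residues(drop)
    if out.n_residues() == 0:
        import warnings
        warnings.warn("pLDDT truncation removed every residue")
    return out


def mr_score(correlation: float, packing: float) -> float:
    """Molecular-replacement score: correlation times packing function.

    The packing function is 1 when no molecules overlap and -1 when they
    overlap completely.
    """
    if not -1.0 <= packing <= 1.0:
        raise ValueError("packing function must lie in [-1, 1]")
    return correlation * packing
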
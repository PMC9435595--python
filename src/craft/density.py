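"""Map statistics, peak picking, dummy-atom flooding, water placement and
structure-factor calculation.

Peak heights are always expressed relative to the map statistics:
``height_sigma = (value - mean) / sigma`` with population statistics over
all voxels.  A peak's volume is the volume of the 6-connected voxel region
(periodic) above the picking threshold that contains it.

Structure factors are computed by direct summation over atoms and
space-group operators with a single-Gaussian form factor per element,
``f(s) = a exp(-b s^2 / 4)`` with ``s = 1/d``.  This is deliberately
simpler than the usual four-Gaussian fits: every consumer in this package
is a correlation or an R factor, which are insensitive to the exact
form-factor shape.  The matching real-space profile (used by
:func:`map_from_model`) is the Fourier transform
``rho(r) = a (4 pi / B)^{3/2} exp(-4 pi^2 r^2 / B)`` with
``B = b + B_iso + extra_width``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy import ndimage

from .model_io import (Chain, CraftError, DensityGrid, Residue, ReflectionSet,
                       StructureModel, AtomRecord)
from .symmetry import SymmetryExpansion, SymOp

__all__ = [
    "Peak",
    "grid_stats",
    "find_peaks",
    "flood_dummy_atoms",
    "pick_waters",
    "map_from_model",
    "structure_factors",
    "structure_factor_values",
    "unique_reflections",
    "positions_to_residues",
]

# single-Gaussian form factors: amplitude = electron count, width b in Å^2.
# widths are rough fits to the small-angle falloff of the tabulated factors;
# unknown elements default to (Z, 15).
FORM_FACTOR_B = {
    "H": 25.0, "C": 16.0, "N": 13.0, "O": 11.0, "S": 6.0, "P": 7.0,
    "SE": 5.0, "FE": 4.0, "MG": 8.0, "ZN": 4.5, "CA": 7.0, "MN": 4.5,
}


def form_factor(element: str) -> tuple[float, float]:
    z = gemmi.Element(element).atomic_number
    if z == 0:
        raise CraftError(f"unknown element {element!r}")
    return float(z), FORM_FACTOR_B.get(element.upper(), 15.0)


@dataclass(frozen=True)
class Peak:
    """A local density maximum."""

    pos: np.ndarray  # orthogonal Å, interpolated
    value: float  # map units at the peak voxel
    height_sigma: float  # (value - mean) / sigma
    volume: float  # Å^3 of the 6-connected region above the threshold


def grid_stats(grid: DensityGrid) -> tuple[float, float]:
    """Population mean and standard deviation over all voxels."""
    if grid.values.size < 8:
        raise CraftError("grid too small for meaningful statistics")
    st = grid.stats
    return st.mean, st.sigma


def _local_maxima_mask(values: np.ndarray) -> np.ndarray:
    """Voxels strictly greater than all 26 periodic neighbours."""
    mask = np.ones_like(values, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                mask &= values > np.roll(values, (di, dj, dk), axis=(0, 1, 2))
    return mask


def _periodic_labels(above: np.ndarray) -> np.ndarray:
    """6-connected labelling with periodic wrap (labels merged across faces)."""
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(above, structure=structure)
    if n == 0:
        return labels
    parent = np.arange(n + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for axis in range(3):
        lo = np.take(labels, 0, axis=axis).ravel()
        hi = np.take(labels, -1, axis=axis).ravel()
        for a, b in zip(lo, hi):
            if a and b:
                union(a, b)
    roots = np.array([find(i) for i in range(n + 1)])
    return roots[labels]


def _interpolated_position(grid: DensityGrid, idx: tuple[int, int, int]) -> np.ndarray:
    """Quadratic (parabolic) sub-voxel refinement along each axis."""
    v = grid.values
    offset = np.zeros(3)
    for axis in range(3):
        n = v.shape[axis]
        sel = list(idx)
        sel[axis] = (idx[axis] - 1) % n
        fm = v[tuple(sel)]
        sel[axis] = (idx[axis] + 1) % n
        fp = v[tuple(sel)]
        f0 = v[idx]
        denom = fm - 2.0 * f0 + fp
        if denom < 0:
            offset[axis] = float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))
    frac = (np.array(idx, dtype=float) + offset) / np.array(v.shape, dtype=float)
    return grid.cell.orthogonalize(frac % 1.0)


def find_peaks(grid: DensityGrid, threshold_sigma: float = 2.0) -> list[Peak]:
    """Locate density peaks at least ``threshold_sigma`` above the mean.

    A peak is a voxel strictly greater than its 26 periodic neighbours with
    ``value >= mean + threshold_sigma * sigma``.  Positions are refined by
    per-axis quadratic interpolation; peaks are returned sorted by
    descending value (ties broken by flat grid index).
    """
    mean, sigma = grid_stats(grid)
    if sigma <= 0.0:
        raise CraftError("degenerate (constant) map: no sigma scale for peaks")
    level = mean + threshold_sigma * sigma
    v = grid.values
    candidates = _local_maxima_mask(v) & (v >= level)
    idxs = np.argwhere(candidates)
    if len(idxs) == 0:
        return []
    labels = _periodic_labels(v >= level)
    counts = np.bincount(labels.ravel())
    vox = grid.voxel_volume
    peaks = []
    for idx in idxs:
        t = tuple(int(i) for i in idx)
        peaks.append(Peak(
            pos=_interpolated_position(grid, t),
            value=float(v[t]),
            height_sigma=float((v[t] - mean) / sigma),
            volume=float(counts[labels[t]] * vox),
        ))
    order = np.lexsort((
        [np.ravel_multi_index(tuple(i), v.shape) for i in idxs],
        [-p.value for p in peaks],
    ))
    return [peaks[i] for i in order]


def flood_dummy_atoms(
    grid: DensityGrid,
    model: StructureModel,
    threshold_sigma: float = 2.0,
    min_model_dist: float = 1.9,
    max_model_dist: float = 10.0,
    min_pair_dist: float = 1.4,
    expand_symmetry: bool = True,
) -> list[np.ndarray]:
    """Positions for dummy (free O) atoms flooded into map peaks.

    Peaks above the sigma threshold are kept when their symmetry-aware
    distance to the model lies in ``[min_model_dist, max_model_dist]``, and
    accepted greedily in descending height subject to a minimum pairwise
    separation among the accepted dummies.
    """
    if model.n_atoms() == 0:
        raise CraftError("cannot flood dummy atoms around an empty model")
    peaks = find_peaks(grid, threshold_sigma)
    if not peaks:
        return []
    exp = SymmetryExpansion(model, expand_symmetry=expand_symmetry)
    dists = exp.nearest(np.array([p.pos for p in peaks]))
    accepted: list[np.ndarray] = []
    for peak, d in zip(peaks, dists):
        if not min_model_dist <= d <= max_model_dist:
            continue
        if any(np.linalg.norm(peak.pos - q) < min_pair_dist for q in accepted):
            continue
        accepted.append(peak.pos)
    return accepted


def pick_waters(
    grid: DensityGrid,
    model: StructureModel,
    threshold_sigma: float = 2.0,
    max_volume: float = 15.0,
    min_any_dist: float = 2.4,
    max_hbond_dist: float = 3.2,
    passes: int = 3,
    expand_symmetry: bool = True,
) -> list[np.ndarray]:
    """Water positions picked from map peaks over several passes.

    A peak becomes a water when its connected volume is below
    ``max_volume``, it is further than ``min_any_dist`` from every current
    atom and within ``max_hbond_dist`` of an N or O atom (a plausible
    hydrogen bond).  Accepted waters join the model as O atoms between
    passes, so outer-shell waters hydrogen-bonded only to earlier waters
    appear in later passes.
    """
    if model.n_atoms() == 0:
        raise CraftError("cannot pick waters around an empty model")
    peaks = find_peaks(grid, threshold_sigma)
    placed: list[np.ndarray] = []
    for _ in range(passes):
        exp = SymmetryExpansion(
            model, expand_symmetry=expand_symmetry,
            extra_positions=np.array(placed) if placed else None,
            extra_elements=["O"] * len(placed),
        )
        remaining = [p for p in peaks
                     if not any(np.array_equal(p.pos, w) for w in placed)]
        if not remaining:
            break
        pts = np.array([p.pos for p in remaining])
        d_any = exp.nearest(pts)
        d_no = exp.nearest_of_elements(pts, ("N", "O"))
        new: list[np.ndarray] = []
        for peak, da, dn in zip(remaining, d_any, d_no):
            if peak.volume >= max_volume:
                continue
            if da <= min_any_dist:
                continue
            # within-pass exclusion against waters just accepted
            if any(np.linalg.norm(peak.pos - w) <= min_any_dist for w in new):
                continue
            if dn > max_hbond_dist:
                continue
            new.append(peak.pos)
        placed.extend(new)
    return placed


def positions_to_residues(
    positions: list[np.ndarray],
    chain_id: str,
    residue_name: str = "HOH",
    atom_name: str = "O",
    b_iso: float = 30.0,
    start_seqnum: int = 1,
) -> Chain:
    """Package picked positions as a chain of single-atom residues."""
    ch = Chain(chain_id)
    for i, pos in enumerate(positions):
        res = Residue(chain_id, start_seqnum + i, residue_name, "",
                      [AtomRecord(atom_name, "O", np.asarray(pos, dtype=float),
                                  1.0, b_iso)])
        ch.residues.append(res)
    return ch


# ---------------------------------------------------------------------------
# map synthesis


def map_from_model(model: StructureModel, grid_spacing: float = 0.7,
                   atom_width_b: float = 0.0) -> DensityGrid:
    """Synthesize a density map as a sum of per-atom 3-D Gaussians.

    Each atom contributes the Fourier mate of its form factor with total
    width ``b_element + B_iso + atom_width_b``, occupancy-weighted, with
    periodic wrap; symmetry mates are included.  The integral of one atom's
    density equals its electron count times its occupancy.
    """
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    cell = model.cell
    shape = tuple(max(4, int(math.ceil(length / grid_spacing)))
                  for length in (cell.a, cell.b, cell.c))
    values = np.zeros(shape)
    lengths = np.array([cell.a, cell.b, cell.c])
    dims = np.array(shape)
    for op in model.spacegroup.ops:
        for atom in model.atoms():
            a, b_elem = form_factor(atom.element)
            btot = b_elem + atom.b_iso + atom_width_b
            amp = atom.occ * a * (4.0 * math.pi / btot) ** 1.5
            decay = 4.0 * math.pi ** 2 / btot
            r_cut = math.sqrt(math.log(1e8) / decay)
            frac = op.apply(cell.fractionalize(atom.pos)) % 1.0
            centre_idx = frac * dims
            # bounding box in grid indices (orthogonal-ish cells assumed for
            # the cutoff; distances below are computed exactly)
            half = np.ceil(r_cut / lengths * dims).astype(int) + 1
            ranges = [np.arange(int(np.floor(centre_idx[i])) - half[i],
                                int(np.ceil(centre_idx[i])) + half[i] + 1)
                      for i in range(3)]
            gi, gj, gk = np.meshgrid(*ranges, indexing="ij")
            frac_pts = np.stack([gi / dims[0], gj / dims[1], gk / dims[2]], axis=-1)
            diff = frac_pts - frac
            diff -= np.round(diff)
            orth = diff.reshape(-1, 3) @ cell.orth_matrix.T
            r2 = np.einsum("ij,ij->i", orth, orth).reshape(gi.shape)
            contrib = amp * np.exp(-decay * r2)
            np.add.at(values,
                      (gi % dims[0], gj % dims[1], gk % dims[2]),
                      contrib)
    return DensityGrid(cell, values)


# ---------------------------------------------------------------------------
# structure factors


def unique_reflections(cell, spacegroup, d_min: float) -> np.ndarray:
    """Unique Miller indices (Laue + Friedel) with d >= d_min, F(000) excluded."""
    if d_min <= 0:
        raise ValueError("d_min must be positive")
    lengths = np.array([cell.a, cell.b, cell.c])
    hmax = np.ceil(lengths / d_min).astype(int) + 1
    h, k, l = np.meshgrid(*(np.arange(-m, m + 1) for m in hmax), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=-1)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    hkl = hkl[cell.d_spacing(hkl) >= d_min]
    rots = {op.rot.tobytes(): op.rot for op in spacegroup.ops}
    keep = []
    for row in hkl:
        orbit = []
        for rot in rots.values():
            img = row @ rot  # h transforms as a row vector
            orbit.append(tuple(img))
            orbit.append(tuple(-img))
        if tuple(row) == max(orbit):
            keep.append(row)
    out = np.array(keep, dtype=int)
    return out[np.lexsort((out[:, 2], out[:, 1], out[:, 0]))]


def structure_factor_values(model: StructureModel, hkl: np.ndarray) -> np.ndarray:
    """Complex structure factors for given Miller indices (direct summation)."""
    if model.n_atoms() == 0:
        raise CraftError("cannot compute structure factors of an empty model")
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    cell = model.cell
    s2 = 1.0 / cell.d_spacing(hkl) ** 2
    atoms = list(model.atoms())
    fracs = cell.fractionalize(np.array([a.pos for a in atoms]))
    ff = np.array([form_factor(a.element) for a in atoms])
    amps = ff[:, 0] * np.array([a.occ for a in atoms])  # (K,)
    widths = ff[:, 1] + np.array([a.b_iso for a in atoms])  # (K,)
    # per-reflection per-atom scattering amplitude
    scat = amps[None, :] * np.exp(-widths[None, :] * s2[:, None] / 4.0)  # (M, K)
    total = np.zeros(len(hkl), dtype=complex)
    for op in model.spacegroup.ops:
        xf = fracs @ op.rot.T + op.tran  # (K, 3)
        phase = np.exp(2j * np.pi * (hkl @ xf.T))  # (M, K)
        total += np.einsum("mk,mk->m", scat, phase)
    return total


def structure_factors(model: StructureModel, d_min: float) -> ReflectionSet:
    """Amplitudes and phases from the model by direct summation to d_min."""
    hkl = unique_reflections(model.cell, model.spacegroup, d_min)
    f = structure_factor_values(model, hkl)
    return ReflectionSet(model.cell, hkl, np.abs(f), np.zeros(len(hkl)),
                         phase=np.degrees(np.angle(f)))
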
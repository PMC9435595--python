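"""Space-group operator algebra and symmetry-expanded distance queries.

Operators act on fractional coordinates as ``x' = R x + t`` with integer
rotation matrices and fractional translations.  Origin shifts are the
translations that leave the whole group invariant; along polar axes of the
group they form a continuum, elsewhere a finite set.  Both facts are needed
to compare a built model with a reference model that may sit in a different
but symmetry-equivalent frame, and to measure distances to a model that is
surrounded by its own crystallographic images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

if TYPE_CHECKING:  # pragma: no cover
    from .model_io import SpaceGroup, StructureModel

__all__ = [
    "SymOp",
    "OriginShift",
    "apply_symop",
    "candidate_origin_shifts",
    "nearest_model_distance",
    "SymmetryExpansion",
]


@dataclass(frozen=True, eq=False)
class SymOp:
    """One space-group operation: fractional rotation matrix + translation."""

    rot: np.ndarray  # (3, 3) integers in the fractional basis
    tran: np.ndarray  # (3,) fractional translation, components in twelfths

    def __post_init__(self) -> None:
        object.__setattr__(self, "rot", np.asarray(self.rot, dtype=int))
        object.__setattr__(self, "tran", np.asarray(self.tran, dtype=float))
        det = round(float(np.linalg.det(self.rot)))
        if det not in (1, -1):
            raise ValueError(f"symmetry rotation has determinant {det}")

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(np.eye(3, dtype=int), np.zeros(3))

    @classmethod
    def from_gemmi(cls, op) -> "SymOp":
        den = float(op.DEN)
        return cls(np.array(op.rot) // op.DEN, np.array(op.tran) / den)

    def apply(self, frac: np.ndarray, wrap: bool = False) -> np.ndarray:
        frac = np.asarray(frac, dtype=float)
        out = frac @ self.rot.T + self.tran
        return out % 1.0 if wrap else out

    def compose(self, other: "SymOp") -> "SymOp":
        """self after other: x -> R_self (R_other x + t_other) + t_self."""
        return SymOp(self.rot @ other.rot, self.rot @ other.tran + self.tran)

    def inverse(self) -> "SymOp":
        rinv = np.linalg.inv(self.rot).round().astype(int)
        return SymOp(rinv, -rinv @ self.tran)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(
            np.array_equal(self.rot, np.eye(3, dtype=int))
            and np.allclose(self.tran % 1.0, 0.0, atol=tol)
        )

    def same_as(self, other: "SymOp", tol: float = 1e-9) -> bool:
        """Equality modulo lattice translations."""
        if not np.array_equal(self.rot, other.rot):
            return False
        d = (self.tran - other.tran) % 1.0
        return bool(np.all((d < tol) | (d > 1.0 - tol)))

    def triplet(self) -> str:
        """Human-readable 'x,y+1/2,-z'-style representation."""
        from fractions import Fraction

        parts = []
        for i in range(3):
            term = ""
            for j, name in enumerate("xyz"):
                c = self.rot[i, j]
                if c == 1:
                    term += ("+" if term else "") + name
                elif c == -1:
                    term += "-" + name
            t = Fraction(self.tran[i]).limit_denominator(24) % 1
            if t:
                term += f"+{t}"
            parts.append(term or "0")
        return ",".join(parts)


@dataclass(frozen=True, eq=False)
class OriginShift:
    """Allowed whole-model origin translation for a space group.

    ``continuous[i]`` is true when axis *i* is polar, i.e. any value of the
    shift component along that axis leaves the group invariant.  For such
    axes ``shift[i]`` is stored as 0 and resolved during model matching.
    """

    shift: np.ndarray  # (3,) fractional
    continuous: np.ndarray  # (3,) bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift", np.asarray(self.shift, dtype=float))
        object.__setattr__(self, "continuous", np.asarray(self.continuous, dtype=bool))


def apply_symop(op: SymOp, pos: np.ndarray, wrap: bool = False) -> np.ndarray:
    """Apply a symmetry operation to a fractional position."""
    return op.apply(pos, wrap=wrap)


def _is_group_invariant_shift(ops: Sequence[SymOp], shift: np.ndarray, tol: float = 1e-9) -> bool:
    """True iff conjugating every op by the shift yields another group op.

    Conjugation by a translation s maps (R, t) to (R, t + (I - R) s); the
    shift is allowed when each conjugated translation coincides, modulo
    lattice translations, with the translation of some group op sharing R.
    """
    eye = np.eye(3)
    for op in ops:
        t_new = op.tran + (eye - op.rot) @ shift
        cand = SymOp(op.rot, t_new)
        if not any(cand.same_as(other, tol) for other in ops):
            return False
    return True


def polar_axes(ops: Sequence[SymOp]) -> np.ndarray:
    """Boolean mask of axes fixed by every rotation (continuous origin)."""
    mask = np.ones(3, dtype=bool)
    eye = np.eye(3, dtype=int)
    for op in ops:
        for i in range(3):
            if not np.array_equal(op.rot @ eye[:, i], eye[:, i]):
                mask[i] = False
    return mask


def candidate_origin_shifts(sg: "SpaceGroup", step: int = 12) -> list[OriginShift]:
    """Enumerate allowed origin shifts of a space group.

    Non-polar components are searched on a 1/``step`` lattice and validated
    with the group-invariance test; polar components are flagged continuous
    and stored as zero.
    """
    ops = sg.ops
    polar = polar_axes(ops)
    grids = [
        np.array([0.0]) if polar[i] else np.arange(step) / step for i in range(3)
    ]
    shifts: list[OriginShift] = []
    for sa in grids[0]:
        for sb in grids[1]:
            for sc in grids[2]:
                s = np.array([sa, sb, sc])
                if _is_group_invariant_shift(ops, s):
                    shifts.append(OriginShift(s, polar.copy()))
    # the zero shift always passes; put it first for deterministic seeding
    shifts.sort(key=lambda o: tuple(o.shift))
    return shifts


class SymmetryExpansion:
    """All atom images of a model under its space group + lattice neighbours.

    Positions are wrapped into the unit cell and replicated over the 27
    neighbouring cells, so any query point wrapped into [0,1) sees the true
    nearest crystallographic contact (for contact distances well below the
    cell dimensions).
    """

    _NEIGHBOURS = np.array(
        [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    )

    def __init__(
        self,
        model: "StructureModel",
        expand_symmetry: bool = True,
        extra_positions: np.ndarray | None = None,
        extra_elements: Sequence[str] | None = None,
    ) -> None:
        cell = model.cell
        pos = []
        elem = []
        for atom in model.atoms():
            pos.append(atom.pos)
            elem.append(atom.element)
        if extra_positions is not None:
            for p, e in zip(np.atleast_2d(extra_positions), extra_elements or []):
                pos.append(np.asarray(p, dtype=float))
                elem.append(e)
        if not pos:
            raise ValueError("model has no atoms to expand")
        pos = np.asarray(pos)
        elem = np.asarray(elem, dtype=object)

        frac = cell.fractionalize(pos)
        ops = model.spacegroup.ops if expand_symmetry else [SymOp.identity()]
        images = []
        images_elem = []
        for op in ops:
            f = (frac @ op.rot.T + op.tran) % 1.0
            for shift in self._NEIGHBOURS:
                images.append(f + shift)
                images_elem.append(elem)
        frac_all = np.concatenate(images)
        self.elements = np.concatenate(images_elem)
        self.positions = cell.orthogonalize(frac_all)
        self._tree = cKDTree(self.positions)
        self._subtrees: dict[frozenset, cKDTree] = {}
        self._cell = cell

    def _wrap(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return self._cell.orthogonalize(self._cell.fractionalize(points) % 1.0)

    def nearest(self, points: np.ndarray) -> np.ndarray:
        """Distance from each query point to the nearest atom image."""
        d, _ = self._tree.query(self._wrap(points))
        return np.atleast_1d(d)

    def nearest_of_elements(self, points: np.ndarray, elements: Iterable[str]) -> np.ndarray:
        """Distance to the nearest image of an atom of the given elements."""
        key = frozenset(elements)
        if key not in self._subtrees:
            mask = np.isin(self.elements.astype(str), list(key))
            if not mask.any():
                return np.full(len(np.atleast_2d(points)), np.inf)
            self._subtrees[key] = cKDTree(self.positions[mask])
        d, _ = self._subtrees[key].query(self._wrap(points))
        return np.atleast_1d(d)


def nearest_model_distance(
    point: np.ndarray, model: "StructureModel", expand_symmetry: bool = True
) -> float:
    """Minimum distance (Å) from a point to any atom of the model.

    With ``expand_symmetry`` the search covers all space-group images and
    lattice translations of the model within the neighbouring cells.
    """
    exp = SymmetryExpansion(model, expand_symmetry=expand_symmetry)
    return float(exp.nearest(np.asarray(point, dtype=float))[0])
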
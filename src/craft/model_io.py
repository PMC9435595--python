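"""Domain types and format IO for crystallographic models, reflections, maps.

The in-memory containers are deliberately small: a hierarchical
:class:`StructureModel` (chains / residues / atoms with a unit cell and
space group), a :class:`ReflectionSet` of Miller-indexed amplitudes and a
:class:`DensityGrid` of map values on a crystallographic grid.  Reading and
writing of PDB, mmCIF, structure-factor mmCIF and CCP4/MRC files is
delegated to :mod:`gemmi`.

Coordinates are stored orthogonal, in Å; fractional coordinates are derived
on demand through the unit cell.  Free-R flags follow the CCP4 convention:
flag value 0 marks the free (cross-validation) set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import gemmi
import numpy as np

from .symmetry import SymOp

logger = logging.getLogger(__name__)

__all__ = [
    "CraftError",
    "FormatError",
    "UnitCell",
    "SpaceGroup",
    "AtomRecord",
    "Residue",
    "Chain",
    "StructureModel",
    "ReflectionSet",
    "GridStats",
    "DensityGrid",
    "read_structure",
    "write_structure",
    "read_reflections",
    "write_reflections",
    "validate_free_flags",
    "generate_free_flags",
    "read_map",
    "write_map",
    "filter_reflections_for_building",
]


class CraftError(Exception):
    """Base class for errors raised by this package."""


class FormatError(CraftError):
    """A file could not be parsed or is missing required records."""


# three-letter codes used to classify residues
PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "MSE", "PHE", "PRO", "SER", "THR", "TRP", "TYR",
    "VAL", "UNK",
}
NUCLEIC_RESIDUES = {"A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI"}
WATER_RESIDUES = {"HOH", "WAT", "H2O", "DOD"}
DUMMY_RESIDUES = {"DUM"}


def residue_category(name: str) -> str:
    name = name.strip().upper()
    if name in PROTEIN_RESIDUES:
        return "protein"
    if name in NUCLEIC_RESIDUES:
        return "nucleic"
    if name in WATER_RESIDUES:
        return "water"
    if name in DUMMY_RESIDUES:
        return "dummy"
    return "other"


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters with orthogonalization helpers.

    Lengths in Å, angles in degrees.  The orthogonalization convention is
    the standard PDB one (a along x, b in the xy plane), as implemented by
    gemmi.
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("cell metric is not positive definite")

    def _gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        return float(self._gemmi().volume)

    @property
    def orth_matrix(self) -> np.ndarray:
        return np.array(self._gemmi().orth.mat.tolist())

    @property
    def frac_matrix(self) -> np.ndarray:
        return np.array(self._gemmi().frac.mat.tolist())

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orth_matrix.T

    def fractionalize(self, orth: np.ndarray) -> np.ndarray:
        return np.asarray(orth, dtype=float) @ self.frac_matrix.T

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) of each Miller index row."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        # |h*|^2 = h^T (F F^T) h with F the fractionalization matrix
        recip_metric = self.frac_matrix @ self.frac_matrix.T
        inv_d2 = np.einsum("ij,jk,ik->i", hkl, recip_metric, hkl)
        return 1.0 / np.sqrt(inv_d2)

    def approx_equal(self, other: "UnitCell", tol: float = 1e-3) -> bool:
        mine = (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        theirs = (other.a, other.b, other.c, other.alpha, other.beta, other.gamma)
        return all(abs(x - y) <= tol * max(1.0, abs(x)) for x, y in zip(mine, theirs))


@dataclass(frozen=True)
class SpaceGroup:
    """A space group: Hermann–Mauguin symbol plus its operator list.

    Operators (including centring copies) come from gemmi's canonical
    tables; any group resolvable from its symbol is supported.
    """

    symbol: str
    ops: tuple = field(repr=False)

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroup":
        try:
            gsg = gemmi.SpaceGroup(symbol)
        except Exception as exc:  # gemmi raises ValueError on unknown symbols
            raise CraftError(f"unsupported space group symbol {symbol!r}") from exc
        ops = tuple(SymOp.from_gemmi(op) for op in gsg.operations())
        return cls(gsg.hm, ops)

    @property
    def order(self) -> int:
        return len(self.ops)


def _canonical_atom_pos(pos) -> np.ndarray:
    arr = np.asarray(pos, dtype=float)
    if arr.shape != (3,) or not np.all(np.isfinite(arr)):
        raise ValueError("atom position must be a finite 3-vector")
    return arr


@dataclass
class AtomRecord:
    """A single atom: name, element, orthogonal position, occ, B.

    For predicted models the B-factor field conventionally carries the
    per-residue pLDDT confidence instead of a displacement parameter.
    """

    name: str
    element: str
    pos: np.ndarray
    occ: float = 1.0
    b_iso: float = 20.0

    def __post_init__(self) -> None:
        self.pos = _canonical_atom_pos(self.pos)
        if gemmi.Element(self.element).atomic_number == 0:
            raise ValueError(f"unrecognized element symbol {self.element!r}")
        if not 0.0 <= self.occ <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.pos.copy(), self.occ, self.b_iso)


@dataclass
class Residue:
    chain_id: str
    seqnum: int
    name: str
    icode: str = ""
    atoms: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.name = self.name.strip().upper()

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.seqnum, self.icode)

    @property
    def category(self) -> str:
        return residue_category(self.name)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names: Iterable[str]) -> bool:
        return all(self.atom(n) is not None for n in names)

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.seqnum, self.name, self.icode,
                       [a.copy() for a in self.atoms])


@dataclass
class Chain:
    chain_id: str
    residues: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def protein_residues(self) -> list:
        return [r for r in self.residues if r.category == "protein"]

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class StructureModel:
    """Hierarchical model: unit cell, space group, ordered chains."""

    cell: UnitCell
    spacegroup: SpaceGroup
    chains: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for res in self.residues():
            if res.key in seen:
                raise ValueError(f"duplicate residue identifier {res.key}")
            seen.add(res.key)

    # --- traversal -------------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        for ch in self.chains:
            yield from ch.residues

    def atoms(self) -> Iterator[AtomRecord]:
        for res in self.residues():
            yield from res.atoms

    def protein_residues(self) -> list:
        return [r for r in self.residues() if r.category == "protein"]

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def n_residues(self) -> int:
        return sum(1 for _ in self.residues())

    def chain(self, chain_id: str) -> Optional[Chain]:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        return None

    def get_residue(self, key: tuple) -> Optional[Residue]:
        ch = self.chain(key[0])
        if ch is None:
            return None
        for r in ch.residues:
            if (r.seqnum, r.icode) == (key[1], key[2]):
                return r
        return None

    def all_positions(self) -> np.ndarray:
        pos = [a.pos for a in self.atoms()]
        if not pos:
            return np.empty((0, 3))
        return np.asarray(pos)

    def copy(self) -> "StructureModel":
        return StructureModel(self.cell, self.spacegroup,
                              [ch.copy() for ch in self.chains])

    # --- editing ---------------------------------------------------------
    def add_chain(self, chain: Chain) -> None:
        if self.chain(chain.chain_id) is not None:
            raise ValueError(f"chain {chain.chain_id!r} already present")
        self.chains.append(chain)

    def remove_chains(self, chain_ids: Iterable[str]) -> None:
        drop = set(chain_ids)
        self.chains = [ch for ch in self.chains if ch.chain_id not in drop]

    def remove_residues(self, keys: Iterable[tuple]) -> None:
        drop = set(keys)
        for ch in self.chains:
            ch.residues = [r for r in ch.residues if r.key not in drop]
        self.chains = [ch for ch in self.chains if ch.residues]

    def remove_category(self, category: str) -> None:
        for ch in self.chains:
            ch.residues = [r for r in ch.residues if r.category != category]
        self.chains = [ch for ch in self.chains if ch.residues]

    def free_chain_id(self) -> str:
        used = {ch.chain_id for ch in self.chains}
        for cid in "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789":
            if cid not in used:
                return cid
        raise CraftError("no free chain identifier left")


# ---------------------------------------------------------------------------
# reflections


@dataclass
class ReflectionSet:
    """Miller-indexed amplitudes with optional free flags and phases.

    ``free_flag`` uses the CCP4 convention (0 = free set).  ``phase`` is in
    degrees, ``fom`` (figure of merit) in [0, 1].
    """

    cell: UnitCell
    hkl: np.ndarray  # (N, 3) int
    f: np.ndarray  # (N,) amplitudes, >= 0
    sigf: np.ndarray  # (N,)
    free_flag: Optional[np.ndarray] = None
    phase: Optional[np.ndarray] = None
    fom: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.f = np.asarray(self.f, dtype=float).ravel()
        self.sigf = np.asarray(self.sigf, dtype=float).ravel()
        n = len(self.hkl)
        if len(self.f) != n or len(self.sigf) != n:
            raise ValueError("column lengths disagree")
        for attr in ("free_flag", "phase", "fom"):
            col = getattr(self, attr)
            if col is not None:
                col = np.asarray(col, dtype=int if attr == "free_flag" else float).ravel()
                if len(col) != n:
                    raise ValueError("column lengths disagree")
                setattr(self, attr, col)
        if np.any(self.f < 0):
            raise ValueError("negative amplitude")
        uniq = {tuple(row) for row in self.hkl}
        if len(uniq) != n:
            raise ValueError("duplicate Miller index")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def d(self) -> np.ndarray:
        return self.cell.d_spacing(self.hkl)

    @property
    def d_min(self) -> float:
        return float(self.d.min()) if len(self) else float("inf")

    def subset(self, mask: np.ndarray) -> "ReflectionSet":
        def take(col):
            return None if col is None else col[mask]

        return ReflectionSet(self.cell, self.hkl[mask], self.f[mask], self.sigf[mask],
                             take(self.free_flag), take(self.phase), take(self.fom))


def validate_free_flags(rs: ReflectionSet) -> bool:
    """Check that the free set is usable: some zeros, but at most half.

    Returns False when the flag column has no zero values or more than 50%
    zero values (such a set must be regenerated before use).
    """
    if rs.free_flag is None:
        raise CraftError("reflection set has no free-R flags")
    frac_zero = float(np.mean(rs.free_flag == 0))
    return 0.0 < frac_zero <= 0.5


def generate_free_flags(rs: ReflectionSet, fraction: float = 0.05,
                        seed: int = 0) -> ReflectionSet:
    """Assign a fresh free-R flag marking ``round(fraction * N)`` reflections.

    Deterministic for a given seed; the result always passes
    :func:`validate_free_flags`.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("free fraction must lie in (0, 0.5)")
    n = len(rs)
    n_free = int(round(fraction * n))
    if n_free == 0:
        raise CraftError("reflection set too small for the requested free fraction")
    rng = np.random.default_rng(seed)
    flags = np.ones(n, dtype=int)
    flags[rng.choice(n, size=n_free, replace=False)] = 0
    out = rs.subset(np.ones(n, dtype=bool))
    out.free_flag = flags
    return out


def filter_reflections_for_building(rs: ReflectionSet,
                                    d_limit: float = 2.0) -> ReflectionSet:
    """Reflection subset used to calculate the map that is built into.

    Drops the free set (so model building cannot see cross-validation data)
    and truncates to a 2 Å resolution limit; lower-resolution sets pass
    through with only the free reflections removed.
    """
    if rs.free_flag is None:
        raise CraftError("free-R flags required to filter building data")
    keep = (rs.free_flag != 0) & (rs.d >= d_limit)
    if not keep.any():
        warnings.warn("no reflections left after building-map filtering")
    return rs.subset(keep)


# ---------------------------------------------------------------------------
# density grids


@dataclass(frozen=True)
class GridStats:
    mean: float
    sigma: float

    @property
    def degenerate(self) -> bool:
        return self.sigma <= 0.0


@dataclass
class DensityGrid:
    """Real-space map sampled on a crystallographic grid.

    ``values[i, j, k]`` is the density at fractional position
    ``(i/nu, j/nv, k/nw)``; the grid is periodic.
    """

    cell: UnitCell
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 2:
            raise ValueError("grid must be 3-D with at least 2 points per axis")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return self.cell.volume / self.values.size

    @property
    def stats(self) -> GridStats:
        # population statistics over all voxels (map-grid convention)
        return GridStats(float(self.values.mean()), float(self.values.std()))

    def frac_coords(self, indices: np.ndarray) -> np.ndarray:
        return np.asarray(indices, dtype=float) / np.asarray(self.shape, dtype=float)


# ---------------------------------------------------------------------------
# structure IO


def _model_from_gemmi(st: gemmi.Structure) -> StructureModel:
    if st.cell.a <= 0 or (st.cell.a == 1 and st.cell.b == 1 and st.cell.c == 1):
        raise FormatError(f"{st.name or 'structure'}: missing unit cell (CRYST1/_cell)")
    if not st.spacegroup_hm:
        raise FormatError("structure has no space-group record")
    cell = UnitCell(st.cell.a, st.cell.b, st.cell.c,
                    st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg = SpaceGroup.from_symbol(st.spacegroup_hm)
    chains = []
    model = st[0]
    for gch in model:
        ch = Chain(gch.name)
        for gres in gch:
            res = Residue(gch.name, gres.seqid.num, gres.name,
                          gres.seqid.icode.strip())
            seen_names = set()
            for ga in gres:
                if ga.has_altloc() and ga.altloc != "A":
                    continue  # first conformer only
                if res.category == "protein" and ga.name in seen_names:
                    raise FormatError(
                        f"duplicate atom {ga.name} in residue {gch.name} {gres.seqid.num}")
                seen_names.add(ga.name)
                res.atoms.append(AtomRecord(ga.name, ga.element.name,
                                            np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                                            ga.occ, ga.b_iso))
            ch.residues.append(res)
        chains.append(ch)
    return StructureModel(cell, sg, chains)


def _model_to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "model"
    st.cell = gemmi.UnitCell(model.cell.a, model.cell.b, model.cell.c,
                             model.cell.alpha, model.cell.beta, model.cell.gamma)
    st.spacegroup_hm = model.spacegroup.symbol
    gm = gemmi.Model("1")
    for ch in model.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
            gres.het_flag = "A" if res.category in ("protein", "nucleic") else "H"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occ
                ga.b_iso = a.b_iso
                gres.add_atom(ga)
            gch.add_residue(gres)
        gm.add_chain(gch)
    st.add_model(gm)
    st.setup_entities()
    return st


def read_structure(path, fmt: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF model file into a :class:`StructureModel`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    st.name = path.name
    return _model_from_gemmi(st)


def write_structure(model: StructureModel, path, fmt: Optional[str] = None) -> None:
    """Write a model as mmCIF (canonical) or PDB (best effort, ≤62 chains)."""
    path = Path(path)
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "mmcif"
    st = _model_to_gemmi(model)
    if fmt == "pdb":
        if len(model.chains) > 62:
            raise CraftError("PDB writing supports at most 62 chains; use mmCIF")
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# reflection IO (structure-factor mmCIF subset)

_REFLN_TAGS = {
    "f": "_refln.F_meas_au",
    "sigf": "_refln.F_meas_sigma_au",
    "flag": "_refln.pdbx_r_free_flag",
    "phase": "_refln.phase_calc",
    "fom": "_refln.fom",
}


def read_reflections(path) -> ReflectionSet:
    """Read a structure-factor mmCIF subset (h, k, l, F, sigF, flag, phase)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = gemmi.cif.read(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    block = doc.sole_block()
    cell_vals = []
    for tag in ("length_a", "length_b", "length_c", "angle_alpha", "angle_beta",
                "angle_gamma"):
        v = block.find_value(f"_cell.{tag}")
        if v is None:
            raise FormatError(f"{path}: missing _cell.{tag}")
        cell_vals.append(float(v))
    cell = UnitCell(*cell_vals)

    def column(tag):
        col = block.find_loop(tag)
        return [x for x in col] if col else None

    h = column("_refln.index_h")
    k = column("_refln.index_k")
    l = column("_refln.index_l")
    f = column(_REFLN_TAGS["f"])
    if h is None or f is None:
        raise FormatError(f"{path}: missing reflection loop (indices/amplitudes)")
    hkl = np.array([h, k, l], dtype=int).T
    f = np.array(f, dtype=float)
    sig = column(_REFLN_TAGS["sigf"])
    sigf = np.array(sig, dtype=float) if sig else np.zeros(len(f))

    def opt(tag, dtype):
        col = column(tag)
        return np.array(col, dtype=dtype) if col else None

    try:
        return ReflectionSet(cell, hkl, f, sigf,
                             free_flag=opt(_REFLN_TAGS["flag"], int),
                             phase=opt(_REFLN_TAGS["phase"], float),
                             fom=opt(_REFLN_TAGS["fom"], float))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_reflections(rs: ReflectionSet, path) -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block("reflections")
    for tag, val in zip(("length_a", "length_b", "length_c", "angle_alpha",
                         "angle_beta", "angle_gamma"),
                        (rs.cell.a, rs.cell.b, rs.cell.c, rs.cell.alpha,
                         rs.cell.beta, rs.cell.gamma)):
        block.set_pair(f"_cell.{tag}", f"{val:.6f}")
    tags = ["_refln.index_h", "_refln.index_k", "_refln.index_l",
            _REFLN_TAGS["f"], _REFLN_TAGS["sigf"]]
    cols = [rs.hkl[:, 0], rs.hkl[:, 1], rs.hkl[:, 2], rs.f, rs.sigf]
    for attr, tag in (("free_flag", _REFLN_TAGS["flag"]),
                      ("phase", _REFLN_TAGS["phase"]),
                      ("fom", _REFLN_TAGS["fom"])):
        col = getattr(rs, attr)
        if col is not None:
            tags.append(tag)
            cols.append(col)
    loop = block.init_loop("", tags)
    for row in zip(*cols):
        loop.add_row([
            str(int(v)) if isinstance(v, (int, np.integer)) else f"{v:.6f}"
            for v in row
        ])
    doc.write_file(str(path))


# ---------------------------------------------------------------------------
# map IO (CCP4/MRC)


def read_map(path) -> DensityGrid:
    """Read a CCP4/MRC volume; axis order is normalized to (u, v, w)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path), setup=True)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable CCP4/MRC map ({exc})") from exc
    mode = ccp4.header_i32(4)
    if mode != 2:
        raise FormatError(f"{path}: unsupported MRC mode {mode} (only mode 2 floats)")
    gcell = ccp4.grid.unit_cell
    cell = UnitCell(gcell.a, gcell.b, gcell.c, gcell.alpha, gcell.beta, gcell.gamma)
    values = np.array(ccp4.grid, copy=True)
    return DensityGrid(cell, values)


def write_map(grid: DensityGrid, path) -> None:
    ccp4 = gemmi.Ccp4Map()
    g = gemmi.FloatGrid(*grid.shape)
    g.set_unit_cell(gemmi.UnitCell(grid.cell.a, grid.cell.b, grid.cell.c,
                                   grid.cell.alpha, grid.cell.beta, grid.cell.gamma))
    g.spacegroup = gemmi.SpaceGroup("P1")
    np.asarray(g, dtype=np.float32)[:] = grid.values.astype(np.float32)
    ccp4.grid = g
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))
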
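"""Crystal structures: CIF input/output, symmetry expansion, molecule extraction.

The in-memory model is deliberately small: a triclinic cell, a list of symmetry
operations in the fractional basis, and the asymmetric-unit atom sites. Whole
molecules are recovered from the expanded cell as connected components of a
covalent-radius bond graph and unwrapped across periodic boundaries, which is
all the downstream landscape analysis needs (densities, dihedrals, RMSD
clusters, per-molecule energies).

CIF handling is built on :mod:`gemmi`: explicit ``_symmetry_equiv_pos_as_xyz``
(or ``_space_group_symop_operation_xyz``) loops take precedence; otherwise a
Hermann–Mauguin symbol or IT number is resolved through gemmi's space-group
table. Partially occupied sites are rejected — landscape structures are fully
ordered by construction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import gemmi
import networkx as nx
import numpy as np

from .errors import (
    CifFormatError,
    ConnectivityError,
    ElementError,
    SymmetryError,
)
from .units import AVOGADRO

__all__ = [
    "UnitCell",
    "AtomSite",
    "SymmetryOp",
    "CrystalStructure",
    "MoleculeInstance",
    "read_cif",
    "write_cif",
    "write_xyz",
    "cell_volume",
    "density",
    "perceive_bonds",
    "extract_molecules",
    "detect_zprime",
    "covalent_radius",
    "atomic_mass",
]

#: Default multiplier on the sum of covalent radii for bond perception.
DEFAULT_BOND_TOLERANCE = 1.2

#: Expanded sites closer than this (Å) indicate special positions / bad symmetry.
MIN_SITE_SEPARATION = 0.1

#: Floor on the H–heavy bond cutoff (Å): tabulated H covalent radii are small
#: enough that scaled-radius sums can fall below real 1.0–1.1 Å X–H bonds.
H_BOND_CUTOFF_FLOOR = 1.3


def _element(symbol: str) -> gemmi.Element:
    el = gemmi.Element(symbol)
    if el.name != symbol.capitalize() or el.covalent_r <= 0 or el.weight <= 0:
        raise ElementError(f"unknown element symbol {symbol!r}")
    return el


def covalent_radius(symbol: str) -> float:
    """Covalent radius in Å for a recognized element symbol."""
    return _element(symbol).covalent_r


def atomic_mass(symbol: str) -> float:
    """Standard atomic mass in g·mol⁻¹."""
    return _element(symbol).weight


@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

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
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0.0:
            raise ValueError("cell angles do not define a positive metric volume")

    def volume(self) -> float:
        """Cell volume in Å³ from the metric-tensor closed form."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return self.a * self.b * self.c * math.sqrt(
            1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        )

    def matrix(self) -> np.ndarray:
        """Row matrix of lattice vectors, a along x, b in the xy plane."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        ax = self.a
        bx, by = self.b * cg, self.b * sg
        cx = self.c * cb
        cy = self.c * (ca - cb * cg) / sg
        cz = math.sqrt(max(self.c * self.c - cx * cx - cy * cy, 0.0))
        return np.array([[ax, 0.0, 0.0], [bx, by, 0.0], [cx, cy, cz]])

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.matrix()

    def cart_to_frac(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ np.linalg.inv(self.matrix())


def cell_volume(cell: UnitCell) -> float:
    """Volume of ``cell`` in Å³."""
    return cell.volume()


@dataclass(frozen=True)
class AtomSite:
    """Asymmetric-unit atom: element symbol, fractional coordinates in [0,1)."""

    element: str
    frac: tuple[float, float, float]
    label: str

    def __post_init__(self) -> None:
        _element(self.element)
        object.__setattr__(self, "frac", tuple(float(x) % 1.0 for x in self.frac))


@dataclass(frozen=True)
class SymmetryOp:
    """Symmetry operation in the fractional basis: x' = R·x + t."""

    rotation: tuple[tuple[int, ...], ...]
    translation: tuple[float, float, float]

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation)
        det = round(float(np.linalg.det(rot)))
        if det not in (1, -1):
            raise SymmetryError(f"rotation determinant must be ±1, got {det}")
        object.__setattr__(
            self, "rotation", tuple(tuple(int(v) for v in row) for row in rot)
        )
        object.__setattr__(self, "translation", tuple(float(t) for t in self.translation))

    @classmethod
    def identity(cls) -> "SymmetryOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymmetryOp":
        try:
            op = gemmi.Op(triplet)
        except (RuntimeError, ValueError) as exc:
            raise SymmetryError(f"cannot parse symmetry triplet {triplet!r}") from exc
        den = gemmi.Op.DEN
        rot = tuple(tuple(v // den for v in row) for row in op.rot)
        tran = tuple(t / den for t in op.tran)
        return cls(rot, tran)

    def to_xyz(self) -> str:
        op = gemmi.Op()
        den = gemmi.Op.DEN
        op.rot = [[v * den for v in row] for row in self.rotation]
        op.tran = [int(round(t * den)) for t in self.translation]
        return op.triplet()

    def is_identity(self) -> bool:
        return self.rotation == ((1, 0, 0), (0, 1, 0), (0, 0, 1)) and all(
            abs(t) < 1e-9 for t in self.translation
        )

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(self.rotation) @ np.asarray(frac, dtype=float) + np.asarray(
            self.translation
        )


@dataclass
class CrystalStructure:
    """A fully ordered molecular crystal (asymmetric unit + symmetry)."""

    id: str
    cell: UnitCell
    ops: list[SymmetryOp]
    sites: list[AtomSite]
    z_total: int | None = None
    z_prime: int | None = None
    provenance: str | None = None

    def __post_init__(self) -> None:
        if not self.ops:
            self.ops = [SymmetryOp.identity()]
        if not self.ops[0].is_identity():
            idx = next((i for i, op in enumerate(self.ops) if op.is_identity()), None)
            if idx is None:
                raise SymmetryError("symmetry operations must include the identity")
            self.ops.insert(0, self.ops.pop(idx))
        labels = [s.label for s in self.sites]
        if len(labels) != len(set(labels)):
            raise CifFormatError(f"duplicate site labels in structure {self.id!r}")
        if self.z_total is not None and self.z_prime is not None:
            if self.z_total != self.z_prime * len(self.ops):
                raise SymmetryError(
                    f"{self.id}: z_total={self.z_total} != z_prime×|ops|="
                    f"{self.z_prime * len(self.ops)}"
                )

    def expand(self) -> tuple[list[str], np.ndarray, list[str], np.ndarray]:
        """Apply every symmetry op to every site.

        Returns (elements, fractional coords in [0,1), labels, op index per atom),
        ordered op-major so each op's copy of the asymmetric unit is contiguous.
        Raises :class:`SymmetryError` if two expanded sites nearly coincide.
        """
        elements: list[str] = []
        labels: list[str] = []
        op_idx: list[int] = []
        fracs: list[np.ndarray] = []
        for k, op in enumerate(self.ops):
            for site in self.sites:
                f = op.apply(np.array(site.frac)) % 1.0
                elements.append(site.element)
                labels.append(site.label)
                op_idx.append(k)
                fracs.append(f)
        frac = np.array(fracs)
        if len(frac) > 1:
            d = _min_image_distances(frac, self.cell)
            np.fill_diagonal(d, np.inf)
            if d.min() < MIN_SITE_SEPARATION:
                i, j = np.unravel_index(np.argmin(d), d.shape)
                raise SymmetryError(
                    f"{self.id}: expanded sites {labels[i]}/{labels[j]} overlap "
                    f"({d[i, j]:.3f} Å); special positions or redundant ops"
                )
        return elements, frac, labels, np.array(op_idx)


@dataclass
class MoleculeInstance:
    """One whole molecule lifted out of the periodic crystal."""

    atom_indices: list[int]
    elements: list[str]
    labels: list[str]
    coords: np.ndarray  # Cartesian Å, unwrapped
    bonds: list[tuple[int, int]]  # local indices
    centroid: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.centroid = self.coords.mean(axis=0)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, e in enumerate(self.elements):
            g.add_node(i, element=e)
        g.add_edges_from(self.bonds)
        return g

    def translated(self, shift: np.ndarray) -> "MoleculeInstance":
        return MoleculeInstance(
            atom_indices=list(self.atom_indices),
            elements=list(self.elements),
            labels=list(self.labels),
            coords=self.coords + shift,
            bonds=list(self.bonds),
        )


# ---------------------------------------------------------------------------
# geometry helpers

_NEIGHBOR_SHIFTS = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def _min_image_vectors(frac: np.ndarray, cell: UnitCell):
    """All-pairs minimum-image Cartesian distances and the image shifts.

    Returns (dist[i,j], shift[i,j]) with shift the integer lattice translation
    to add to atom j's fractional coordinates to realize the minimum image
    relative to atom i.
    """
    m = cell.matrix()
    df = frac[None, :, :] - frac[:, None, :]
    base = -np.round(df)
    best_d = np.full(df.shape[:2], np.inf)
    best_s = np.zeros_like(df)
    for s in _NEIGHBOR_SHIFTS:
        cand = df + base + s
        d = np.linalg.norm(cand @ m, axis=-1)
        better = d < best_d
        best_d = np.where(better, d, best_d)
        best_s[better] = (base + s)[better]
    return best_d, best_s


def _min_image_distances(frac: np.ndarray, cell: UnitCell) -> np.ndarray:
    return _min_image_vectors(frac, cell)[0]


def perceive_bonds(
    coords: np.ndarray,
    elements: list[str],
    cell: UnitCell,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
) -> list[tuple[int, int]]:
    """Covalent bonds by minimum-image distance vs scaled covalent-radius sums.

    ``coords`` are Cartesian Å for the expanded cell. Hydrogens are bonded to
    their single nearest heavy atom only.
    """
    frac = cell.cart_to_frac(np.asarray(coords, dtype=float))
    pairs = _bonded_pairs(frac, elements, cell, tolerance)
    return sorted((i, j) for i, j, _ in pairs)


def _bonded_pairs(frac, elements, cell, tolerance):
    """Bonds as (i, j, shift_j) with i<j; shift_j is j's minimum image vs i."""
    n = len(elements)
    if n < 2:
        return []
    radii = np.array([covalent_radius(e) for e in elements])
    dist, shifts = _min_image_vectors(frac, cell)
    cutoff = (radii[None, :] + radii[:, None]) * tolerance
    np.fill_diagonal(dist, np.inf)
    is_h = np.array([e == "H" for e in elements])
    bonded = dist <= cutoff
    # hydrogens: single bond to the nearest heavy atom
    for i in np.where(is_h)[0]:
        heavy = np.where(~is_h)[0]
        if heavy.size == 0:
            bonded[i, :] = bonded[:, i] = False
            continue
        nearest = heavy[np.argmin(dist[i, heavy])]
        keep = np.zeros(n, dtype=bool)
        if dist[i, nearest] <= max(cutoff[i, nearest], H_BOND_CUTOFF_FLOOR):
            keep[nearest] = True
        bonded[i, :] = bonded[:, i] = False
        bonded[i, keep] = bonded[keep, i] = True
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if bonded[i, j]:
                out.append((i, j, shifts[i, j]))
    return out


def extract_molecules(
    structure: CrystalStructure,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
) -> list[MoleculeInstance]:
    """Whole molecules of the expanded cell, unwrapped across boundaries.

    Connected components of the minimum-image bond graph are traversed
    breadth-first, accumulating image shifts so that no bond crosses a cell
    boundary in the returned Cartesian coordinates.
    """
    elements, frac, labels, _ = structure.expand()
    n = len(elements)
    pairs = _bonded_pairs(frac, elements, structure.cell, tolerance)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    shift_of = {}
    for i, j, s in pairs:
        g.add_edge(i, j)
        shift_of[(i, j)] = np.asarray(s)
        shift_of[(j, i)] = -np.asarray(s)
    molecules = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        start = comp[0]
        unwrapped = {start: frac[start].copy()}
        for u, v in nx.bfs_edges(g.subgraph(comp), start):
            unwrapped[v] = unwrapped[u] + (frac[v] + shift_of[(u, v)] - frac[u])
        idx = comp
        fr = np.array([unwrapped[i] for i in idx])
        local = {a: k for k, a in enumerate(idx)}
        molecules.append(
            MoleculeInstance(
                atom_indices=idx,
                elements=[elements[i] for i in idx],
                labels=[labels[i] for i in idx],
                coords=structure.cell.frac_to_cart(fr),
                bonds=sorted(
                    (local[u], local[v])
                    for u, v in g.subgraph(comp).edges
                ),
            )
        )
    molecules.sort(key=lambda m: m.atom_indices[0])
    if structure.z_total is not None and len(molecules) != structure.z_total:
        raise ConnectivityError(
            f"{structure.id}: found {len(molecules)} molecules, declared "
            f"z_total={structure.z_total}"
        )
    if len(molecules) > 0 and n % len(molecules) != 0:
        raise ConnectivityError(
            f"{structure.id}: {n} atoms do not divide into {len(molecules)} molecules"
        )
    return molecules


def detect_zprime(
    structure: CrystalStructure, tolerance: float = DEFAULT_BOND_TOLERANCE
) -> tuple[int, int]:
    """(Z, Z′): molecules per cell and per asymmetric unit."""
    mols = extract_molecules(structure, tolerance)
    z_total = len(mols)
    n_ops = len(structure.ops)
    if z_total % n_ops != 0:
        raise ConnectivityError(
            f"{structure.id}: {z_total} molecules not divisible by {n_ops} ops"
        )
    return z_total, z_total // n_ops


def asymmetric_molecules(
    structure: CrystalStructure, tolerance: float = DEFAULT_BOND_TOLERANCE
) -> list[MoleculeInstance]:
    """The Z′ symmetry-unique molecules (those built from identity-op atoms)."""
    elements, _, _, op_idx = structure.expand()
    mols = extract_molecules(structure, tolerance)
    unique = [m for m in mols if all(op_idx[i] == 0 for i in m.atom_indices)]
    if not unique:
        # asymmetric unit split across op copies (origin choice); fall back
        unique = mols[: max(1, len(mols) // len(structure.ops))]
    return unique


def density(
    structure: CrystalStructure,
    molar_mass: float | None = None,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
) -> float:
    """Crystal density in g·cm⁻³: ρ = Z·M / (N_A·V).

    If ``molar_mass`` (g·mol⁻¹ per molecule) is omitted it is computed from the
    cell contents (total atomic mass / Z).
    """
    vol = structure.cell.volume()
    if vol <= 0:
        raise ValueError("zero cell volume")
    z = structure.z_total
    if z is None:
        z = detect_zprime(structure, tolerance)[0]
    if molar_mass is None:
        cell_mass = sum(atomic_mass(s.element) for s in structure.sites) * len(structure.ops)
        return cell_mass / (AVOGADRO * 1e-24 * vol)
    return z * molar_mass / (AVOGADRO * 1e-24 * vol)


# ---------------------------------------------------------------------------
# CIF

_CELL_TAGS = {
    "a": "_cell_length_a",
    "b": "_cell_length_b",
    "c": "_cell_length_c",
    "alpha": "_cell_angle_alpha",
    "beta": "_cell_angle_beta",
    "gamma": "_cell_angle_gamma",
}
_SYMOP_TAGS = ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz")
_HM_TAGS = ("_symmetry_space_group_name_H-M", "_space_group_name_H-M_alt")


def _cif_number(block: "gemmi.cif.Block", tag: str) -> float:
    raw = block.find_value(tag)
    if raw is None:
        raise CifFormatError(f"missing required CIF item {tag}")
    val = gemmi.cif.as_number(raw)
    if math.isnan(val):
        raise CifFormatError(f"non-numeric CIF value for {tag}: {raw!r}")
    return val


def read_cif(path) -> CrystalStructure:
    """Read a small-molecule CIF into a :class:`CrystalStructure`.

    Explicit symmetry-operation loops take precedence; otherwise the
    Hermann–Mauguin symbol (or IT number) is resolved via gemmi's table.
    """
    try:
        doc = gemmi.cif.read(str(path))
    except (RuntimeError, ValueError) as exc:
        raise CifFormatError(f"cannot parse CIF {path}: {exc}") from exc
    block = doc.sole_block()
    cell = UnitCell(**{k: _cif_number(block, tag) for k, tag in _CELL_TAGS.items()})

    ops: list[SymmetryOp] = []
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        triplets = [gemmi.cif.as_string(v) for v in col]
        if triplets:
            ops = [SymmetryOp.from_xyz(t) for t in triplets]
            break
    if not ops:
        symbol = None
        for tag in _HM_TAGS:
            raw = block.find_value(tag)
            if raw is not None:
                symbol = gemmi.cif.as_string(raw)
                break
        sg = gemmi.find_spacegroup_by_name(symbol) if symbol else None
        if sg is None:
            raw = block.find_value("_space_group_IT_number")
            if raw is not None:
                sg = gemmi.find_spacegroup_by_number(int(gemmi.cif.as_number(raw)))
        if sg is None:
            raise SymmetryError(
                f"{path}: no symmetry operation loop and no resolvable space-group name"
            )
        ops = [SymmetryOp.from_xyz(op.triplet()) for op in sg.operations()]

    table = block.find(
        "_atom_site_", ["label", "?type_symbol", "fract_x", "fract_y", "fract_z", "?occupancy"]
    )
    if len(table) == 0:
        raise CifFormatError(f"{path}: no _atom_site_ loop")
    sites = []
    for row in table:
        label = gemmi.cif.as_string(row[0])
        symbol = gemmi.cif.as_string(row[1]) if row.has(1) else "".join(
            ch for ch in label if ch.isalpha()
        )
        if row.has(5):
            occ = gemmi.cif.as_number(row[5])
            if not math.isnan(occ) and abs(occ - 1.0) > 1e-6:
                raise CifFormatError(
                    f"{path}: site {label} has occupancy {occ}; only fully "
                    "ordered structures are supported"
                )
        frac = tuple(gemmi.cif.as_number(row[k]) for k in (2, 3, 4))
        if any(math.isnan(x) for x in frac):
            raise CifFormatError(f"{path}: non-numeric coordinates for site {label}")
        try:
            site = AtomSite(element=symbol, frac=frac, label=label)
        except ElementError:
            raise
        sites.append(site)

    z_total = None
    raw = block.find_value("_cell_formula_units_Z")
    if raw is not None:
        z_total = int(gemmi.cif.as_number(raw))
    prov = block.find_value("_polyscape_provenance")
    provenance = gemmi.cif.as_string(prov) if prov is not None else None
    z_prime = None
    if z_total is not None and z_total % len(ops) == 0:
        z_prime = z_total // len(ops)
    return CrystalStructure(
        id=block.name or str(path),
        cell=cell,
        ops=ops,
        sites=sites,
        z_total=z_total,
        z_prime=z_prime,
        provenance=provenance,
    )


def write_cif(structure: CrystalStructure, path) -> None:
    """Write ``structure`` as a CIF re-readable losslessly by :func:`read_cif`."""
    if not structure.sites:
        raise CifFormatError(f"{structure.id}: refusing to write a structure with no sites")
    doc = gemmi.cif.Document()
    block = doc.add_new_block(structure.id)
    c = structure.cell
    for tag, val, fmt in (
        ("_cell_length_a", c.a, "%.6f"),
        ("_cell_length_b", c.b, "%.6f"),
        ("_cell_length_c", c.c, "%.6f"),
        ("_cell_angle_alpha", c.alpha, "%.6f"),
        ("_cell_angle_beta", c.beta, "%.6f"),
        ("_cell_angle_gamma", c.gamma, "%.6f"),
    ):
        block.set_pair(tag, fmt % val)
    if structure.z_total is not None:
        block.set_pair("_cell_formula_units_Z", str(structure.z_total))
    if structure.provenance is not None:
        block.set_pair("_polyscape_provenance", gemmi.cif.quote(structure.provenance))
    loop = block.init_loop("_symmetry_equiv_pos_as_xyz", [""])
    for op in structure.ops:
        loop.add_row([gemmi.cif.quote(op.to_xyz())])
    atoms = block.init_loop(
        "_atom_site_", ["label", "type_symbol", "fract_x", "fract_y", "fract_z"]
    )
    for site in structure.sites:
        atoms.add_row(
            [site.label, site.element]
            + ["%.9f" % x for x in site.frac]
        )
    doc.write_file(str(path))


def write_xyz(structure: CrystalStructure, path) -> None:
    """Export the expanded cell as extended XYZ (debugging aid)."""
    elements, frac, _, _ = structure.expand()
    cart = structure.cell.frac_to_cart(frac)
    m = structure.cell.matrix()
    lattice = " ".join("%.6f" % v for v in m.ravel())
    with open(path, "w") as fh:
        fh.write(f"{len(elements)}\n")
        fh.write(f'Lattice="{lattice}" Properties=species:S:1:pos:R:3 id={structure.id}\n')
        for el, xyz in zip(elements, cart):
            fh.write(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


def supercell_molecules(
    molecules: list[MoleculeInstance],
    cell: UnitCell,
    shells: int = 2,
) -> list[MoleculeInstance]:
    """Lattice translates of ``molecules`` over a (2·shells+1)³ block of cells."""
    m = cell.matrix()
    out = []
    for shift in itertools.product(range(-shells, shells + 1), repeat=3):
        cart_shift = np.array(shift, dtype=float) @ m
        for mol in molecules:
            out.append(mol if shift == (0, 0, 0) else mol.translated(cart_shift))
    return out
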
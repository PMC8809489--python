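"""Synthetic crystal landscapes with a controllable planarity bias.

The generator emulates, at toy scale, the situation where a base-level energy
model (a GGA density functional) spuriously stabilizes the more planar, more
π-conjugated conformations of a flexible molecule, corrupting the polymorph
energy ranking, while matching gas-phase monomer energies at a base and a
target level let the monomer correction remove the bias exactly.

Every structure carries one key torsion θ (an S–C–N–C path in a rigid 10-atom
toy molecule). Ground truth per-molecule energy is a double-well conformational
term w(θ) = w0·sin²(2(θ−θ0)) — minima near 45° and 135°, barrier near 90° —
plus a seeded uniform packing term. The biased base crystal energy subtracts
δ·cos²θ (maximal stabilization of planar θ → 0°/180°), and the monomer pairs
satisfy e_target − e_base = δ·cos²θ, so the correction reconstructs the truth
to machine precision. Near-duplicates are planted by jittering atomic
coordinates, and Birch–Murnaghan phase pairs provide pressure–enthalpy test
curves with analytically known crossovers.

Everything is deterministic under the configured seed. The packing term is
drawn noise rather than an interatomic potential: the pipeline under test
consumes energies, it does not need them to be physical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .correction import EnergyRecord, MonomerEnergyPair
from .crystal_io import AtomSite, CrystalStructure, MoleculeInstance, SymmetryOp, UnitCell
from .errors import PlacementError
from .pressure import EOSParams, PVPoint, PVSeries, bm3_energy, bm3_enthalpy, bm3_volume
from scipy.optimize import brentq

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "LatticeSpec",
    "LandscapeSample",
    "generate_toy_molecule",
    "generate_rigid_chain",
    "generate_crystal",
    "generate_landscape",
    "generate_pv_series",
]

#: Gauge offsets making the synthetic tables look like lattice/monomer energies.
TRUE_ENERGY_OFFSET = -120.0  # kJ·mol⁻¹ per molecule
MONOMER_ENERGY_OFFSET = -50.0  # kJ·mol⁻¹

#: Minimum intermolecular heavy-atom contact accepted by the packer (Å).
#: Kept above the largest scaled covalent-radius sum (S–S: 2.52 Å at tol 1.2)
#: so packed molecules can never merge under bond perception.
MIN_CONTACT = 2.6


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic landscape."""

    n_structures: int = 100
    bias_strength: float = 10.0  # δ, kJ·mol⁻¹
    packing_noise: float = 1.0  # σ, kJ·mol⁻¹ (uniform on ±σ)
    #: mixture over θ in [0,180]: (weight, mean°, std°) components, planar-rich
    #: so red/orange conformations outnumber yellow ones roughly 2:1.
    dihedral_mixture: tuple = ((0.55, 40.0, 20.0), (0.45, 110.0, 28.0))
    duplicate_fraction: float = 0.0
    jitter_xyz: float = 0.05  # Å
    seed: int = 0
    well_depth: float = 6.0  # w0, kJ·mol⁻¹
    well_origin: float = 45.0  # θ0, degrees

    def __post_init__(self) -> None:
        for name in ("bias_strength", "packing_noise", "duplicate_fraction", "jitter_xyz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_structures < 1:
            raise ValueError("n_structures must be ≥ 1")


def conformational_well(theta: float, config: SyntheticConfig) -> float:
    """Double-well conformational energy w(θ), kJ·mol⁻¹."""
    return config.well_depth * math.sin(
        2.0 * math.radians(theta - config.well_origin)
    ) ** 2


def planarity_bias(theta: float, delta: float) -> float:
    """δ·cos²θ — the spurious stabilization of planar conformations."""
    return delta * math.cos(math.radians(theta)) ** 2


# ---------------------------------------------------------------------------
# toy molecule


def _nerf(a, b, c, r, angle_deg, torsion_deg):
    """Place atom d bonded to c with angle(b,c,d) and torsion(a,b,c,d)."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    t, p = math.radians(angle_deg), math.radians(torsion_deg)
    d_local = np.array(
        [-r * math.cos(t), r * math.sin(t) * math.cos(p), r * math.sin(t) * math.sin(p)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def generate_toy_molecule(theta: float) -> MoleculeInstance:
    """Rigid 10-atom molecule with exactly one S–C–N–C path at torsion θ.

    θ in [0, 180] degrees. The fragment is a stand-in for a flexible
    conformational polymorph former: S–C1–N–C2 carries the key torsion, with a
    short carbon tail and hydrogens completing chemically plausible valences.
    """
    if not 0.0 <= theta <= 180.0:
        raise ValueError("theta must lie in [0, 180]")
    s = np.array([0.0, 0.0, 0.0])
    c1 = np.array([1.75, 0.0, 0.0])
    n1 = c1 + 1.38 * np.array([math.cos(math.radians(60)), math.sin(math.radians(60)), 0.0])
    c2 = _nerf(s, c1, n1, 1.40, 125.0, theta)
    c3 = _nerf(c1, n1, c2, 1.48, 115.0, 180.0)
    h1 = _nerf(n1, s, c1, 1.08, 118.0, 180.0)
    h2 = _nerf(s, c1, n1, 1.01, 117.0, theta + 180.0)
    h3 = _nerf(c1, n1, c2, 1.08, 122.0, 0.0)
    h4 = _nerf(n1, c2, c3, 1.09, 110.0, 60.0)
    h5 = _nerf(n1, c2, c3, 1.09, 110.0, -60.0)
    coords = np.array([s, c1, n1, c2, c3, h1, h2, h3, h4, h5])
    elements = ["S", "C", "N", "C", "C", "H", "H", "H", "H", "H"]
    labels = ["S1", "C1", "N1", "C2", "C3", "H1", "H2", "H3", "H4", "H5"]
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (1, 5), (2, 6), (3, 7), (4, 8), (4, 9)]
    return MoleculeInstance(
        atom_indices=list(range(10)),
        elements=elements,
        labels=labels,
        coords=coords,
        bonds=bonds,
    )


def generate_rigid_chain(n_heavy: int, seed: int = 0) -> MoleculeInstance:
    """A rigid self-avoiding carbon chain (bond 1.5 Å) for cluster statistics."""
    rng = np.random.default_rng(seed)
    coords = [np.zeros(3), np.array([1.5, 0.0, 0.0])]
    while len(coords) < n_heavy:
        for _ in range(1000):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cand = coords[-1] + 1.5 * direction
            prev = coords[-1] - coords[-2]
            cos_ang = np.dot(direction, prev / np.linalg.norm(prev))
            if cos_ang < -0.3:  # avoid doubling back
                continue
            if all(np.linalg.norm(cand - p) > 1.9 for p in coords[:-1]):
                coords.append(cand)
                break
        else:
            raise PlacementError("rigid chain construction stalled")
    coords = np.array(coords)
    return MoleculeInstance(
        atom_indices=list(range(n_heavy)),
        elements=["C"] * n_heavy,
        labels=[f"C{i + 1}" for i in range(n_heavy)],
        coords=coords - coords.mean(axis=0),
        bonds=[(i, i + 1) for i in range(n_heavy - 1)],
    )


# ---------------------------------------------------------------------------
# crystal packing


_SPACEGROUP_OPS = {
    "P1": ["x,y,z"],
    "P21": ["x,y,z", "-x,y+1/2,-z"],
}


@dataclass(frozen=True)
class LatticeSpec:
    """Cell plus space-group setting for the toy packer (P1 or P2₁, Z′ = 1)."""

    cell: UnitCell
    spacegroup: str = "P1"

    def ops(self) -> list[SymmetryOp]:
        try:
            triplets = _SPACEGROUP_OPS[self.spacegroup]
        except KeyError:
            raise ValueError(
                f"unsupported space group {self.spacegroup!r}; "
                f"supported: {sorted(_SPACEGROUP_OPS)}"
            ) from None
        return [SymmetryOp.from_xyz(t) for t in triplets]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _heavy_contacts_ok(structure: CrystalStructure, min_contact: float) -> bool:
    elements, frac, _, op_idx = structure.expand()
    heavy = np.array([e != "H" for e in elements])
    cart = structure.cell.frac_to_cart(frac)[heavy]
    ops = np.asarray(op_idx)[heavy]
    m = structure.cell.matrix()
    import itertools as it

    for shift in it.product((-1, 0, 1), repeat=3):
        offset = np.array(shift, dtype=float) @ m
        d = np.linalg.norm(cart[:, None, :] - (cart + offset)[None, :, :], axis=-1)
        if shift == (0, 0, 0):
            inter = ops[:, None] != ops[None, :]
            if inter.any() and d[inter].min() < min_contact:
                return False
        else:
            if d.min() < min_contact:
                return False
    return True


def generate_crystal(
    molecule: MoleculeInstance,
    packing: LatticeSpec,
    seed: int = 0,
    structure_id: str | None = None,
    max_attempts: int = 10_000,
) -> CrystalStructure:
    """Pack one rigid molecule per asymmetric unit into ``packing``.

    Random orientations and offsets are tried until no intermolecular
    heavy-atom contact falls below 2.6 Å; exhaustion raises
    :class:`PlacementError`.
    """
    rng = np.random.default_rng(seed)
    ops = packing.ops()
    sid = structure_id or f"synthetic-{seed}"
    centered = molecule.coords - molecule.coords.mean(axis=0)
    for _ in range(max_attempts):
        rot = _random_rotation(rng)
        t_frac = rng.uniform(0.0, 1.0, size=3)
        cart = centered @ rot.T + packing.cell.frac_to_cart(t_frac)
        frac = packing.cell.cart_to_frac(cart)
        sites = [
            AtomSite(element=el, frac=tuple(f), label=lb)
            for el, f, lb in zip(molecule.elements, frac, molecule.labels)
        ]
        structure = CrystalStructure(
            id=sid,
            cell=packing.cell,
            ops=ops,
            sites=sites,
            z_total=len(ops),
            z_prime=1,
        )
        try:
            ok = _heavy_contacts_ok(structure, MIN_CONTACT)
        except Exception:
            ok = False
        if ok:
            return structure
    raise PlacementError(
        f"{sid}: no non-overlapping placement in {max_attempts} attempts "
        f"(cell {packing.cell.a:.1f}×{packing.cell.b:.1f}×{packing.cell.c:.1f} Å)"
    )


# ---------------------------------------------------------------------------
# landscapes


@dataclass
class SyntheticTruth:
    """Generator bookkeeping: per-structure ground truth."""

    table: pd.DataFrame  # structure_id, theta, true_e_per_molecule, ...

    def theta(self, sid: str) -> float:
        return float(self.table.set_index("structure_id").loc[sid, "theta"])

    def intended_ranking(self) -> list[str]:
        t = self.table.sort_values(["true_e_per_molecule", "structure_id"])
        return list(t["structure_id"])

    def duplicate_partition(self) -> dict[str, set]:
        groups: dict[str, set] = {}
        for row in self.table.itertuples():
            groups.setdefault(row.duplicate_group, set()).add(row.structure_id)
        return groups


@dataclass
class LandscapeSample:
    """One generated landscape: structures, energy tables, and ground truth."""

    config: SyntheticConfig
    structures: dict[str, CrystalStructure] | None
    crystal_energies: pd.DataFrame
    monomer_energies: pd.DataFrame
    truth: SyntheticTruth

    def records(self) -> list[EnergyRecord]:
        """Uncorrected energy records assembled from the generated tables."""
        mono = {
            sid: [
                MonomerEnergyPair(
                    monomer_id=str(r.monomer_id),
                    multiplicity=int(r.multiplicity),
                    e_base=float(r.e_base),
                    e_target=float(r.e_target),
                )
                for r in grp.itertuples()
            ]
            for sid, grp in self.monomer_energies.groupby("structure_id", sort=False)
        }
        return [
            EnergyRecord(
                structure_id=str(r.structure_id),
                e_crystal_cell=float(r.e_crystal_cell),
                z_total=int(r.z_total),
                monomers=mono[str(r.structure_id)],
            )
            for r in self.crystal_energies.itertuples()
        ]


def _draw_theta(rng: np.random.Generator, mixture) -> float:
    weights = np.array([c[0] for c in mixture])
    weights = weights / weights.sum()
    k = rng.choice(len(mixture), p=weights)
    theta = rng.normal(mixture[k][1], mixture[k][2])
    theta = abs(theta)
    if theta > 180.0:
        theta = 360.0 - theta
    return float(min(max(theta, 0.0), 180.0))


def generate_landscape(
    config: SyntheticConfig, with_structures: bool = True
) -> LandscapeSample:
    """Generate a full synthetic landscape under ``config``.

    Structures are P1, Z = 1 toy-molecule crystals in cells of 9.5–11.5 Å.
    ``with_structures=False`` skips crystal packing and returns energy tables
    plus truth only (sufficient for ranking studies).
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_structures
    n_dup = int(round(config.duplicate_fraction * n_total))
    n_unique = n_total - n_dup
    if n_unique < 1:
        raise ValueError("duplicate_fraction leaves no unique structures")

    delta = config.bias_strength
    ids, thetas, trues, groups = [], [], [], []
    for i in range(n_unique):
        theta = _draw_theta(rng, config.dihedral_mixture)
        packing = config.packing_noise * rng.uniform(-1.0, 1.0)
        ids.append(f"xtal-{i:04d}")
        thetas.append(theta)
        trues.append(TRUE_ENERGY_OFFSET + conformational_well(theta, config) + packing)
        groups.append(ids[-1])

    dup_of = rng.choice(n_unique, size=n_dup, replace=False) if n_dup else []
    for k, orig in enumerate(dup_of):
        ids.append(f"{ids[orig]}-dup")
        thetas.append(thetas[orig])
        trues.append(trues[orig] + rng.uniform(-0.05, 0.05))
        groups.append(ids[orig])

    order = sorted(range(len(ids)), key=lambda i: (trues[i], ids[i]))
    ranks = {ids[i]: r for r, i in enumerate(order, start=1)}

    crystal_rows, monomer_rows, truth_rows = [], [], []
    for sid, theta, true_e, group in zip(ids, thetas, trues, groups):
        bias = planarity_bias(theta, delta)
        base_cell = true_e - bias  # z_total = 1
        crystal_rows.append(
            {"structure_id": sid, "e_crystal_cell": base_cell, "z_total": 1}
        )
        monomer_rows.append(
            {
                "structure_id": sid,
                "monomer_id": f"{sid}-m0",
                "multiplicity": 1,
                "e_base": MONOMER_ENERGY_OFFSET - bias,
                "e_target": MONOMER_ENERGY_OFFSET,
            }
        )
        truth_rows.append(
            {
                "structure_id": sid,
                "theta": theta,
                "true_e_per_molecule": true_e,
                "base_e_cell": base_cell,
                "duplicate_group": group,
                "intended_rank": ranks[sid],
            }
        )

    structures = None
    if with_structures:
        structures = {}
        originals: dict[str, CrystalStructure] = {}
        for sid, theta, group in zip(ids, thetas, groups):
            if sid == group:  # an original
                cell = UnitCell(*rng.uniform(9.5, 11.5, size=3))
                mol = generate_toy_molecule(theta)
                structure = generate_crystal(
                    mol,
                    LatticeSpec(cell=cell, spacegroup="P1"),
                    seed=int(rng.integers(2**31)),
                    structure_id=sid,
                )
                structures[sid] = structure
                originals[sid] = structure
            else:  # jittered near-duplicate of its group's original
                src = originals[group]
                noise = rng.normal(0.0, config.jitter_xyz, size=(len(src.sites), 3))
                frac_noise = src.cell.cart_to_frac(noise)
                sites = [
                    AtomSite(
                        element=s.element,
                        frac=tuple(np.array(s.frac) + fn),
                        label=s.label,
                    )
                    for s, fn in zip(src.sites, frac_noise)
                ]
                structures[sid] = CrystalStructure(
                    id=sid,
                    cell=src.cell,
                    ops=list(src.ops),
                    sites=sites,
                    z_total=src.z_total,
                    z_prime=src.z_prime,
                )

    return LandscapeSample(
        config=config,
        structures=structures,
        crystal_energies=pd.DataFrame(crystal_rows),
        monomer_energies=pd.DataFrame(monomer_rows),
        truth=SyntheticTruth(table=pd.DataFrame(truth_rows)),
    )


# ---------------------------------------------------------------------------
# pressure curves


def generate_pv_series(
    eos_a: EOSParams,
    eos_b: EOSParams,
    grid,
    ids: tuple[str, str] = ("phase-a", "phase-b"),
) -> tuple[PVSeries, PVSeries, list[float]]:
    """Sample two Birch–Murnaghan phases on a pressure grid.

    Returns the two PV series plus the analytic enthalpy-equality crossover
    pressures within the grid range (solved on the exact EOS enthalpies, not
    the sampled curves).
    """
    grid = np.sort(np.asarray(grid, dtype=float))

    def series(eos: EOSParams, sid: str) -> PVSeries:
        points = []
        for p in grid:
            v = bm3_volume(float(p), eos)
            points.append(PVPoint(pressure=float(p), energy=float(bm3_energy(v, eos)), volume=v))
        return PVSeries(structure_id=sid, points=points)

    def dh(p: float) -> float:
        return bm3_enthalpy(p, eos_a) - bm3_enthalpy(p, eos_b)

    dense = np.linspace(grid[0], grid[-1], 4001)
    vals = np.array([dh(p) for p in dense])
    # sign changes between nonzero samples; zero runs (identical phases) are
    # not crossings
    nz = np.nonzero(np.sign(vals))[0]
    crossings = []
    for k in range(len(nz) - 1):
        i, j = nz[k], nz[k + 1]
        if vals[i] * vals[j] < 0.0:
            crossings.append(float(brentq(dh, dense[i], dense[j], xtol=1e-10)))
    return series(eos_a, ids[0]), series(eos_b, ids[1]), crossings
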
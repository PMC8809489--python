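"""Conformational analysis: the S–C–N–C torsion, color class, and basins.

For ROY-type conformational polymorphs, crystal color tracks the torsion θ
between the two aromatic ring systems. θ is reported as |θ| in [0°, 180°]:
conformations with 50° ≤ θ ≤ 130° give yellow crystals, while more planar,
more π-conjugated conformations (θ below 50° or above 130°) give red/orange
ones. The gas-phase conformational profile has two basins separated by a
barrier near 80°, which splits the landscape into basin A (θ < 80°) and
basin B (θ ≥ 80°). Boundary ties (exactly 50°, 80°, 130°) are assigned to the
yellow / basin-B side by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .crystal_io import CrystalStructure, MoleculeInstance, asymmetric_molecules
from .errors import DihedralError

__all__ = [
    "DihedralSpec",
    "ConformationRecord",
    "measure_dihedral",
    "classify_color",
    "assign_basin",
    "conformation_profile",
    "SCNC",
]

YELLOW_LOW = 50.0
YELLOW_HIGH = 130.0
BASIN_SPLIT = 80.0


@dataclass(frozen=True)
class DihedralSpec:
    """Selects one ordered atom quadruple per molecule.

    Either four site ``labels``, or an ``element_path`` traced through the bond
    graph (e.g. S–C–N–C). If the element path is ambiguous, quadruples whose
    nitrogen bridges two ring-member carbons are preferred; remaining ambiguity
    is an error rather than a guess.
    """

    labels: tuple[str, str, str, str] | None = None
    element_path: tuple[str, str, str, str] = ("S", "C", "N", "C")

    def resolve(self, molecule: MoleculeInstance) -> tuple[int, int, int, int]:
        if self.labels is not None:
            try:
                return tuple(molecule.labels.index(lb) for lb in self.labels)  # type: ignore[return-value]
            except ValueError as exc:
                raise DihedralError(f"label quadruple {self.labels} not found") from exc
        g = molecule.graph()
        e0, e1, e2, e3 = self.element_path
        quads = []
        for a in g.nodes:
            if molecule.elements[a] != e0:
                continue
            for b in g.neighbors(a):
                if molecule.elements[b] != e1:
                    continue
                for c in g.neighbors(b):
                    if c == a or molecule.elements[c] != e2:
                        continue
                    for d in g.neighbors(c):
                        if d == b or molecule.elements[d] != e3:
                            continue
                        quads.append((a, b, c, d))
        if len(quads) > 1:
            ring_nodes = set().union(*nx.cycle_basis(g)) if g.number_of_edges() else set()
            constrained = [
                q
                for q in quads
                if sum(
                    1
                    for nb in g.neighbors(q[2])
                    if molecule.elements[nb] == "C" and nb in ring_nodes
                )
                >= 2
            ]
            if constrained:
                quads = constrained
        if not quads:
            raise DihedralError(
                f"no {'-'.join(self.element_path)} path in molecule bond graph"
            )
        if len(quads) > 1:
            raise DihedralError(
                f"ambiguous {'-'.join(self.element_path)} path: {len(quads)} candidates"
            )
        return quads[0]


#: Default ROY-style torsion spec.
SCNC = DihedralSpec()


@dataclass(frozen=True)
class ConformationRecord:
    """θ (degrees, |θ| in [0,180]) with its derived color class and basin."""

    theta: float
    color_class: str
    basin: str

    @classmethod
    def from_theta(cls, theta: float) -> "ConformationRecord":
        return cls(theta=theta, color_class=classify_color(theta), basin=assign_basin(theta))


def measure_dihedral(molecule: MoleculeInstance, spec: DihedralSpec = SCNC) -> float:
    """Torsion angle |θ| in degrees over the quadruple selected by ``spec``."""
    i, j, k, l = spec.resolve(molecule)
    p = molecule.coords
    b1, b2, b3 = p[j] - p[i], p[k] - p[j], p[l] - p[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DihedralError("three consecutive atoms are collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / np.linalg.norm(b2))
    return abs(np.degrees(np.arctan2(y, x)))


def _check_range(theta: float) -> None:
    if not 0.0 <= theta <= 180.0:
        raise ValueError(f"theta must lie in [0, 180] degrees, got {theta}")


def classify_color(theta: float) -> str:
    """'yellow' for 50° ≤ θ ≤ 130° (inclusive), else 'red_orange'."""
    _check_range(theta)
    return "yellow" if YELLOW_LOW <= theta <= YELLOW_HIGH else "red_orange"


def assign_basin(theta: float) -> str:
    """'A' for θ < 80°, 'B' otherwise (the boundary goes upward)."""
    _check_range(theta)
    return "A" if theta < BASIN_SPLIT else "B"


def conformation_profile(
    entries: list[tuple[CrystalStructure, float]],
    spec: DihedralSpec = SCNC,
    window: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Tabulate (id, θ, relative energy, color, basin) over a landscape.

    One row per symmetry-unique molecule (Z′ > 1 structures contribute Z′
    rows). Returns the table and, restricted to entries with relative energy
    ≤ ``window`` (all entries if None), the per-color and per-basin counts.
    """
    rows = []
    for structure, rel_energy in entries:
        for mol in asymmetric_molecules(structure):
            theta = measure_dihedral(mol, spec)
            rec = ConformationRecord.from_theta(theta)
            rows.append(
                {
                    "structure_id": structure.id,
                    "theta": theta,
                    "rel_energy": rel_energy,
                    "color_class": rec.color_class,
                    "basin": rec.basin,
                }
            )
    table = pd.DataFrame(
        rows, columns=["structure_id", "theta", "rel_energy", "color_class", "basin"]
    )
    sel = table if window is None else table[table["rel_energy"] <= window]
    counts = {
        "color": sel["color_class"].value_counts().to_dict(),
        "basin": sel["basin"].value_counts().to_dict(),
    }
    return table, counts
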
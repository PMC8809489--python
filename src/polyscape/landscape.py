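"""Ranked energy–density landscapes and packing-similarity analysis.

A crystal energy landscape is the scatter of candidate structures in the
(relative lattice energy per molecule, density) plane, ranked by energy.
Packing similarity between two crystals is quantified COMPACK-style: build an
N-molecule cluster around a central molecule in each structure (the central
molecule plus its N−1 nearest neighbours by centroid distance), pair the
molecules of the two clusters, superpose by least squares, and report the
heavy-atom RMSD (RMSD_N, conventionally N = 15). Near-duplicate landscape
entries are merged when they agree in both energy and RMSD_N; experimental
reference structures are assigned to candidates the same way.

Molecule pairing is transform-guided: after a quick compatibility check on the
sorted centroid-distance sets, the two central molecules are superposed to get
a trial rigid transform, cluster centroids are matched under that transform by
optimal assignment, and the superposition is refined once on all paired heavy
atoms. This is robust to the equidistant centroid shells of a lattice, where
pairing on distances alone is degenerate. Enantiomorph (inverted) matches are
tried by default; hydrogens never enter the RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from . import crystal_io
from .conformation import SCNC, DihedralSpec, classify_color, measure_dihedral
from .correction import EnergyRecord
from .crystal_io import CrystalStructure, MoleculeInstance
from .errors import DihedralError, MatchError

__all__ = [
    "LandscapeEntry",
    "MatchResult",
    "build_landscape",
    "count_in_window",
    "rmsd_n_cluster",
    "deduplicate",
    "label_experimental",
    "landscape_to_frame",
    "ClusterSource",
]

DEFAULT_N = 15
DEFAULT_DISTANCE_TOL = 0.2
DEFAULT_RMSD_TOL = 0.3
DEFAULT_ENERGY_TOL = 0.5
_SUPERCELL_SHELLS = 2  # 5×5×5 block


@dataclass
class LandscapeEntry:
    """One structure on the landscape."""

    structure_id: str
    rel_energy: float  # kJ·mol⁻¹ per molecule vs the global minimum
    density: float  # g·cm⁻³
    color_class: str | None = None
    experimental_label: str | None = None
    rank: int = 0


@dataclass(frozen=True)
class MatchResult:
    """Outcome of an N-molecule cluster comparison."""

    n_matched: int
    rmsd: float
    success: bool


def build_landscape(
    records: list[EnergyRecord],
    structures: dict[str, CrystalStructure],
    dihedral: DihedralSpec | None = SCNC,
) -> list[LandscapeEntry]:
    """Rank records by per-molecule energy and attach density and color.

    Ties are broken lexicographically on structure id; the global minimum
    defines rel_energy = 0 and rank 1.
    """
    ids = [r.structure_id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate structure ids among records")
    ordered = sorted(records, key=lambda r: (r.e_per_molecule, r.structure_id))
    e_min = ordered[0].e_per_molecule
    entries = []
    for rank, rec in enumerate(ordered, start=1):
        structure = structures[rec.structure_id]
        color = None
        if dihedral is not None:
            try:
                mol = crystal_io.asymmetric_molecules(structure)[0]
                color = classify_color(measure_dihedral(mol, dihedral))
            except DihedralError:
                color = None
        entries.append(
            LandscapeEntry(
                structure_id=rec.structure_id,
                rel_energy=rec.e_per_molecule - e_min,
                density=crystal_io.density(structure),
                color_class=color,
                experimental_label=structure.provenance,
                rank=rank,
            )
        )
    return entries


def count_in_window(
    landscape: list[LandscapeEntry],
    window: float,
    predicate=None,
) -> int:
    """Entries with rel_energy ≤ window (inclusive) satisfying ``predicate``."""
    if window < 0:
        raise ValueError("energy window must be nonnegative")
    return sum(
        1
        for e in landscape
        if e.rel_energy <= window and (predicate is None or predicate(e))
    )


# ---------------------------------------------------------------------------
# RMSD_N packing similarity


class ClusterSource:
    """Cached molecule expansion of one structure for repeated comparisons."""

    def __init__(self, structure: CrystalStructure, bond_tolerance: float = crystal_io.DEFAULT_BOND_TOLERANCE):
        self.structure = structure
        self.molecules = crystal_io.extract_molecules(structure, bond_tolerance)
        if not self.molecules:
            raise MatchError(f"{structure.id}: no molecules")
        self.supercell = crystal_io.supercell_molecules(
            self.molecules, structure.cell, shells=_SUPERCELL_SHELLS
        )
        self._centroids = np.array([m.centroid for m in self.supercell])
        self._heavy = [m.coords[m.heavy_mask] for m in self.supercell]

    def central_molecule_index(self) -> int:
        center = self.structure.cell.frac_to_cart(np.array([0.5, 0.5, 0.5]))
        cell_cents = np.array([m.centroid for m in self.molecules])
        return int(np.argmin(np.linalg.norm(cell_cents - center, axis=1)))

    def cluster(self, center_idx: int, n: int, margin: float = 0.0) -> list[int]:
        """Indices (into the supercell list) of the n-molecule cluster.

        With ``margin`` > 0, every molecule within (n-th distance + margin) is
        included (capped at 3n) so that degenerate neighbour shells — where
        the n-th nearest molecule is not unique — cannot exclude the member a
        partner cluster happens to contain.
        """
        if n > len(self.supercell):
            raise MatchError(
                f"{self.structure.id}: cluster size {n} exceeds the "
                f"{2 * _SUPERCELL_SHELLS + 1}³ supercell ({len(self.supercell)} molecules)"
            )
        c = self.molecules[center_idx].centroid
        d = np.linalg.norm(self._centroids - c, axis=1)
        order = np.lexsort((np.arange(len(d)), np.round(d, 9)))
        count = n
        if margin > 0.0:
            cutoff = d[order[n - 1]] + margin
            count = min(int(np.sum(d <= cutoff)), max(3 * n, n), len(order))
            count = max(count, n)
        return list(order[:count])

    def heavy_coords(self, idx: int, invert: bool) -> np.ndarray:
        coords = self._heavy[idx]
        return -coords if invert else coords

    def centroid(self, idx: int, invert: bool) -> np.ndarray:
        c = self._centroids[idx]
        return -c if invert else c


def _as_source(obj) -> ClusterSource:
    return obj if isinstance(obj, ClusterSource) else ClusterSource(obj)


def _heavy_graph(mol: MoleculeInstance) -> nx.Graph:
    g = mol.graph()
    return g.subgraph([i for i in g.nodes if mol.elements[i] != "H"])


def _heavy_atom_map(a: MoleculeInstance, b: MoleculeInstance) -> np.ndarray:
    """Indices into b's heavy atoms matching a's heavy-atom order."""
    ha = [i for i, e in enumerate(a.elements) if e != "H"]
    hb = [i for i, e in enumerate(b.elements) if e != "H"]
    if len(ha) != len(hb):
        raise MatchError("heavy-atom counts differ; molecules are not the same species")
    if [a.elements[i] for i in ha] == [b.elements[i] for i in hb]:
        return np.arange(len(ha))
    gm = nx.algorithms.isomorphism.GraphMatcher(
        _heavy_graph(a),
        _heavy_graph(b),
        node_match=lambda x, y: x["element"] == y["element"],
    )
    if not gm.is_isomorphic():
        raise MatchError("heavy-atom skeletons are not graph-isomorphic")
    mapping = gm.mapping
    pos_b = {atom: k for k, atom in enumerate(hb)}
    return np.array([pos_b[mapping[i]] for i in ha])


def _kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> tuple[float, Rotation, np.ndarray, np.ndarray]:
    """Least-squares superpose b onto a; returns (rmsd, rotation, ca, cb)."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a - ca, b - cb)
    return float(rssd) / np.sqrt(len(a)), rot, ca, cb


def rmsd_n_cluster(
    a,
    b,
    n: int = DEFAULT_N,
    distance_tol: float = DEFAULT_DISTANCE_TOL,
    allow_inversion: bool = True,
) -> MatchResult:
    """COMPACK-style N-molecule cluster comparison of two crystals.

    ``a`` and ``b`` are :class:`CrystalStructure` or pre-built
    :class:`ClusterSource` objects. The cluster in ``a`` is centred on the
    molecule nearest the cell midpoint; every molecule of ``b`` is tried as the
    opposing centre (both hands if ``allow_inversion``) and the best result is
    kept. RMSD is over non-hydrogen atoms of the paired molecules.
    """
    src_a, src_b = _as_source(a), _as_source(b)
    atom_map = _heavy_atom_map(src_a.molecules[0], src_b.molecules[0])

    ia = src_a.central_molecule_index()
    cluster_a = src_a.cluster(ia, n)
    cen_a = src_a.centroid(cluster_a[0], False)
    cents_a = np.array([src_a.centroid(k, False) for k in cluster_a]) - cen_a
    d_a = np.linalg.norm(cents_a, axis=1)
    coords_a = [src_a.heavy_coords(k, False) for k in cluster_a]

    best = MatchResult(n_matched=0, rmsd=np.inf, success=False)
    hands = (False, True) if allow_inversion else (False,)
    shell_margin = distance_tol * max(float(d_a[-1]), 1.0)
    for invert in hands:
        for jb in range(len(src_b.molecules)):
            cluster_b = src_b.cluster(jb, n, margin=shell_margin)
            cen_b = src_b.centroid(cluster_b[0], invert)
            cents_b = np.array(
                [src_b.centroid(k, invert) for k in cluster_b]
            ) - cen_b
            d_b = np.linalg.norm(cents_b, axis=1)
            # compatibility of the sorted centroid-distance sets
            d_b_head = d_b[:n]
            tol_abs = distance_tol * np.maximum(np.maximum(d_a, d_b_head), 1.0)
            if np.any(np.abs(d_a - d_b_head) > tol_abs):
                continue
            coords_b = [src_b.heavy_coords(k, invert)[atom_map] for k in cluster_b]
            # trial transform from the two central molecules
            try:
                _, rot, ca0, cb0 = _kabsch_rmsd(coords_a[0], coords_b[0])
            except ValueError:
                continue
            result = None
            for _ in range(2):
                mapped = rot.apply(cents_b + cen_b - cb0) + ca0 - cen_a
                cost = np.linalg.norm(
                    cents_a[:, None, :] - mapped[None, :, :], axis=-1
                )
                rows, cols = linear_sum_assignment(cost)
                ok = cost[rows, cols] <= distance_tol * np.maximum(d_a[rows], 1.0)
                pairs = [(r, c) for r, c, good in zip(rows, cols, ok) if good]
                if not pairs:
                    result = MatchResult(0, np.inf, False)
                    break
                stack_a = np.vstack([coords_a[r] for r, _ in pairs])
                stack_b = np.vstack([coords_b[c] for _, c in pairs])
                # refine the transform on all paired heavy atoms, then loop
                # once more so the assignment can benefit from it
                rmsd, rot, ca0, cb0 = _kabsch_rmsd(stack_a, stack_b)
                result = MatchResult(len(pairs), rmsd, len(pairs) == n)
            if result is not None and (
                result.n_matched > best.n_matched
                or (result.n_matched == best.n_matched and result.rmsd < best.rmsd)
            ):
                best = result
            if best.success and best.rmsd < 1e-12:
                return best
    return best


# ---------------------------------------------------------------------------
# deduplication and experimental labeling


def _rerank(entries: list[LandscapeEntry]) -> list[LandscapeEntry]:
    ordered = sorted(entries, key=lambda e: (e.rel_energy, e.structure_id))
    e_min = ordered[0].rel_energy
    return [
        replace(e, rel_energy=e.rel_energy - e_min, rank=i)
        for i, e in enumerate(ordered, start=1)
    ]


def deduplicate(
    landscape: list[LandscapeEntry],
    structures: dict[str, CrystalStructure],
    rmsd_tol: float = DEFAULT_RMSD_TOL,
    energy_tol: float = DEFAULT_ENERGY_TOL,
    n: int = DEFAULT_N,
    distance_tol: float = DEFAULT_DISTANCE_TOL,
) -> tuple[list[LandscapeEntry], list[dict]]:
    """Merge near-duplicates: energy gap ≤ energy_tol AND RMSD_N ≤ rmsd_tol.

    The lower-energy member of each duplicate group survives (lexicographic on
    ties); ranks and relative energies are recomputed. Returns the reduced
    landscape and a merge log with one row per collapsed structure.
    """
    entries = sorted(landscape, key=lambda e: (e.rel_energy, e.structure_id))
    sources: dict[str, ClusterSource] = {}

    def source(sid: str) -> ClusterSource:
        if sid not in sources:
            sources[sid] = ClusterSource(structures[sid])
        return sources[sid]

    parent = {e.structure_id: e.structure_id for e in entries}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merge_log = []
    for i, ei in enumerate(entries):
        for ej in entries[i + 1 :]:
            if ej.rel_energy - ei.rel_energy > energy_tol:
                break
            if find(ei.structure_id) == find(ej.structure_id):
                continue
            match = rmsd_n_cluster(
                source(ei.structure_id),
                source(ej.structure_id),
                n=n,
                distance_tol=distance_tol,
            )
            if match.success and match.rmsd <= rmsd_tol:
                # ei precedes ej in (energy, id) order, so ei survives
                parent[find(ej.structure_id)] = find(ei.structure_id)
                merge_log.append(
                    {
                        "kept": ei.structure_id,
                        "removed": ej.structure_id,
                        "rmsd": match.rmsd,
                        "energy_gap": ej.rel_energy - ei.rel_energy,
                    }
                )
    survivors = [e for e in entries if find(e.structure_id) == e.structure_id]
    return _rerank(survivors), merge_log


def label_experimental(
    landscape: list[LandscapeEntry],
    candidates: dict[str, CrystalStructure],
    references: dict[str, CrystalStructure],
    rmsd_tol: float = DEFAULT_RMSD_TOL,
    n: int = DEFAULT_N,
    distance_tol: float = DEFAULT_DISTANCE_TOL,
) -> tuple[list[LandscapeEntry], list[str]]:
    """Assign experimental form names to landscape entries by best RMSD_N.

    Each reference labels at most one entry and vice versa (globally greedy on
    ascending RMSD among successful matches under ``rmsd_tol``). Returns the
    relabeled landscape and the names of references that matched nothing.
    """
    cand_sources = {e.structure_id: ClusterSource(candidates[e.structure_id]) for e in landscape}
    scored = []
    for name, ref in references.items():
        ref_src = ClusterSource(ref)
        for e in landscape:
            try:
                match = rmsd_n_cluster(
                    cand_sources[e.structure_id], ref_src, n=n, distance_tol=distance_tol
                )
            except MatchError:
                continue
            if match.success and match.rmsd <= rmsd_tol:
                scored.append((match.rmsd, name, e.structure_id))
    scored.sort()
    used_refs: set[str] = set()
    used_entries: set[str] = set()
    assignment: dict[str, str] = {}
    for rmsd, name, sid in scored:
        if name in used_refs or sid in used_entries:
            continue
        assignment[sid] = name
        used_refs.add(name)
        used_entries.add(sid)
    out = [
        replace(e, experimental_label=assignment.get(e.structure_id, e.experimental_label))
        for e in landscape
    ]
    unmatched = [name for name in references if name not in used_refs]
    return out, unmatched


def landscape_to_frame(landscape: list[LandscapeEntry]) -> pd.DataFrame:
    """Landscape as a tidy table (the data behind an energy–density plot)."""
    return pd.DataFrame(
        {
            "structure_id": [e.structure_id for e in landscape],
            "rel_energy": [e.rel_energy for e in landscape],
            "density": [e.density for e in landscape],
            "color_class": [e.color_class for e in landscape],
            "experimental_label": [e.experimental_label for e in landscape],
            "rank": [e.rank for e in landscape],
        }
    )
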
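"""Monomer conformational-energy correction and experimental benchmarking.

Approximate density functionals suffer from delocalization error, which
over-stabilizes the more planar, more π-conjugated conformations of a flexible
molecule and thereby skews crystal-energy-landscape rankings of conformational
polymorphs. A pragmatic fix replaces the intramolecular conformational energy
of each crystal with one computed at a higher level of theory on the isolated
monomers in their crystalline geometries:

    E_corrected = E_crystal + Σ_i m_i · (E_mon,i^target − E_mon,i^base)

where the sum runs over the symmetry-unique monomers of the unit cell and m_i
is the multiplicity of monomer i (so the sum effectively runs over all Z
molecules in the cell). All landscape comparisons downstream are per molecule:
per-cell energies divided by Z, so Z′ = 1 and Z′ = 2 forms share one axis.

Energies are kJ·mol⁻¹ throughout; converters from hartree and eV live in
:mod:`polyscape.units`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import CorrectionError

__all__ = [
    "MonomerEnergyPair",
    "EnergyRecord",
    "ExperimentalReference",
    "apply_monomer_correction",
    "relative_energies",
    "rmse_vs_experiment",
    "ranking_comparison",
    "read_energy_tables",
    "records_to_frame",
]


@dataclass(frozen=True)
class MonomerEnergyPair:
    """Gas-phase energies of one symmetry-unique monomer at two levels."""

    monomer_id: str
    multiplicity: int
    e_base: float
    e_target: float

    def __post_init__(self) -> None:
        if self.multiplicity < 1:
            raise CorrectionError(f"monomer {self.monomer_id}: multiplicity must be ≥ 1")

    @property
    def delta(self) -> float:
        return self.e_target - self.e_base


@dataclass
class EnergyRecord:
    """Per-structure energies: crystal energy per cell plus monomer pairs."""

    structure_id: str
    e_crystal_cell: float
    z_total: int
    monomers: list[MonomerEnergyPair] = field(default_factory=list)
    e_corrected_cell: float | None = None
    corrected: bool = False

    @property
    def e_per_molecule(self) -> float:
        """Corrected (if applied) else raw crystal energy per molecule."""
        cell = self.e_corrected_cell if self.corrected else self.e_crystal_cell
        return cell / self.z_total


def apply_monomer_correction(record: EnergyRecord) -> EnergyRecord:
    """Return a corrected copy of ``record``; re-application is an error.

    The monomer multiplicities must sum to Z — the symmetry-unique monomers,
    weighted by multiplicity, stand in for all molecules of the cell.
    """
    if record.corrected:
        raise CorrectionError(
            f"{record.structure_id}: monomer correction already applied"
        )
    msum = sum(m.multiplicity for m in record.monomers)
    if msum != record.z_total:
        raise CorrectionError(
            f"{record.structure_id}: monomer multiplicities sum to {msum}, "
            f"expected z_total={record.z_total}"
        )
    shift = sum(m.multiplicity * m.delta for m in record.monomers)
    return replace(
        record,
        e_corrected_cell=record.e_crystal_cell + shift,
        corrected=True,
        monomers=list(record.monomers),
    )


def relative_energies(records: list[EnergyRecord], reference_id: str) -> list[float]:
    """Per-molecule energies relative to ``reference_id``, in input order."""
    by_id = {r.structure_id: r for r in records}
    if reference_id not in by_id:
        raise KeyError(f"reference structure {reference_id!r} not among records")
    ref = by_id[reference_id].e_per_molecule
    return [r.e_per_molecule - ref for r in records]


@dataclass(frozen=True)
class ExperimentalReference:
    """Relative enthalpy (kJ·mol⁻¹) of one polymorph vs a stated reference form."""

    form: str
    rel_enthalpy: float


def _as_mapping(values) -> dict[str, float]:
    if isinstance(values, dict):
        return dict(values)
    return {v.form: v.rel_enthalpy for v in values}


def rmse_vs_experiment(
    predicted,
    experimental,
    reference_form: str,
) -> float:
    """RMSE of relative energies vs relative enthalpies over non-reference forms.

    Both inputs map form name → relative value; each is re-referenced so the
    stated reference form sits at zero, making the statistic independent of
    whichever zero the two sets were originally quoted against.
    """
    pred = _as_mapping(predicted)
    exp = _as_mapping(experimental)
    if set(pred) != set(exp):
        raise KeyError(
            f"form sets differ: {sorted(set(pred) ^ set(exp))} not shared"
        )
    if reference_form not in pred:
        raise KeyError(f"reference form {reference_form!r} missing")
    diffs = [
        (pred[f] - pred[reference_form]) - (exp[f] - exp[reference_form])
        for f in pred
        if f != reference_form
    ]
    if not diffs:
        raise ValueError("no non-reference forms to compare")
    return float(np.sqrt(np.mean(np.square(diffs))))


def ranking_comparison(
    predicted_order: list[str],
    experimental_order: list[str],
) -> list[tuple[str, str]]:
    """Discordant pairs between two stability orderings.

    Returns every pair (x, y) that ``experimental_order`` ranks x before y but
    ``predicted_order`` reverses; empty iff the orders are identical. A single
    adjacent swap yields exactly that one pair, and the length equals the
    permutation inversion count.
    """
    if set(predicted_order) != set(experimental_order) or len(predicted_order) != len(
        set(predicted_order)
    ):
        raise ValueError("orders must be permutations of the same form set")
    pos = {f: i for i, f in enumerate(predicted_order)}
    out = []
    for i, x in enumerate(experimental_order):
        for y in experimental_order[i + 1 :]:
            if pos[x] > pos[y]:
                out.append((x, y))
    return out


# ---------------------------------------------------------------------------
# delimited-text I/O

CRYSTAL_COLUMNS = ["structure_id", "e_crystal_cell", "z_total"]
MONOMER_COLUMNS = ["structure_id", "monomer_id", "multiplicity", "e_base", "e_target"]


def read_energy_tables(crystal_csv, monomers_csv) -> list[EnergyRecord]:
    """Assemble records from the two-table CSV layout.

    ``crystal_csv``: one row per structure (structure_id, e_crystal_cell,
    z_total). ``monomers_csv``: long format, one row per symmetry-unique
    monomer (structure_id, monomer_id, multiplicity, e_base, e_target).
    """
    crystals = pd.read_csv(crystal_csv)
    monomers = pd.read_csv(monomers_csv)
    for frame, cols, name in (
        (crystals, CRYSTAL_COLUMNS, "crystal"),
        (monomers, MONOMER_COLUMNS, "monomer"),
    ):
        missing = set(cols) - set(frame.columns)
        if missing:
            raise CorrectionError(f"{name} table missing columns {sorted(missing)}")
    grouped = {
        sid: [
            MonomerEnergyPair(
                monomer_id=str(row.monomer_id),
                multiplicity=int(row.multiplicity),
                e_base=float(row.e_base),
                e_target=float(row.e_target),
            )
            for row in grp.itertuples()
        ]
        for sid, grp in monomers.groupby("structure_id", sort=False)
    }
    records = []
    for row in crystals.itertuples():
        sid = str(row.structure_id)
        records.append(
            EnergyRecord(
                structure_id=sid,
                e_crystal_cell=float(row.e_crystal_cell),
                z_total=int(row.z_total),
                monomers=grouped.get(sid, []),
            )
        )
    return records


def records_to_frame(records: list[EnergyRecord]) -> pd.DataFrame:
    """Flatten records (corrected or not) to a tidy per-structure table."""
    return pd.DataFrame(
        {
            "structure_id": [r.structure_id for r in records],
            "e_crystal_cell": [r.e_crystal_cell for r in records],
            "z_total": [r.z_total for r in records],
            "e_corrected_cell": [r.e_corrected_cell for r in records],
            "e_per_molecule": [r.e_per_molecule for r in records],
            "corrected": [r.corrected for r in records],
        }
    )
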
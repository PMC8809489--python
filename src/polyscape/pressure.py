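"""Pressure-dependent polymorph stability: H = E_latt + P·V screening.

At 0 K and neglecting phonon/finite-temperature contributions, the enthalpy of
a crystal at pressure P is approximated by H = E_latt + PV. Relative-enthalpy
curves ΔH(P) between polymorphs then locate pressure-induced stability
reversals as sign changes. Energies are kJ·mol⁻¹ per molecule, volumes Å³ per
molecule, pressures GPa; the PV cross term carries the Avogadro factor
0.602214 kJ·mol⁻¹ per GPa·Å³.

Tabulated (P, E, V) samples are interpolated in pressure with a monotone
shape-preserving piecewise cubic (PCHIP), which cannot ring between samples —
essential for trustworthy crossover bracketing. A third-order Birch–Murnaghan
equation of state is provided as the smooth-interpolation alternative when
only E(V) samples are available. Extrapolation beyond the sampled pressure
range (plus a 5% grace margin) is a hard error, not a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, least_squares

from .errors import CoverageError, EosError
from .units import GPA_A3_TO_KJMOL

__all__ = [
    "PVPoint",
    "PVSeries",
    "EOSParams",
    "enthalpy",
    "relative_enthalpy_curve",
    "crossover_pressure",
    "fit_eos",
    "pressure_screen",
    "bm3_energy",
    "bm3_pressure",
    "bm3_volume",
    "bm3_enthalpy",
    "read_pv_csv",
    "DeltaHCurve",
    "StabilityReport",
]

#: Fractional grace margin for interpolation beyond the sampled pressure range.
EXTRAPOLATION_MARGIN = 0.05


@dataclass(frozen=True)
class PVPoint:
    """One (pressure GPa, energy kJ·mol⁻¹, volume Å³) sample, per molecule."""

    pressure: float
    energy: float
    volume: float

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.pressure < 0:
            raise ValueError("pressure must be nonnegative")


def enthalpy(point: PVPoint) -> float:
    """H = E + P·V in kJ·mol⁻¹."""
    return point.energy + point.pressure * point.volume * GPA_A3_TO_KJMOL


@dataclass
class PVSeries:
    """Per-structure (P, E, V) samples, sorted by pressure."""

    structure_id: str
    points: list[PVPoint]

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.pressure)
        pressures = [p.pressure for p in self.points]
        if len(set(pressures)) != len(pressures):
            raise ValueError(f"{self.structure_id}: duplicate pressures")
        if len(self.points) < 2:
            raise ValueError(f"{self.structure_id}: need ≥ 2 points for interpolation")
        vols = [p.volume for p in self.points]
        if any(b > a + 1e-9 for a, b in zip(vols, vols[1:])):
            warnings.warn(
                f"{self.structure_id}: volume increases with pressure", stacklevel=2
            )

    @property
    def pressures(self) -> np.ndarray:
        return np.array([p.pressure for p in self.points])

    @property
    def enthalpies(self) -> np.ndarray:
        return np.array([enthalpy(p) for p in self.points])

    def interpolator(self) -> PchipInterpolator:
        return PchipInterpolator(self.pressures, self.enthalpies)

    def coverage(self) -> tuple[float, float]:
        p = self.pressures
        span = p[-1] - p[0]
        return p[0] - EXTRAPOLATION_MARGIN * span, p[-1] + EXTRAPOLATION_MARGIN * span


@dataclass
class DeltaHCurve:
    """ΔH(P) between two series: sampled values plus a smooth evaluator."""

    pressures: np.ndarray
    values: np.ndarray
    _fn: object = field(repr=False, default=None)

    def __call__(self, p):
        return self._fn(p)

    @property
    def p_min(self) -> float:
        return float(self.pressures[0])

    @property
    def p_max(self) -> float:
        return float(self.pressures[-1])


def relative_enthalpy_curve(
    series: PVSeries, reference: PVSeries, pressures
) -> DeltaHCurve:
    """ΔH(P) = H_series(P) − H_reference(P) on the requested grid."""
    grid = np.sort(np.asarray(pressures, dtype=float))
    if grid.size < 1:
        raise ValueError("empty pressure grid")
    lo = max(series.coverage()[0], reference.coverage()[0])
    hi = min(series.coverage()[1], reference.coverage()[1])
    if grid[0] < lo - 1e-12 or grid[-1] > hi + 1e-12:
        raise CoverageError(
            f"grid [{grid[0]}, {grid[-1]}] GPa exceeds sampled coverage "
            f"[{lo:.4f}, {hi:.4f}] of {series.structure_id}/{reference.structure_id}"
        )
    fs, fr = series.interpolator(), reference.interpolator()
    fn = lambda p: fs(p) - fr(p)  # noqa: E731
    return DeltaHCurve(pressures=grid, values=fn(grid), _fn=fn)


def crossover_pressure(delta_curve: DeltaHCurve, xtol: float = 1e-6) -> list[float]:
    """All sign changes of ΔH(P), bracketed on a dense scan and bisected.

    Pressures are returned ascending; an empty list means no crossing. The
    default tolerance (1e-6 GPa) is well inside the 1e-4 GPa reporting
    precision so results are stable under grid refinement.
    """
    dense = np.linspace(delta_curve.p_min, delta_curve.p_max,
                        max(2001, 8 * delta_curve.pressures.size))
    vals = np.asarray(delta_curve(dense), dtype=float)
    signs = np.sign(vals)
    roots: list[float] = []
    # a genuine stability reversal needs opposite signs on the two flanks;
    # runs of exact zeros (identical phases, tangency) are not crossings
    nz = np.nonzero(signs)[0]
    for k in range(len(nz) - 1):
        i, j = nz[k], nz[k + 1]
        if signs[i] * signs[j] < 0:
            roots.append(float(brentq(delta_curve, dense[i], dense[j], xtol=xtol)))
    # collapse near-identical roots from grazing zeros
    out: list[float] = []
    for r in sorted(roots):
        if not out or r - out[-1] > 10 * xtol:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# third-order Birch–Murnaghan equation of state


@dataclass(frozen=True)
class EOSParams:
    """Third-order Birch–Murnaghan parameters (per molecule)."""

    e0: float  # kJ·mol⁻¹
    v0: float  # Å³
    b0: float  # GPa
    b0_prime: float  # unitless

    def __post_init__(self) -> None:
        if self.v0 <= 0 or self.b0 <= 0:
            raise EosError("V0 and B0 must be positive")


def bm3_energy(volume, params: EOSParams):
    """E(V) in kJ·mol⁻¹."""
    eta = (params.v0 / np.asarray(volume, dtype=float)) ** (2.0 / 3.0)
    f = eta - 1.0
    return params.e0 + (
        9.0 * params.v0 * params.b0 * GPA_A3_TO_KJMOL / 16.0
    ) * (f**3 * params.b0_prime + f**2 * (6.0 - 4.0 * eta))


def bm3_pressure(volume, params: EOSParams):
    """P(V) in GPa."""
    v = np.asarray(volume, dtype=float)
    r = params.v0 / v
    return (
        1.5
        * params.b0
        * (r ** (7.0 / 3.0) - r ** (5.0 / 3.0))
        * (1.0 + 0.75 * (params.b0_prime - 4.0) * (r ** (2.0 / 3.0) - 1.0))
    )


def bm3_volume(pressure: float, params: EOSParams, rtol: float = 1e-12) -> float:
    """V(P) by root bracketing of the pressure equation."""
    lo, hi = 0.2 * params.v0, 2.0 * params.v0
    f = lambda v: bm3_pressure(v, params) - pressure  # noqa: E731
    if f(lo) * f(hi) > 0:
        raise EosError(f"cannot bracket V(P={pressure} GPa)")
    return float(brentq(f, lo, hi, rtol=rtol))


def bm3_enthalpy(pressure: float, params: EOSParams) -> float:
    """H(P) = E(V(P)) + P·V(P) in kJ·mol⁻¹."""
    v = bm3_volume(pressure, params)
    return float(bm3_energy(v, params)) + pressure * v * GPA_A3_TO_KJMOL


def fit_eos(samples) -> tuple[EOSParams, float]:
    """Least-squares third-order Birch–Murnaghan fit to (V, E) samples.

    Requires ≥ 4 samples spanning ≥ 10% in volume. Returns the parameters and
    the RMS residual (kJ·mol⁻¹).
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 4:
        raise EosError("need ≥ 4 (V, E) samples")
    v, e = arr[:, 0], arr[:, 1]
    if (v.max() - v.min()) / v.max() < 0.10:
        raise EosError("volume span < 10%; fit is degenerate")
    # initial guess: quadratic in V around the sampled minimum
    coeffs = np.polyfit(v, e, 2)
    v0 = float(-coeffs[1] / (2 * coeffs[0])) if coeffs[0] > 0 else float(v[np.argmin(e)])
    if not v.min() * 0.5 < v0 < v.max() * 1.5:
        v0 = float(v[np.argmin(e)])
    b0 = max(2.0 * abs(coeffs[0]) * v0 / GPA_A3_TO_KJMOL, 1.0)
    x0 = np.array([float(e.min()), v0, b0, 6.0])

    def resid(x):
        return bm3_energy(v, EOSParams(x[0], max(x[1], 1e-6), max(x[2], 1e-6), x[3])) - e

    sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise EosError(f"Birch–Murnaghan fit failed: {sol.message}")
    params = EOSParams(*sol.x)
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return params, rms


# ---------------------------------------------------------------------------
# screening


@dataclass
class StabilityReport:
    """Per-pressure enthalpy ordering and pairwise crossovers vs a reference."""

    enthalpies: pd.DataFrame  # index: pressure grid, columns: structure ids
    reference_id: str
    minimum_by_pressure: pd.Series = field(init=False)
    orderings: dict = field(init=False)
    crossovers: dict = field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.minimum_by_pressure = self.enthalpies.idxmin(axis=1)
        self.orderings = {
            float(p): list(self.enthalpies.loc[p].sort_values().index)
            for p in self.enthalpies.index
        }


def pressure_screen(
    series_map: dict[str, PVSeries], reference_id: str, pressures
) -> StabilityReport:
    """Screen a set of forms: H(P) table, per-P ordering, crossovers vs reference."""
    if reference_id not in series_map:
        raise KeyError(f"reference {reference_id!r} not among series")
    grid = np.sort(np.asarray(pressures, dtype=float))
    ref = series_map[reference_id]
    data = {}
    crossovers = {}
    for sid, series in series_map.items():
        curve = relative_enthalpy_curve(series, ref, grid)
        data[sid] = np.asarray(series.interpolator()(grid), dtype=float)
        if sid != reference_id:
            crossovers[sid] = crossover_pressure(curve)
    frame = pd.DataFrame(data, index=grid)
    report = StabilityReport(enthalpies=frame, reference_id=reference_id)
    report.crossovers = crossovers
    return report


def read_pv_csv(path) -> dict[str, PVSeries]:
    """Read (structure_id, pressure_GPa, e_kjmol_per_molecule, v_A3_per_molecule)."""
    frame = pd.read_csv(path)
    required = {
        "structure_id",
        "pressure_GPa",
        "e_kjmol_per_molecule",
        "v_A3_per_molecule",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"PV table missing columns {sorted(missing)}")
    out = {}
    for sid, grp in frame.groupby("structure_id", sort=False):
        out[str(sid)] = PVSeries(
            structure_id=str(sid),
            points=[
                PVPoint(
                    pressure=float(r.pressure_GPa),
                    energy=float(r.e_kjmol_per_molecule),
                    volume=float(r.v_A3_per_molecule),
                )
                for r in grp.itertuples()
            ],
        )
    return out
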
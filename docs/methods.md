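# Methods

## The problem and the model

Conformational polymorphs are crystal forms of one molecule that differ in an
intramolecular torsion. For ROY-type systems the key coordinate is the
S–C–N–C torsion θ between two aromatic systems: it controls π conjugation and
hence crystal color (yellow for θ between 50° and 130°, red/orange for more
planar conformations outside that band), and the gas-phase conformational
profile has two basins separated by a barrier near θ ≈ 80°. Generalized
gradient and hybrid density functionals carry delocalization error, which
spuriously stabilizes the more conjugated planar conformations; on a CSP
landscape this systematically pushes red/orange packings below yellow ones
and corrupts the stability ranking.

The correction implemented here replaces the crystal model's intramolecular
conformational energy with a higher-level gas-phase monomer energy computed at
the crystalline geometry:

E_corrected = E_crystal + Σ_i m_i (E_mon,i^target − E_mon,i^base),

summing over symmetry-unique monomers with multiplicities m_i (Σ m_i = Z).
The package does not compute E_mon itself — energies enter through delimited
tables from any electronic-structure back-end — but it owns the bookkeeping:
multiplicity validation, a re-application guard (records carry a `corrected`
flag; correcting twice is an error, since silent double-correction is the
likeliest real-world bug), per-molecule normalization, and the downstream
landscape statistics.

All landscape comparisons are per molecule (per-cell energies divided by Z).
This is the only convention under which Z′ = 1 and Z′ = 2 forms share one
energy axis, and it is applied uniformly to lattice energies, enthalpies and
volumes. Units are fixed at the I/O boundary to kJ·mol⁻¹, Å, Å³ and GPa;
hartree and eV converters (CODATA 2018) are provided in `polyscape.units` but
internal arithmetic is unit-homogeneous. The PV cross term uses
0.602214076 kJ·mol⁻¹ per GPa·Å³ (the Avogadro factor).

## Crystal I/O and molecule extraction

CIF handling is built on gemmi. Explicit `_symmetry_equiv_pos_as_xyz` /
`_space_group_symop_operation_xyz` loops take precedence; otherwise a
Hermann–Mauguin symbol or IT number is resolved through gemmi's space-group
table. Fractional coordinates are stored in [0,1); Cartesian conversion uses
the a-along-x, b-in-xy lattice convention. Sites with occupancy ≠ 1 are
rejected outright — landscape structures are fully ordered, and silently
"handling" disorder would corrupt molecule extraction. Written CIFs round-trip
to 1e-6 in fractional coordinates and 1e-4 in cell parameters.

Bonds are perceived with the standard crystallographic heuristic: a bond
exists when the minimum-image distance is at most 1.2× the sum of covalent
radii (gemmi's tables). Hydrogens are bonded to their single nearest heavy
atom only, with the cutoff floored at 1.3 Å because tabulated hydrogen
covalent radii are small enough that the scaled-radius sum (≈1.25 Å for C–H)
sits uncomfortably close to real 1.0–1.1 Å X–H bond lengths; without the
floor, sub-0.1 Å coordinate noise can sever X–H bonds. Whole molecules are
connected components of this bond graph, unwrapped by breadth-first traversal
that accumulates minimum-image shifts so no bond crosses a cell boundary.
Z′ is reported as (number of molecules)/(number of operations); structures
whose molecule count contradicts their declared Z raise a connectivity error.

## RMSD_N packing similarity

Packing similarity follows the COMPACK idea: an N-molecule cluster (default
N = 15) is built in each structure — the central molecule (nearest the cell
midpoint) plus its N−1 nearest neighbours by centroid distance, drawn from a
5×5×5 supercell — clusters are superposed, and the heavy-atom RMSD is
reported. Two structures "match" when all N molecules pair up.

Molecule pairing is transform-guided rather than matched on centroid-distance
sets alone. Sorted centroid-distance sets are used as a fast compatibility
filter (relative tolerance `distance_tol`, default 0.2), but a pure
distance-set pairing is degenerate wherever a lattice produces equidistant
neighbour shells — the common case, where backtracking over tied
permutations explodes combinatorially. Instead, the two central molecules
are superposed (least-squares rotation via scipy; atom correspondence by
element sequence, with a graph-isomorphism fallback through networkx), the
trial transform maps one cluster's centroids onto the other, optimal
assignment (`linear_sum_assignment`) pairs them under the distance cap, and
the transform is refined once on all paired heavy atoms. Candidate clusters
on the second structure are grown past N by a distance margin so that a
degenerate N-th shell cannot exclude the member the first cluster happens to
contain. Every molecule of the second structure is tried as the opposing
center and the best result kept, which removes any dependence on arbitrary
site ordering; the enantiomorph (inverted) match is tried by default.
Hydrogens never enter the RMSD, following packing-similarity convention.

Deduplication merges entries that agree in energy (≤ 0.5 kJ·mol⁻¹ per
molecule) *and* packing (RMSD₁₅ ≤ 0.3 Å with a full match), keeping the
lower-energy member and re-ranking. The tolerances are exposed because no
single pair is right for every landscape; the defaults bracket typical
CSP duplicate jitter while staying far below genuine polymorph differences.
Experimental labeling uses the same comparison, assigning each reference
form to at most one candidate (globally greedy on ascending RMSD) and
reporting unmatched references.

## Pressure screening

The enthalpy at pressure P is approximated as H = E_latt + PV, neglecting
phonon and finite-temperature contributions. Tabulated (P, E, V) samples per
structure are interpolated in pressure with a monotone shape-preserving
piecewise cubic (PCHIP). The monotone contract matters: ΔH(P) curves between
polymorphs are smooth and nearly linear, and an oscillating interpolant would
manufacture spurious sign changes exactly where crossover detection looks for
them. Crossovers are located by a dense sign scan followed by Brent bracketing
(tolerance 1e-6 GPa, well inside the 1e-4 GPa reporting precision); runs of
exact zeros (identical phases, tangencies) are not counted as crossings.
Extrapolation beyond the sampled pressure range plus a 5% grace margin is a
hard error — high-pressure conclusions from extrapolated equations of state
are not trustworthy enough to emit silently.

When only E(V) samples are available, a third-order Birch–Murnaghan fit
(scipy least-squares, initialized from a quadratic fit; ≥ 4 points spanning
≥ 10% in volume required) provides the smooth E(V)/P(V)/H(P) forms. The fit
is also the synthetic test surface: phase pairs generated from known EOS
parameters have analytically solvable enthalpy-equality pressures against
which the sampled-curve pipeline is checked to 1e-3 GPa.

## The synthetic generator

The generator's role is to make every pipeline stage falsifiable with known
ground truth; it is not a physical model. Each structure carries one torsion
θ drawn from a two-component truncated-normal mixture over [0°, 180°]
(weights 0.55/0.45, centers 40°/110°, widths 20°/28°), planar-rich so
red/orange conformations outnumber yellow roughly 2:1 as on realistic
landscapes of this kind. Ground-truth per-molecule energy is a double-well
conformational term w(θ) = w0·sin²(2(θ−45°)) — minima near 45° and 135°,
barrier near 90°, w0 = 6 kJ·mol⁻¹ — plus a packing term drawn uniformly on
±σ (σ = 1 kJ·mol⁻¹ by default). The biased base crystal energy subtracts
δ·cos²θ (default δ = 10 kJ·mol⁻¹), the functional form that maximally
stabilizes planar θ → 0°/180°, mirroring the delocalization-error direction;
monomer pairs satisfy e_target − e_base = δ·cos²θ, so the correction cancels
the bias to machine precision by construction. Gauge offsets (−120 kJ·mol⁻¹
per molecule, −50 kJ·mol⁻¹ per monomer) make the tables look like real
lattice/monomer energies; every statistic downstream is gauge-invariant.

Crystals are P1, Z = 1 packings of a rigid 10-atom toy molecule containing
exactly one S–C–N–C path whose torsion is planted to 1e-6°: random rigid
placements in 9.5–11.5 Å cells are rejected until no intermolecular
heavy-atom contact falls below 2.6 Å (kept above the largest scaled
covalent-radius sum, 2.52 Å for S–S, so packed molecules can never merge
under bond perception). A P2₁ packer exists for symmetry tests.
Near-duplicates are planted as jittered copies (per-coordinate Gaussian,
default 0.05 Å) with energy perturbations within ±0.05 kJ·mol⁻¹. Everything
is deterministic under the configured seed, to byte-identical CIFs.

What the generator does *not* emulate: real intermolecular energetics (the
packing term is drawn noise — the pipeline consumes energies, it does not
need them physical), space groups beyond P1/P2₁, Z′ > 1, disorder, thermal
effects, or the actual conformational profile of any real molecule. Passing
tests therefore demonstrate the correctness of the bookkeeping, geometry,
matching and root-finding machinery under known truth — not the accuracy of
any energy model on real crystals.

## Problem sizes, tolerances, tie-breaks

The shipped verification uses 100-structure landscapes for correction/ranking
properties (energies only; crystal packing adds nothing to those checks),
100 seeded replicates for the ranking-improvement statistic and for
Gaussian-jitter RMSD recovery, a 50-structure landscape with 20% planted
duplicates for dedup recovery, and 1000-entry randomized landscapes for
window-count checks — sizes at which every property is already
sharply diagnostic. The jitter-recovery band [0.5, 1.0]×σ√3 is asserted on
the Monte-Carlo mean over replicates: a least-squares superposition can only
remove variance, so the mean ratio sits just below 1, while individual
replicates fluctuate by several percent at ~200 atoms.

Deterministic tie-breaks throughout: equal energies rank lexicographically by
structure id; color/basin boundary values (exactly 50°, 80°, 130°) assign to
the yellow/basin-B side; window boundaries are inclusive (≤), matching the
plain reading of "within an energy window". θ is always reported as |θ| in
[0°, 180°] — the sign is not physically meaningful for the color/basin
analysis, and the |θ| convention makes mirror-image molecules equivalent.

## Known limitations

- The monomer correction assumes the base model's *inter*molecular
  description is sound; nothing here can detect a case where it is not.
- RMSD_N matching is heuristic: transform-guided assignment can in principle
  miss a match for pathological packings whose central-molecule superposition
  is misleading (e.g. molecules with near-symmetric heavy-atom skeletons).
  All failure modes degrade to `n_matched < N`, never to a false merge at
  tight tolerances.
- H = E_latt + PV neglects phonons and thermal expansion; crossover pressures
  are 0 K electronic-enthalpy statements.
- The CIF reader targets ordered small-molecule structures; no disorder,
  partial occupancy, or full space-group normalization.
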
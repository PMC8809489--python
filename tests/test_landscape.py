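"""Landscape ranking, window queries, RMSD_N clusters, dedup and labeling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyscape.correction import EnergyRecord, apply_monomer_correction
from polyscape.crystal_io import AtomSite, CrystalStructure, SymmetryOp, UnitCell
from polyscape.errors import MatchError
from polyscape.landscape import (
    ClusterSource,
    LandscapeEntry,
    build_landscape,
    count_in_window,
    deduplicate,
    label_experimental,
    landscape_to_frame,
    rmsd_n_cluster,
)
from polyscape.synthetic_data import (
    LatticeSpec,
    SyntheticConfig,
    generate_crystal,
    generate_landscape,
    generate_rigid_chain,
    generate_toy_molecule,
)


def jittered(structure, sigma, seed, new_id):
    rng = np.random.default_rng(seed)
    noise = structure.cell.cart_to_frac(rng.normal(0, sigma, size=(len(structure.sites), 3)))
    return CrystalStructure(
        new_id,
        structure.cell,
        list(structure.ops),
        [
            AtomSite(s.element, tuple(np.array(s.frac) + d), s.label)
            for s, d in zip(structure.sites, noise)
        ],
        z_total=structure.z_total,
        z_prime=structure.z_prime,
    )


@pytest.fixture(scope="module")
def sample():
    return generate_landscape(SyntheticConfig(n_structures=8, bias_strength=5.0, seed=3))


@pytest.fixture(scope="module")
def planted():
    sample = generate_landscape(
        SyntheticConfig(
            n_structures=20,
            bias_strength=5.0,
            packing_noise=1.0,
            duplicate_fraction=0.2,
            jitter_xyz=0.05,
            seed=11,
        )
    )
    records = [apply_monomer_correction(r) for r in sample.records()]
    entries = build_landscape(records, sample.structures)
    return sample, entries


class TestBuildLandscape:
    def test_ordering_and_relative_energies(self, sample):
        records = [apply_monomer_correction(r) for r in sample.records()]
        entries = build_landscape(records, sample.structures)
        assert [e.rank for e in entries] == list(range(1, 9))
        assert entries[0].rel_energy == 0.0
        rel = [e.rel_energy for e in entries]
        assert rel == sorted(rel)
        assert [e.structure_id for e in entries] == sample.truth.intended_ranking()
        assert all(e.color_class in ("yellow", "red_orange") for e in entries)
        frame = landscape_to_frame(entries)
        assert list(frame["rank"]) == list(range(1, 9))

    def test_tie_broken_lexicographically(self, toy_p1):
        records = [EnergyRecord("b", -100.0, 1), EnergyRecord("a", -100.0, 1)]
        structures = {
            "a": CrystalStructure("a", toy_p1.cell, list(toy_p1.ops), list(toy_p1.sites), z_total=1),
            "b": CrystalStructure("b", toy_p1.cell, list(toy_p1.ops), list(toy_p1.sites), z_total=1),
        }
        entries = build_landscape(records, structures)
        assert [e.structure_id for e in entries] == ["a", "b"]
        assert entries[1].rel_energy == 0.0

    def test_duplicate_ids_rejected(self, toy_p1):
        records = [EnergyRecord("a", -1.0, 1), EnergyRecord("a", -2.0, 1)]
        with pytest.raises(ValueError):
            build_landscape(records, {"a": toy_p1})


def make_entries(rel_energies, labels=None):
    labels = labels or [None] * len(rel_energies)
    return [
        LandscapeEntry(f"s{i}", rel, density=1.3, experimental_label=lab, rank=i + 1)
        for i, (rel, lab) in enumerate(zip(rel_energies, labels))
    ]


class TestWindowCounts:
    def test_inclusive_boundary(self):
        assert count_in_window(make_entries([0.0, 1.0, 2.0]), 1.0) == 2

    def test_label_predicate(self):
        entries = make_entries([0, 1, 2, 3, 4], labels=["Y", None, "R", None, None])
        unknown = count_in_window(entries, 10.0, lambda e: e.experimental_label is None)
        assert unknown == 3

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            count_in_window(make_entries([0.0]), -1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_and_monotone(self, seed):
        rng = np.random.default_rng(seed)
        rel = np.sort(rng.uniform(0, 20, size=200))
        rel[0] = 0.0
        entries = make_entries(list(rel))
        windows = [0.0, *rng.uniform(0, 22, size=10)]
        counts = []
        for w in sorted(windows):
            got = count_in_window(entries, w)
            assert got == int(np.sum(rel <= w))
            counts.append(got)
        assert counts == sorted(counts)


class TestRmsdCluster:
    def test_self_match(self, toy_p21):
        res = rmsd_n_cluster(toy_p21, toy_p21, n=15)
        assert res.success and res.n_matched == 15
        assert res.rmsd < 1e-6

    def test_rigid_translation(self, toy_p1):
        moved = CrystalStructure(
            "mv",
            toy_p1.cell,
            list(toy_p1.ops),
            [
                AtomSite(s.element, tuple(np.array(s.frac) + 0.31), s.label)
                for s in toy_p1.sites
            ],
            z_total=1,
        )
        res = rmsd_n_cluster(toy_p1, moved, n=15)
        assert res.success and res.rmsd < 1e-6

    def test_symmetric_in_arguments(self, toy_p1):
        other = jittered(toy_p1, 0.03, 9, "jit")
        r1 = rmsd_n_cluster(toy_p1, other, n=12)
        r2 = rmsd_n_cluster(other, toy_p1, n=12)
        assert r1.success and r2.success
        assert r1.rmsd == pytest.approx(r2.rmsd, abs=1e-6)

    def test_supercell_match_is_exact(self, toy_p1):
        sites = [
            AtomSite(s.element, tuple((np.array(s.frac) + [i, j, k]) / 2), f"{s.label}_{i}{j}{k}")
            for i in range(2)
            for j in range(2)
            for k in range(2)
            for s in toy_p1.sites
        ]
        big = CrystalStructure(
            "big",
            UnitCell(2 * toy_p1.cell.a, 2 * toy_p1.cell.b, 2 * toy_p1.cell.c),
            [SymmetryOp.identity()],
            sites,
            z_total=8,
        )
        res = rmsd_n_cluster(toy_p1, big, n=15)
        assert res.success and res.rmsd < 1e-6

    def test_enantiomorph_matched_only_with_inversion(self, toy_p1):
        inverted = CrystalStructure(
            "inv",
            toy_p1.cell,
            list(toy_p1.ops),
            [
                AtomSite(s.element, tuple(-np.array(s.frac)), s.label)
                for s in toy_p1.sites
            ],
            z_total=1,
        )
        with_inv = rmsd_n_cluster(toy_p1, inverted, n=12, allow_inversion=True)
        assert with_inv.success and with_inv.rmsd < 1e-6
        without = rmsd_n_cluster(toy_p1, inverted, n=12, allow_inversion=False)
        assert (not without.success) or without.rmsd > 0.1

    def test_jitter_recovered_within_band(self):
        # a larger rigid molecule so each 15-molecule cluster has ≥ 200 atoms
        mol = generate_rigid_chain(14, seed=0)
        base = generate_crystal(
            mol, LatticeSpec(cell=UnitCell(14, 15, 16)), seed=4, structure_id="chain"
        )
        src = ClusterSource(base)
        sigma = 0.05
        ratios = []
        for rep in range(10):
            res = rmsd_n_cluster(src, jittered(base, sigma, 100 + rep, "j"), n=15)
            assert res.success
            ratios.append(res.rmsd / (sigma * np.sqrt(3)))
        assert 0.5 <= np.mean(ratios) <= 1.0

    def test_different_species_rejected(self, toy_p1):
        chain = generate_crystal(
            generate_rigid_chain(14, seed=1),
            LatticeSpec(cell=UnitCell(14, 15, 16)),
            seed=5,
            structure_id="chain2",
        )
        with pytest.raises(MatchError):
            rmsd_n_cluster(toy_p1, chain, n=6)

    def test_cluster_larger_than_supercell_rejected(self, toy_p1):
        with pytest.raises(MatchError):
            rmsd_n_cluster(toy_p1, toy_p1, n=126)


class TestDeduplicate:
    def test_recovers_planted_partition(self, planted):
        sample, entries = planted
        reduced, log = deduplicate(entries, sample.structures)
        planted_groups = {
            frozenset(m) for m in sample.truth.duplicate_partition().values()
        }
        parent = {e.structure_id: e.structure_id for e in entries}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for row in log:
            parent[find(row["removed"])] = find(row["kept"])
        recovered = {}
        for e in entries:
            recovered.setdefault(find(e.structure_id), set()).add(e.structure_id)
        assert {frozenset(m) for m in recovered.values()} == planted_groups
        assert [e.rank for e in reduced] == list(range(1, len(reduced) + 1))

    def test_idempotent(self, planted):
        sample, entries = planted
        reduced, _ = deduplicate(entries, sample.structures)
        again, log2 = deduplicate(reduced, sample.structures)
        assert log2 == []
        assert [e.structure_id for e in again] == [e.structure_id for e in reduced]

    def test_energy_agreement_alone_insufficient(self):
        # two structures with identical energies but unrelated packings
        a = generate_crystal(
            generate_toy_molecule(40.0),
            LatticeSpec(cell=UnitCell(10, 10.4, 10.8)),
            seed=21,
            structure_id="a",
        )
        b = generate_crystal(
            generate_toy_molecule(150.0),
            LatticeSpec(cell=UnitCell(11, 10.1, 10.6)),
            seed=22,
            structure_id="b",
        )
        entries = [
            LandscapeEntry("a", 0.0, 1.3, rank=1),
            LandscapeEntry("b", 0.0, 1.3, rank=2),
        ]
        reduced, log = deduplicate(entries, {"a": a, "b": b})
        assert len(reduced) == 2 and log == []


class TestLabelExperimental:
    def test_exact_reference_labels_best_candidate(self, toy_p1):
        near = jittered(toy_p1, 0.04, 31, "near")
        entries = [
            LandscapeEntry("toy-p1", 0.0, 1.3, rank=1),
            LandscapeEntry("near", 0.1, 1.3, rank=2),
        ]
        candidates = {"toy-p1": toy_p1, "near": near}
        refs = {"Y": jittered(toy_p1, 0.005, 32, "Y")}
        labeled, unmatched = label_experimental(entries, candidates, refs)
        assert unmatched == []
        by_id = {e.structure_id: e.experimental_label for e in labeled}
        assert by_id["toy-p1"] == "Y" and by_id["near"] is None

    def test_unmatched_reference_reported(self, toy_p1):
        far = generate_crystal(
            generate_toy_molecule(30.0),
            LatticeSpec(cell=UnitCell(10.3, 10.9, 11.3)),
            seed=33,
            structure_id="far",
        )
        entries = [LandscapeEntry("toy-p1", 0.0, 1.3, rank=1)]
        labeled, unmatched = label_experimental(entries, {"toy-p1": toy_p1}, {"X": far})
        assert unmatched == ["X"]
        assert labeled[0].experimental_label is None
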
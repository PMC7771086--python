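"""Energy model, moves, Metropolis criterion and trajectory generation."""

import numpy as np
import pytest

from subsites.constants import LJ_EPSILON, VDW_RADII, WATER_NAMES
from subsites.errors import EnergyError
from subsites.sampling import (
    COULOMB_CONSTANT,
    EnergyModel,
    EnergySystem,
    SamplerConfig,
    backrub_move,
    interface_energy_per_position,
    metropolis_accept,
    run_sampling,
    sidechain_move,
    total_energy,
)
from subsites.structure import Atom, Chain, Residue, Structure


def _pair_structure(distance, element="C", names=("X1", "X2")):
    a = Residue("LIG", 1, "", [Atom(names[0], element, np.zeros(3))], hetero=True)
    b = Residue(
        "LIG", 1, "", [Atom(names[1], element, np.array([distance, 0.0, 0.0]))],
        hetero=True,
    )
    return Structure([Chain("A", [a]), Chain("B", [b])])


LJ_ONLY = EnergyModel(w_coulomb=0.0, w_hbond=0.0)


class TestEnergy:
    def test_lj_minimum_closed_form(self):
        rmin = 2 * VDW_RADII["C"]
        s = _pair_structure(rmin)
        assert total_energy(s, LJ_ONLY) == pytest.approx(-LJ_EPSILON["C"], abs=1e-9)

    def test_distant_pair_is_zero(self):
        s = _pair_structure(50.0)
        assert total_energy(s, LJ_ONLY) == pytest.approx(0.0, abs=1e-12)

    def test_coincident_atoms_rejected(self):
        s = _pair_structure(0.0)
        with pytest.raises(EnergyError):
            total_energy(s)

    def test_matches_brute_force_pair_sum(self, toy):
        """Full O(N^2) re-derivation of the energy, independently coded."""
        structure, _, _ = toy
        model = EnergyModel()
        atoms = []
        for cid, res, a in structure.iter_atoms():
            if res.res_name in WATER_NAMES:
                continue
            atoms.append((cid, id(res), a))
        n = len(atoms)
        coords = np.array([a.coords for _, _, a in atoms])
        # bonds by distance, then 1-2/1-3 exclusion via two-step paths
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                d = np.linalg.norm(coords[i] - coords[j])
                ei = atoms[i][2].element.upper()
                ej = atoms[j][2].element.upper()
                cut = 1.3 if "H" in (ei, ej) else (2.1 if "S" in (ei, ej) else 1.9)
                if d <= cut:
                    adj[i].add(j)
                    adj[j].add(i)
        excluded = set()
        for i in range(n):
            for j in adj[i]:
                excluded.add(frozenset((i, j)))
                for k in adj[j]:
                    if k != i:
                        excluded.add(frozenset((i, k)))
        from subsites.sampling import _charge

        total = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if frozenset((i, j)) in excluded:
                    continue
                r = np.linalg.norm(coords[i] - coords[j])
                if r >= model.cutoff:
                    continue
                ei = atoms[i][2].element.upper()
                ej = atoms[j][2].element.upper()
                rmin = VDW_RADII.get(ei, 1.7) + VDW_RADII.get(ej, 1.7)
                eps = np.sqrt(LJ_EPSILON.get(ei, 0.1) * LJ_EPSILON.get(ej, 0.1))
                x6 = (rmin / r) ** 6
                total += eps * (x6 * x6 - 2 * x6)
                qq = _charge(atoms[i][2].name, ei) * _charge(atoms[j][2].name, ej)
                total += COULOMB_CONSTANT * qq / (model.dielectric * r * r)
                polar = ei in "NO" and ej in "NO" and atoms[i][1] != atoms[j][1]
                if polar:
                    total -= np.clip((3.5 - r) / 0.7, 0.0, 1.0)
        assert total_energy(structure, model) == pytest.approx(total, rel=1e-9)


class TestInterfaceEnergy:
    def test_distant_peptide_is_zero(self, toy):
        structure, _, gt = toy
        moved = structure.copy()
        for res in moved.chain("P").residues:
            for a in res.atoms:
                a.coords = a.coords + np.array([100.0, 0.0, 0.0])
        energies = interface_energy_per_position(moved, gt)
        assert all(abs(v) < 1e-9 for v in energies.values())

    def test_decomposition_sums_to_direct_total(self, toy):
        """Per-position terms must reconstruct an independently computed
        cross-partition total."""
        structure, _, gt = toy
        model = EnergyModel()
        energies = interface_energy_per_position(structure, gt, model)
        from subsites.sampling import _charge

        pep, prot = [], []
        for cid, res, a in structure.iter_atoms():
            (pep if cid == "P" else prot).append((id(res), a))
        total = 0.0
        for rid_p, a in pep:
            for rid_q, b in prot:
                r = np.linalg.norm(a.coords - b.coords)
                if r >= model.cutoff:
                    continue
                ea, eb = a.element.upper(), b.element.upper()
                rmin = VDW_RADII.get(ea, 1.7) + VDW_RADII.get(eb, 1.7)
                eps = np.sqrt(LJ_EPSILON.get(ea, 0.1) * LJ_EPSILON.get(eb, 0.1))
                x6 = (rmin / r) ** 6
                total += eps * (x6 * x6 - 2 * x6)
                total += (
                    COULOMB_CONSTANT
                    * _charge(a.name, ea) * _charge(b.name, eb)
                    / (model.dielectric * r * r)
                )
                if ea in "NO" and eb in "NO":
                    total -= np.clip((3.5 - r) / 0.7, 0.0, 1.0)
        assert sum(energies.values()) == pytest.approx(total, rel=1e-9)

    def test_single_contact_dominates(self):
        """Only P1 touches the enzyme: its magnitude exceeds the others."""
        from subsites.fixtures import FixtureSpec, make_toy_complex

        structure, _, gt = make_toy_complex(FixtureSpec())
        stripped = Structure([structure.chain("P").copy()])
        p1 = stripped.chain("P").get(4)
        probe = Residue(
            "BLK", 1, "",
            [Atom("C1", "C", p1.atom("CB").coords + np.array([0.0, 0.0, 3.4]))],
            hetero=True,
        )
        stripped.chains.append(Chain("E", [probe]))
        energies = interface_energy_per_position(stripped, gt)
        assert abs(energies["P1"]) > max(
            abs(v) for k, v in energies.items() if k != "P1"
        )


class TestMoves:
    def test_backrub_zero_angle_is_identity(self, toy, rng):
        structure, _, gt = toy
        out = backrub_move(structure, rng, assignment=gt, max_angle=0.0)
        assert np.allclose(out.all_coords(), structure.all_coords())

    def test_backrub_preserves_bond_lengths(self, toy, rng):
        structure, _, gt = toy

        def bond_lengths(s):
            out = []
            for chain in s.chains:
                for res in chain.residues:
                    for pair in (("N", "CA"), ("CA", "C"), ("C", "O")):
                        a, b = res.atom(pair[0]), res.atom(pair[1])
                        if a is not None and b is not None:
                            out.append(np.linalg.norm(a.coords - b.coords))
                for r1, r2 in zip(chain.residues, chain.residues[1:]):
                    c, nn = r1.atom("C"), r2.atom("N")
                    if c is not None and nn is not None:
                        d = np.linalg.norm(c.coords - nn.coords)
                        if d < 2.0:
                            out.append(d)
            return np.array(out)

        before = bond_lengths(structure)
        moved = structure
        for _ in range(5):
            moved = backrub_move(moved, rng, assignment=gt)
        assert np.allclose(bond_lengths(moved), before, atol=1e-6)

    def test_backrub_matches_rotation_oracle(self, rng):
        """A rigid segment rotation must equal the explicit Rodrigues
        matrix applied about the pivot axis."""
        from subsites.geometry import rotation_about_axis, rotate_about_line

        pts = rng.random((5, 3)) * 10
        origin = np.array([1.0, 2.0, 3.0])
        axis = np.array([0.3, -0.5, 0.81])
        angle = 9.0
        R = rotation_about_axis(axis, angle)
        expected = (pts - origin) @ R.T + origin
        assert np.allclose(rotate_about_line(pts, origin, axis, angle), expected)

    def test_sidechain_move_leaves_backbone(self, toy, rng):
        structure, _, gt = toy
        out = sidechain_move(structure, rng, assignment=gt)
        for (c1, r1, a1), (c2, r2, a2) in zip(
            structure.iter_atoms(), out.iter_atoms()
        ):
            if a1.is_backbone:
                assert np.allclose(a1.coords, a2.coords, atol=1e-9)

    def test_chi_rotation_round_trip(self, toy):
        from subsites.sidechains import measure_chi, set_chi

        structure, _, _ = toy
        mutated, _ = __import__("subsites.modelling", fromlist=["mutate_residue"]).mutate_residue(
            structure, "P", 2, "L"
        )
        res = mutated.chain("P").get(2)
        set_chi(res, 0, 73.0)
        assert measure_chi(res, 0) == pytest.approx(73.0, abs=1e-6)
        set_chi(res, 1, -112.0)
        assert measure_chi(res, 1) == pytest.approx(-112.0, abs=1e-6)


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-5.0, 1.2, rng) for _ in range(100))

    def test_zero_delta_always_accepted(self, rng):
        assert all(metropolis_accept(0.0, 1.2, rng) for _ in range(100))

    def test_acceptance_rate_at_delta_equal_kt(self, rng):
        n = 100_000
        accepted = sum(metropolis_accept(1.2, 1.2, rng) for _ in range(n))
        p = np.exp(-1.0)
        sigma = np.sqrt(p * (1 - p) / n)
        assert abs(accepted / n - p) < 3 * sigma


class TestSampling:
    def test_frame_count(self, toy):
        structure, _, gt = toy
        config = SamplerConfig(n_steps=300, frame_stride=10, seed=2)
        traj = run_sampling(structure, config, assignment=gt)
        assert len(traj.frames) == 30
        assert len(traj.energies) == 30

    def test_seed_reproducibility(self, toy):
        structure, _, gt = toy
        config = SamplerConfig(n_steps=200, frame_stride=10, seed=9)
        t1 = run_sampling(structure, config, assignment=gt)
        t2 = run_sampling(structure, config, assignment=gt)
        assert t1.energies == t2.energies
        assert t1.accepted == t2.accepted

    def test_chain_connectivity_preserved(self, toy):
        structure, _, gt = toy
        config = SamplerConfig(n_steps=400, frame_stride=100, seed=3)
        traj = run_sampling(structure, config, assignment=gt)

        def backbone_bonds(s):
            out = []
            for chain in s.chains:
                for r1, r2 in zip(chain.residues, chain.residues[1:]):
                    c, nn = r1.atom("C"), r2.atom("N")
                    if c is not None and nn is not None:
                        d = np.linalg.norm(c.coords - nn.coords)
                        if d < 2.5:
                            out.append(d)
            return np.array(out)

        start = backbone_bonds(structure)
        for frame in traj.frames:
            assert np.all(np.abs(backbone_bonds(frame) - start) < 0.05)

    def test_decomposition_conserved_on_frames(self, toy):
        structure, _, gt = toy
        config = SamplerConfig(n_steps=100, frame_stride=50, seed=4)
        traj = run_sampling(structure, config, assignment=gt)
        for frame in traj.frames:
            from subsites.sampling import total_interface_energy

            per_pos = interface_energy_per_position(frame, gt)
            assert sum(per_pos.values()) == pytest.approx(
                total_interface_energy(frame, gt), abs=1e-6
            )

    def test_two_state_boltzmann(self, rng):
        """Two-well toy system: occupancies follow the Boltzmann ratio."""
        kT, delta_e = 1.2, 1.0
        n = 100_000
        state, visits_high = 0, 0
        for _ in range(n):
            proposed = 1 - state
            de = delta_e if proposed == 1 else -delta_e
            if metropolis_accept(de, kT, rng):
                state = proposed
            visits_high += state
        p_high = 1.0 / (1.0 + np.exp(delta_e / kT))
        sigma = np.sqrt(p_high * (1 - p_high) / n)
        assert abs(visits_high / n - p_high) < 3 * sigma
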
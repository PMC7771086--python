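"""Pluggable energy model and Metropolis Monte Carlo sampler.

The energy is a comparative, model-internal score: a 12-6 Lennard-Jones
term with element-based radii and well depths, Coulomb electrostatics
with a distance-dependent dielectric (eps = k*r), and a short-range
geometric hydrogen-bond bonus between polar N/O pairs. Units are
arbitrary; every downstream use is an average or a trend.

Backbone sampling uses backrub-style moves: a randomly chosen segment of
2-12 consecutive flexible residues rotates rigidly about the axis through
its flanking CA atoms, which leaves every bond length unchanged. Side
chains move by Gaussian perturbations of single chi angles. Proposals are
accepted with the Metropolis criterion min(1, exp(-dE/kT)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .annotation import PocketAssignment
from .constants import CHI_ATOMS, LJ_EPSILON, POCKET_ORDER, POSITION_ORDER, VDW_RADII, WATER_NAMES
from .errors import EnergyError, SamplingError
from .geometry import rotate_about_line
from .sidechains import _moving_atoms
from .structure import Structure

COULOMB_CONSTANT = 332.0637  # kcal*A/(mol*e^2); nominal, units are internal


@dataclass
class EnergyModel:
    w_lj: float = 1.0
    w_coulomb: float = 1.0
    w_hbond: float = 1.0
    dielectric: float = 4.0  # eps(r) = dielectric * r
    cutoff: float = 10.0


@dataclass
class SamplerConfig:
    n_steps: int = 5000
    kT: float = 1.2
    frame_stride: int = 10
    seed: int = 0
    p_backbone: float = 0.5
    max_backrub_angle: float = 11.0
    sidechain_sigma: float = 20.0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise SamplingError("n_steps must be >= 1")
        if self.kT <= 0:
            raise SamplingError("kT must be positive")
        if self.frame_stride < 1 or self.n_steps % self.frame_stride:
            raise SamplingError("frame_stride must divide n_steps")

    @property
    def n_frames(self) -> int:
        return self.n_steps // self.frame_stride


@dataclass
class Trajectory:
    run_index: int
    frames: list[Structure]
    energies: list[float]
    accepted: int
    n_steps: int

    @property
    def acceptance_rate(self) -> float:
        return self.accepted / self.n_steps if self.n_steps else 0.0


def _charge(atom_name: str, element: str) -> float:
    if atom_name == "N":
        return -0.35
    if atom_name in ("O", "OXT"):
        return -0.50
    if atom_name == "C":
        return 0.45
    e = element.upper()
    return {"O": -0.40, "N": -0.30, "S": -0.15, "H": 0.10}.get(e, 0.0)


class EnergySystem:
    """Flattened atom table with precomputed pair lists and exclusions.

    Pairs at bonded graph distance <= 2 (1-2 and 1-3) are excluded from
    all non-bonded terms. Topology is fixed; only coordinates vary.
    """

    def __init__(self, structure: Structure, model: Optional[EnergyModel] = None):
        self.model = model or EnergyModel()
        self.structure = structure
        coords, radii, eps, charges = [], [], [], []
        self.atom_meta: list[tuple[str, int, str]] = []  # chain, res_index, atom name
        self.res_keys: list[tuple[str, int, str]] = []
        self.res_spans: list[tuple[int, int]] = []
        self.res_objects = []
        self.chain_of_res: list[str] = []
        idx = 0
        res_index = -1
        for cid, res in structure.iter_residues():
            if res.res_name in WATER_NAMES:
                continue
            res_index += 1
            start = idx
            self.res_keys.append(res.key(cid))
            self.res_objects.append(res)
            self.chain_of_res.append(cid)
            for a in res.atoms:
                coords.append(a.coords)
                r = VDW_RADII.get(a.element.upper(), 1.7)
                radii.append(r)
                eps.append(LJ_EPSILON.get(a.element.upper(), 0.1))
                charges.append(_charge(a.name, a.element))
                self.atom_meta.append((cid, res_index, a.name))
                idx += 1
            self.res_spans.append((start, idx))
        self.coords0 = np.asarray(coords, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(radii)
        self.eps = np.asarray(eps)
        self.charges = np.asarray(charges)
        self.elements = np.array(
            [structure_elem for structure_elem in self._elements()], dtype=object
        )
        self._build_pairs()

    def _elements(self):
        for _, res in self.structure.iter_residues():
            if res.res_name in WATER_NAMES:
                continue
            for a in res.atoms:
                yield a.element.upper()

    def _build_pairs(self) -> None:
        n = len(self.coords0)
        tree = cKDTree(self.coords0)
        bonded = tree.query_pairs(2.1, output_type="ndarray")
        # keep only plausible covalent pairs
        adj: dict[int, set[int]] = {i: set() for i in range(n)}
        for i, j in bonded:
            d = np.linalg.norm(self.coords0[i] - self.coords0[j])
            if d < 1e-6:
                raise EnergyError(
                    f"coincident atoms (r = 0) at indices {int(i)}, {int(j)}"
                )
            ei, ej = self.elements[i], self.elements[j]
            cut = 1.3 if "H" in (ei, ej) else (2.1 if "S" in (ei, ej) else 1.9)
            if d <= cut:
                adj[i].add(j)
                adj[j].add(i)
        excluded: set[tuple[int, int]] = set()
        for i in range(n):
            for j in adj[i]:
                excluded.add((min(i, j), max(i, j)))
                for k in adj[j]:
                    if k != i:
                        excluded.add((min(i, k), max(i, k)))
        iu, ju = np.triu_indices(n, k=1)
        if excluded:
            ex = np.asarray(sorted(excluded))
            keys = iu.astype(np.int64) * n + ju
            ex_keys = ex[:, 0].astype(np.int64) * n + ex[:, 1]
            keep = ~np.isin(keys, ex_keys)
            iu, ju = iu[keep], ju[keep]
        self.iu, self.ju = iu, ju
        self.pair_rmin = self.radii[iu] + self.radii[ju]
        self.pair_eps = np.sqrt(self.eps[iu] * self.eps[ju])
        self.pair_qq = self.charges[iu] * self.charges[ju]
        pol = np.isin(self.elements, ("N", "O"))
        res_of_atom = np.array([m[1] for m in self.atom_meta])
        self.pair_hb = pol[iu] & pol[ju] & (res_of_atom[iu] != res_of_atom[ju])

    # -- energies ----------------------------------------------------------

    def pair_energy(self, r, rmin, eps, qq, hb_mask):
        m = self.model
        with np.errstate(divide="ignore", over="ignore"):
            x6 = (rmin / r) ** 6
        e_lj = eps * (x6 * x6 - 2.0 * x6)
        e_coul = COULOMB_CONSTANT * qq / (m.dielectric * r * r)
        s = np.clip((3.5 - r) / 0.7, 0.0, 1.0)
        e_hb = -np.where(hb_mask, s, 0.0)
        return m.w_lj * e_lj + m.w_coulomb * e_coul + m.w_hbond * e_hb

    def energy(self, coords: Optional[np.ndarray] = None) -> float:
        if coords is None:
            coords = self.coords0
        d = coords[self.iu] - coords[self.ju]
        r = np.sqrt((d * d).sum(axis=1))
        within = r < self.model.cutoff
        r_in = r[within]
        if r_in.size and r_in.min() < 1e-6:
            raise EnergyError("coincident atoms (r = 0) in energy evaluation")
        e = self.pair_energy(
            r_in,
            self.pair_rmin[within],
            self.pair_eps[within],
            self.pair_qq[within],
            self.pair_hb[within],
        )
        return float(e.sum())


def total_energy(complex: Structure, model: Optional[EnergyModel] = None) -> float:
    """Total non-bonded energy of the complex (arbitrary units)."""
    return EnergySystem(complex, model).energy()


def interface_energy_per_position(
    complex: Structure,
    assignment: PocketAssignment,
    model: Optional[EnergyModel] = None,
) -> dict[str, float]:
    """Protease-peptide interface energy decomposed by substrate position.

    The per-position values sum exactly to the total interface energy
    (every cross-partition pair belongs to exactly one peptide residue).
    """
    model = model or EnergyModel()
    pep_chain = assignment.peptide_chain_id
    prot_coords, prot_radii, prot_eps, prot_q, prot_pol = [], [], [], [], []
    for cid, res in complex.iter_residues():
        if cid == pep_chain or res.res_name in WATER_NAMES:
            continue
        for a in res.atoms:
            prot_coords.append(a.coords)
            e = a.element.upper()
            prot_radii.append(VDW_RADII.get(e, 1.7))
            prot_eps.append(LJ_EPSILON.get(e, 0.1))
            prot_q.append(_charge(a.name, a.element))
            prot_pol.append(e in ("N", "O"))
    if not prot_coords:
        return {}
    P = np.asarray(prot_coords)
    pr, pe, pq = np.asarray(prot_radii), np.asarray(prot_eps), np.asarray(prot_q)
    ppol = np.asarray(prot_pol)
    label_to_pos = dict(zip(POCKET_ORDER, POSITION_ORDER))
    out: dict[str, float] = {}
    for key, label in assignment.peptide_map:
        if label is None:
            continue
        res = complex.residue(key)
        e_sum = 0.0
        for a in res.atoms:
            el = a.element.upper()
            d = P - a.coords
            r = np.sqrt((d * d).sum(axis=1))
            within = r < model.cutoff
            if not within.any():
                continue
            r_in = r[within]
            rmin = VDW_RADII.get(el, 1.7) + pr[within]
            eps = np.sqrt(LJ_EPSILON.get(el, 0.1) * pe[within])
            qq = _charge(a.name, a.element) * pq[within]
            hb = (el in ("N", "O")) & ppol[within]
            x6 = (rmin / r_in) ** 6
            e_lj = eps * (x6 * x6 - 2.0 * x6)
            e_coul = COULOMB_CONSTANT * qq / (model.dielectric * r_in * r_in)
            s = np.clip((3.5 - r_in) / 0.7, 0.0, 1.0)
            e_hb = -np.where(hb, s, 0.0)
            e_sum += float(
                (model.w_lj * e_lj + model.w_coulomb * e_coul + model.w_hbond * e_hb).sum()
            )
        out[label_to_pos[label]] = e_sum
    return out


def total_interface_energy(
    complex: Structure, assignment: PocketAssignment, model: Optional[EnergyModel] = None
) -> float:
    return float(sum(interface_energy_per_position(complex, assignment, model).values()))


# ---------------------------------------------------------------------------
# Moves


def metropolis_accept(delta_e: float, kT: float, rng: np.random.Generator) -> bool:
    """Metropolis criterion: accept with probability min(1, exp(-dE/kT))."""
    if kT <= 0:
        raise SamplingError("kT must be positive")
    if delta_e <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_e / kT))


class _MoveEngine:
    """Proposal generator on the flattened coordinate array."""

    def __init__(
        self,
        system: EnergySystem,
        flexible_res: list[int],
        max_backrub_angle: float = 11.0,
        sidechain_sigma: float = 20.0,
    ):
        self.system = system
        self.flexible = flexible_res
        self.max_angle = max_backrub_angle
        self.sigma = sidechain_sigma
        self._runs = self._contiguous_runs()
        self._chi_cache: dict[int, list[tuple[int, int, np.ndarray]]] = {}
        self._atom_index: dict[tuple[int, str], int] = {}
        for i, (cid, ridx, name) in enumerate(system.atom_meta):
            self._atom_index[(ridx, name)] = i

    def _contiguous_runs(self) -> list[list[int]]:
        runs: list[list[int]] = []
        flex = sorted(self.flexible)
        for ridx in flex:
            key = self.system.res_keys[ridx]
            if (
                runs
                and runs[-1][-1] == ridx - 1
                and self.system.chain_of_res[ridx - 1] == self.system.chain_of_res[ridx]
                and self.system.res_keys[ridx - 1][1] == key[1] - 1
            ):
                runs[-1].append(ridx)
            else:
                runs.append([ridx])
        return [r for r in runs if len(r) >= 2]

    def _chi_moves(self, ridx: int):
        if ridx not in self._chi_cache:
            res = self.system.res_objects[ridx]
            moves = []
            if res.res_name in CHI_ATOMS and res.res_name != "PRO":
                for quad in CHI_ATOMS[res.res_name]:
                    if any(res.atom(n) is None for n in quad):
                        continue
                    a_idx = self._atom_index.get((ridx, quad[1]))
                    b_idx = self._atom_index.get((ridx, quad[2]))
                    moving_names = _moving_atoms(res, quad[1], quad[2])
                    moving = np.array(
                        [
                            self._atom_index[(ridx, n)]
                            for n in moving_names
                            if (ridx, n) in self._atom_index
                        ],
                        dtype=int,
                    )
                    if a_idx is not None and b_idx is not None and moving.size:
                        moves.append((a_idx, b_idx, moving))
            self._chi_cache[ridx] = moves
        return self._chi_cache[ridx]

    def propose_backrub(self, coords: np.ndarray, rng: np.random.Generator):
        if not self._runs:
            return None
        run = self._runs[rng.integers(len(self._runs))]
        max_len = min(12, len(run))
        seg_len = int(rng.integers(2, max_len + 1))
        start = int(rng.integers(0, len(run) - seg_len + 1))
        seg = run[start : start + seg_len]
        i_res, j_res = seg[0], seg[-1]
        ca_i = self._atom_index.get((i_res, "CA"))
        ca_j = self._atom_index.get((j_res, "CA"))
        if ca_i is None or ca_j is None:
            return None
        moved = []
        for name in ("C", "O", "OXT"):
            k = self._atom_index.get((i_res, name))
            if k is not None:
                moved.append(k)
        for ridx in seg[1:-1]:
            s, e = self.system.res_spans[ridx]
            moved.extend(range(s, e))
        for name in ("N", "H"):
            k = self._atom_index.get((j_res, name))
            if k is not None:
                moved.append(k)
        moved = np.asarray(sorted(set(moved)), dtype=int)
        axis = coords[ca_j] - coords[ca_i]
        if np.linalg.norm(axis) < 1e-6:
            return None
        angle = float(rng.uniform(-self.max_angle, self.max_angle))
        new_sub = rotate_about_line(coords[moved], coords[ca_i], axis, angle)
        return moved, new_sub

    def propose_sidechain(self, coords: np.ndarray, rng: np.random.Generator):
        candidates = [r for r in self.flexible if self._chi_moves(r)]
        if not candidates:
            return None
        ridx = candidates[int(rng.integers(len(candidates)))]
        moves = self._chi_moves(ridx)
        a_idx, b_idx, moving = moves[int(rng.integers(len(moves)))]
        delta = float(rng.normal(0.0, self.sigma))
        axis = coords[b_idx] - coords[a_idx]
        new_sub = rotate_about_line(coords[moving], coords[a_idx], axis, delta)
        return moving, new_sub


def _flexible_residues(system: EnergySystem, assignment: PocketAssignment) -> list[int]:
    flexible_keys = {k for k, lab in assignment.peptide_map}
    flexible_keys |= assignment.binding_site()
    return [i for i, k in enumerate(system.res_keys) if k in flexible_keys]


def backrub_move(
    complex: Structure,
    rng: np.random.Generator,
    assignment: Optional[PocketAssignment] = None,
    max_angle: float = 11.0,
) -> Structure:
    """Single backrub proposal applied to a copy of the complex."""
    system = EnergySystem(complex)
    flexible = (
        _flexible_residues(system, assignment)
        if assignment is not None
        else list(range(len(system.res_keys)))
    )
    engine = _MoveEngine(system, flexible, max_backrub_angle=max_angle)
    coords = system.coords0.copy()
    proposal = engine.propose_backrub(coords, rng)
    out = complex.copy()
    if proposal is None:
        return out
    moved, new_sub = proposal
    coords[moved] = new_sub
    _write_coords(out, system, coords)
    return out


def sidechain_move(
    complex: Structure,
    rng: np.random.Generator,
    assignment: Optional[PocketAssignment] = None,
    sigma: float = 20.0,
) -> Structure:
    """Single Gaussian chi perturbation applied to a copy of the complex."""
    system = EnergySystem(complex)
    flexible = (
        _flexible_residues(system, assignment)
        if assignment is not None
        else list(range(len(system.res_keys)))
    )
    engine = _MoveEngine(system, flexible, sidechain_sigma=sigma)
    coords = system.coords0.copy()
    proposal = engine.propose_sidechain(coords, rng)
    out = complex.copy()
    if proposal is None:
        return out
    moved, new_sub = proposal
    coords[moved] = new_sub
    _write_coords(out, system, coords)
    return out


def _write_coords(structure: Structure, system: EnergySystem, coords: np.ndarray) -> None:
    i = 0
    for cid, res in structure.iter_residues():
        if res.res_name in WATER_NAMES:
            continue
        for a in res.atoms:
            a.coords = coords[i].copy()
            i += 1


def run_sampling(
    complex: Structure,
    config: SamplerConfig,
    model: Optional[EnergyModel] = None,
    assignment: Optional[PocketAssignment] = None,
    run_index: int = 0,
) -> Trajectory:
    """Metropolis Monte Carlo run mixing backrub and side-chain moves.

    The flexible region is the peptide plus the pocket-forming residues
    when an assignment is supplied (all residues otherwise). A frame is
    recorded every ``frame_stride`` steps, accepted or not, giving
    ``n_steps / frame_stride`` frames.
    """
    rng = np.random.default_rng(config.seed)
    system = EnergySystem(complex, model)
    flexible = (
        _flexible_residues(system, assignment)
        if assignment is not None
        else list(range(len(system.res_keys)))
    )
    engine = _MoveEngine(
        system, flexible, config.max_backrub_angle, config.sidechain_sigma
    )
    coords = system.coords0.copy()
    energy = system.energy(coords)
    frames: list[Structure] = []
    energies: list[float] = []
    accepted = 0
    for step in range(1, config.n_steps + 1):
        use_backbone = rng.random() < config.p_backbone
        proposal = (
            engine.propose_backrub(coords, rng)
            if use_backbone
            else engine.propose_sidechain(coords, rng)
        )
        if proposal is None:
            proposal = engine.propose_sidechain(coords, rng) or engine.propose_backrub(
                coords, rng
            )
        if proposal is not None:
            moved, new_sub = proposal
            trial = coords.copy()
            trial[moved] = new_sub
            trial_energy = system.energy(trial)
            if not np.isfinite(trial_energy):
                raise SamplingError(f"non-finite energy at step {step}")
            if metropolis_accept(trial_energy - energy, config.kT, rng):
                coords, energy = trial, trial_energy
                accepted += 1
        if step % config.frame_stride == 0:
            snap = complex.copy()
            _write_coords(snap, system, coords)
            frames.append(snap)
            energies.append(energy)
    return Trajectory(run_index, frames, energies, accepted, config.n_steps)


def trajectory_to_pdb(trajectory: Trajectory) -> str:
    """Multi-MODEL PDB serialization of a trajectory."""
    from .structure import write_pdb

    parts = []
    for f, frame in enumerate(trajectory.frames, start=1):
        body = write_pdb(frame).replace("END\n", "")
        parts.append(f"MODEL     {f:>4}\n{body}ENDMDL\n")
    return "".join(parts) + "END\n"
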
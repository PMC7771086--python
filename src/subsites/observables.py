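"""Per-frame structural observables for the P4-P4' positions: solvent
accessibility (Shrake-Rupley), hydrogen bonds and non-bonded contacts
split by main/side chain, per-position interface energy, and the
run-and-frame averaging that produces the per-amino-acid, per-position
table O_ij.

ASA is computed with a deterministic golden-spiral quadrature on each
atomic sphere; relative ASA divides the residue total by its theoretical
maximum in an extended Gly-X-Gly context. Hydrogen-bond criteria follow
the usual geometric defaults (donor-acceptor <= 3.9 A, hydrogen-acceptor
<= 2.5 A, donor-hydrogen-acceptor angle >= 90 deg); crystal structures
lack hydrogens, so backbone amide hydrogens are placed geometrically and
rotatable side-chain donors fall back to a heavy-atom angle criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (
    BACKBONE_NAMES,
    MAX_ASA,
    POCKET_ORDER,
    POSITION_ORDER,
    VDW_RADII,
    WATER_NAMES,
)
from .errors import SubsitesError
from .structure import Residue, ResidueKey, Structure

OBSERVABLE_NAMES = (
    "rel_asa",
    "hbond_main",
    "hbond_side",
    "nonbonded_main",
    "nonbonded_side",
    "interface_energy",
)

#: default probe radius (water) in Angstrom
PROBE_RADIUS = 1.4


@dataclass
class AsaResult:
    atom_asa: list[float]
    residue_asa: dict[ResidueKey, float]
    relative_asa: dict[ResidueKey, float]


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere.

    A golden-spiral set symmetrized antipodally (for even ``n``): the
    inversion symmetry makes mirror-image environments bury identical
    point counts and tightens convergence.
    """
    if n % 2 == 0:
        half = n // 2
        k = np.arange(half, dtype=float) + 0.5
        phi = np.arccos(1.0 - 2.0 * k / n)  # upper hemisphere only
        theta = np.pi * (1.0 + 5.0**0.5) * k
        upper = np.column_stack(
            (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
        )
        return np.vstack((upper, -upper))
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def shrake_rupley_asa(
    structure: Structure,
    probe: float = PROBE_RADIUS,
    n_sphere_points: int = 960,
    include_waters: bool = False,
    include_hydrogens: bool = True,
) -> AsaResult:
    """Per-atom and per-residue solvent accessible surface area (A^2)."""
    atoms, owners, resnames = [], [], {}
    for cid, res in structure.iter_residues():
        if not include_waters and res.res_name in WATER_NAMES:
            continue
        key = res.key(cid)
        resnames[key] = res.res_name
        for a in res.atoms:
            if not include_hydrogens and a.is_hydrogen:
                continue
            atoms.append(a)
            owners.append(key)
    if not atoms:
        raise SubsitesError("no atoms to compute ASA for")
    coords = np.asarray([a.coords for a in atoms])
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        r = VDW_RADII.get(a.element.upper())
        if r is None:
            raise SubsitesError(
                f"no van der Waals radius configured for element {a.element!r} "
                f"(atom {a.name})"
            )
        radii[i] = r
    unit_pts = _sphere_points(n_sphere_points)
    extended = radii + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * extended.max()
    atom_asa = np.zeros(len(atoms))
    for i in range(len(atoms)):
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        pts = coords[i] + extended[i] * unit_pts
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (extended[nb] ** 2)[None, :]).any(axis=1)
            exposed = int((~buried).sum())
        else:
            exposed = n_sphere_points
        atom_asa[i] = 4.0 * np.pi * extended[i] ** 2 * exposed / n_sphere_points
    residue_asa: dict[ResidueKey, float] = {}
    for i, key in enumerate(owners):
        residue_asa[key] = residue_asa.get(key, 0.0) + atom_asa[i]
    rel: dict[ResidueKey, float] = {}
    for key, asa in residue_asa.items():
        ref = MAX_ASA.get(resnames[key])
        if ref:
            rel[key] = asa / ref
    return AsaResult(list(atom_asa), residue_asa, rel)


def relative_asa(residue_asa: float, res_name: str) -> float:
    """Residue ASA divided by its theoretical Gly-X-Gly maximum."""
    ref = MAX_ASA.get(res_name)
    if ref is None:
        raise SubsitesError(f"no reference maximum ASA for residue {res_name!r}")
    return residue_asa / ref


# ---------------------------------------------------------------------------
# Contacts


@dataclass
class ContactRecord:
    kind: str  # "hbond" | "nonbonded"
    peptide_key: ResidueKey
    peptide_atom: str
    partner_key: ResidueKey
    partner_atom: str
    chain_part: str  # "main" | "side"
    distance: float


_SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "CYS": ("SG",),
    "LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"),
    "ASN": ("ND2",), "GLN": ("NE2",), "TRP": ("NE1",),
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}


@dataclass
class HBondCriteria:
    max_da: float = 3.9
    max_ha: float = 2.5
    min_dha_angle: float = 90.0


def place_backbone_amide_hydrogens(structure: Structure) -> dict[tuple[ResidueKey, str], np.ndarray]:
    """Geometric backbone amide hydrogen positions (N-H 1.01 A, in the
    C(prev)-N-CA plane, opposite the bisector). First residues are skipped."""
    out: dict[tuple[ResidueKey, str], np.ndarray] = {}
    for chain in structure.chains:
        for prev, res in zip(chain.residues, chain.residues[1:]):
            if res.res_name == "PRO":
                continue
            n, ca, c_prev = res.atom("N"), res.atom("CA"), prev.atom("C")
            if n is None or ca is None or c_prev is None:
                continue
            if np.linalg.norm(c_prev.coords - n.coords) > 2.0:
                continue  # chain break
            u1 = c_prev.coords - n.coords
            u2 = ca.coords - n.coords
            u1 /= np.linalg.norm(u1)
            u2 /= np.linalg.norm(u2)
            h_dir = -(u1 + u2)
            norm = np.linalg.norm(h_dir)
            if norm < 1e-8:
                continue
            out[(res.key(chain.chain_id), "N")] = n.coords + 1.01 * h_dir / norm
    return out


def _chain_part(atom_name: str) -> str:
    return "main" if atom_name in BACKBONE_NAMES else "side"


def _donors_acceptors(structure: Structure, chain_filter) -> tuple[list, list]:
    donors, acceptors = [], []
    for cid, res in structure.iter_residues():
        if not chain_filter(cid) or res.res_name in WATER_NAMES:
            continue
        key = res.key(cid)
        for a in res.atoms:
            if a.is_hydrogen:
                continue
            if a.name == "N" and res.res_name != "PRO":
                donors.append((key, res, a))
            elif a.name in _SIDECHAIN_DONORS.get(res.res_name, ()):
                donors.append((key, res, a))
            if a.name in ("O", "OXT"):
                acceptors.append((key, res, a))
            elif a.name in _SIDECHAIN_ACCEPTORS.get(res.res_name, ()):
                acceptors.append((key, res, a))
    return donors, acceptors


def _antecedent(res: Residue, atom_name: str) -> Optional[np.ndarray]:
    """Heavy atom covalently preceding a donor, for the fallback angle test."""
    prev = {
        "N": "CA", "OG": "CB", "OG1": "CB", "OH": "CZ", "SG": "CB", "NZ": "CE",
        "NE": "CD", "NH1": "CZ", "NH2": "CZ", "ND1": "CG", "NE2": "CD2",
        "ND2": "CG", "NE1": "CD1",
    }.get(atom_name)
    if prev is None:
        return None
    a = res.atom(prev)
    return a.coords if a is not None else None


def detect_hbonds(
    structure: Structure,
    peptide_chain_id: str,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[ContactRecord]:
    """Cross-partition (peptide vs protease) hydrogen bonds.

    Donors with a placeable hydrogen use the full H-A distance and D-H-A
    angle criteria; rotatable donors without one use the D-A distance plus
    an antecedent-D-A angle >= the configured angle.
    """
    hydrogens = place_backbone_amide_hydrogens(structure)
    explicit_h: dict[tuple[ResidueKey, str], np.ndarray] = {}
    for cid, res in structure.iter_residues():
        key = res.key(cid)
        for a in res.atoms:
            if a.is_hydrogen:
                heavy = _nearest_heavy(res, a)
                if heavy is not None:
                    explicit_h[(key, heavy.name)] = a.coords
    hydrogens = {**hydrogens, **explicit_h}

    records: list[ContactRecord] = []
    for donor_side in ("peptide", "protease"):
        if donor_side == "peptide":
            donors, _ = _donors_acceptors(structure, lambda c: c == peptide_chain_id)
            _, acceptors = _donors_acceptors(structure, lambda c: c != peptide_chain_id)
        else:
            donors, _ = _donors_acceptors(structure, lambda c: c != peptide_chain_id)
            _, acceptors = _donors_acceptors(structure, lambda c: c == peptide_chain_id)
        for dkey, dres, datom in donors:
            h_pos = hydrogens.get((dkey, datom.name))
            for akey, ares, aatom in acceptors:
                da = float(np.linalg.norm(datom.coords - aatom.coords))
                if da > criteria.max_da:
                    continue
                if h_pos is not None:
                    ha = float(np.linalg.norm(h_pos - aatom.coords))
                    if ha > criteria.max_ha:
                        continue
                    cosang = np.dot(
                        _unit(datom.coords - h_pos), _unit(aatom.coords - h_pos)
                    )
                    ang = float(np.rad2deg(np.arccos(np.clip(cosang, -1, 1))))
                    if ang < criteria.min_dha_angle:
                        continue
                else:
                    ante = _antecedent(dres, datom.name)
                    if ante is not None:
                        cosang = np.dot(
                            _unit(ante - datom.coords), _unit(aatom.coords - datom.coords)
                        )
                        ang = float(np.rad2deg(np.arccos(np.clip(cosang, -1, 1))))
                        if ang < criteria.min_dha_angle:
                            continue
                if donor_side == "peptide":
                    pep_key, pep_atom = dkey, datom.name
                    partner_key, partner_atom = akey, aatom.name
                else:
                    pep_key, pep_atom = akey, aatom.name
                    partner_key, partner_atom = dkey, datom.name
                records.append(
                    ContactRecord(
                        "hbond", pep_key, pep_atom, partner_key, partner_atom,
                        _chain_part(pep_atom), da,
                    )
                )
    return records


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _nearest_heavy(res: Residue, h_atom) -> Optional[object]:
    best, best_d = None, 1.3
    for a in res.atoms:
        if a.is_hydrogen:
            continue
        d = np.linalg.norm(a.coords - h_atom.coords)
        if d < best_d:
            best, best_d = a, d
    return best


def detect_nonbonded(
    structure: Structure,
    peptide_chain_id: str,
    cutoff: float = 3.9,
    hbonds: Optional[list[ContactRecord]] = None,
) -> list[ContactRecord]:
    """Cross-partition heavy-atom pairs within ``cutoff``, excluding pairs
    already counted as hydrogen bonds."""
    if hbonds is None:
        hbonds = detect_hbonds(structure, peptide_chain_id)
    hb_pairs = {
        (r.peptide_key, r.peptide_atom, r.partner_key, r.partner_atom) for r in hbonds
    }
    pep, prot = [], []
    for cid, res in structure.iter_residues():
        if res.res_name in WATER_NAMES:
            continue
        bucket = pep if cid == peptide_chain_id else prot
        for a in res.atoms:
            if not a.is_hydrogen:
                bucket.append((res.key(cid), a))
    if not pep or not prot:
        return []
    prot_coords = np.asarray([a.coords for _, a in prot])
    tree = cKDTree(prot_coords)
    records = []
    for pkey, patom in pep:
        for j in tree.query_ball_point(patom.coords, cutoff):
            okey, oatom = prot[j]
            if (pkey, patom.name, okey, oatom.name) in hb_pairs:
                continue
            d = float(np.linalg.norm(patom.coords - oatom.coords))
            records.append(
                ContactRecord(
                    "nonbonded", pkey, patom.name, okey, oatom.name,
                    _chain_part(patom.name), d,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Per-frame records and averaging


POCKET_TO_POSITION = dict(zip(POCKET_ORDER, POSITION_ORDER))


@dataclass
class FrameRecord:
    """Observable values per substrate position for one frame."""

    run_index: int
    frame_index: int
    values: dict[str, dict[str, float]]  # position -> observable -> value
    amino_acids: dict[str, str] = field(default_factory=dict)  # position -> 1-letter


def frame_observables(
    frame: Structure,
    assignment,
    energy_model=None,
    run_index: int = 0,
    frame_index: int = 0,
    n_sphere_points: int = 240,
) -> FrameRecord:
    """All six observables for each assigned substrate position of a frame."""
    from .sampling import interface_energy_per_position  # local: avoid cycle

    peptide_chain = assignment.peptide_chain_id
    asa = shrake_rupley_asa(frame, n_sphere_points=n_sphere_points)
    hbonds = detect_hbonds(frame, peptide_chain)
    nonbonded = detect_nonbonded(frame, peptide_chain, hbonds=hbonds)
    energies = (
        interface_energy_per_position(frame, assignment, energy_model)
        if energy_model is not None
        else {}
    )
    values: dict[str, dict[str, float]] = {}
    amino_acids: dict[str, str] = {}
    key_to_pos = {
        key: POCKET_TO_POSITION[label]
        for key, label in assignment.peptide_map
        if label is not None
    }
    for key, pos in key_to_pos.items():
        res = frame.residue(key)
        amino_acids[pos] = res.one_letter
        values[pos] = {
            "rel_asa": asa.relative_asa.get(key, float("nan")),
            "hbond_main": 0.0,
            "hbond_side": 0.0,
            "nonbonded_main": 0.0,
            "nonbonded_side": 0.0,
            "interface_energy": float(energies.get(pos, 0.0)),
        }
    for rec in hbonds:
        pos = key_to_pos.get(rec.peptide_key)
        if pos is not None:
            values[pos][f"hbond_{rec.chain_part}"] += 1.0
    for rec in nonbonded:
        pos = key_to_pos.get(rec.peptide_key)
        if pos is not None:
            values[pos][f"nonbonded_{rec.chain_part}"] += 1.0
    return FrameRecord(run_index, frame_index, values, amino_acids)


@dataclass
class ObservableTable:
    """Averaged observables O_ij (amino acid i, position j) plus the
    per-position summaries used for trend comparison."""

    table: pd.DataFrame  # columns: observable, position, aa, mean, n_frames
    n_frames: int

    def per_position(self, observable: str, normalized: bool = False) -> pd.Series:
        """Average over amino acids at each position; optional min-max
        normalization across the eight positions."""
        sub = self.table[self.table.observable == observable]
        prof = (
            sub.groupby("position")["mean"]
            .mean()
            .reindex([p for p in POSITION_ORDER if p in set(sub.position)])
        )
        if normalized:
            lo, hi = prof.min(), prof.max()
            if hi > lo:
                prof = (prof - lo) / (hi - lo)
            else:
                prof = prof * 0.0
        return prof

    def value(self, observable: str, aa: str, position: str) -> float:
        sub = self.table[
            (self.table.observable == observable)
            & (self.table.aa == aa)
            & (self.table.position == position)
        ]
        return float(sub["mean"].iloc[0])


def average_observables(records: list[FrameRecord]) -> ObservableTable:
    """O_ij = (1/N_f) sum over runs and frames of o_ij; N_f counts the
    frames contributing to each (amino acid, position) cell."""
    if not records:
        raise SubsitesError("no frame records to average")
    sums: dict[tuple[str, str, str], float] = {}
    counts: dict[tuple[str, str, str], int] = {}
    for rec in records:
        for pos, obs_values in rec.values.items():
            aa = rec.amino_acids.get(pos, "X")
            for obs, v in obs_values.items():
                if np.isnan(v):
                    continue
                cell = (obs, pos, aa)
                sums[cell] = sums.get(cell, 0.0) + v
                counts[cell] = counts.get(cell, 0) + 1
    rows = [
        {
            "observable": obs,
            "position": pos,
            "aa": aa,
            "mean": sums[(obs, pos, aa)] / counts[(obs, pos, aa)],
            "n_frames": counts[(obs, pos, aa)],
        }
        for (obs, pos, aa) in sorted(sums)
    ]
    return ObservableTable(pd.DataFrame(rows), len(records))
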
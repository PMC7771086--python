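"""Substrate modelling: replacement of non-natural amino acids (NNAAs) by
their most similar natural counterpart, side-chain mutation with ideal
geometry, geometric reconstruction of missing P positions, and random
peptide library generation / threading.

The mutation engine keeps the crystallographic backbone bit-for-bit and
rebuilds side chains from ideal residue templates; chi angles are copied
from the original residue where the torsion definitions coincide and
otherwise set from a compact most-common-rotamer table. An adapter hook
lets callers substitute an external packing engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .annotation import PocketAssignment
from .constants import (
    AA_SMILES,
    ANGLE_C_N_CA,
    ANGLE_CA_C_N,
    ANGLE_CA_C_O,
    ANGLE_N_CA_C,
    BOND_C_N,
    BOND_C_O,
    BOND_CA_C,
    BOND_N_CA,
    CHI_ATOMS,
    ONE_TO_THREE,
    OMEGA_TRANS,
    PHI_EXTENDED,
    POCKET_ORDER,
    POSITION_ORDER,
    PSI_EXTENDED,
    STANDARD_AA1,
    WATER_NAMES,
)
from .errors import SubsitesError, UnmodellableComplex, UnreplaceableNnaa
from .geometry import place_atom
from .sidechains import build_sidechain, measure_chi, n_chi, set_chi
from .structure import Atom, Residue, Structure

#: heavy-atom distance below which a protease-peptide pair counts as a clash
CLASH_DISTANCE = 2.0


# ---------------------------------------------------------------------------
# NNAA -> natural amino acid mapping


@dataclass
class NnaaMapping:
    nnaa_name: str
    candidate_aa: str
    similarity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("Tanimoto similarity must lie in [0, 1]")


class MorganFingerprinter:
    """Circular (Morgan) fingerprints with Tanimoto similarity (rdkit)."""

    def __init__(self, radius: int = 2, n_bits: int = 2048) -> None:
        from rdkit.Chem import rdFingerprintGenerator

        self._gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits
        )

    def fingerprint(self, smiles: str):
        from rdkit import Chem

        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SubsitesError(f"unparseable SMILES {smiles!r}")
        return self._gen.GetFingerprint(mol)

    def similarity(self, smiles_a: str, smiles_b: str) -> float:
        from rdkit import DataStructs

        return float(
            DataStructs.TanimotoSimilarity(
                self.fingerprint(smiles_a), self.fingerprint(smiles_b)
            )
        )


class ElementCountFingerprinter:
    """Heavy-atom element-count profile similarity; coarse fallback used
    when no cheminformatics backend is wanted."""

    def similarity(self, smiles_a: str, smiles_b: str) -> float:
        ca, cb = self._counts(smiles_a), self._counts(smiles_b)
        inter = sum(min(ca.get(e, 0), cb.get(e, 0)) for e in set(ca) | set(cb))
        union = sum(max(ca.get(e, 0), cb.get(e, 0)) for e in set(ca) | set(cb))
        return inter / union if union else 0.0

    @staticmethod
    def _counts(smiles: str) -> dict[str, int]:
        counts: dict[str, int] = {}
        i = 0
        while i < len(smiles):
            ch = smiles[i]
            if ch.isalpha() and ch.upper() != "H":
                elem = ch.upper()
                if smiles[i : i + 2] in ("Cl", "Br"):
                    elem = smiles[i : i + 2].upper()
                    i += 1
                counts[elem] = counts.get(elem, 0) + 1
            i += 1
        return counts


def map_nnaa_to_natural(
    nnaa_smiles: str,
    substrate_candidates: Iterable[str] = STANDARD_AA1,
    fingerprinter=None,
    similarity_floor: float = 0.4,
    nnaa_name: str = "NNAA",
) -> NnaaMapping:
    """Most similar natural amino acid by fingerprint Tanimoto.

    Ties break alphabetically. If no candidate reaches
    ``similarity_floor`` the NNAA is unreplaceable and the complex should
    be discarded.
    """
    candidates = sorted(set(substrate_candidates))
    if not candidates:
        raise SubsitesError("empty candidate amino-acid set")
    if fingerprinter is None:
        fingerprinter = MorganFingerprinter()
    best_aa, best_sim = None, -1.0
    for aa in candidates:
        if aa not in AA_SMILES:
            raise SubsitesError(f"unknown amino acid candidate {aa!r}")
        sim = fingerprinter.similarity(nnaa_smiles, AA_SMILES[aa])
        if sim > best_sim:
            best_aa, best_sim = aa, sim
    if best_sim < similarity_floor:
        raise UnreplaceableNnaa(
            f"{nnaa_name}: best Tanimoto {best_sim:.3f} below floor {similarity_floor}"
        )
    return NnaaMapping(nnaa_name, best_aa, best_sim)


# ---------------------------------------------------------------------------
# Mutation


def count_clashes(
    structure: Structure,
    chain_id: str,
    res_seq: int,
    insertion_code: str = "",
    clash_distance: float = CLASH_DISTANCE,
    sidechain_only: bool = True,
) -> int:
    """Heavy-atom pairs closer than ``clash_distance`` between the residue
    (by default its side chain) and atoms outside the residue."""
    res = structure.chain(chain_id).get(res_seq, insertion_code)
    probe = [
        a for a in res.atoms
        if not a.is_hydrogen and (not sidechain_only or not a.is_backbone)
    ]
    if not probe:
        return 0
    others = []
    for cid, r in structure.iter_residues():
        if cid == chain_id and r.res_seq == res_seq and r.insertion_code == insertion_code:
            continue
        if r.res_name in WATER_NAMES:
            continue
        others.extend(a.coords for a in r.atoms if not a.is_hydrogen)
    if not others:
        return 0
    tree = cKDTree(np.asarray(others))
    return int(sum(len(tree.query_ball_point(a.coords, clash_distance)) for a in probe))


def mutate_residue(
    complex: Structure,
    chain_id: str,
    res_seq: int,
    new_aa: str,
    insertion_code: str = "",
) -> tuple[Structure, int]:
    """Replace a residue's side chain with ideal-geometry ``new_aa``.

    Backbone atoms are untouched. Returns the mutated structure and the
    steric clash count of the new side chain against the rest of the
    complex (heavy-atom pairs under 2 A).
    """
    if new_aa not in ONE_TO_THREE:
        raise SubsitesError(f"unknown amino acid {new_aa!r}")
    new3 = ONE_TO_THREE[new_aa]
    out = complex.copy()
    chain = out.chain(chain_id)
    if chain is None:
        raise SubsitesError(f"chain {chain_id!r} not found")
    res = chain.get(res_seq, insertion_code)
    if res is None:
        raise SubsitesError(f"residue {chain_id}/{res_seq} not found")
    backbone = {}
    for name in ("N", "CA", "C"):
        a = res.atom(name)
        if a is None:
            raise SubsitesError(f"residue {chain_id}/{res_seq} lacks backbone atom {name}")
        backbone[name] = a.coords
    if res.res_name == new3:
        return out, count_clashes(out, chain_id, res_seq, insertion_code)

    old_chis = {}
    if res.res_name in CHI_ATOMS:
        for k in range(n_chi(res.res_name)):
            try:
                old_chis[CHI_ATOMS[res.res_name][k]] = measure_chi(res, k)
            except SubsitesError:
                break

    kept = [a for a in res.atoms if a.name in ("N", "CA", "C", "O", "OXT")]
    new_res = Residue(new3, res.res_seq, res.insertion_code, kept, res.hetero)
    new_res.atoms = kept + build_sidechain(backbone, new3)
    # chi angles: copy where the torsion definition carries over, else rotamer
    if new3 in CHI_ATOMS and new3 != "PRO":
        from .constants import ROTAMER_CHI

        rotamer = ROTAMER_CHI.get(new3, ())
        for k, quad in enumerate(CHI_ATOMS[new3]):
            if quad in old_chis:
                set_chi(new_res, k, old_chis[quad])
            elif k < len(rotamer):
                set_chi(new_res, k, rotamer[k])
    chain.residues[chain.residues.index(res)] = new_res
    clashes = count_clashes(out, chain_id, res_seq, insertion_code)
    return out, clashes


def _sidechain_interaction_energy(
    structure: Structure, chain_id: str, res_seq: int, insertion_code: str = ""
) -> float:
    """Lennard-Jones interaction of the residue's side chain with every
    atom outside the residue (the relaxation objective)."""
    from .constants import LJ_EPSILON, VDW_RADII

    res = structure.chain(chain_id).get(res_seq, insertion_code)
    probe = [a for a in res.atoms if not a.is_hydrogen and not a.is_backbone]
    if not probe:
        return 0.0
    other_xyz, other_r, other_e = [], [], []
    for cid, r in structure.iter_residues():
        if cid == chain_id and r.res_seq == res_seq and r.insertion_code == insertion_code:
            continue
        if r.res_name in WATER_NAMES:
            continue
        for a in r.atoms:
            if a.is_hydrogen:
                continue
            other_xyz.append(a.coords)
            other_r.append(VDW_RADII.get(a.element.upper(), 1.7))
            other_e.append(LJ_EPSILON.get(a.element.upper(), 0.1))
    if not other_xyz:
        return 0.0
    O = np.asarray(other_xyz)
    orad, oeps = np.asarray(other_r), np.asarray(other_e)
    total = 0.0
    for a in probe:
        d = O - a.coords
        rdist = np.sqrt((d * d).sum(axis=1))
        within = (rdist < 10.0) & (rdist > 1e-6)
        if not within.any():
            continue
        rmin = VDW_RADII.get(a.element.upper(), 1.7) + orad[within]
        eps = np.sqrt(LJ_EPSILON.get(a.element.upper(), 0.1) * oeps[within])
        x6 = (rmin / rdist[within]) ** 6
        total += float((eps * (x6 * x6 - 2.0 * x6)).sum())
    return total


def relax_sidechain(
    structure: Structure,
    chain_id: str,
    res_seq: int,
    insertion_code: str = "",
    step_deg: float = 30.0,
) -> Structure:
    """Internal relaxation: scan chi1 (and chi2 where present) on a grid
    and keep the lowest-energy orientation under the Lennard-Jones part of
    the energy model (current orientation kept on ties)."""
    res = structure.chain(chain_id).get(res_seq, insertion_code)
    if res is None or res.res_name not in CHI_ATOMS or res.res_name == "PRO":
        return structure
    best = _sidechain_interaction_energy(structure, chain_id, res_seq, insertion_code)
    chi1_base = measure_chi(res, 0)
    has_chi2 = n_chi(res.res_name) >= 2
    chi2_base = measure_chi(res, 1) if has_chi2 else 0.0
    chi2_grid = (
        [chi2_base + k * 60.0 for k in range(6)] if has_chi2 else [chi2_base]
    )
    best_pair = (chi1_base, chi2_base)
    for d1 in range(int(360 // step_deg)):
        chi1 = chi1_base + d1 * step_deg
        set_chi(res, 0, chi1)
        for chi2 in chi2_grid:
            if has_chi2:
                set_chi(res, 1, chi2)
            e = _sidechain_interaction_energy(
                structure, chain_id, res_seq, insertion_code
            )
            if e < best - 1e-9:
                best, best_pair = e, (chi1, chi2)
    set_chi(res, 0, best_pair[0])
    if has_chi2:
        set_chi(res, 1, best_pair[1])
    return structure


# ---------------------------------------------------------------------------
# Missing-position reconstruction


def _extend_c_terminal(
    chain, phi: float, psi: float, res_seq: int
) -> Residue:
    last = chain.residues[-1]
    n, ca, c = (last.atom(x).coords for x in ("N", "CA", "C"))
    new_n = place_atom(n, ca, c, BOND_C_N, ANGLE_CA_C_N, psi)
    new_ca = place_atom(ca, c, new_n, BOND_N_CA, ANGLE_C_N_CA, OMEGA_TRANS)
    new_c = place_atom(c, new_n, new_ca, BOND_CA_C, ANGLE_N_CA_C, phi)
    new_o = place_atom(new_n, new_ca, new_c, BOND_C_O, ANGLE_CA_C_O, psi - 180.0)
    return Residue(
        "GLY", res_seq, "",
        [Atom("N", "N", new_n), Atom("CA", "C", new_ca),
         Atom("C", "C", new_c), Atom("O", "O", new_o)],
    )


def _extend_n_terminal(
    chain, phi: float, psi: float, res_seq: int
) -> Residue:
    first = chain.residues[0]
    n, ca, c = (first.atom(x).coords for x in ("N", "CA", "C"))
    new_c = place_atom(c, ca, n, BOND_C_N, ANGLE_C_N_CA, phi)
    new_ca = place_atom(ca, n, new_c, BOND_CA_C, ANGLE_CA_C_N, OMEGA_TRANS)
    new_n = place_atom(n, new_c, new_ca, BOND_N_CA, ANGLE_N_CA_C, psi)
    new_o = place_atom(new_n, new_ca, new_c, BOND_C_O, ANGLE_CA_C_O, psi - 180.0)
    return Residue(
        "GLY", res_seq, "",
        [Atom("N", "N", new_n), Atom("CA", "C", new_ca),
         Atom("C", "C", new_c), Atom("O", "O", new_o)],
    )


def _backbone_clashes(
    structure: Structure, residue: Residue, peptide_chain_id: str
) -> int:
    pts = [a.coords for a in residue.atoms if not a.is_hydrogen]
    others = []
    for cid, r in structure.iter_residues():
        if cid == peptide_chain_id or r.res_name in WATER_NAMES:
            continue
        others.extend(a.coords for a in r.atoms if not a.is_hydrogen)
    if not others:
        return 0
    tree = cKDTree(np.asarray(others))
    return int(sum(len(tree.query_ball_point(p, CLASH_DISTANCE)) for p in pts))


def _torsion_grid() -> list[tuple[float, float]]:
    """Extended conformer first, then a 30-degree phi/psi grid."""
    grid = [(PHI_EXTENDED, PSI_EXTENDED)]
    for phi in range(-180, 180, 30):
        for psi in range(-180, 180, 30):
            grid.append((float(phi), float(psi)))
    return grid


def reconstruct_missing(
    complex: Structure,
    assignment: PocketAssignment,
    target_sequence: str,
) -> Structure:
    """Extend the bound peptide to a full P4-P4' 8-mer.

    New residues get ideal trans backbone geometry; phi/psi are scanned on
    a 30-degree grid and the minimum-clash conformer is kept. If no grid
    point is clash-free the complex is unmodellable. Side chains follow
    the mutation engine; existing positions are mutated to match
    ``target_sequence`` where they differ.
    """
    if len(target_sequence) != len(POSITION_ORDER):
        raise SubsitesError("target sequence must cover P4-P4' (8 residues)")
    labels = {lab for _, lab in assignment.peptide_map if lab}
    if len(labels) < 3:
        raise SubsitesError("existing peptide must cover at least 3 pockets")
    out = complex.copy()
    pep_chain = out.chain(assignment.peptide_chain_id)
    key_label = [(k, lab) for k, lab in assignment.peptide_map if lab]
    first_idx = POCKET_ORDER.index(key_label[0][1])
    last_idx = POCKET_ORDER.index(key_label[-1][1])

    # N-terminal extension toward P4
    for idx in range(first_idx - 1, -1, -1):
        res_seq = pep_chain.residues[0].res_seq - 1
        best = None
        for phi, psi in _torsion_grid():
            cand = _extend_n_terminal(pep_chain, phi, psi, res_seq)
            clashes = _backbone_clashes(out, cand, pep_chain.chain_id)
            if best is None or clashes < best[1]:
                best = (cand, clashes)
            if clashes == 0:
                break
        if best[1] > 0:
            raise UnmodellableComplex(
                f"extension toward {POCKET_ORDER[idx]} clashes with the enzyme"
            )
        pep_chain.residues.insert(0, best[0])
    # C-terminal extension toward P4'
    for idx in range(last_idx + 1, len(POCKET_ORDER)):
        res_seq = pep_chain.residues[-1].res_seq + 1
        best = None
        for phi, psi in _torsion_grid():
            cand = _extend_c_terminal(pep_chain, phi, psi, res_seq)
            clashes = _backbone_clashes(out, cand, pep_chain.chain_id)
            if best is None or clashes < best[1]:
                best = (cand, clashes)
            if clashes == 0:
                break
        if best[1] > 0:
            raise UnmodellableComplex(
                f"extension toward {POCKET_ORDER[idx]} clashes with the enzyme"
            )
        pep_chain.residues.append(best[0])

    if len(pep_chain.residues) != len(POSITION_ORDER):
        raise UnmodellableComplex(
            f"peptide has {len(pep_chain.residues)} residues after extension"
        )
    # thread the target sequence over all eight positions
    for res, aa in zip(list(pep_chain.residues), target_sequence):
        if res.one_letter != aa:
            out, _ = mutate_residue(
                out, pep_chain.chain_id, res.res_seq, aa, res.insertion_code
            )
            pep_chain = out.chain(assignment.peptide_chain_id)
    return out


def full_assignment(structure: Structure, peptide_chain_id: str) -> PocketAssignment:
    """P4-P4' assignment for a peptide already spanning eight residues."""
    chain = structure.chain(peptide_chain_id)
    if chain is None or len(chain.residues) != len(POCKET_ORDER):
        raise SubsitesError("peptide chain must have exactly 8 residues")
    peptide_map = [
        (r.key(peptide_chain_id), POCKET_ORDER[i]) for i, r in enumerate(chain.residues)
    ]
    from .annotation import assign_pockets_from_reference

    return assign_pockets_from_reference(structure, peptide_map)


# ---------------------------------------------------------------------------
# Random libraries and threading


@dataclass
class PeptideLibrary:
    sequences: list[str]
    seed: int
    library_id: str = "library"

    def __post_init__(self) -> None:
        for s in self.sequences:
            if any(c not in STANDARD_AA1 for c in s):
                raise SubsitesError(f"non-standard letter in sequence {s!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def to_text(self) -> str:
        header = f"# library_id={self.library_id} seed={self.seed} n={len(self)}\n"
        return header + "\n".join(self.sequences) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "PeptideLibrary":
        seed, library_id = 0, "library"
        sequences = []
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("seed="):
                        seed = int(tok[5:])
                    elif tok.startswith("library_id="):
                        library_id = tok[11:]
                continue
            sequences.append(line)
        return cls(sequences, seed, library_id)


def generate_library(
    n: int = 480, length: int = 8, seed: int = 0, library_id: str = "library"
) -> PeptideLibrary:
    """Random peptide library, i.i.d. uniform over the 20 amino acids at
    each position; reproducible for a fixed seed."""
    if n < 1:
        raise SubsitesError("library size must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_AA1))
    seqs = ["".join(row) for row in rng.choice(letters, size=(n, length))]
    return PeptideLibrary(seqs, seed, library_id)


def thread_library(
    complex: Structure,
    library: PeptideLibrary,
    peptide_chain_id: str,
    relax_hook: Optional[Callable[[Structure, str, int], Structure]] = None,
) -> list[Structure]:
    """One modelled complex per library sequence, produced by successive
    single-residue mutations P4 -> P4' on the template peptide.

    ``relax_hook(structure, chain_id, res_seq)`` runs after each mutation;
    the default scans chi1 for the lowest-clash orientation.
    """
    chain = complex.chain(peptide_chain_id)
    if chain is None or len(chain.residues) != 8:
        raise SubsitesError("template must carry an 8-residue peptide")
    if relax_hook is None:
        relax_hook = lambda s, c, r: relax_sidechain(s, c, r)  # noqa: E731
    out = []
    for seq in library.sequences:
        model = complex.copy()
        for res, aa in zip(list(chain.residues), seq):
            if model.chain(peptide_chain_id).get(res.res_seq, res.insertion_code).one_letter == aa:
                continue
            model, _ = mutate_residue(
                model, peptide_chain_id, res.res_seq, aa, res.insertion_code
            )
            model = relax_hook(model, peptide_chain_id, res.res_seq)
        out.append(model)
    return out
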
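"""Deterministic toy complexes and specificity matrices.

The toy complex is an ideal-geometry beta-groove: an extended peptide
flanked by two parallel extended strands of a single "enzyme" chain, with
catalytic residues across from the scissile position and, optionally, a
cage of pocket atoms deepening the S1 subsite and a steric wall blocking
the prime side. No physical realism is claimed; the fixtures exist to
exercise the annotation, modelling and sampling contracts with ground
truth known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .annotation import CatalyticAnnotation, PocketAssignment
from .constants import (
    ANGLE_CA_C_N,
    ANGLE_C_N_CA,
    ANGLE_CA_C_O,
    ANGLE_N_CA_C,
    BOND_C_N,
    BOND_C_O,
    BOND_CA_C,
    BOND_N_CA,
    POCKET_ORDER,
    POSITION_ORDER,
    STANDARD_AA1,
)
from .errors import SubsitesError
from .geometry import place_atom
from .modelling import mutate_residue
from .structure import Atom, Chain, Residue, Structure

PEPTIDE_CHAIN = "P"
ENZYME_CHAIN = "E"


@dataclass
class FixtureSpec:
    seed: int = 0
    groove_depth: float = 5.0  # peptide-axis to strand-axis distance (A)
    peptide_length: int = 8
    peptide_sequence: Optional[str] = None
    catalytic_positions: Optional[list[int]] = None  # enzyme res_seq values
    blocked_prime_side: bool = False
    nnaa_at: Optional[int] = None  # 1-based peptide position renamed to NLE
    deep_pocket: bool = True  # cage of atoms deepening S1
    strand_sequence_letter: str = "A"

    def __post_init__(self) -> None:
        if not 2 <= self.peptide_length <= 12:
            raise SubsitesError("peptide_length must lie in [2, 12]")
        if self.peptide_sequence is not None:
            if len(self.peptide_sequence) != self.peptide_length:
                raise SubsitesError("peptide_sequence length mismatch")
            if any(c not in STANDARD_AA1 for c in self.peptide_sequence):
                raise SubsitesError("peptide_sequence must use standard letters")


def _extended_backbone(n_res: int, start_seq: int = 1) -> list[Residue]:
    """Glycine backbone in an extended beta-strand conformation."""
    from .constants import PHI_EXTENDED, PSI_EXTENDED

    phi, psi = PHI_EXTENDED, PSI_EXTENDED
    n0 = np.zeros(3)
    ca0 = n0 + np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    residues = []
    n, ca, c = n0, ca0, c0
    for i in range(n_res):
        o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi - 180.0)
        residues.append(
            Residue(
                "GLY", start_seq + i, "",
                [Atom("N", "N", n), Atom("CA", "C", ca),
                 Atom("C", "C", c), Atom("O", "O", o)],
            )
        )
        if i == n_res - 1:
            break
        n_next = place_atom(n, ca, c, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_next = place_atom(ca, c, n_next, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c_next = place_atom(c, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi)
        n, ca, c = n_next, ca_next, c_next
    return residues


def _translate(residues: list[Residue], offset: np.ndarray) -> None:
    for r in residues:
        for a in r.atoms:
            a.coords = a.coords + offset


def _brute_force_pockets(
    structure: Structure,
    peptide_labels: list[tuple[tuple[str, int, str], Optional[str]]],
    cutoff: float = 4.5,
) -> dict[str, set]:
    """Ground-truth pocket membership by direct double-loop distance check."""
    pockets: dict[str, set] = {}
    for key, label in peptide_labels:
        if label is None:
            continue
        pep_res = structure.residue(key)
        pep_xyz = pep_res.coords()
        for cid, res in structure.iter_residues():
            if cid == key[0]:
                continue
            near = False
            for a in res.atoms:
                d = np.sqrt(((pep_xyz - a.coords) ** 2).sum(axis=1))
                if (d <= cutoff).any():
                    near = True
                    break
            if near:
                pockets.setdefault(label, set()).add(res.key(cid))
    return pockets


def make_toy_complex(
    spec: FixtureSpec = FixtureSpec(),
) -> tuple[Structure, CatalyticAnnotation, PocketAssignment]:
    """Build the groove fixture with its catalytic annotation and
    ground-truth pocket assignment."""
    L = spec.peptide_length
    sequence = spec.peptide_sequence or "A" * L
    d = spec.groove_depth

    peptide = _extended_backbone(L, start_seq=1)
    # the enzyme chain must stay clearly longer than the 3-12 residue
    # ligand window, whatever the peptide length
    strand_len = max(L + 2, 7)
    strand_a = _extended_backbone(strand_len, start_seq=1)
    strand_b = _extended_backbone(strand_len, start_seq=101)
    # strands flank the peptide, shifted one residue back so residue i+1
    # of each strand faces peptide residue i; the offset is perpendicular
    # to the chain axis within the backbone plane
    axis = peptide[-1].atom("CA").coords - peptide[0].atom("CA").coords
    axis /= np.linalg.norm(axis)
    perp = np.array([-axis[1], axis[0], 0.0])
    perp /= np.linalg.norm(perp)
    shift = peptide[0].atom("N").coords - strand_a[1].atom("N").coords
    _translate(strand_a, shift + d * perp)
    _translate(strand_b, shift - d * perp)

    structure = Structure(
        [Chain(PEPTIDE_CHAIN, peptide), Chain(ENZYME_CHAIN, strand_a + strand_b)],
        source_id="toy-groove",
    )
    # dress the glycine backbones with alanine (or requested) side chains
    for i, aa in enumerate(sequence):
        if aa != "G":
            structure, _ = mutate_residue(structure, PEPTIDE_CHAIN, i + 1, aa)
    for res in list(structure.chain(ENZYME_CHAIN).residues):
        if spec.strand_sequence_letter != "G":
            structure, _ = mutate_residue(
                structure, ENZYME_CHAIN, res.res_seq, spec.strand_sequence_letter
            )

    # peptide position labels: N->C mapped onto S4..S4'
    chain_p = structure.chain(PEPTIDE_CHAIN)
    peptide_labels = []
    for i, res in enumerate(chain_p.residues):
        label = POCKET_ORDER[i] if i < len(POCKET_ORDER) else None
        peptide_labels.append((res.key(PEPTIDE_CHAIN), label))

    p1_index = min(POCKET_ORDER.index("S1"), L - 1)

    extras: list[Residue] = []
    if spec.deep_pocket and L > p1_index:
        p1 = chain_p.residues[p1_index]
        cb = p1.atom("CB") or p1.atom("CA")
        ca = p1.atom("CA")
        v = cb.coords - ca.coords
        v = v / np.linalg.norm(v)
        # open-ended cage around the S1 side-chain direction: rings of
        # carbons wide enough to admit any natural side chain (lateral
        # clearance >= 3 A from a side chain relaxed along the pocket
        # axis), kept clear (>3.3 A) of every existing atom
        existing = np.asarray(
            [a.coords for _, _, a in structure.iter_atoms()]
        ).reshape(-1, 3)
        w1 = np.cross(v, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(w1) < 1e-6:
            w1 = np.cross(v, np.array([0.0, 1.0, 0.0]))
        w1 /= np.linalg.norm(w1)
        w2 = np.cross(v, w1)
        candidates = []
        for height, radius in ((1.5, 5.2), (4.5, 5.2), (8.2, 2.4)):
            for ang in range(0, 360, 60):
                rad = np.deg2rad(ang)
                offset = radius * (np.cos(rad) * w1 + np.sin(rad) * w2)
                candidates.append(cb.coords + height * v + offset)
        cage_pts = [
            p for p in candidates
            if np.min(np.sqrt(((existing - p) ** 2).sum(axis=1))) > 3.3
        ]
        extras.append(
            Residue(
                "BLK", 200, "",
                [Atom(f"C{i+1}", "C", p) for i, p in enumerate(cage_pts)],
                hetero=True,
            )
        )

    if spec.deep_pocket and L > p1_index:
        # oxyanion-hole-like probes: carbonyl-carbon atoms placed near the
        # P1 backbone N and O, in open groove space, giving the scissile
        # position a sequence-independent favourable contact
        p1 = chain_p.residues[p1_index]
        for probe_idx, anchor_name in enumerate(("N", "O")):
            anchor = p1.atom(anchor_name)
            if anchor is None:
                continue
            existing = np.asarray(
                [a.coords for _, _, a in structure.iter_atoms()]
            ).reshape(-1, 3)
            for extra in extras:
                existing = np.vstack([existing, [a.coords for a in extra.atoms]])
            best_pt, best_clear = None, 0.0
            for theta in np.linspace(0.0, 2 * np.pi, 24, endpoint=False):
                for z in (-0.3, 0.0, 0.3):
                    direction = np.array(
                        [np.cos(theta) * np.sqrt(1 - z * z),
                         np.sin(theta) * np.sqrt(1 - z * z), z]
                    )
                    pt = anchor.coords + 3.2 * direction
                    d = np.sqrt(((existing - pt) ** 2).sum(axis=1))
                    clear = np.partition(d, 1)[1]  # nearest non-anchor atom
                    if clear > best_clear:
                        best_clear, best_pt = clear, pt
            if best_pt is not None and best_clear > 3.0:
                extras.append(
                    Residue(
                        "BLK", 210 + probe_idx, "",
                        [Atom("C", "C", best_pt)],
                        hetero=True,
                    )
                )

    if spec.blocked_prime_side:
        last = chain_p.residues[-1]
        c_last = last.atom("C").coords
        existing = np.asarray(
            [a.coords for _, _, a in structure.iter_atoms()]
        ).reshape(-1, 3)
        grid = []
        for x in np.arange(c_last[0] - 1.0, c_last[0] + 8.0, 1.6):
            for y in np.arange(c_last[1] - 6.0, c_last[1] + 6.0, 1.6):
                for z in np.arange(c_last[2] - 6.0, c_last[2] + 6.0, 1.6):
                    p = np.array([x, y, z])
                    if np.min(np.sqrt(((existing - p) ** 2).sum(axis=1))) > 2.05:
                        grid.append(p)
        for g, start in enumerate(range(0, len(grid), 40)):
            block = grid[start : start + 40]
            extras.append(
                Residue(
                    "BLK", 300 + g, "",
                    [Atom(f"C{i+1}", "C", p) for i, p in enumerate(block)],
                    hetero=True,
                )
            )

    if extras:
        structure.chain(ENZYME_CHAIN).residues.extend(extras)

    if spec.nnaa_at is not None:
        res = structure.chain(PEPTIDE_CHAIN).get(spec.nnaa_at)
        if res is None:
            raise SubsitesError(f"nnaa_at position {spec.nnaa_at} outside peptide")
        res.res_name = "NLE"
        res.hetero = True

    catalytic_positions = spec.catalytic_positions
    if catalytic_positions is None:
        # strand residues facing P1 and P1' (strand numbering is offset by 1)
        catalytic_positions = [p1_index + 2]
        if L > p1_index + 1:
            catalytic_positions.append(p1_index + 3)
    roles = ["nucleophile", "base", "acid"]
    catalytic = CatalyticAnnotation(
        [
            (ENZYME_CHAIN, pos, roles[i % len(roles)])
            for i, pos in enumerate(catalytic_positions)
        ]
    )
    for cid, pos, _ in catalytic.entries:
        if structure.residue((cid, pos, "")) is None:
            raise SubsitesError(f"catalytic residue {pos} outside the groove")

    assignment = PocketAssignment(
        PEPTIDE_CHAIN,
        peptide_labels,
        _brute_force_pockets(structure, peptide_labels),
    )
    return structure, catalytic, assignment


def make_toy_matrix(
    specific_positions: set[str],
    promiscuous_positions: set[str],
    seed: int = 0,
):
    """Specificity matrix with one-hot columns at the specific positions
    and uniform columns at the promiscuous ones; entropies are known by
    construction (0 and 1 respectively)."""
    import pandas as pd

    from .entropy import SpecificityMatrix

    if specific_positions & promiscuous_positions:
        raise SubsitesError("specific and promiscuous positions overlap")
    if specific_positions | promiscuous_positions != set(POSITION_ORDER):
        raise SubsitesError("positions must partition P4..P4'")
    rng = np.random.default_rng(seed)
    letters = sorted(STANDARD_AA1)
    data = {}
    for pos in POSITION_ORDER:
        if pos in promiscuous_positions:
            data[pos] = np.full(20, 0.05)
        else:
            col = np.zeros(20)
            col[rng.integers(20)] = 1.0
            data[pos] = col
    df = pd.DataFrame(data, index=letters)[list(POSITION_ORDER)]
    return SpecificityMatrix(df, substrate_count=0.0, family_id=f"toy-{seed}")


def write_fixture_files(directory, spec: FixtureSpec = FixtureSpec()) -> dict[str, str]:
    """Emit the toy complex as user-facing input files (PDB + delimited
    annotation tables). Returns the path map."""
    import os

    from .structure import write_pdb

    structure, catalytic, assignment = make_toy_complex(spec)
    os.makedirs(directory, exist_ok=True)
    paths = {}

    pdb_path = os.path.join(directory, "toy_complex.pdb")
    with open(pdb_path, "w") as fh:
        fh.write(write_pdb(structure))
    paths["structure"] = pdb_path

    cat_path = os.path.join(directory, "toy_catalytic.tsv")
    with open(cat_path, "w") as fh:
        fh.write("pdb_id\tchain\tres_seq\trole\n")
        for chain, seq, role in catalytic.entries:
            fh.write(f"{structure.source_id}\t{chain}\t{seq}\t{role}\n")
    paths["catalytic"] = cat_path

    ref_path = os.path.join(directory, "toy_reference_positions.tsv")
    with open(ref_path, "w") as fh:
        fh.write("chain\tres_seq\tpocket\n")
        for (cid, seq, _), label in assignment.peptide_map:
            if label is not None:
                fh.write(f"{cid}\t{seq}\t{label}\n")
    paths["reference_positions"] = ref_path

    matrix = make_toy_matrix({"P1"}, set(POSITION_ORDER) - {"P1"}, seed=spec.seed)
    mat_path = os.path.join(directory, "toy_matrix.tsv")
    matrix.fractions.to_csv(mat_path, sep="\t")
    paths["matrix"] = mat_path
    return paths
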
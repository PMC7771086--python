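"""Hierarchical structure model, PDB I/O, rigid superposition and global
pairwise sequence alignment.

The hierarchy is deliberately small (Atom / Residue / Chain / Structure,
author numbering, first model only): it is the substrate for every
distance cutoff in the annotation and sampling stages, not a general
crystallographic model. Parsing is delegated to gemmi; writing uses the
fixed wwPDB v3.3 column layout so that a written file re-parses to the
same identifiers and coordinates (3 decimals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import gemmi
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .constants import BACKBONE_NAMES, STANDARD_AA3, THREE_TO_ONE
from .errors import AlignmentError, PDBFormatError, PDBParseError, SuperpositionError
from . import geometry

ResidueKey = tuple[str, int, str]  # (chain_id, res_seq, insertion_code)


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy(), self.occupancy, self.b_iso)


@dataclass
class Residue:
    res_name: str
    res_seq: int
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)
    hetero: bool = False

    @property
    def is_standard_aa(self) -> bool:
        return self.res_name in STANDARD_AA3

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        sel = [a.coords for a in self.atoms if not (heavy_only and a.is_hydrogen)]
        return np.asarray(sel, dtype=float).reshape(-1, 3)

    def key(self, chain_id: str) -> ResidueKey:
        return (chain_id, self.res_seq, self.insertion_code)

    def copy(self) -> "Residue":
        return Residue(
            self.res_name, self.res_seq, self.insertion_code,
            [a.copy() for a in self.atoms], self.hetero,
        )


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def get(self, res_seq: int, insertion_code: str = "") -> Optional[Residue]:
        for r in self.residues:
            if r.res_seq == res_seq and r.insertion_code == insertion_code:
                return r
        return None

    def sequence(self) -> str:
        """One-letter sequence over standard residues (X for others)."""
        return "".join(r.one_letter for r in self.residues)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    source_id: str = ""

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        return None

    def residue(self, key: ResidueKey) -> Optional[Residue]:
        c = self.chain(key[0])
        return c.get(key[1], key[2]) if c else None

    def iter_residues(self) -> Iterator[tuple[str, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c.chain_id, r

    def iter_atoms(self) -> Iterator[tuple[str, Residue, Atom]]:
        for cid, r in self.iter_residues():
            for a in r.atoms:
                yield cid, r, a

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def all_coords(self) -> np.ndarray:
        return np.asarray([a.coords for _, _, a in self.iter_atoms()]).reshape(-1, 3)

    def set_all_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        for i, (_, _, a) in enumerate(self.iter_atoms()):
            a.coords = coords[i].copy()

    def transform(self, R: np.ndarray, t: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        out = self.copy()
        for _, _, a in out.iter_atoms():
            a.coords = R @ a.coords + t
        return out

    def without_chain(self, chain_id: str) -> "Structure":
        return Structure(
            [c.copy() for c in self.chains if c.chain_id != chain_id], self.source_id
        )

    def copy(self) -> "Structure":
        return Structure([c.copy() for c in self.chains], self.source_id)


@dataclass
class Superposition:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class PairwiseAlignment:
    aligned_query: str
    aligned_target: str
    identity_fraction: float
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_target):
            raise AlignmentError("gapped sequences differ in length")


# ---------------------------------------------------------------------------
# PDB I/O


def parse_pdb(text: str, source_id: str = "") -> Structure:
    """Parse a PDB document into a :class:`Structure`.

    Only the first MODEL is read. Alternate locations are resolved to the
    highest-occupancy conformer (ties: first encountered). Chains and
    residues keep file order; numbering is author numbering.
    """
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(f"unreadable PDB document: {exc}") from exc
    if len(st) == 0 or sum(ch.count_atom_sites() for ch in st[0]) == 0:
        first = next((ln for ln in text.splitlines() if ln.strip()), "<empty>")
        raise PDBParseError(f"no ATOM/HETATM records found; first line: {first!r}")
    model = st[0]
    chains: list[Chain] = []
    for gch in model:
        chain = Chain(gch.name)
        for gres in gch:
            res = Residue(
                res_name=gres.name,
                res_seq=gres.seqid.num,
                insertion_code=(gres.seqid.icode or "").strip(),
                hetero=(gres.het_flag == "H"),
            )
            # altloc resolution: group by atom name, keep max occupancy
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for ga in gres:
                if ga.name not in best:
                    best[ga.name] = ga
                    order.append(ga.name)
                elif ga.occ > best[ga.name].occ:
                    best[ga.name] = ga
            for name in order:
                ga = best[name]
                elem = ga.element.name.upper() if ga.element.name else _guess_element(name)
                res.atoms.append(
                    Atom(name, elem, np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                         ga.occ, ga.b_iso)
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            # residue identity must be unique within the chain
            keys = [(r.res_seq, r.insertion_code, r.res_name) for r in chain.residues]
            if len({(s, i) for s, i, _ in keys}) != len(keys):
                merged: dict[tuple[int, str], Residue] = {}
                kept: list[Residue] = []
                for r in chain.residues:
                    k = (r.res_seq, r.insertion_code)
                    if k in merged:
                        merged[k].atoms.extend(r.atoms)
                    else:
                        merged[k] = r
                        kept.append(r)
                chain.residues = kept
            chains.append(chain)
    return Structure(chains, source_id)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip("0123456789'\"")
    return (stripped[:1] or "X").upper()


def _format_atom_name(name: str, element: str) -> str:
    if len(name) > 4:
        raise PDBFormatError(f"atom name {name!r} exceeds the 4-column PDB field")
    if len(name) < 4 and len(element) < 2:
        return f" {name:<3}"
    return f"{name:<4}"


def write_pdb(structure: Structure) -> str:
    """Serialize to PDB text (ATOM/HETATM/TER/END, wwPDB v3.3 columns)."""
    if not structure.chains:
        raise PDBFormatError("cannot write an empty structure")
    lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        last_res = None
        for res in chain.residues:
            rec = "HETATM" if (res.hetero or not res.is_standard_aa) else "ATOM"
            for atom in res.atoms:
                serial += 1
                name = _format_atom_name(atom.name, atom.element)
                lines.append(
                    f"{rec:<6}{serial % 100000:>5} {name} {res.res_name:>3} "
                    f"{chain.chain_id:1}{res.res_seq:>4}{res.insertion_code or ' ':1}   "
                    f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{atom.b_iso:6.2f}          "
                    f"{atom.element:>2}"
                )
            last_res = res
        if last_res is not None:
            serial += 1
            lines.append(
                f"TER   {serial % 100000:>5}      {last_res.res_name:>3} "
                f"{chain.chain_id:1}{last_res.res_seq:>4}{last_res.insertion_code or ' ':1}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Superposition


def superpose(ref_coords: np.ndarray, mov_coords: np.ndarray) -> Superposition:
    """Kabsch least-squares rigid superposition of matched coordinate sets."""
    R, t, rmsd = geometry.kabsch(ref_coords, mov_coords)
    if abs(np.linalg.det(R) - 1.0) > 1e-6:
        raise SuperpositionError("superposition produced an improper rotation")
    return Superposition(R, t, rmsd)


# ---------------------------------------------------------------------------
# Sequence alignment

_ALLOWED_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_sequences(
    query: str, target: str, gap_open: float = -10.0, gap_extend: float = -0.5
) -> PairwiseAlignment:
    """Global pairwise alignment (BLOSUM62; gap of length L scores
    ``gap_open + (L-1) * gap_extend``).

    ``identity_fraction`` counts identical non-gap, non-X columns over all
    alignment columns including gaps.
    """
    for seq, label in ((query, "query"), (target, "target")):
        if not seq:
            raise AlignmentError(f"{label} sequence is empty")
        bad = set(seq) - _ALLOWED_LETTERS
        if bad:
            raise AlignmentError(f"illegal {label} characters: {sorted(bad)}")
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(query, target)[0]
    gapped_q, gapped_t = str(alignment[0]), str(alignment[1])
    matches = sum(
        1 for a, b in zip(gapped_q, gapped_t) if a == b and a not in ("-", "X")
    )
    identity = matches / len(gapped_q)
    return PairwiseAlignment(gapped_q, gapped_t, identity, float(alignment.score))


def alignment_column_map(alignment: PairwiseAlignment) -> list[tuple[int | None, int | None]]:
    """Per-column (query_index, target_index) pairs; ``None`` marks a gap."""
    out: list[tuple[int | None, int | None]] = []
    qi = ti = 0
    for a, b in zip(alignment.aligned_query, alignment.aligned_target):
        q = qi if a != "-" else None
        t = ti if b != "-" else None
        out.append((q, t))
        if a != "-":
            qi += 1
        if b != "-":
            ti += 1
    return out
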
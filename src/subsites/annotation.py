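"""Annotation workflow: peptide-ligand detection, catalytic-site occupancy
by accessibility change, pocket assignment (S4-S4') around a reference
substrate, projection of that assignment onto homologous complexes, gap
closing, cap stripping and homology transfer of catalytic residues.

Substrate positions are labelled P4..P4' in chain N->C order; the scissile
bond sits between the residues assigned to S1 and S1'. A protease residue
may belong to several pockets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .constants import CAP_RESIDUE_NAMES, POCKET_ORDER, STANDARD_AA3, WATER_NAMES
from .errors import AnnotationError, NotAnnotatable
from .structure import (
    PairwiseAlignment,
    Residue,
    ResidueKey,
    Structure,
    align_sequences,
    alignment_column_map,
    superpose,
)

DEFAULT_PEPTIDE_LIKE = frozenset(STANDARD_AA3)


@dataclass
class CatalyticAnnotation:
    """Catalytic residues (chain, author number, free-text role)."""

    entries: list[tuple[str, int, str]] = field(default_factory=list)

    def keys(self) -> list[ResidueKey]:
        return [(c, n, "") for c, n, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class PeptideLigand:
    chain_id: str
    residues: list[Residue]

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)


@dataclass
class PocketAssignment:
    """Mapping of peptide residues to pockets plus pocket-forming residues."""

    peptide_chain_id: str
    peptide_map: list[tuple[ResidueKey, Optional[str]]]
    pocket_residues: dict[str, set[ResidueKey]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for _, label in self.peptide_map:
            if label is not None and label not in POCKET_ORDER:
                raise AnnotationError(f"unknown pocket label {label!r}")

    @property
    def cleavage_site_present(self) -> bool:
        labels = {lab for _, lab in self.peptide_map if lab}
        return "S1" in labels and "S1'" in labels

    @property
    def assigned_count(self) -> int:
        return sum(1 for _, lab in self.peptide_map if lab)

    def label_of(self, key: ResidueKey) -> Optional[str]:
        for k, lab in self.peptide_map:
            if k == key:
                return lab
        return None

    def binding_site(self) -> set[ResidueKey]:
        out: set[ResidueKey] = set()
        for members in self.pocket_residues.values():
            out |= members
        return out


@dataclass
class FilterDecision:
    keep: bool
    reason: str


# ---------------------------------------------------------------------------


def detect_peptide_ligands(
    structure: Structure,
    peptide_like_names: Iterable[str] = DEFAULT_PEPTIDE_LIKE,
    min_len: int = 3,
    max_len: int = 12,
) -> list[PeptideLigand]:
    """Candidate peptide ligands: chains of ``min_len``..``max_len`` residues
    with at least one peptide-like residue, excluding all-UNK chains."""
    names = set(peptide_like_names)
    if not names:
        raise AnnotationError("peptide_like_names must be non-empty")
    ligands = []
    for chain in structure.chains:
        residues = [r for r in chain.residues if r.res_name not in WATER_NAMES]
        if not (min_len <= len(residues) <= max_len):
            continue
        if all(r.res_name == "UNK" for r in residues):
            continue
        if not any(r.res_name in names for r in residues):
            continue
        ligands.append(PeptideLigand(chain.chain_id, residues))
    return ligands


def catalytic_site_occupancy(
    structure: Structure,
    catalytic: CatalyticAnnotation,
    ligand: PeptideLigand,
    asa_engine: Callable[[Structure], "object"],
    threshold: float = 0.0,
) -> bool:
    """True iff removing the ligand increases the summed accessible surface
    of the catalytic residues by strictly more than ``threshold`` (A^2)."""
    if len(catalytic) == 0:
        raise AnnotationError("structure lacks annotated catalytic residues")
    keys = catalytic.keys()
    for key in keys:
        if structure.residue(key) is None:
            raise AnnotationError(f"catalytic residue {key} not present in structure")
    with_ligand = asa_engine(structure)
    without_ligand = asa_engine(structure.without_chain(ligand.chain_id))
    delta = sum(
        without_ligand.residue_asa[key] - with_ligand.residue_asa[key] for key in keys
    )
    return bool(delta > threshold)


def _protease_residue_atoms(
    structure: Structure, peptide_chain_id: str
) -> tuple[np.ndarray, list[ResidueKey]]:
    coords, owners = [], []
    for cid, res in structure.iter_residues():
        if cid == peptide_chain_id or res.res_name in WATER_NAMES:
            continue
        for a in res.atoms:
            coords.append(a.coords)
            owners.append(res.key(cid))
    return np.asarray(coords).reshape(-1, 3), owners


def assign_pockets_from_reference(
    complex: Structure,
    ref_peptide_positions: Sequence[tuple[ResidueKey, str]],
    cutoff: float = 4.5,
) -> PocketAssignment:
    """Pocket assignment around a reference substrate.

    Every protease residue with >= 1 atom within ``cutoff`` of >= 1 atom of
    a given peptide residue joins that residue's pocket; a residue may join
    several pockets. Waters are excluded from the distance search.
    """
    if cutoff <= 0:
        raise AnnotationError("cutoff must be positive")
    if not ref_peptide_positions:
        raise AnnotationError("reference peptide positions are empty")
    peptide_chain_id = ref_peptide_positions[0][0][0]
    prot_coords, prot_owner = _protease_residue_atoms(complex, peptide_chain_id)
    tree = cKDTree(prot_coords) if len(prot_coords) else None
    peptide_map: list[tuple[ResidueKey, Optional[str]]] = []
    pockets: dict[str, set[ResidueKey]] = {}
    for key, label in ref_peptide_positions:
        res = complex.residue(key)
        if res is None:
            raise AnnotationError(f"reference peptide residue {key} missing")
        peptide_map.append((key, label))
        if label is None or tree is None:
            continue
        hits = tree.query_ball_point(res.coords(), r=cutoff)
        members = {prot_owner[i] for lst in hits for i in lst}
        if members:
            pockets.setdefault(label, set()).update(members)
    return PocketAssignment(peptide_chain_id, peptide_map, pockets)


def _primary_protease_chain(structure: Structure, peptide_chain_id: str):
    candidates = [
        c for c in structure.chains
        if c.chain_id != peptide_chain_id
        and sum(r.is_standard_aa for r in c.residues) >= 3
    ]
    if not candidates:
        raise AnnotationError("no protease chain found for superposition")
    return max(candidates, key=lambda c: sum(r.is_standard_aa for r in c.residues))


def _matched_ca_coords(
    ref_chain, tgt_chain, alignment: PairwiseAlignment
) -> tuple[np.ndarray, np.ndarray]:
    ref_res = ref_chain.residues
    tgt_res = tgt_chain.residues
    ref_pts, tgt_pts = [], []
    for qi, ti in alignment_column_map(alignment):
        if qi is None or ti is None:
            continue
        ra, ta = ref_res[qi].atom("CA"), tgt_res[ti].atom("CA")
        if ra is not None and ta is not None:
            ref_pts.append(ra.coords)
            tgt_pts.append(ta.coords)
    return np.asarray(ref_pts), np.asarray(tgt_pts)


def project_annotation(
    ref_complex: Structure,
    ref_assignment: PocketAssignment,
    target_complex: Structure,
    proj_cutoff: float = 2.0,
    target_peptide_chain: Optional[str] = None,
    identity_floor: float = 0.3,
    pocket_cutoff: float = 4.5,
) -> PocketAssignment:
    """Project the reference pocket annotation onto a homologous complex.

    The target protease is superposed on the reference via a
    sequence-guided matched-CA fit; each target peptide residue is then
    assigned the pocket of the reference residue with the most of its atoms
    within ``proj_cutoff``. Ties go to the N-terminal-most reference
    residue; zero-count residues stay unassigned. Pocket-forming residues
    are recomputed in the target frame with the ``pocket_cutoff`` rule.
    """
    if target_peptide_chain is None:
        ligands = detect_peptide_ligands(target_complex)
        if not ligands:
            raise AnnotationError("no peptide ligand found in target complex")
        target_peptide_chain = ligands[0].chain_id
    ref_prot = _primary_protease_chain(ref_complex, ref_assignment.peptide_chain_id)
    tgt_prot = _primary_protease_chain(target_complex, target_peptide_chain)
    alignment = align_sequences(ref_prot.sequence(), tgt_prot.sequence())
    if alignment.identity_fraction < identity_floor:
        raise AnnotationError(
            f"protease identity {alignment.identity_fraction:.2f} below floor "
            f"{identity_floor:.2f}; cannot superpose"
        )
    ref_pts, tgt_pts = _matched_ca_coords(ref_prot, tgt_prot, alignment)
    sup = superpose(ref_pts, tgt_pts)
    moved_target = target_complex.transform(sup.rotation, sup.translation)

    ref_residues = [
        (key, lab) for key, lab in ref_assignment.peptide_map if lab is not None
    ]
    ref_atom_sets = [
        ref_complex.residue(key).coords() for key, _ in ref_residues
    ]
    ref_trees = [cKDTree(pts) for pts in ref_atom_sets]

    tgt_chain = moved_target.chain(target_peptide_chain)
    peptide_map: list[tuple[ResidueKey, Optional[str]]] = []
    for res in tgt_chain.residues:
        if res.res_name in WATER_NAMES:
            continue
        pts = res.coords()
        counts = [
            int(np.sum(tree.query(pts, k=1)[0] <= proj_cutoff)) for tree in ref_trees
        ]
        best = int(np.argmax(counts)) if counts else 0
        label = ref_residues[best][1] if counts and counts[best] > 0 else None
        peptide_map.append((res.key(target_peptide_chain), label))

    projected = PocketAssignment(target_peptide_chain, peptide_map, {})
    labelled = [(k, lab) for k, lab in projected.peptide_map]
    recomputed = assign_pockets_from_reference(
        target_complex, labelled, cutoff=pocket_cutoff
    )
    projected.pocket_residues = recomputed.pocket_residues
    return projected


def _assigned_runs(labels: list[Optional[str]]) -> list[tuple[int, int]]:
    """Maximal stretches of assigned residues whose pocket labels advance
    by exactly one per residue; a label jump opens a new run."""
    runs, start = [], None
    prev_idx: Optional[int] = None
    for i, lab in enumerate(labels):
        if lab is None:
            if start is not None:
                runs.append((start, i - 1))
            start, prev_idx = None, None
            continue
        idx = POCKET_ORDER.index(lab)
        if start is None:
            start = i
        elif prev_idx is not None and idx != prev_idx + 1:
            runs.append((start, i - 1))
            start = i
        prev_idx = idx
    if start is not None:
        runs.append((start, len(labels) - 1))
    return runs


def close_annotation_gaps(assignment: PocketAssignment) -> PocketAssignment:
    """Re-label the shorter of two assigned runs so pocket labels are
    consecutive along the peptide; the longer run (ties: the N-terminal
    run) is taken to be correct and anchors the numbering."""
    labels = [lab for _, lab in assignment.peptide_map]
    runs = _assigned_runs(labels)
    if len(runs) < 2:
        return assignment
    # anchor = longest run; ties -> N-terminal-most
    anchor = max(runs, key=lambda r: (r[1] - r[0] + 1, -r[0]))
    anchor_pos = anchor[0]
    anchor_idx = POCKET_ORDER.index(labels[anchor_pos])
    new_labels: list[Optional[str]] = list(labels)
    for start, end in runs:
        for i in range(start, end + 1):
            idx = anchor_idx + (i - anchor_pos)
            new_labels[i] = POCKET_ORDER[idx] if 0 <= idx < len(POCKET_ORDER) else None
    peptide_map = [
        (key, new_labels[i]) for i, (key, _) in enumerate(assignment.peptide_map)
    ]
    return PocketAssignment(
        assignment.peptide_chain_id, peptide_map, dict(assignment.pocket_residues)
    )


def strip_capping_groups(
    ligand: PeptideLigand, cap_names: Iterable[str] = CAP_RESIDUE_NAMES
) -> PeptideLigand:
    """Remove capping residues (acetyl, diazomethane and similar blocking
    groups) added to substrates prior to crystallization."""
    caps = set(cap_names)
    kept = [r for r in ligand.residues if r.res_name not in caps]
    return PeptideLigand(ligand.chain_id, kept)


def filter_assignment(
    assignment: PocketAssignment, min_residues: int = 3
) -> FilterDecision:
    """Discard substrates with fewer than ``min_residues`` residues assigned
    to binding pockets."""
    n = assignment.assigned_count
    if n < min_residues:
        return FilterDecision(False, f"only {n} residues in binding pockets (< {min_residues})")
    return FilterDecision(True, f"{n} residues in binding pockets")


def infer_catalytic_by_homology(
    query_chain_seq: str,
    annotated_library: Sequence[tuple[str, CatalyticAnnotation]],
    identity_floor: float = 0.5,
    query_chain_id: str = "A",
) -> CatalyticAnnotation:
    """Transfer catalytic residues from the first library homologue whose
    global alignment exceeds ``identity_floor`` sequence identity.

    Library annotations use 1-based positions in the library sequence;
    transferred entries use 1-based positions in the query. Catalytic
    positions aligned to query gaps are dropped with a warning.
    """
    if not annotated_library:
        raise AnnotationError("annotated library is empty")
    for seq, annot in annotated_library:
        alignment = align_sequences(query_chain_seq, seq)
        if alignment.identity_fraction <= identity_floor:
            continue
        target_to_query: dict[int, int] = {}
        for qi, ti in alignment_column_map(alignment):
            if ti is not None and qi is not None:
                target_to_query[ti] = qi
        entries = []
        for _, pos, role in annot.entries:
            qpos = target_to_query.get(pos - 1)
            if qpos is None:
                warnings.warn(
                    f"catalytic position {pos} aligns to a query gap; dropped",
                    stacklevel=2,
                )
                continue
            entries.append((query_chain_id, qpos + 1, role))
        return CatalyticAnnotation(entries)
    raise NotAnnotatable(
        f"no library entry exceeds {identity_floor:.0%} sequence identity"
    )
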
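"""Side-chain geometry utilities shared by the mutation engine and the
Monte Carlo side-chain mover: ideal residue templates (from the bundled
chemical-component definitions in biotite), intra-residue bond graphs,
and chi-angle measurement / setting by rigid rotation of the distal part.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .constants import CHI_ATOMS, ROTAMER_CHI
from .errors import SubsitesError
from .geometry import dihedral, rotate_about_line
from .structure import Atom, Residue

# heavy-atom bond distance ceilings for graph inference
_BOND_CUTOFF = 1.9
_BOND_CUTOFF_H = 1.3


@lru_cache(maxsize=32)
def ideal_residue_template(res_name: str) -> tuple[tuple[str, str], ...]:
    """Ideal heavy-atom geometry for a standard residue: tuples of
    (atom_name, element) paired with coordinates via
    :func:`ideal_residue_coords`."""
    import biotite.structure.info as info

    arr = info.residue(res_name)
    if arr is None:
        raise SubsitesError(f"no ideal template for residue {res_name!r}")
    names = []
    for name, elem in zip(arr.atom_name, arr.element):
        if elem.upper() == "H":
            continue
        names.append((str(name), str(elem)))
    return tuple(names)


@lru_cache(maxsize=32)
def ideal_residue_coords(res_name: str) -> np.ndarray:
    import biotite.structure.info as info

    arr = info.residue(res_name)
    mask = np.array([e.upper() != "H" for e in arr.element])
    return np.asarray(arr.coord[mask], dtype=float)


def residue_bond_graph(residue: Residue) -> dict[str, set[str]]:
    """Distance-inferred covalent bonds among the residue's atoms."""
    adj: dict[str, set[str]] = {a.name: set() for a in residue.atoms}
    atoms = residue.atoms
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            a, b = atoms[i], atoms[j]
            cutoff = (
                _BOND_CUTOFF_H
                if (a.is_hydrogen or b.is_hydrogen)
                else (2.1 if "S" in (a.element.upper(), b.element.upper()) else _BOND_CUTOFF)
            )
            if np.linalg.norm(a.coords - b.coords) <= cutoff:
                adj[a.name].add(b.name)
                adj[b.name].add(a.name)
    return adj


def n_chi(res_name: str) -> int:
    return len(CHI_ATOMS.get(res_name, ()))


def measure_chi(residue: Residue, chi_index: int) -> float:
    """Chi angle (degrees) number ``chi_index`` (0-based)."""
    quad = CHI_ATOMS[residue.res_name][chi_index]
    pts = []
    for name in quad:
        a = residue.atom(name)
        if a is None:
            raise SubsitesError(
                f"{residue.res_name} {residue.res_seq}: missing atom {name} for chi"
            )
        pts.append(a.coords)
    return dihedral(*pts)


def _moving_atoms(residue: Residue, axis_a: str, axis_b: str) -> list[str]:
    """Atom names distal to the ``axis_a``-``axis_b`` bond (excluding the
    axis atoms themselves), found on the bond graph with that edge cut.

    Backbone atoms never move: chi rotations are side-chain internal, and
    the distance-inferred graph may contain spurious short contacts that
    would otherwise leak the traversal into the backbone.
    """
    from .constants import BACKBONE_NAMES

    adj = {k: set(v) for k, v in residue_bond_graph(residue).items()}
    adj[axis_a].discard(axis_b)
    adj[axis_b].discard(axis_a)
    seen = {axis_b}
    stack = [axis_b]
    while stack:
        cur = stack.pop()
        for nxt in adj.get(cur, ()):
            if nxt not in seen and nxt not in BACKBONE_NAMES:
                seen.add(nxt)
                stack.append(nxt)
    seen.discard(axis_b)
    seen.discard(axis_a)
    return sorted(seen)


def rotate_chi(residue: Residue, chi_index: int, delta_deg: float) -> None:
    """Rotate chi ``chi_index`` by ``delta_deg`` in place (backbone fixed)."""
    quad = CHI_ATOMS[residue.res_name][chi_index]
    axis_a, axis_b = quad[1], quad[2]
    pa, pb = residue.atom(axis_a), residue.atom(axis_b)
    if pa is None or pb is None:
        raise SubsitesError("chi axis atoms missing")
    moving = _moving_atoms(residue, axis_a, axis_b)
    axis = pb.coords - pa.coords
    for name in moving:
        atom = residue.atom(name)
        if atom is not None:
            atom.coords = rotate_about_line(
                atom.coords[None, :], pa.coords, axis, delta_deg
            )[0]


def set_chi(residue: Residue, chi_index: int, target_deg: float) -> None:
    current = measure_chi(residue, chi_index)
    rotate_chi(residue, chi_index, target_deg - current)


def apply_rotamer(residue: Residue, chi_values=None) -> None:
    """Set all chi angles; defaults to the built-in most-common rotamer."""
    if residue.res_name == "PRO":
        return  # ring geometry kept from the template
    values = chi_values or ROTAMER_CHI.get(residue.res_name, ())
    for k, v in enumerate(values):
        if k < n_chi(residue.res_name):
            set_chi(residue, k, v)


def build_sidechain(
    backbone: dict[str, np.ndarray], res_name: str
) -> list[Atom]:
    """Side-chain heavy atoms (incl. CB) for ``res_name`` placed by
    superposing the ideal template's N/CA/C frame onto ``backbone``."""
    from .geometry import kabsch

    names = ideal_residue_template(res_name)
    coords = ideal_residue_coords(res_name)
    index = {n: i for i, (n, _) in enumerate(names)}
    for required in ("N", "CA", "C"):
        if required not in index:
            raise SubsitesError(f"template {res_name} lacks backbone atom {required}")
    ref = np.asarray([backbone["N"], backbone["CA"], backbone["C"]])
    mov = coords[[index["N"], index["CA"], index["C"]]]
    R, t, _ = kabsch(ref, mov)
    placed = coords @ R.T + t
    out = []
    for (name, elem), xyz in zip(names, placed):
        if name in ("N", "CA", "C", "O", "OXT"):
            continue
        out.append(Atom(name, elem, xyz))
    return out
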
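"""Idealised side-chain placement for in-silico mutagenesis.

Each residue type's side chain is taken from the Chemical Component
Dictionary ideal geometry bundled with biotite, rigidly mapped onto the
host backbone by superposing the template (N, CA, C) triad, and then
relaxed by a discrete chi1/chi2 rotamer search that minimises the
heavy-atom clash count. No continuous minimisation is performed, so
placement is fully deterministic.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree
import biotite.structure.info as bstinfo

from .geometry import dihedral, rotate_about_axis, superpose
from .structure import Atom, Residue, vdw_radius

# chi1/chi2 atom quadruples (standard definitions); residues without an
# entry have no rotatable chi or a rigid ring (PRO).
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# most common rotamer first; search is best-of-set on clash count with
# deterministic first-wins tie-breaking
CHI1_SET = (-60.0, 180.0, 60.0)
CHI2_SET = (180.0, -60.0, 60.0)

CLASH_OVERLAP = 0.75  # clash when d < 0.75 * (vdw_i + vdw_j)


@lru_cache(maxsize=32)
def _template(res_name: str) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray, dict]:
    """Heavy-atom CCD template: atom names, elements, ideal coordinates
    and a bond adjacency map (hydrogens and OXT removed)."""
    arr = bstinfo.residue(res_name)
    if arr is None:
        raise ValueError(f"no template for residue {res_name!r}")
    keep = (~np.isin(arr.element, ("H", "D"))) & (arr.atom_name != "OXT")
    idx = np.where(keep)[0]
    names = tuple(str(n) for n in arr.atom_name[idx])
    elements = tuple(str(e) for e in arr.element[idx])
    coords = np.array(arr.coord[idx], dtype=float)
    pos = {orig: new for new, orig in enumerate(idx)}
    adj: dict[int, set[int]] = {i: set() for i in range(len(idx))}
    bonds, _ = arr.bonds.get_all_bonds()
    for orig_i in idx:
        for orig_j in bonds[orig_i]:
            if orig_j >= 0 and orig_j in pos:
                adj[pos[orig_i]].add(pos[orig_j])
                adj[pos[orig_j]].add(pos[orig_i])
    return names, elements, coords, adj


def _downstream(adj: dict, start: int, blocked: int) -> list[int]:
    """Atoms on ``start``'s side when the ``blocked``-``start`` bond is cut."""
    seen = {blocked, start}
    stack = [start]
    out = [start]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
                out.append(nb)
    return out


def sidechain_atom_names(res_name: str) -> list[str]:
    names, _, _, _ = _template(res_name)
    return [n for n in names if n not in ("N", "CA", "C", "O")]


def build_residue(res_name: str, n_xyz: np.ndarray, ca_xyz: np.ndarray,
                  c_xyz: np.ndarray, o_xyz: np.ndarray,
                  number: int, icode: str = "",
                  environment: np.ndarray | None = None,
                  env_vdw: np.ndarray | None = None,
                  ) -> Residue:
    """Build a full residue on a fixed backbone.

    The backbone heavy atoms keep the supplied coordinates exactly; the
    side chain comes from the ideal template, oriented by (N, CA, C)
    superposition, then chi1/chi2 are searched over a fixed rotamer set
    for the placement with the fewest clashes against ``environment``
    (an (m, 3) array of all other heavy atoms, with ``env_vdw`` radii).
    """
    names, elements, tmpl, adj = _template(res_name)
    name_idx = {n: i for i, n in enumerate(names)}
    triad = np.array([tmpl[name_idx["N"]], tmpl[name_idx["CA"]], tmpl[name_idx["C"]]])
    target = np.array([n_xyz, ca_xyz, c_xyz])
    coords = superpose(triad, target, apply_to=tmpl)
    coords[name_idx["N"]] = n_xyz
    coords[name_idx["CA"]] = ca_xyz
    coords[name_idx["C"]] = c_xyz
    coords[name_idx["O"]] = o_xyz

    chis = CHI_ATOMS.get(res_name, [])
    if chis and environment is not None and environment.shape[0]:
        coords = _rotamer_search(res_name, coords, name_idx, adj, chis,
                                 elements, environment, env_vdw)
    elif chis:
        coords = _set_chis(coords, name_idx, adj, chis,
                           [CHI1_SET[0]] + ([CHI2_SET[0]] if len(chis) > 1 else []))

    atoms = [Atom(nm, el, coords[i].copy(), vdw_radius(el))
             for i, (nm, el) in enumerate(zip(names, elements))]
    return Residue(name=res_name, number=number, icode=icode, atoms=atoms)


def _set_chis(coords: np.ndarray, name_idx: dict, adj: dict,
              chis: list, targets: list[float]) -> np.ndarray:
    coords = coords.copy()
    for (a, b, c, d), tgt in zip(chis, targets):
        ia, ib, ic, id_ = (name_idx[x] for x in (a, b, c, d))
        current = dihedral(coords[ia], coords[ib], coords[ic], coords[id_])
        moving = _downstream(adj, ic, ib)
        moving = [m for m in moving if m != ic]
        if not moving:
            continue
        coords[moving] = rotate_about_axis(
            coords[moving], coords[ib], coords[ic] - coords[ib], tgt - current)
    return coords


def clash_count(points: np.ndarray, point_vdw: np.ndarray,
                environment: np.ndarray, env_vdw: np.ndarray) -> int:
    """Number of (point, environment) pairs closer than the clash limit."""
    if environment.shape[0] == 0 or points.shape[0] == 0:
        return 0
    tree = cKDTree(environment)
    limit = CLASH_OVERLAP * (point_vdw.max() + env_vdw.max())
    total = 0
    for p, rv in zip(points, point_vdw):
        for j in tree.query_ball_point(p, limit):
            if np.linalg.norm(p - environment[j]) < CLASH_OVERLAP * (rv + env_vdw[j]):
                total += 1
    return total


def set_residue_chis(residue, chi_targets: list[float]) -> None:
    """Rotate an existing residue's side chain to the given chi angles
    (degrees), in place. Uses the template bond graph to decide which
    atoms move with each rotation."""
    res_name = residue.name
    chis = CHI_ATOMS.get(res_name, [])[:len(chi_targets)]
    if not chis:
        return
    names, _, _, adj = _template(res_name)
    name_idx = {n: i for i, n in enumerate(names)}
    atom_by_name = {a.name: a for a in residue.atoms}
    coords = np.array([atom_by_name[n].coord if n in atom_by_name
                       else np.zeros(3) for n in names])
    present = [n in atom_by_name for n in names]
    for (a, b, c, d), tgt in zip(chis, chi_targets):
        if not all(x in atom_by_name for x in (a, b, c, d)):
            return
        ia, ib, ic, id_ = (name_idx[x] for x in (a, b, c, d))
        current = dihedral(coords[ia], coords[ib], coords[ic], coords[id_])
        moving = [m for m in _downstream(adj, ic, ib) if m != ic and present[m]]
        if not moving:
            continue
        coords[moving] = rotate_about_axis(
            coords[moving], coords[ib], coords[ic] - coords[ib], tgt - current)
    for n, i in name_idx.items():
        if n in atom_by_name:
            atom_by_name[n].coord = coords[i].copy()


def residue_chis(residue) -> list[float]:
    """Current chi angles (degrees) of a residue's side chain."""
    chis = CHI_ATOMS.get(residue.name, [])
    out = []
    for quad in chis:
        atoms = [residue.atom(n) for n in quad]
        if any(a is None for a in atoms):
            break
        out.append(dihedral(*(a.coord for a in atoms)))
    return out


def _rotamer_search(res_name: str, coords: np.ndarray, name_idx: dict, adj: dict,
                    chis: list, elements, environment: np.ndarray,
                    env_vdw: np.ndarray | None) -> np.ndarray:
    if env_vdw is None:
        env_vdw = np.full(environment.shape[0], 1.7)
    side_idx = [name_idx[n] for n in sidechain_atom_names(res_name)]
    side_vdw = np.array([vdw_radius(elements[i]) for i in side_idx])
    grids: list[list[float]]
    if len(chis) == 1:
        grids = [[c1] for c1 in CHI1_SET]
    else:
        grids = [[c1, c2] for c1 in CHI1_SET for c2 in CHI2_SET]
    best = None
    best_score = None
    for targets in grids:
        cand = _set_chis(coords, name_idx, adj, chis, targets)
        score = clash_count(cand[side_idx], side_vdw, environment, env_vdw)
        if best_score is None or score < best_score:
            best, best_score = cand, score
        if best_score == 0:
            break
    return best
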
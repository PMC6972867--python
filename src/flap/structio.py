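"""Structure I/O and per-structure annotation.

Reading goes through biotite's PDB parser; the hierarchy is then
rebuilt heavy-atom-only (hydrogens and water stripped, highest-occupancy
ALTLOC conformer kept) with van der Waals radii from a fixed element
table. Secondary structure and SASA are re-exported here so this module
is the single entry point for structure preparation.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .sasa import compute_sasa  # noqa: F401  (module surface)
from .secstruct import assign_secondary_structure  # noqa: F401
from .structure import (
    SASAProfile,
    STANDARD_AA,
    Structure,
    Chain,
    Residue,
    Atom,
    WATER_NAMES,
    vdw_radius,
)

DEFAULT_SG_CUTOFF = 2.5  # A, S-S bonded distance


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted as a structure."""


def _atom_array_to_structure(arr: bst.AtomArray, struct_id: str) -> Structure:
    keep = (~np.isin(arr.element, ("H", "D"))) & (~np.isin(arr.res_name, tuple(WATER_NAMES)))
    arr = arr[keep]
    if arr.array_length() == 0:
        raise FormatError("no standard residues: file contains no heavy protein atoms")

    chains: list[Chain] = []
    chain_map: dict[str, Chain] = {}
    res_map: dict[tuple[str, int, str], Residue] = {}
    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i])
        if cid not in chain_map:
            chain_map[cid] = Chain(id=cid)
            chains.append(chain_map[cid])
        icode = str(arr.ins_code[i]) if hasattr(arr, "ins_code") else ""
        rkey = (cid, int(arr.res_id[i]), icode)
        if rkey not in res_map:
            res = Residue(name=str(arr.res_name[i]), number=int(arr.res_id[i]), icode=icode)
            res_map[rkey] = res
            chain_map[cid].residues.append(res)
        el = str(arr.element[i])
        res_map[rkey].atoms.append(
            Atom(name=str(arr.atom_name[i]), element=el,
                 coord=np.array(arr.coord[i], dtype=float), vdw=vdw_radius(el))
        )

    kept_chains = []
    for c in chains:
        if not any(r.is_standard for r in c.residues):
            warnings.warn(f"chain {c.id}: no standard residues, skipped")
            continue
        kept_chains.append(c)
    if not kept_chains:
        raise FormatError("no standard residues in any chain")
    s = Structure(id=struct_id, chains=kept_chains)
    s.validate()
    return s


def read_structure(path: str | Path, format: str = "pdb", model: int = 1) -> Structure:
    """Read a single-model structure from a PDB file.

    ALTLOC groups are resolved to the highest-occupancy conformer,
    hydrogens are dropped and water HETATM records stripped.
    """
    if format != "pdb":
        raise FormatError(f"unsupported format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=model, altloc="occupancy",
                                extra_fields=["occupancy"])
    except Exception as exc:  # biotite raises several parse error types
        raise FormatError(f"cannot parse {path.name} as PDB: {exc}") from exc
    return _atom_array_to_structure(arr, struct_id=path.stem)


def read_ensemble_coords(path: str | Path) -> tuple[Structure, np.ndarray]:
    """Read a multi-model PDB; returns the first model as the reference
    Structure plus an (F, n_atoms, 3) coordinate stack for all models."""
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="occupancy",
                                  extra_fields=["occupancy"])
    except Exception as exc:
        raise FormatError(f"cannot parse {path.name} as PDB: {exc}") from exc
    keep = (~np.isin(stack.element, ("H", "D"))) & \
           (~np.isin(stack.res_name, tuple(WATER_NAMES)))
    stack = stack[..., keep]
    first = stack[0]
    ref = _atom_array_to_structure(first, struct_id=path.stem)
    if stack.coord.shape[1] != ref.n_atoms:
        raise FormatError("ensemble frames and reference atom lists differ")
    return ref, np.array(stack.coord, dtype=float)


def write_structure(s: Structure, path: str | Path,
                    remarks: list[str] | None = None) -> None:
    """Write a single-model PDB file."""
    _write_pdb(path, [s.coords()], s, remarks=remarks)


def write_ensemble(reference: Structure, frames: np.ndarray, path: str | Path,
                   remarks: list[str] | None = None) -> None:
    """Write a multi-model PDB from a reference structure and an
    (F, n_atoms, 3) coordinate stack."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[1] != reference.n_atoms:
        raise ValueError("frame stack must be (F, n_atoms, 3)")
    _write_pdb(path, list(frames), reference, remarks=remarks)


def _write_pdb(path: str | Path, frames: list[np.ndarray], template: Structure,
               remarks: list[str] | None) -> None:
    arrays = []
    for xyz in frames:
        arr = bst.AtomArray(template.n_atoms)
        i = 0
        for c, r, a in template.iter_atoms():
            arr.chain_id[i] = c.id
            arr.res_id[i] = r.number
            arr.ins_code[i] = r.icode
            arr.res_name[i] = r.name
            arr.atom_name[i] = a.name
            arr.element[i] = a.element
            arr.hetero[i] = r.name not in STANDARD_AA
            i += 1
        arr.coord = np.asarray(xyz, dtype=np.float32)
        arrays.append(arr)
    stack = bst.stack(arrays) if len(arrays) > 1 else arrays[0]
    pdb = PDBFile()
    pdb.set_structure(stack)
    if remarks:
        remark_lines = [f"REMARK 250 {r}"[:80] for r in remarks]
        pdb.lines = remark_lines + pdb.lines
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# disulfides
# ---------------------------------------------------------------------------

def find_disulfides(s: Structure, sg_cutoff: float = DEFAULT_SG_CUTOFF
                    ) -> list[tuple[tuple[str, int, str], tuple[str, int, str]]]:
    """Cys SG-SG pairs within ``sg_cutoff`` A, greedily matched
    nearest-first so each cysteine appears in at most one pair."""
    if sg_cutoff <= 0:
        raise ValueError("sg_cutoff must be positive")
    sg = []
    for c, r in s.iter_residues():
        if r.name == "CYS":
            a = r.atom("SG")
            if a is not None:
                sg.append(((c.id, r.number, r.icode), a.coord))
    candidates = []
    for i in range(len(sg)):
        for j in range(i + 1, len(sg)):
            d = float(np.linalg.norm(sg[i][1] - sg[j][1]))
            if d <= sg_cutoff:
                candidates.append((d, sg[i][0], sg[j][0]))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used: set = set()
    pairs = []
    for _, ki, kj in candidates:
        if ki in used or kj in used:
            continue
        pairs.append((ki, kj))
        used.update((ki, kj))
    return pairs


def disulfide_map(pairs) -> dict:
    """Symmetric residue->partner map from a disulfide pair list."""
    out = {}
    for a, b in pairs:
        out[a] = b
        out[b] = a
    return out


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def sasa_to_tsv(profile: SASAProfile, s: Structure, path: str | Path) -> None:
    """Write per-residue SASA as TSV (chain, resnum, resname, sasa_A2)."""
    import pandas as pd

    rows = []
    for c, r in s.iter_residues():
        key = (c.id, r.number, r.icode)
        if key in profile.values:
            rows.append({"chain": c.id, "resnum": r.number, "resname": r.name,
                         "sasa_A2": round(profile.values[key], 3)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
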
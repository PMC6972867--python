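"""Hierarchical heavy-atom structure model (chains -> residues -> atoms).

All coordinates are in Angstrom. Hydrogens are never stored: every
downstream operation (fluctuation, SASA, RMSD, energies) is defined over
heavy atoms only, so they are dropped at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

# Fixed element table used for SASA and clash detection; hydrogens are
# excluded from the model entirely.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

AA3_TO_1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3: dict[str, str] = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = frozenset(AA3_TO_1)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), float64
    vdw: float

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    name: str          # 3-letter code
    number: int        # author numbering, preserved end-to-end
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_AA and self.atom("CA") is not None

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    def index_of(self, number: int, icode: str = "") -> int:
        for i, r in enumerate(self.residues):
            if r.number == number and r.icode == icode:
                return i
        raise KeyError(f"residue {number}{icode} not in chain {self.id}")

    def standard_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_standard]


@dataclass
class Structure:
    id: str
    chains: list[Chain] = field(default_factory=list)

    # ---- traversal -------------------------------------------------

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id!r}")

    def iter_residues(self) -> Iterator[tuple[Chain, Residue]]:
        for c in self.chains:
            for r in c.residues:
                yield c, r

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c, r in self.iter_residues():
            for a in r.atoms:
                yield c, r, a

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    # ---- flat numeric views ---------------------------------------

    def coords(self) -> np.ndarray:
        """All heavy-atom coordinates, (n_atoms, 3), in traversal order."""
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.coord for _, _, a in self.iter_atoms()], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for (_, _, a), row in zip(self.iter_atoms(), xyz):
            a.coord = row.copy()

    def vdw(self) -> np.ndarray:
        return np.array([a.vdw for _, _, a in self.iter_atoms()], dtype=float)

    def atom_residue_keys(self) -> list[tuple[str, int, str]]:
        """Per-atom (chain id, residue number, icode), aligned with coords()."""
        return [(c.id, r.number, r.icode) for c, r, _ in self.iter_atoms()]

    def residue_atom_indices(self) -> dict[tuple[str, int, str], np.ndarray]:
        """Map (chain, resnum, icode) -> flat atom indices into coords()."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, key in enumerate(self.atom_residue_keys()):
            out.setdefault(key, []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def copy(self) -> "Structure":
        return Structure(
            id=self.id,
            chains=[
                Chain(
                    id=c.id,
                    residues=[
                        Residue(
                            name=r.name,
                            number=r.number,
                            icode=r.icode,
                            atoms=[Atom(a.name, a.element, a.coord.copy(), a.vdw) for a in r.atoms],
                        )
                        for r in c.residues
                    ],
                )
                for c in self.chains
            ],
        )

    def validate(self) -> None:
        """Check model invariants; raise ValueError on violation."""
        for c in self.chains:
            keys = [r.key for r in c.residues]
            for k1, k2 in zip(keys, keys[1:]):
                if not (k1 < k2):
                    raise ValueError(
                        f"chain {c.id}: residues not strictly ordered at {k1} -> {k2}"
                    )
        coords = self.coords()
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")


@dataclass
class SSAnnotation:
    """Per-residue 3-state secondary structure plus disulfide pairing.

    ``states`` holds one of H (helix), E (strand) or C (coil) for every
    residue of the structure in traversal order; ``disulfides`` maps a
    residue key (chain, number, icode) to its bonded Cys partner.
    """

    states: list[str]
    residue_keys: list[tuple[str, int, str]]
    disulfides: dict[tuple[str, int, str], tuple[str, int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.states) != len(self.residue_keys):
            raise ValueError("state list length must equal residue count")
        bad = set(self.states) - {"H", "E", "C"}
        if bad:
            raise ValueError(f"invalid secondary-structure states: {bad}")
        for a, b in self.disulfides.items():
            if self.disulfides.get(b) != a:
                raise ValueError("disulfide map must be symmetric")

    def state_of(self, key: tuple[str, int, str]) -> str:
        return self.states[self.residue_keys.index(key)]

    def chain_states(self, chain_id: str) -> str:
        return "".join(
            s for s, k in zip(self.states, self.residue_keys) if k[0] == chain_id
        )

    def is_disulfide_cys(self, key: tuple[str, int, str]) -> bool:
        return key in self.disulfides


@dataclass
class SASAProfile:
    """Per-residue solvent-accessible surface area in A^2."""

    values: dict[tuple[str, int, str], float]
    probe_radius: float
    n_points: int

    def __post_init__(self) -> None:
        if any(v < -1e-9 for v in self.values.values()):
            raise ValueError("SASA values must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.values.values()))


@dataclass(frozen=True)
class MDProtocolSpec:
    """Provenance record of the MD protocol the thresholds were derived
    under; the package never runs MD itself."""

    timestep_fs: float = 2.0
    temperature_K: float = 300.0
    production_ns: float = 10.0
    analysis_window_ns: float = 5.0
    nonbonded_cutoff_A: float = 999.9

    def __post_init__(self) -> None:
        vals = (self.timestep_fs, self.temperature_K, self.production_ns,
                self.analysis_window_ns, self.nonbonded_cutoff_A)
        if any(v <= 0 for v in vals):
            raise ValueError("all protocol constants must be positive")
        if self.analysis_window_ns > self.production_ns:
            raise ValueError("analysis window cannot exceed production length")
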
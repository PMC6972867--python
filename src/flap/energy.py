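"""Simplified physics score for protein-protein interfaces.

Pairwise Lennard-Jones (element-level parameters) plus screened Coulomb
electrostatics with a distance-dependent dielectric eps(r) = 4r, and an
optional per-residue burial solvation term. This is a deliberately
coarse, deterministic score for *ranking* binding-energy losses in
alanine-hexapeptide scans; its absolute values are in score units, not
force-field kcal/mol.

Charge model (version 1): ionizable side-chain termini carry +/-1
distributed over their terminal heavy atoms, the backbone amide carries
a +/-0.4 dipole (N negative is approximated by the carbonyl dipole
C +0.4 / O -0.4 and N -0.4 / CA +0.4); all other atoms are neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import STANDARD_AA, Structure

COULOMB_CONST = 332.0          # kcal/mol * A * e^-2
CHARGE_MODEL_VERSION = 1

# element-level LJ parameters: sigma (A), epsilon (score units)
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "C": (3.40, 0.086),
    "N": (3.25, 0.170),
    "O": (2.96, 0.210),
    "S": (3.56, 0.250),
}
LJ_DEFAULT = (3.40, 0.086)

# backbone dipole charges, every standard residue
BACKBONE_CHARGES: dict[str, float] = {"N": -0.40, "CA": 0.40, "C": 0.40, "O": -0.40}

# ionizable side-chain termini, +/-1 per charged group
SIDECHAIN_CHARGES: dict[tuple[str, str], float] = {
    ("ASP", "OD1"): -0.5, ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5, ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5, ("ARG", "NH2"): 0.5,
}


@dataclass
class EnergyConfig:
    contact_cutoff: float = 4.5     # A, interface contact definition
    pair_cutoff: float = 12.0       # A, nonbonded summation cutoff
    dielectric_scale: float = 4.0   # eps(r) = dielectric_scale * r
    clash_distance: float = 0.5     # A, hard error below this across chains
    relax: str = "none"             # "none" | "steepest_descent"
    relax_steps: int = 200
    relax_step_size: float = 0.01   # A per step along -grad direction
    solvation: bool = False
    solvation_sigma: float = 0.005  # score units per A^2 buried

    def __post_init__(self) -> None:
        if self.relax not in ("none", "steepest_descent"):
            raise ValueError(f"unknown relaxation mode {self.relax!r}")


def atom_charges(s: Structure) -> np.ndarray:
    """Coarse per-atom partial charges, aligned with ``s.coords()``."""
    q = np.zeros(s.n_atoms)
    for i, (c, r, a) in enumerate(s.iter_atoms()):
        if r.name not in STANDARD_AA:
            continue
        if a.name in BACKBONE_CHARGES:
            q[i] = BACKBONE_CHARGES[a.name]
        else:
            q[i] = SIDECHAIN_CHARGES.get((r.name, a.name), 0.0)
    return q


def _lj_arrays(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    sig = np.empty(s.n_atoms)
    eps = np.empty(s.n_atoms)
    for i, (_, _, a) in enumerate(s.iter_atoms()):
        p = LJ_PARAMS.get(a.element.upper(), LJ_DEFAULT)
        sig[i], eps[i] = p
    return sig, eps


def lj_pair_energy(r: float, sigma: float, epsilon: float) -> float:
    """4 eps [(sigma/r)^12 - (sigma/r)^6]; minimum -eps at r = 2^(1/6) sigma."""
    sr6 = (sigma / r) ** 6
    return 4.0 * epsilon * (sr6 * sr6 - sr6)


def pairwise_energy(s: Structure, config: EnergyConfig | None = None,
                    group_a: np.ndarray | None = None,
                    group_b: np.ndarray | None = None) -> float:
    """Nonbonded energy of a structure (score units).

    Sums LJ + screened Coulomb over atom pairs within ``pair_cutoff``,
    excluding pairs inside one residue or between sequence-adjacent
    residues (their geometry is covalent, not nonbonded). With
    ``group_a``/``group_b`` (flat atom index arrays) only cross-group
    pairs are summed.
    """
    config = config or EnergyConfig()
    coords = s.coords()
    q = atom_charges(s)
    sig, eps = _lj_arrays(s)
    keys = s.atom_residue_keys()
    order: dict[tuple, int] = {}
    for k in keys:
        order.setdefault(k, len(order))
    res_ord = np.array([order[k] for k in keys])
    chain_of = np.array([hash(k[0]) for k in keys])

    in_a = np.zeros(len(coords), dtype=bool)
    in_b = np.zeros(len(coords), dtype=bool)
    if group_a is not None:
        in_a[np.asarray(group_a, int)] = True
    if group_b is not None:
        in_b[np.asarray(group_b, int)] = True
    cross_only = group_a is not None and group_b is not None

    tree = cKDTree(coords)
    total = 0.0
    for i, j in tree.query_pairs(config.pair_cutoff):
        if cross_only and not ((in_a[i] and in_b[j]) or (in_a[j] and in_b[i])):
            continue
        if chain_of[i] == chain_of[j] and abs(res_ord[i] - res_ord[j]) <= 1:
            continue
        r = float(np.linalg.norm(coords[i] - coords[j]))
        sigma = 0.5 * (sig[i] + sig[j])
        epsilon = float(np.sqrt(eps[i] * eps[j]))
        e = lj_pair_energy(r, sigma, epsilon)
        if q[i] and q[j]:
            e += COULOMB_CONST * q[i] * q[j] / (config.dielectric_scale * r * r)
        total += e
    return total


def _nonbonded_gradient(coords: np.ndarray, q: np.ndarray, sig: np.ndarray,
                        eps: np.ndarray, res_ord: np.ndarray,
                        chain_of: np.ndarray, config: EnergyConfig) -> np.ndarray:
    grad = np.zeros_like(coords)
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(config.pair_cutoff):
        if chain_of[i] == chain_of[j] and abs(res_ord[i] - res_ord[j]) <= 1:
            continue
        dvec = coords[i] - coords[j]
        r = float(np.linalg.norm(dvec))
        if r < 1e-6:
            continue
        sigma = 0.5 * (sig[i] + sig[j])
        epsilon = float(np.sqrt(eps[i] * eps[j]))
        sr6 = (sigma / r) ** 6
        de = 4.0 * epsilon * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
        if q[i] and q[j]:
            de += -2.0 * COULOMB_CONST * q[i] * q[j] / (config.dielectric_scale * r ** 3)
        g = de * dvec / r
        grad[i] += g
        grad[j] -= g
    return grad


def relax_structure(s: Structure, config: EnergyConfig) -> Structure:
    """Fixed-step steepest-descent relaxation of the nonbonded energy
    (iteration-capped, deterministic); returns a relaxed copy."""
    if config.relax == "none":
        return s
    out = s.copy()
    coords = out.coords()
    q = atom_charges(out)
    sig, eps = _lj_arrays(out)
    keys = out.atom_residue_keys()
    order: dict[tuple, int] = {}
    for k in keys:
        order.setdefault(k, len(order))
    res_ord = np.array([order[k] for k in keys])
    chain_of = np.array([hash(k[0]) for k in keys])
    for _ in range(config.relax_steps):
        grad = _nonbonded_gradient(coords, q, sig, eps, res_ord, chain_of, config)
        norm = np.linalg.norm(grad, axis=1).max()
        if norm < 1e-6:
            break
        coords = coords - config.relax_step_size * grad / max(norm, 1.0)
    out.set_coords(coords)
    return out
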
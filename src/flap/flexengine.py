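"""Per-atom fluctuation (RMSF) estimation.

Two interchangeable backends produce a :class:`FluctuationProfile`:

* ``ensemble`` — textbook RMSF over a conformational ensemble (e.g. a
  multi-model PDB standing in for an MD trajectory), after least-squares
  superposition of every frame onto the reference.
* ``enm`` — a Cα Gaussian network model. Residue mean-square
  fluctuations are proportional to the diagonal of the Kirchhoff-matrix
  pseudoinverse; an explicit calibration constant maps the dimensionless
  mode amplitudes onto the Angstrom scale on which the selection
  thresholds (1.5 / 1.0 A) are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import pinvh
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .geometry import superpose
from .structure import Structure

DEFAULT_ENM_CUTOFF = 7.5          # A, Cα contact cutoff
DEFAULT_CALIBRATION_TARGET = 0.8  # A, median Cα RMSF after auto-calibration


@dataclass
class Ensemble:
    """A reference structure plus F congruent coordinate frames."""

    reference: Structure
    frames: np.ndarray            # (F, n_atoms, 3)
    frame_spacing: float | None = None   # e.g. ns per frame, metadata only

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != self.reference.n_atoms:
            raise ValueError("frames must be (F, n_atoms, 3) congruent with reference")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class FluctuationProfile:
    """Per-heavy-atom RMSF in A, aligned with the structure's atom order."""

    structure: Structure
    rmsf: np.ndarray
    backend: str                     # "ensemble" | "enm"
    calibration: float | None = None  # A per mode unit (enm only)
    _res_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        if self.rmsf.shape != (self.structure.n_atoms,):
            raise ValueError("RMSF length must equal heavy-atom count")
        if np.any(self.rmsf < -1e-12):
            raise ValueError("RMSF must be non-negative")
        self._res_index = self.structure.residue_atom_indices()

    def residue_mean(self, key: tuple[str, int, str]) -> float:
        idx = self._res_index.get(key)
        if idx is None:
            raise IndexError(f"residue {key} not covered by profile")
        return float(self.rmsf[idx].mean())

    def atoms_of(self, key: tuple[str, int, str]) -> np.ndarray:
        idx = self._res_index.get(key)
        if idx is None:
            raise IndexError(f"residue {key} not covered by profile")
        return idx


# ---------------------------------------------------------------------------
# ensemble backend
# ---------------------------------------------------------------------------

def rmsf_from_ensemble(e: Ensemble,
                       fit_selection: np.ndarray | None = None,
                       window: tuple[int, int] | None = None) -> FluctuationProfile:
    """RMSF of every heavy atom over the ensemble.

    Frames are Kabsch-superposed onto the reference using
    ``fit_selection`` (flat atom indices; default all atoms), then
    RMSF_a = sqrt(<|r_a - <r_a>|^2>) over the analysis ``window``
    (frame slice, default the final half of the trajectory, mirroring
    an equilibrated-tail analysis).
    """
    if e.n_frames < 2:
        raise ValueError("RMSF undefined: ensemble must contain at least 2 frames")
    if window is None:
        window = (e.n_frames // 2, e.n_frames)
    lo, hi = window
    if not (0 <= lo < hi <= e.n_frames):
        raise ValueError(f"analysis window {window} outside frame range")
    frames = e.frames[lo:hi]
    if frames.shape[0] < 2:
        raise ValueError("RMSF undefined: analysis window has fewer than 2 frames")
    if fit_selection is None:
        fit_idx = np.arange(e.reference.n_atoms)
    else:
        fit_idx = np.asarray(fit_selection, dtype=int)
        if fit_idx.size == 0:
            raise ValueError("fit_selection must not be empty")
    ref = e.reference.coords()
    fitted = np.empty_like(frames)
    for f in range(frames.shape[0]):
        fitted[f] = superpose(frames[f][fit_idx], ref[fit_idx], apply_to=frames[f])
    mean = fitted.mean(axis=0)
    msf = np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0)
    return FluctuationProfile(structure=e.reference, rmsf=np.sqrt(msf),
                              backend="ensemble")


def read_rmsf_table(path: str | Path, structure: Structure) -> FluctuationProfile:
    """Import an externally computed per-atom RMSF profile.

    Plain-text table with columns ``atom_index`` (1-based, in the
    structure's heavy-atom order) and ``rmsf_A``.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    if not {"atom_index", "rmsf_A"} <= set(df.columns):
        raise ValueError("RMSF table needs columns: atom_index, rmsf_A")
    rmsf = np.zeros(structure.n_atoms)
    idx = df["atom_index"].to_numpy(dtype=int) - 1
    if idx.min() < 0 or idx.max() >= structure.n_atoms or len(idx) != structure.n_atoms:
        raise ValueError("RMSF table does not cover the structure's atoms")
    rmsf[idx] = df["rmsf_A"].to_numpy(dtype=float)
    return FluctuationProfile(structure=structure, rmsf=rmsf, backend="ensemble")


# ---------------------------------------------------------------------------
# elastic-network backend
# ---------------------------------------------------------------------------

def kirchhoff_matrix(ca_coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Gaussian-network Kirchhoff (connectivity) matrix for Cα nodes."""
    n = ca_coords.shape[0]
    K = np.zeros((n, n))
    tree = cKDTree(ca_coords)
    for i, j in tree.query_pairs(cutoff):
        K[i, j] = K[j, i] = -1.0
    np.fill_diagonal(K, -K.sum(axis=1))
    return K


def contact_kirchhoff(s: Structure, contact_cutoff: float) -> tuple[np.ndarray, list]:
    """Contact-weighted Kirchhoff matrix on residue nodes.

    The spring constant between residues i and j is the number of
    heavy-atom pairs (one atom from each residue) closer than
    ``contact_cutoff``, so side-chain packing, disulfide clamps and
    grafted-sequence bulk all stiffen the network while glycine-rich or
    open segments soften it — the feature that makes homo-hexapeptide
    profiling sequence-sensitive.
    """
    res_keys = [(c.id, r.number, r.icode) for c, r in s.iter_residues() if r.is_standard]
    ridx = {k: i for i, k in enumerate(res_keys)}
    atom_res = np.array([ridx.get(k, -1) for k in s.atom_residue_keys()])
    n = len(res_keys)
    K = np.zeros((n, n))
    tree = cKDTree(s.coords())
    for i, j in tree.query_pairs(contact_cutoff):
        ri, rj = atom_res[i], atom_res[j]
        if ri >= 0 and rj >= 0 and ri != rj:
            K[ri, rj] -= 1.0
            K[rj, ri] -= 1.0
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -K.sum(axis=1))
    return K, res_keys


def gnm_msf(K: np.ndarray) -> np.ndarray:
    """Diagonal of the Kirchhoff pseudoinverse (mode-unit mean-square
    fluctuations). The single zero mode of a connected graph is removed
    by the pseudoinverse."""
    return np.clip(np.diag(pinvh(K)), 0.0, None)


def rmsf_from_enm(s: Structure,
                  cutoff: float = DEFAULT_ENM_CUTOFF,
                  temperature: float = 300.0,
                  calibration: float | None = None,
                  calibration_target: float = DEFAULT_CALIBRATION_TARGET,
                  weighting: str = "uniform",
                  contact_cutoff: float = 4.5,
                  ) -> FluctuationProfile:
    """Gaussian-network RMSF estimate for a static structure.

    A Kirchhoff matrix is built on the Cα (residue) nodes of all
    standard residues; residue mean-square fluctuations are kT times
    the pseudoinverse diagonal in mode units and are broadcast to each
    residue's heavy atoms.

    ``weighting="uniform"`` uses unit springs between Cα pairs within
    ``cutoff`` (classic GNM). ``weighting="contact"`` weights each
    spring by the residue pair's heavy-atom contact count within
    ``contact_cutoff`` (see :func:`contact_kirchhoff`), which makes the
    profile sensitive to side-chain packing and grafted sequences.

    If ``calibration`` (A per mode unit) is None, it is chosen so that
    the median Cα RMSF of *this* structure equals ``calibration_target``.
    Pipelines compute the constant once, on a constrained reference
    structure, and pass it explicitly so fluctuations of different
    structures share one physical scale; the constant is recorded on
    the returned profile either way.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ca, keys = [], []
    for c, r in s.iter_residues():
        if r.is_standard:
            ca.append(r.atom("CA").coord)
            keys.append((c.id, r.number, r.icode))
    ca = np.array(ca)
    if ca.shape[0] < 3:
        raise ValueError("ENM needs at least 3 Cα atoms")
    if weighting == "uniform":
        K = kirchhoff_matrix(ca, cutoff)
    elif weighting == "contact":
        K, keys = contact_kirchhoff(s, contact_cutoff)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    adjacency = (K != 0) & ~np.eye(K.shape[0], dtype=bool)
    n_comp, labels = connected_components(adjacency, directed=False)
    if n_comp > 1:
        groups = [list(np.array(keys, dtype=object)[labels == k][:3]) for k in range(n_comp)]
        raise ValueError(
            f"contact graph disconnected into {n_comp} components "
            f"(first members: {groups}); increase the cutoff"
        )
    msf = gnm_msf(K) * (temperature / 300.0)
    res_rmsf_raw = np.sqrt(msf)
    if calibration is None:
        med = float(np.median(res_rmsf_raw))
        if med <= 0:
            raise ValueError("degenerate network: zero median fluctuation")
        calibration = calibration_target / med
    res_rmsf = calibration * res_rmsf_raw

    per_res = dict(zip(keys, res_rmsf))
    rmsf = np.zeros(s.n_atoms)
    for i, key in enumerate(s.atom_residue_keys()):
        rmsf[i] = per_res.get(key, 0.0)
    return FluctuationProfile(structure=s, rmsf=rmsf, backend="enm",
                              calibration=float(calibration))


def site_mean_rmsf(p: FluctuationProfile, site) -> float:
    """Arithmetic mean RMSF over all heavy atoms of a hexapeptide site.

    ``site`` may be a :class:`flap.sitefinder.HexSite` or an iterable of
    residue keys (chain, number, icode).
    """
    keys = site.residue_keys() if hasattr(site, "residue_keys") else list(site)
    idx = np.concatenate([p.atoms_of(k) for k in keys])
    return float(p.rmsf[idx].mean())
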
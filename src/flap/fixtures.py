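"""Synthetic structures, ensembles and complexes with known ground truth.

Every stage of the grafting pipeline is exercised on structures built
here from ideal peptide geometry, so the test matrix needs no external
downloads. The generator records its seed in every output and is fully
deterministic: identical specs give byte-identical PDB files.

Fixture kinds
-------------
helix / strand / linear_peptide
    Single chains built from canonical φ/ψ (helix −57/−47, strand and
    linear −120/+120).
hairpin
    Two antiparallel strands joined by a loop whose dihedrals are
    optimised (deterministically) for sheet hydrogen bonding. The loop
    is left geometrically open — its residues touch only their chain
    neighbours — so it is a *mobile* loop by construction.
clamped_hairpin
    As ``hairpin`` but the loop is pulled into a compact conformation
    against the strand tips and the two loop-flanking cysteines are
    disulfide-bonded: an *immobilised* loop by construction.
toy_complex
    A short acidic receptor strand paired laterally (sheet-style)
    against an extended ligand peptide whose designed contact positions
    carry basic residues, docked so that exactly those positions form
    the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares, minimize

from .flexengine import Ensemble
from .geometry import place_atom, rotate_about_axis
from .sidechains import build_residue
from .structure import AA1_TO_3, Chain, Residue, Structure, vdw_radius

# ideal backbone internal coordinates (A / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.5
OMEGA = 180.0

PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-120.0, 120.0),
    "linear_peptide": (-120.0, 120.0),
}


@dataclass
class FixtureSpec:
    kind: str
    sequence: str | None = None
    length: int = 12
    loop_length: int = 6
    strand_length: int = 7
    jitter: dict[str, float] = field(default_factory=dict)  # region -> per-axis sigma (A)
    seed: int = 0
    contact_positions: tuple[int, ...] = (9, 10, 11, 12, 13, 14)

    def __post_init__(self) -> None:
        valid = {"helix", "strand", "hairpin", "clamped_hairpin",
                 "linear_peptide", "toy_complex"}
        if self.kind not in valid:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if any(v < 0 for v in self.jitter.values()):
            raise ValueError("jitter amplitudes must be non-negative")


# ---------------------------------------------------------------------------
# backbone construction
# ---------------------------------------------------------------------------

def build_backbone(phi_psi: list[tuple[float, float]]) -> np.ndarray:
    """Backbone coordinates (n, 4, 3) = N, CA, C, O per residue from a
    φ/ψ schedule (ω fixed trans)."""
    n = len(phi_psi)
    bb = np.zeros((n, 4, 3))
    bb[0, 0] = [0.0, 0.0, 0.0]
    bb[0, 1] = [B_N_CA, 0.0, 0.0]
    ang = np.deg2rad(A_N_CA_C)
    bb[0, 2] = bb[0, 1] + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n):
        phi, psi = phi_psi[i]
        if i > 0:
            bb[i, 0] = place_atom(bb[i - 1, 0], bb[i - 1, 1], bb[i - 1, 2],
                                  B_C_N, A_CA_C_N, phi_psi[i - 1][1])
            bb[i, 1] = place_atom(bb[i - 1, 1], bb[i - 1, 2], bb[i, 0],
                                  B_N_CA, A_C_N_CA, OMEGA)
            bb[i, 2] = place_atom(bb[i - 1, 2], bb[i, 0], bb[i, 1],
                                  B_CA_C, A_N_CA_C, phi)
        # carbonyl O: trans to the next amide nitrogen (ψ + 180)
        bb[i, 3] = place_atom(bb[i, 0], bb[i, 1], bb[i, 2],
                              B_C_O, A_CA_C_O, psi + 180.0)
    return bb


def build_chain(sequence: str, phi_psi: list[tuple[float, float]],
                chain_id: str = "A", start_number: int = 1,
                backbone: np.ndarray | None = None,
                extra_env: np.ndarray | None = None,
                extra_env_vdw: np.ndarray | None = None) -> Chain:
    """Full heavy-atom chain: ideal backbone plus template side chains
    (clash-aware rotamer choice against everything already placed and,
    optionally, the ``extra_env`` atoms of neighbouring molecules)."""
    if backbone is None:
        backbone = build_backbone(phi_psi)
    if len(sequence) != backbone.shape[0]:
        raise ValueError("sequence length must match backbone length")
    residues: list[Residue] = []
    env_pts: list[np.ndarray] = [bb for res in backbone for bb in res]
    env_vdw: list[float] = []
    for res in backbone:
        for nm in ("N", "C", "C", "O"):
            env_vdw.append(vdw_radius(nm[0]))
    if extra_env is not None and len(extra_env):
        env_pts.extend(np.asarray(extra_env, dtype=float))
        if extra_env_vdw is None:
            extra_env_vdw = np.full(len(extra_env), 1.7)
        env_vdw.extend(np.asarray(extra_env_vdw, dtype=float))
    for i, aa in enumerate(sequence):
        res_name = AA1_TO_3[aa.upper()]
        env = np.array(env_pts)
        r = build_residue(res_name, backbone[i, 0], backbone[i, 1],
                          backbone[i, 2], backbone[i, 3],
                          number=start_number + i,
                          environment=env, env_vdw=np.array(env_vdw))
        residues.append(r)
        for a in r.atoms:
            if a.name not in ("N", "CA", "C", "O"):
                env_pts.append(a.coord)
                env_vdw.append(a.vdw)
    return Chain(id=chain_id, residues=residues)


# ---------------------------------------------------------------------------
# hairpins
# ---------------------------------------------------------------------------

@lru_cache(maxsize=16)
def _hairpin_phi_psi(n_strand: int, loop_len: int, compact: bool
                     ) -> tuple[tuple[float, float], ...]:
    """φ/ψ schedule for a two-strand hairpin with an optimised loop.

    The loop dihedrals minimise a deterministic objective: antiparallel
    Cα pairing with the canonical narrow/wide hydrogen-bond register
    for the strands, plus a loop-shape term that pulls the loop against
    the strand tips (``compact=True``) or pushes it away from them
    (``compact=False``). Cached — the schedule is a pure function of
    its arguments.
    """
    strand = PHI_PSI["strand"]

    def schedule(x: np.ndarray) -> list[tuple[float, float]]:
        loop = [(float(x[2 * k]), float(x[2 * k + 1])) for k in range(loop_len)]
        return [strand] * n_strand + loop + [strand] * n_strand

    pair_targets = [(n_strand - 1 - k, n_strand + loop_len + k)
                    for k in range(n_strand)]

    def residuals(x: np.ndarray) -> np.ndarray:
        bb = build_backbone(schedule(x))
        ca = bb[:, 1]
        res = []
        for k, (i, j) in enumerate(pair_targets):
            if k % 2 == 0:
                # narrow pair: both inter-strand amide H-bonds
                res.append(np.linalg.norm(ca[i] - ca[j]) - 4.6)
                res.append(np.linalg.norm(bb[i, 3] - bb[j, 0]) - 2.9)
                res.append(np.linalg.norm(bb[i, 0] - bb[j, 3]) - 2.9)
            else:
                res.append(0.7 * (np.linalg.norm(ca[i] - ca[j]) - 5.4))
        tips = [ca[n_strand - 1], ca[n_strand + loop_len]]
        mid = ca[n_strand:n_strand + loop_len]
        for m in mid[1:-1]:
            d = min(np.linalg.norm(m - t) for t in tips)
            if compact:
                res.append(0.55 * max(0.0, d - 6.0))
            else:
                res.append(0.55 * max(0.0, 9.5 - d))
        if compact:
            # keep the loop coil-like: no amide H-bond geometry between
            # loop residues and the strands, or the loop stops being a loop
            strand_idx = list(range(n_strand)) + \
                list(range(n_strand + loop_len, 2 * n_strand + loop_len))
            for k in range(n_strand, n_strand + loop_len):
                dmin = min(
                    min(np.linalg.norm(bb[k, 0] - bb[sj, 3]),
                        np.linalg.norm(bb[k, 3] - bb[sj, 0]))
                    for sj in strand_idx
                )
                res.append(1.5 * max(0.0, 3.4 - dmin))
        return np.array(res)

    # type-I' turn seed in the loop middle, extended elsewhere
    x0 = []
    mid = loop_len // 2
    for k in range(loop_len):
        if k == mid - 1:
            x0 += [60.0, 30.0]
        elif k == mid:
            x0 += [90.0, 0.0]
        else:
            x0 += [-100.0, 110.0]
    fit = least_squares(residuals, np.array(x0), diff_step=1e-3,
                        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=400)
    return tuple(schedule(fit.x))


def _close_disulfide(structure: Structure, key_a, key_b) -> None:
    """Continuously rotate the two cysteine chi1 angles so the SG-SG
    distance reaches bonding range (deterministic local optimisation)."""
    res = {}
    for c, r in structure.iter_residues():
        if (c.id, r.number, r.icode) in (key_a, key_b):
            res[(c.id, r.number, r.icode)] = r
    ra, rb = res[key_a], res[key_b]

    def sg_dist(angles: np.ndarray) -> float:
        pts = []
        for r, ang in zip((ra, rb), angles):
            ca, cb, sg = (r.atom(n).coord for n in ("CA", "CB", "SG"))
            pts.append(rotate_about_axis(sg[None, :], ca, cb - ca, ang)[0])
        return float(np.linalg.norm(pts[0] - pts[1]))

    best = min(
        (np.array([a, b]) for a in range(0, 360, 30) for b in range(0, 360, 30)),
        key=lambda x: abs(sg_dist(x) - 2.04),
    )
    out = minimize(lambda x: (sg_dist(x) - 2.04) ** 2, best.astype(float),
                   method="Nelder-Mead", options={"xatol": 1e-4, "fatol": 1e-10})
    for r, ang in zip((ra, rb), out.x):
        ca, cb = r.atom("CA").coord, r.atom("CB").coord
        sg = r.atom("SG")
        sg.coord = rotate_about_axis(sg.coord[None, :], ca, cb - ca, float(ang))[0]


def _hairpin_structure(spec: FixtureSpec, compact: bool) -> Structure:
    ns, nl = spec.strand_length, spec.loop_length
    if nl < 2:
        raise ValueError("loop too short to close the hairpin")
    seq = spec.sequence
    if seq is None:
        if compact:
            # cysteines at the loop-flanking strand tips for the clamp
            seq = "T" * (ns - 1) + "C" + "G" + "S" * (nl - 2) + "G" + "C" + "T" * (ns - 1)
        else:
            seq = "T" * ns + "G" + "S" * (nl - 2) + "G" + "T" * ns
    if len(seq) != 2 * ns + nl:
        raise ValueError("sequence length must be 2*strand_length + loop_length")
    phi_psi = list(_hairpin_phi_psi(ns, nl, compact))
    chain = build_chain(seq, phi_psi, chain_id="A")
    s = Structure(id=spec.kind, chains=[chain])
    if compact:
        key_a = ("A", ns, "")
        key_b = ("A", ns + nl + 1, "")
        _close_disulfide(s, key_a, key_b)
    return s


# ---------------------------------------------------------------------------
# toy antibody-antigen complex
# ---------------------------------------------------------------------------

def _toy_complex(spec: FixtureSpec) -> Structure:
    """Acidic receptor strand (chain A) paired laterally against the
    backbone of an extended ligand peptide (chain B) over the designed
    contact block, so exactly those ligand residues are interface
    contacts.

    The ligand carries lysines at the contact positions and serines
    elsewhere; its side chains are built *after* docking, with the
    receptor in the clash environment, so the contact lysines pack
    against the acidic helix without steric overlap.
    """
    contacts = tuple(sorted(spec.contact_positions))
    if not contacts:
        raise ValueError("toy_complex needs at least one contact position")
    lig_len = max(24, contacts[-1] + 8)
    lig_seq = spec.sequence
    if lig_seq is None:
        lig_seq = "".join("K" if (i + 1) in contacts else "S" for i in range(lig_len))

    # ligand backbone: extended strand along +x
    lig_bb = build_backbone([PHI_PSI["strand"]] * lig_len)   # (n, 4, 3)
    flat = lig_bb.reshape(-1, 3)
    ca = lig_bb[:, 1]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    flat = _align_axis(flat, axis, np.array([1.0, 0.0, 0.0]))
    lig_bb = flat.reshape(lig_len, 4, 3)
    ca = lig_bb[:, 1]

    # receptor: a short acidic strand paired laterally with the contact
    # block, like a neighbouring sheet strand — lateral pairing is what
    # lets every consecutive block residue touch the partner. It is one
    # residue shorter than the block so the flanking ligand residues
    # stay out of contact range.
    rec_len = max(3, len(contacts) - 1)
    rec_seq = "A" + "E" * (rec_len - 2) + "A"
    rec_bb = build_backbone([PHI_PSI["strand"]] * rec_len)
    rflat = rec_bb.reshape(-1, 3)
    rca = rec_bb[:, 1]
    raxis = rca[-1] - rca[0]
    raxis /= np.linalg.norm(raxis)
    rflat = _align_axis(rflat, raxis, np.array([1.0, 0.0, 0.0]))
    # antiparallel orientation: aligned pair register, uniform lateral
    # backbone distances (parallel pairing would be sheared)
    rflat = rflat * np.array([-1.0, 1.0, -1.0])
    rec_bb = rflat.reshape(rec_len, 4, 3)

    block = [c - 1 for c in contacts]
    center = ca[block].mean(axis=0)
    rec_bb = rec_bb - rec_bb.reshape(-1, 3).mean(axis=0) + center \
        + np.array([0.0, 16.0, 0.0])
    rec_bb = _dock_lateral(rec_bb, lig_bb, block)

    def assemble(bb: np.ndarray) -> Structure:
        # side chains: receptor first (ligand backbone in the
        # environment), then the ligand against the complete receptor
        rec_chain = build_chain(rec_seq, [PHI_PSI["strand"]] * rec_len,
                                chain_id="A", backbone=bb,
                                extra_env=lig_bb.reshape(-1, 3))
        rec = Structure(id="toy_receptor", chains=[rec_chain])
        lig_chain = build_chain(lig_seq, [PHI_PSI["strand"]] * lig_len,
                                chain_id="B", backbone=lig_bb,
                                extra_env=rec.coords(), extra_env_vdw=rec.vdw())
        s = Structure(id="toy_complex", chains=[rec.chains[0], lig_chain])
        _steer_salt_bridges(s, contacts)
        return s

    # verify the designed contact set on the full heavy-atom model and
    # nudge the approach depth if a side chain leaks over the cutoff
    from scipy.spatial import cKDTree

    target = set(contacts)
    best = None
    for nudge in np.arange(0.0, 1.01, 0.1):
        s = assemble(rec_bb + np.array([0.0, nudge, 0.0]))
        rec_pts = np.array([a.coord for c, r, a in s.iter_atoms() if c.id == "A"])
        tree = cKDTree(rec_pts)
        found = set()
        for r in s.chain("B").residues:
            if any(tree.query(a.coord)[0] <= 4.5 for a in r.atoms):
                found.add(r.number)
        if best is None:
            best = s
        if found == target:
            return s
    return best


def _align_axis(points: np.ndarray, current: np.ndarray, target: np.ndarray) -> np.ndarray:
    center = points.mean(axis=0)
    v = np.cross(current, target)
    s = np.linalg.norm(v)
    c = float(np.dot(current, target))
    if s < 1e-12:
        return points - center
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    R = np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)
    return (points - center) @ R.T


def _steer_salt_bridges(s: Structure, contacts: tuple[int, ...]) -> None:
    """Turn every contact lysine into its most favourable rotamer with
    respect to the rest of the complex: a deterministic chi1/chi2 grid
    search scored by the residue's nonbonded (LJ + screened Coulomb)
    energy, emulating the electrostatic steering that forms the
    designed salt bridges."""
    from .energy import COULOMB_CONST, LJ_PARAMS, lj_pair_energy
    from .sidechains import set_residue_chis

    def atom_q(chain_id, res, atom):
        from .energy import BACKBONE_CHARGES, SIDECHAIN_CHARGES

        if atom.name in BACKBONE_CHARGES:
            return BACKBONE_CHARGES[atom.name]
        return SIDECHAIN_CHARGES.get((res.name, atom.name), 0.0)

    lig = s.chain("B")
    for num in contacts:
        res = lig.residue(num)
        if res is None or res.name != "LYS":
            continue
        env = [(a.coord, LJ_PARAMS.get(a.element.upper(), (3.4, 0.086)),
                atom_q(c.id, r, a))
               for c, r, a in s.iter_atoms()
               if not (c.id == "B" and abs(r.number - num) <= 1)]
        best = None
        for c1 in (-60.0, 60.0, 180.0):
            for c2 in (-60.0, 60.0, 180.0):
                set_residue_chis(res, [c1, c2])
                e = 0.0
                for a in res.atoms:
                    if a.name in ("N", "CA", "C", "O", "CB"):
                        continue
                    pa, qa = LJ_PARAMS.get(a.element.upper(), (3.4, 0.086)), \
                        atom_q("B", res, a)
                    for coord, pb, qb in env:
                        rdist = float(np.linalg.norm(a.coord - coord))
                        if rdist > 12.0:
                            continue
                        e += lj_pair_energy(rdist, 0.5 * (pa[0] + pb[0]),
                                            float(np.sqrt(pa[1] * pb[1])))
                        if qa and qb:
                            e += COULOMB_CONST * qa * qb / (4.0 * rdist * rdist)
                if best is None or e < best[0] - 1e-12:
                    best = (e, (c1, c2))
        set_residue_chis(res, list(best[1]))


def _dock_lateral(rec_bb: np.ndarray, lig_bb: np.ndarray, block: list[int]
                  ) -> np.ndarray:
    """Dock a receptor strand laterally against the ligand's contact
    block: a deterministic register search over x-shift, with the
    approach depth (y) bisected so the farthest block residue still
    touches. Scored on backbone distances: every block residue within
    4.2 A, both flanking residues beyond 5.0 A, no steric overlap."""
    def res_min(bb_shifted: np.ndarray, res_idx: int) -> float:
        d = np.sqrt(((lig_bb[res_idx][:, None, :]
                      - bb_shifted.reshape(-1, 3)[None, :, :]) ** 2).sum(axis=2))
        return float(d.min())

    def dock_at(dx: float) -> tuple[np.ndarray, float]:
        shifted = rec_bb + np.array([dx, 0.0, 0.0])
        lo, hi = 0.0, 30.0
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            trial = shifted + np.array([0.0, -mid, 0.0])
            worst = max(res_min(trial, r) for r in block)
            if worst > 4.0:
                lo = mid
            else:
                hi = mid
        trial = shifted + np.array([0.0, -0.5 * (lo + hi), 0.0])
        worst = max(res_min(trial, r) for r in block)
        closest = min(res_min(trial, r) for r in block)
        flank = [r for r in (block[0] - 1, block[-1] + 1)
                 if 0 <= r < lig_bb.shape[0]]
        nbr = min((res_min(trial, r) for r in flank), default=10.0)
        score = (10.0 * max(0.0, 2.95 - closest)
                 + 10.0 * max(0.0, 5.4 - nbr)
                 + (worst - closest))
        return trial, score

    best_bb, best_score = None, None
    for dx in np.arange(-2.0, 2.01, 0.1):
        trial, score = dock_at(float(dx))
        if best_score is None or score < best_score - 1e-9:
            best_bb, best_score = trial, score
    return best_bb


def _approach_offset(mobile: np.ndarray, target_pts: np.ndarray, target: float,
                     direction: np.ndarray | None = None) -> float:
    """Travel along ``direction`` (default -z) that brings the minimum
    distance(mobile, target_pts) to ``target`` A (bisection; mobile
    starts fully separated)."""
    if direction is None:
        direction = np.array([0.0, 0.0, -1.0])

    def min_d(t: float) -> float:
        shifted = mobile + t * direction
        d = np.sqrt(((shifted[:, None, :] - target_pts[None, :, :]) ** 2).sum(axis=2))
        return float(d.min())

    lo, hi = 0.0, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if min_d(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def build_structure(spec: FixtureSpec) -> Structure:
    """Construct the fixture structure described by ``spec``."""
    if spec.kind in ("helix", "strand", "linear_peptide"):
        seq = spec.sequence or ("A" * spec.length)
        chain = build_chain(seq, [PHI_PSI[spec.kind]] * len(seq), chain_id="A")
        return Structure(id=spec.kind, chains=[chain])
    if spec.kind == "hairpin":
        return _hairpin_structure(spec, compact=False)
    if spec.kind == "clamped_hairpin":
        return _hairpin_structure(spec, compact=True)
    if spec.kind == "toy_complex":
        return _toy_complex(spec)
    raise ValueError(spec.kind)


def build_ensemble(spec: FixtureSpec, frames: int,
                   sigma_per_residue: np.ndarray | None = None,
                   rigid_noise: bool = False) -> Ensemble:
    """Reference structure plus ``frames`` jittered copies.

    Each residue's atoms receive independent Gaussian displacement with
    the per-axis sigma given by ``sigma_per_residue`` (A; default: the
    ``spec.jitter`` value for "all", else 0). With ``rigid_noise`` a
    random rigid-body motion is applied to every frame on top, which a
    correct superposition must remove.
    """
    if frames < 2:
        raise ValueError("need at least 2 frames")
    ref = build_structure(spec)
    rng = np.random.default_rng(spec.seed)
    n_res = ref.n_residues
    if sigma_per_residue is None:
        sigma_per_residue = np.full(n_res, spec.jitter.get("all", 0.0))
    sigma_per_residue = np.asarray(sigma_per_residue, dtype=float)
    if sigma_per_residue.shape != (n_res,):
        raise ValueError("sigma_per_residue must have one value per residue")
    res_of_atom = []
    for i, (c, r) in enumerate(ref.iter_residues()):
        res_of_atom.extend([i] * len(r.atoms))
    res_of_atom = np.asarray(res_of_atom)
    sigma_atom = sigma_per_residue[res_of_atom][:, None]

    base = ref.coords()
    stack = np.empty((frames, base.shape[0], 3))
    for f in range(frames):
        xyz = base + rng.normal(0.0, 1.0, size=base.shape) * sigma_atom
        if rigid_noise:
            ang = rng.uniform(0.0, 360.0, size=3)
            for axis_idx in range(3):
                axis = np.eye(3)[axis_idx]
                xyz = rotate_about_axis(xyz, base.mean(axis=0), axis, ang[axis_idx])
            xyz = xyz + rng.normal(0.0, 5.0, size=3)
        stack[f] = xyz
    return Ensemble(reference=ref, frames=stack)


def manifest(spec: FixtureSpec) -> dict:
    """Machine-readable record of the fixture's designed ground truth."""
    info: dict = {"kind": spec.kind, "seed": spec.seed}
    if spec.kind in ("hairpin", "clamped_hairpin"):
        ns, nl = spec.strand_length, spec.loop_length
        info["loop_residues"] = list(range(ns + 1, ns + nl + 1))
        info["strand_residues"] = (list(range(1, ns + 1)) +
                                   list(range(ns + nl + 1, 2 * ns + nl + 1)))
        info["clamped"] = spec.kind == "clamped_hairpin"
    if spec.kind == "toy_complex":
        info["contact_positions"] = list(spec.contact_positions)
        info["receptor_chain"] = "A"
        info["ligand_chain"] = "B"
    if spec.jitter:
        info["jitter_sigma_A"] = dict(spec.jitter)
    return info
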
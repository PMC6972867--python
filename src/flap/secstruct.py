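"""Three-state secondary-structure assignment.

Implements hydrogen-bond detection with the Kabsch–Sander electrostatic
energy (bond if E < -0.5 kcal/mol), then the classic n-turn / bridge
pattern rules, collapsed to the three states the grafting pipeline
consumes: H (any helix), E (strand or bridge), C (everything else).

The amide hydrogen is not stored in the model; it is reconstructed on
the donor nitrogen, 1 A along the C=O direction of the preceding
residue, exactly as reference DSSP implementations do.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .structure import SSAnnotation, Structure

HB_Q1Q2_F = 0.084 * 332.0   # kcal/mol * A, Kabsch-Sander coupling constant
HB_CUTOFF = -0.5            # kcal/mol
PEPTIDE_BOND_BREAK = 2.5    # A, C(i)-N(i+1) beyond this is a chain break
CA_SEARCH = 9.0             # A, CA-CA prefilter for H-bond partners


def _backbone_frames(s: Structure):
    """Flat arrays of backbone coordinates for standard residues that have
    a complete N/CA/C/O backbone; others are reported for C labelling."""
    keys, n_xyz, ca_xyz, c_xyz, o_xyz, chain_ids = [], [], [], [], [], []
    incomplete = []
    for c, r in s.iter_residues():
        if not r.is_standard:
            continue
        bb = [r.atom(nm) for nm in ("N", "CA", "C", "O")]
        if any(a is None for a in bb):
            incomplete.append((c.id, r.number, r.icode))
            continue
        keys.append((c.id, r.number, r.icode))
        n_xyz.append(bb[0].coord)
        ca_xyz.append(bb[1].coord)
        c_xyz.append(bb[2].coord)
        o_xyz.append(bb[3].coord)
        chain_ids.append(c.id)
    return (keys, np.array(n_xyz).reshape(-1, 3), np.array(ca_xyz).reshape(-1, 3),
            np.array(c_xyz).reshape(-1, 3), np.array(o_xyz).reshape(-1, 3),
            chain_ids, incomplete)


def assign_secondary_structure(s: Structure,
                               disulfides: dict | None = None) -> SSAnnotation:
    """Assign H/E/C to every residue of ``s``.

    Residues lacking any of N, CA, C, O are labelled C with a warning;
    non-standard residues are labelled C silently. ``disulfides`` (as
    returned by :func:`flap.structio.disulfide_map`) is attached to the
    annotation unchanged.
    """
    keys, N, CA, C, O, chain_ids, incomplete = _backbone_frames(s)
    if incomplete:
        warnings.warn(
            f"{len(incomplete)} residue(s) with incomplete backbone labelled C: "
            f"{incomplete[:5]}"
        )
    n = len(keys)
    state = {}

    if n >= 4:
        # connectivity: residue i follows i-1 without a chain break
        connected = np.zeros(n, dtype=bool)
        for i in range(1, n):
            if chain_ids[i] == chain_ids[i - 1]:
                connected[i] = np.linalg.norm(N[i] - C[i - 1]) < PEPTIDE_BOND_BREAK

        # reconstructed amide H on each donor (undefined at chain starts)
        H = np.full((n, 3), np.nan)
        for i in range(n):
            if connected[i]:
                co = C[i - 1] - O[i - 1]
                H[i] = N[i] + co / np.linalg.norm(co)

        hbond = _hbond_matrix(N, CA, C, O, H, chain_ids)

        def turn(i: int, m: int) -> bool:
            j = i + m
            if j >= n or chain_ids[i] != chain_ids[j]:
                return False
            if not all(connected[k] for k in range(i + 1, j + 1)):
                return False
            return hbond[j, i]

        helix = np.zeros(n, dtype=bool)       # alpha
        helix_minor = np.zeros(n, dtype=bool)  # 3-10 / pi, collapsed to H
        for m, target in ((4, helix), (3, helix_minor), (5, helix_minor)):
            for i in range(1, n - m):
                if turn(i - 1, m) and turn(i, m):
                    target[i:i + m] = True

        bridge = np.zeros(n, dtype=bool)
        tree = cKDTree(CA)
        pairs = tree.query_pairs(CA_SEARCH)
        for i, j in pairs:
            if abs(i - j) <= 2 and chain_ids[i] == chain_ids[j]:
                continue
            i, j = min(i, j), max(i, j)
            # HB(a, b) in the classic bridge patterns means "CO of a
            # accepts from NH of b", i.e. hbond[b, a] here
            para = ((_hb(hbond, j, i - 1) and _hb(hbond, i + 1, j)) or
                    (_hb(hbond, i, j - 1) and _hb(hbond, j + 1, i)))
            anti = ((_hb(hbond, j, i) and _hb(hbond, i, j)) or
                    (_hb(hbond, j + 1, i - 1) and _hb(hbond, i + 1, j - 1)))
            if para or anti:
                bridge[i] = bridge[j] = True

        for i, key in enumerate(keys):
            if helix[i]:
                state[key] = "H"
            elif bridge[i]:
                state[key] = "E"
            elif helix_minor[i]:
                state[key] = "H"
            else:
                state[key] = "C"
    else:
        # too short for any secondary-structure element
        for key in keys:
            state[key] = "C"

    residue_keys = [(c.id, r.number, r.icode) for c, r in s.iter_residues()]
    states = [state.get(k, "C") for k in residue_keys]
    return SSAnnotation(states=states, residue_keys=residue_keys,
                        disulfides=dict(disulfides or {}))


def _hb(hbond: np.ndarray, donor: int, acceptor: int) -> bool:
    n = hbond.shape[0]
    if donor < 0 or acceptor < 0 or donor >= n or acceptor >= n:
        return False
    return bool(hbond[donor, acceptor])


def _hbond_matrix(N, CA, C, O, H, chain_ids) -> np.ndarray:
    """hbond[i, j] is True when the NH of residue i donates to the CO of
    residue j under the Kabsch-Sander energy criterion."""
    n = N.shape[0]
    hbond = np.zeros((n, n), dtype=bool)
    tree = cKDTree(CA)
    for i, j in tree.query_pairs(CA_SEARCH):
        for donor, acceptor in ((i, j), (j, i)):
            if chain_ids[donor] == chain_ids[acceptor] and abs(donor - acceptor) < 2:
                continue
            h = H[donor]
            if np.any(np.isnan(h)):
                continue
            d_on = np.linalg.norm(O[acceptor] - N[donor])
            d_ch = np.linalg.norm(C[acceptor] - h)
            d_oh = np.linalg.norm(O[acceptor] - h)
            d_cn = np.linalg.norm(C[acceptor] - N[donor])
            if min(d_on, d_ch, d_oh, d_cn) < 1e-6:
                continue
            e = HB_Q1Q2_F * (1.0 / d_on + 1.0 / d_ch - 1.0 / d_oh - 1.0 / d_cn)
            if e < HB_CUTOFF:
                hbond[donor, acceptor] = True
    return hbond
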
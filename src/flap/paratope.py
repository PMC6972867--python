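"""Antigen-binding CDR hexapeptide identification.

Given an antibody-antigen complex and CDR boundary annotations, this
module finds antigen-contact residues, enumerates candidate 6-mer CDR
windows, and ranks them by the binding-energy loss incurred when the
window is mutated to an alanine hexapeptide (A6) — the in-silico
alanine-hexapeptide scan. Windows whose loss is largest carry the
antigen-binding hot spots and become the grafting payloads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import graftlab
from .energy import EnergyConfig, pairwise_energy, relax_structure
from .sasa import compute_sasa
from .structure import Structure

DEFAULT_CONTACT_CUTOFF = 4.5  # A, heavy-atom


@dataclass
class CDRRange:
    name: str       # e.g. "CDR-H3"
    start: int      # author numbering, inclusive
    end: int        # inclusive

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"CDR {self.name}: end before start")


@dataclass
class ComplexSpec:
    """An antibody-antigen complex with chain roles and CDR annotation."""

    structure: Structure
    receptor_chains: tuple[str, ...]        # antigen
    ligand_chains: tuple[str, ...]          # antibody variable domain
    cdrs: dict[str, list[CDRRange]] = field(default_factory=dict)
    window_prefix: dict[str, str] = field(default_factory=dict)  # chain -> "TH" etc.

    def __post_init__(self) -> None:
        self.receptor_chains = tuple(self.receptor_chains)
        self.ligand_chains = tuple(self.ligand_chains)
        if set(self.receptor_chains) & set(self.ligand_chains):
            raise ValueError("receptor and ligand chain sets must be disjoint")
        for cid, ranges in self.cdrs.items():
            chain = self.structure.chain(cid)
            numbers = {r.number for r in chain.residues}
            for rng in ranges:
                if rng.start not in numbers or rng.end not in numbers:
                    raise ValueError(
                        f"CDR {rng.name} [{rng.start}-{rng.end}] outside chain {cid}"
                    )

    def atom_groups(self) -> tuple[np.ndarray, np.ndarray]:
        """(receptor, ligand) flat atom index arrays."""
        rec, lig = [], []
        for i, key in enumerate(self.structure.atom_residue_keys()):
            if key[0] in self.receptor_chains:
                rec.append(i)
            elif key[0] in self.ligand_chains:
                lig.append(i)
        return np.asarray(rec, int), np.asarray(lig, int)


@dataclass
class CDRWindow:
    """A candidate 6-mer window overlapping a CDR."""

    name: str               # e.g. TH3
    chain_id: str
    start: int              # author number, 1-based inclusive
    sequence: str
    contact_count: int = 0  # designed contact residues inside the window

    def __post_init__(self) -> None:
        if len(self.sequence) != 6:
            raise ValueError("CDR window must cover exactly 6 residues")
        if not (0 <= self.contact_count <= 6):
            raise ValueError("contact count must be within [0, 6]")


@dataclass
class DeltaGReport:
    """Alanine-hexapeptide scan result for one window."""

    window: CDRWindow
    dg_wt: float            # binding score of the wild-type complex
    dg_ala6: float          # binding score after A6 mutation
    selected: bool = False
    failed: bool = False

    @property
    def loss(self) -> float:
        """Binding-energy loss = dG(A6) - dG(wild type); positive when
        the mutation weakens binding."""
        return self.dg_ala6 - self.dg_wt


# ---------------------------------------------------------------------------
# interface analysis
# ---------------------------------------------------------------------------

def find_contact_residues(c: ComplexSpec,
                          cutoff: float = DEFAULT_CONTACT_CUTOFF
                          ) -> dict[str, set[int]]:
    """Ligand residues with any heavy atom within ``cutoff`` of any
    receptor heavy atom, per ligand chain (author numbers)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coords = c.structure.coords()
    keys = c.structure.atom_residue_keys()
    rec_idx, lig_idx = c.atom_groups()
    out: dict[str, set[int]] = {cid: set() for cid in c.ligand_chains}
    if rec_idx.size == 0 or lig_idx.size == 0:
        warnings.warn("empty interface: one side has no atoms")
        return out
    tree = cKDTree(coords[rec_idx])
    hits = tree.query_ball_point(coords[lig_idx], cutoff)
    for pos, neighbours in zip(lig_idx, hits):
        if neighbours:
            cid, num, _ = keys[pos]
            out[cid].add(num)
    if not any(out.values()):
        warnings.warn("empty interface: no ligand residue within cutoff")
    return out


def longest_contact_run(contacts: set[int], chain_residue_numbers: list[int]
                        ) -> int:
    """Length of the longest run of consecutive chain residues that are
    all in the contact set (the hexapeptide statistic: this run is six
    residues in nearly all antibody chains)."""
    best = cur = 0
    for num in chain_residue_numbers:
        if num in contacts:
            cur += 1
            best = max(best, cur)
        else:
            cur = 0
    return best


def enumerate_cdr_windows(c: ComplexSpec, contacts: dict[str, set[int]],
                          require_contact: bool = True) -> list[CDRWindow]:
    """All 6-mer windows of the ligand chains that overlap a CDR range,
    named [prefix][ordinal] from N- to C-terminus per chain.

    With ``require_contact`` only windows containing at least one
    antigen-contact residue are kept (the ordinals still reflect the
    kept windows, mirroring the TH1..TH11 style series).
    """
    windows: list[CDRWindow] = []
    for cid in c.ligand_chains:
        ranges = c.cdrs.get(cid, [])
        if not ranges:
            continue
        chain = c.structure.chain(cid)
        residues = chain.standard_residues()
        prefix = c.window_prefix.get(cid, f"{cid}W")
        chain_contacts = contacts.get(cid, set())
        ordinal = 0
        for i0 in range(len(residues) - 5):
            window = residues[i0:i0 + 6]
            numbers = [r.number for r in window]
            if numbers[-1] - numbers[0] != 5:
                warnings.warn(
                    f"window at {cid}:{numbers[0]} crosses a chain break, skipped")
                continue
            overlaps = any(
                rng.start <= num <= rng.end for rng in ranges for num in numbers)
            if not overlaps:
                continue
            n_contact = sum(1 for num in numbers if num in chain_contacts)
            if require_contact and n_contact == 0:
                continue
            ordinal += 1
            windows.append(CDRWindow(
                name=f"{prefix}{ordinal}", chain_id=cid, start=numbers[0],
                sequence="".join(r.one_letter for r in window),
                contact_count=n_contact,
            ))
    return windows


# ---------------------------------------------------------------------------
# binding energy
# ---------------------------------------------------------------------------

def interaction_energy(c: ComplexSpec, config: EnergyConfig | None = None
                       ) -> float:
    """Binding score E(complex) - E(receptor) - E(ligand).

    Each term is evaluated after the configured relaxation (default:
    none, single-point on identical coordinates, in which case the
    intra-chain terms cancel and the score reduces to the cross-
    interface nonbonded sum).
    """
    config = config or EnergyConfig()
    rec_idx, lig_idx = c.atom_groups()
    coords = c.structure.coords()
    if rec_idx.size and lig_idx.size:
        tree = cKDTree(coords[rec_idx])
        dmin, _ = tree.query(coords[lig_idx], k=1)
        if float(np.min(dmin)) < config.clash_distance:
            raise ValueError("steric clash across the interface, relax first")
    if config.relax == "none":
        e_bind = pairwise_energy(c.structure, config,
                                 group_a=rec_idx, group_b=lig_idx)
    else:
        relaxed = relax_structure(c.structure, config)
        e_complex = pairwise_energy(relaxed, config)
        rec = _subset(relaxed, c.receptor_chains)
        lig = _subset(relaxed, c.ligand_chains)
        e_bind = (e_complex
                  - pairwise_energy(relax_structure(rec, config), config)
                  - pairwise_energy(relax_structure(lig, config), config))
    if config.solvation:
        e_bind += config.solvation_sigma * _buried_area(c, config)
    return float(e_bind)


def _subset(s: Structure, chain_ids: tuple[str, ...]) -> Structure:
    out = s.copy()
    out.chains = [ch for ch in out.chains if ch.id in chain_ids]
    return out


def _buried_area(c: ComplexSpec, config: EnergyConfig) -> float:
    """Interface area buried on binding (negative contribution favours
    binding when solvation_sigma > 0 is subtracted; reported as the
    negative buried area)."""
    whole = compute_sasa(c.structure)
    rec = compute_sasa(_subset(c.structure, c.receptor_chains))
    lig = compute_sasa(_subset(c.structure, c.ligand_chains))
    return whole.total - rec.total - lig.total


def alanine_hexapeptide_scan(c: ComplexSpec, windows: list[CDRWindow],
                             config: EnergyConfig | None = None,
                             mode: str = "rank", top_k: int = 3,
                             threshold: float | None = None
                             ) -> list[DeltaGReport]:
    """Alanine-hexapeptide scan of candidate CDR windows.

    Each window is mutated to AAAAAA on the fixed backbone, the binding
    score recomputed, and the loss dG(A6) - dG(wt) recorded. Selection:
    ``mode="rank"`` keeps the ``top_k`` largest losses (ties broken
    N-terminal-first); ``mode="threshold"`` keeps losses >= ``threshold``.
    Reports are returned in the input window order.
    """
    if mode not in ("rank", "threshold"):
        raise ValueError(f"unknown selection mode {mode!r}")
    if mode == "threshold" and threshold is None:
        raise ValueError("threshold mode needs a threshold value")
    config = config or EnergyConfig()
    dg_wt = interaction_energy(c, config)
    reports: list[DeltaGReport] = []
    for window in windows:
        try:
            mutant = graftlab.mutate_window(
                c.structure, (window.chain_id, window.start), "AAAAAA")
            mutant_spec = ComplexSpec(
                structure=mutant, receptor_chains=c.receptor_chains,
                ligand_chains=c.ligand_chains, cdrs=c.cdrs,
                window_prefix=c.window_prefix)
            dg_ala6 = interaction_energy(mutant_spec, config)
            reports.append(DeltaGReport(window=window, dg_wt=dg_wt,
                                        dg_ala6=dg_ala6))
        except Exception as exc:
            warnings.warn(f"mutation failed for {window.name}: {exc}")
            reports.append(DeltaGReport(window=window, dg_wt=dg_wt,
                                        dg_ala6=dg_wt, failed=True))
    ok = [r for r in reports if not r.failed]
    if mode == "rank":
        ranked = sorted(ok, key=lambda r: (-r.loss, r.window.chain_id,
                                           r.window.start))
        for r in ranked[:top_k]:
            r.selected = True
    else:
        for r in ok:
            r.selected = r.loss >= threshold
    return reports


def scan_to_dataframe(reports: list[DeltaGReport]):
    import pandas as pd

    rows = []
    for r in reports:
        rows.append({
            "window": r.window.name,
            "chain": r.window.chain_id,
            "start": r.window.start,
            "seq": r.window.sequence,
            "contacts": r.window.contact_count,
            "dG_wt": round(r.dg_wt, 4),
            "dG_ala6": round(r.dg_ala6, 4),
            "loss": round(r.loss, 4),
            "selected": r.selected,
            "failed": r.failed,
        })
    return pd.DataFrame(rows)
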
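"""Candidate hexapeptide graft-site enumeration and filtering.

A graft site is a six-residue loop window flanked by secondary-structure
anchors (α-helix, β-strand, or a disulfide-bonded cysteine). Candidate
windows pass through two filters mirroring the scaffold funnel:

* SA — solvent accessible: every residue's SASA strictly above
  ``sasa_min`` (default 15 A²);
* constrained / CSA — mean heavy-atom RMSF of the window below 1.5 A
  (constrained) and below 1.0 A (constrained *and* solvent accessible).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .flexengine import FluctuationProfile, site_mean_rmsf
from .structure import SASAProfile, SSAnnotation, Structure

FLANK_STRAND = "S"
FLANK_HELIX = "H"
FLANK_CYS = "C"


@dataclass
class HexSite:
    """A candidate 6-residue graft site in a scaffold chain."""

    scaffold_id: str
    chain_id: str
    start: int                      # author number of the first residue
    icode: str = ""
    sequence: str = ""
    n_flank: str = ""               # S | H | C
    c_flank: str = ""
    sasa: tuple[float, ...] = ()    # per-residue, 6 values once filled
    mean_rmsf: float | None = None
    ca_dist: float | None = None
    name: str | None = None         # e.g. "Sca8-1", assigned post-filter

    def __post_init__(self) -> None:
        if self.sequence and len(self.sequence) != 6:
            raise ValueError("hexapeptide site must have exactly 6 residues")
        for f in (self.n_flank, self.c_flank):
            if f and f not in (FLANK_STRAND, FLANK_HELIX, FLANK_CYS):
                raise ValueError(f"invalid flank type {f!r}")

    @property
    def motif(self) -> str:
        """Motif class, e.g. SLS (strand-loop-strand) or CLH."""
        return f"{self.n_flank}L{self.c_flank}"

    def residue_keys(self) -> list[tuple[str, int, str]]:
        return [(self.chain_id, self.start + k, "") for k in range(6)]

    def resolve_keys(self, s: Structure) -> list[tuple[str, int, str]]:
        """Residue keys via positional offsets (robust to insertion codes)."""
        chain = s.chain(self.chain_id)
        i0 = chain.index_of(self.start, self.icode)
        return [(self.chain_id, chain.residues[i0 + k].number,
                 chain.residues[i0 + k].icode) for k in range(6)]


@dataclass
class SiteCriteria:
    """Selection thresholds for the site funnel."""

    sasa_min: float = 15.0          # A^2, strictly greater-than
    rmsf_constrained: float = 1.5   # A
    rmsf_csa: float = 1.0           # A
    mode: str = "windowed"          # "strict" | "windowed"
    flank_reach: int = 2            # residues, windowed mode

    def __post_init__(self) -> None:
        if not (0 < self.rmsf_csa <= self.rmsf_constrained):
            raise ValueError("require 0 < rmsf_csa <= rmsf_constrained")
        if self.sasa_min < 0:
            raise ValueError("sasa_min must be non-negative")
        if self.mode not in ("strict", "windowed"):
            raise ValueError(f"unknown enumeration mode {self.mode!r}")
        if self.flank_reach < 1:
            raise ValueError("flank_reach must be >= 1")


def _flank_type(res, state: str, ss: SSAnnotation, key) -> str | None:
    """Anchor letter for a residue, or None if it cannot anchor a loop.

    A strand or helix letter wins over disulfide-cysteine when both
    apply, so SLC/CLH/... remain distinct minority motifs.
    """
    if state == "E":
        return FLANK_STRAND
    if state == "H":
        return FLANK_HELIX
    if res.name == "CYS" and ss.is_disulfide_cys(key):
        return FLANK_CYS
    return None


def enumerate_loop_hexapeptides(s: Structure, ss: SSAnnotation,
                                mode: str = "windowed",
                                flank_reach: int = 2) -> list[HexSite]:
    """All candidate hexapeptide sites in loop regions of ``s``.

    strict mode: one site per maximal coil run of length exactly 6 whose
    immediate neighbours both anchor (H/E/disulfide-Cys). A
    disulfide-bonded cysteine acts as a loop *boundary* even when its
    own state is coil — it is a covalent anchor, which is what makes
    CLC/CLS/SLC motifs possible.

    windowed mode: every 6-residue window inside a coil run such that an
    anchoring residue lies within ``flank_reach`` intervening coil
    residues of each window end (the nearest anchor defines the flank
    letter); an 8-residue loop between anchors thus yields 3 sites at
    reach 2.
    """
    sites: list[HexSite] = []
    state_of = dict(zip(ss.residue_keys, ss.states))
    for chain in s.chains:
        residues = chain.standard_residues()
        keys = [(chain.id, r.number, r.icode) for r in residues]
        states = [state_of[k] for k in keys]
        n = len(residues)

        def anchor(idx: int) -> str | None:
            if idx < 0 or idx >= n:
                return None
            return _flank_type(residues[idx], states[idx], ss, keys[idx])

        # maximal coil runs; anchor-capable residues (incl. coil-state
        # disulfide cysteines) terminate a run
        def is_loop(idx: int) -> bool:
            return states[idx] == "C" and anchor(idx) is None

        runs: list[tuple[int, int]] = []
        i = 0
        while i < n:
            if is_loop(i):
                j = i
                while j + 1 < n and is_loop(j + 1):
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1

        for lo, hi in runs:
            length = hi - lo + 1
            if mode == "strict":
                if length != 6:
                    continue
                nf, cf = anchor(lo - 1), anchor(hi + 1)
                if nf and cf:
                    sites.append(_make_site(s, chain, residues, lo, nf, cf))
            else:
                for w in range(lo, hi - 4):
                    nf = cf = None
                    for d in range(1, flank_reach + 2):
                        nf = nf or anchor(w - d)
                        cf = cf or anchor(w + 5 + d)
                    if nf and cf:
                        sites.append(_make_site(s, chain, residues, w, nf, cf))
    return sites


def _make_site(s: Structure, chain, residues, w: int, nf: str, cf: str) -> HexSite:
    window = residues[w:w + 6]
    site = HexSite(
        scaffold_id=s.id,
        chain_id=chain.id,
        start=window[0].number,
        icode=window[0].icode,
        sequence="".join(r.one_letter for r in window),
        n_flank=nf,
        c_flank=cf,
    )
    site.ca_dist = ca_distance(s, site)
    return site


def filter_solvent_accessible(sites: list[HexSite], sasa: SASAProfile,
                              criteria: SiteCriteria) -> list[HexSite]:
    """Keep sites whose six residues all have SASA strictly above
    ``criteria.sasa_min`` (exactly 15.0 A² is rejected)."""
    kept = []
    for site in sites:
        vals = []
        for key in site.residue_keys():
            if key not in sasa.values:
                raise KeyError(f"residue {key} missing from SASA profile")
            vals.append(sasa.values[key])
        site = replace(site, sasa=tuple(round(v, 3) for v in vals))
        if all(v > criteria.sasa_min for v in vals):
            kept.append(site)
    return kept


def filter_constrained(sites: list[HexSite], profile: FluctuationProfile,
                       criteria: SiteCriteria
                       ) -> tuple[list[HexSite], list[HexSite]]:
    """Split sites by mean heavy-atom RMSF: (constrained, CSA) lists.

    constrained: mean < rmsf_constrained; CSA: mean < rmsf_csa.
    CSA is always a subset of constrained.
    """
    constrained, csa = [], []
    for site in sites:
        mean = site_mean_rmsf(profile, site)
        site = replace(site, mean_rmsf=round(mean, 4))
        if mean < criteria.rmsf_constrained:
            constrained.append(site)
            if mean < criteria.rmsf_csa:
                csa.append(site)
    return constrained, csa


def ca_distance(s: Structure, site: HexSite) -> float:
    """Distance (A) between the Cα atoms of the site's first and sixth
    residues — the peptide deflection measure."""
    keys = site.resolve_keys(s)
    chain = s.chain(site.chain_id)
    first = chain.residue(keys[0][1], keys[0][2])
    sixth = chain.residue(keys[5][1], keys[5][2])
    ca1 = first.atom("CA") if first else None
    ca6 = sixth.atom("CA") if sixth else None
    if ca1 is None or ca6 is None:
        raise ValueError("site lacks a Cα atom at position 1 or 6")
    return float(np.linalg.norm(ca1.coord - ca6.coord))


def assign_site_names(sites: list[HexSite]) -> list[HexSite]:
    """Stable "[scaffold]-[ordinal]" names, ordinals counted from the
    N-terminus within each scaffold (chain order, then position)."""
    bucket: dict[str, list[HexSite]] = {}
    for site in sites:
        bucket.setdefault(site.scaffold_id, []).append(site)
    named = []
    for scaffold_id, group in bucket.items():
        group = sorted(group, key=lambda t: (t.chain_id, t.start, t.icode))
        for k, site in enumerate(group, start=1):
            named.append(replace(site, name=f"{scaffold_id}-{k}"))
    return named


def site_key(site: HexSite) -> tuple[str, str, int, str]:
    return (site.scaffold_id, site.chain_id, site.start, site.icode)


def sites_to_dataframe(sites: list[HexSite], flags: dict[str, set] | None = None):
    """Tabular site report; ``flags`` maps a flag name (SA, constrained,
    CSA) to the set of :func:`site_key` values holding that flag."""
    import pandas as pd

    rows = []
    for site in sites:
        row = {
            "scaffold": site.scaffold_id,
            "site_name": site.name or "",
            "chain": site.chain_id,
            "start": site.start,
            "seq": site.sequence,
            "motif": site.motif,
            "min_res_sasa": min(site.sasa) if site.sasa else np.nan,
            "mean_rmsf": site.mean_rmsf if site.mean_rmsf is not None else np.nan,
            "ca1_ca6_dist": round(site.ca_dist, 3) if site.ca_dist is not None else np.nan,
        }
        for flag, members in (flags or {}).items():
            row[flag] = site_key(site) in members
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["scaffold", "site_name", "chain", "start",
                                     "seq", "motif", "min_res_sasa", "mean_rmsf",
                                     "ca1_ca6_dist", *(flags or {})])
    return pd.DataFrame(rows)
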
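"""In-silico mutagenesis and graft evaluation.

Implements the validation and design stages of the grafting pipeline:

* window mutagenesis on a fixed backbone (side chains rebuilt from
  ideal templates with a discrete rotamer search);
* homo-hexapeptide RMSF profiling — a candidate site is a graft
  acceptor (GA) only if every one of the 20 homo-hexapeptides grafted
  into it stays below the constrained-RMSF threshold;
* cross-product design construction (GA sites x CDR hexapeptides) and
  heavy-atom RMSD of a grafted peptide against its source conformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .flexengine import FluctuationProfile, site_mean_rmsf
from .geometry import rmsd as _kabsch_rmsd
from .sidechains import build_residue, clash_count
from .sitefinder import HexSite, SiteCriteria
from .structure import AA1_TO_3, Structure

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def enumerate_homohexapeptides() -> list[str]:
    """The 20 homo-hexapeptides (A6 ... Y6) in one-letter alphabetical
    order; G6 is the smallest, W6 the bulkiest, I6 the most hydrophobic,
    E6 the most acidic and R6 the most basic probe of a site's
    immobilising capacity."""
    return [aa * 6 for aa in AA_ALPHABET]


def hexapeptide_space_size(alphabet_size: int = 20, length: int = 6) -> int:
    """Number of theoretical peptide species: alphabet^length
    (20^6 = 6.4e7 hexapeptides)."""
    if alphabet_size < 1 or length < 1:
        raise ValueError("alphabet size and length must be positive integers")
    return alphabet_size ** length


def mutate_window(s: Structure, site: HexSite | tuple[str, int],
                  new_seq: str) -> Structure:
    """Replace the six residues of ``site`` with ``new_seq`` on a fixed
    backbone.

    Backbone N/CA/C/O coordinates are untouched. A residue whose type
    already matches keeps all its atoms; otherwise the side chain is
    rebuilt from the ideal template in the least-clashing rotamer
    (chi1/chi2 grid) against the rest of the structure.
    """
    if len(new_seq) != 6:
        raise ValueError("grafted sequence must have exactly 6 residues")
    bad = [a for a in new_seq.upper() if a not in AA1_TO_3]
    if bad:
        raise ValueError(f"invalid amino-acid letters: {bad}")
    if isinstance(site, tuple):
        chain_id, start = site
        site = HexSite(scaffold_id=s.id, chain_id=chain_id, start=start)
    out = s.copy()
    chain = out.chain(site.chain_id)
    i0 = chain.index_of(site.start, site.icode)
    if i0 + 6 > len(chain.residues):
        raise IndexError("site window extends beyond chain end")

    for k, aa in enumerate(new_seq.upper()):
        res = chain.residues[i0 + k]
        new_name = AA1_TO_3[aa]
        if res.name == new_name:
            continue
        bb = {nm: res.atom(nm) for nm in ("N", "CA", "C", "O")}
        if bb["N"] is None or bb["CA"] is None or bb["C"] is None:
            raise ValueError(
                f"residue {res.number}{res.icode}: backbone incomplete, cannot graft"
            )
        o = bb["O"].coord if bb["O"] is not None else bb["C"].coord + np.array([0, 0, 1.23])
        env_pts, env_vdw = [], []
        for c2, r2, a2 in out.iter_atoms():
            if r2 is res:
                continue
            env_pts.append(a2.coord)
            env_vdw.append(a2.vdw)
        new_res = build_residue(
            new_name, bb["N"].coord, bb["CA"].coord, bb["C"].coord, o,
            number=res.number, icode=res.icode,
            environment=np.array(env_pts), env_vdw=np.array(env_vdw),
        )
        chain.residues[i0 + k] = new_res
    return out


def structure_clash_count(s: Structure) -> int:
    """Total heavy-atom clash pairs between non-adjacent residues."""
    coords = s.coords()
    vdw = s.vdw()
    keys = s.atom_residue_keys()
    order: dict[tuple, int] = {}
    for k in keys:
        order.setdefault(k, len(order))
    from scipy.spatial import cKDTree

    tree = cKDTree(coords)
    total = 0
    for i, j in tree.query_pairs(0.75 * (2 * vdw.max())):
        ki, kj = keys[i], keys[j]
        if ki == kj:
            continue
        if ki[0] == kj[0] and abs(order[ki] - order[kj]) == 1:
            continue
        if np.linalg.norm(coords[i] - coords[j]) < 0.75 * (vdw[i] + vdw[j]):
            total += 1
    return total


@dataclass
class GAProfile:
    """RMSF profile of one site under all 20 homo-hexapeptide grafts."""

    site: HexSite
    entries: dict[str, float]          # amino-acid letter -> mean RMSF (A)
    threshold: float                   # constrained-RMSF criterion (A)
    incomplete: bool = False

    def __post_init__(self) -> None:
        if not self.incomplete and len(self.entries) != 20:
            raise ValueError("complete profile must have exactly 20 entries")

    @property
    def verdict(self) -> str | None:
        """"GA" when every homo-hexapeptide stays below the threshold;
        None while the profile is incomplete."""
        if self.incomplete:
            return None
        return "GA" if max(self.entries.values()) < self.threshold else "not-GA"


def profile_site(s: Structure, site: HexSite,
                 backend: Callable[[Structure], FluctuationProfile],
                 criteria: SiteCriteria | None = None,
                 csa_checked: bool = True) -> GAProfile:
    """Homo-hexapeptide RMSF profiling of one candidate site.

    Each of the 20 homo-hexapeptides is grafted with
    :func:`mutate_window`; ``backend`` maps the mutated structure to a
    fluctuation profile (it should carry a fixed, pre-computed
    calibration so all variants share one scale). Backend failure on
    any variant leaves the profile incomplete with no verdict.
    """
    criteria = criteria or SiteCriteria()
    if not csa_checked:
        warnings.warn(f"profiling site {site.name or site.start} that did not "
                      "pass the CSA filter")
    entries: dict[str, float] = {}
    incomplete = False
    for seq in enumerate_homohexapeptides():
        try:
            mutant = mutate_window(s, site, seq)
            prof = backend(mutant)
            entries[seq[0]] = round(site_mean_rmsf(prof, site), 4)
        except Exception as exc:
            warnings.warn(f"backend failed on {seq}: {exc}")
            incomplete = True
    return GAProfile(site=site, entries=entries,
                     threshold=criteria.rmsf_constrained, incomplete=incomplete)


@dataclass
class GraftDesign:
    """One grafted antibody-mimetic candidate."""

    name: str                       # "[GA site]-[peptide]", e.g. Sca8-1-TH3
    scaffold_id: str
    site: HexSite
    peptide_name: str
    sequence: str
    structure: Structure = field(repr=False)
    mean_rmsf: float | None = None  # grafted-window mean (A)
    rmsd: float | None = None       # heavy-atom RMSD vs source CDR (A)


def build_designs(ga_sites: list[HexSite], cdr_peps: list[tuple[str, str]],
                  scaffolds: dict[str, Structure],
                  backend: Callable[[Structure], FluctuationProfile] | None = None,
                  ) -> list[GraftDesign]:
    """Full cross product of GA sites and CDR hexapeptides.

    ``cdr_peps`` is a list of (name, 6-letter sequence); 5 peptides on
    13 sites give the 65-candidate design set. Each design carries the
    grafted structure and, when ``backend`` is given, the grafted
    window's mean RMSF.
    """
    if not ga_sites or not cdr_peps:
        raise ValueError("need at least one GA site and one peptide")
    designs = []
    seen: set[str] = set()
    for site in ga_sites:
        host = scaffolds[site.scaffold_id]
        for pep_name, pep_seq in cdr_peps:
            name = f"{site.name or site.scaffold_id}-{pep_name}"
            if name in seen:
                raise ValueError(f"duplicate design name {name}")
            seen.add(name)
            grafted = mutate_window(host, site, pep_seq)
            mean = None
            if backend is not None:
                mean = round(site_mean_rmsf(backend(grafted), site), 4)
            designs.append(GraftDesign(
                name=name, scaffold_id=site.scaffold_id, site=site,
                peptide_name=pep_name, sequence=pep_seq.upper(),
                structure=grafted, mean_rmsf=mean,
            ))
    return designs


def _window_atoms(s: Structure, chain_id: str, start: int, icode: str = ""
                  ) -> dict[tuple[int, str], dict[str, np.ndarray]]:
    chain = s.chain(chain_id)
    i0 = chain.index_of(start, icode)
    out = {}
    for k in range(6):
        res = chain.residues[i0 + k]
        out[(k, res.name)] = {a.name: a.coord for a in res.atoms}
    return out


def graft_rmsd(design_structure: Structure, design_site: HexSite,
               source: Structure, source_chain: str, source_start: int,
               source_icode: str = "") -> float:
    """Heavy-atom RMSD between a grafted hexapeptide and its source CDR
    conformation after optimal (Kabsch) superposition on the shared
    heavy atoms of the two windows."""
    win_a = _window_atoms(design_structure, design_site.chain_id,
                          design_site.start, design_site.icode)
    win_b = _window_atoms(source, source_chain, source_start, source_icode)
    if set(win_a) != set(win_b):
        raise ValueError("window sequences differ; graft RMSD undefined")
    pa, pb = [], []
    for key in sorted(win_a):
        shared = sorted(set(win_a[key]) & set(win_b[key]))
        if not {"N", "CA", "C"} <= set(shared):
            raise ValueError("windows share fewer than the backbone atoms")
        for nm in shared:
            pa.append(win_a[key][nm])
            pb.append(win_b[key][nm])
    return _kabsch_rmsd(np.array(pa), np.array(pb))


def designs_to_dataframe(designs: list[GraftDesign], criteria: SiteCriteria | None = None):
    import pandas as pd

    criteria = criteria or SiteCriteria()
    rows = []
    for d in designs:
        rows.append({
            "design": d.name,
            "scaffold": d.scaffold_id,
            "site": d.site.name or f"{d.site.chain_id}:{d.site.start}",
            "peptide": d.peptide_name,
            "seq": d.sequence,
            "mean_rmsf_A": d.mean_rmsf,
            "rmsd_A": d.rmsd,
            "constrained": (d.mean_rmsf is not None
                            and d.mean_rmsf < criteria.rmsf_constrained),
        })
    return pd.DataFrame(rows)
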
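"""Pipeline stages behind the command-line interface.

Each stage is an ordinary function over :class:`flap.config.RunConfig`
so the library can be driven programmatically (tests, notebooks) and
the CLI stays a thin wrapper. Reports are TSV with a ``#`` comment
header carrying the config hash, package version and backend
calibration, so every number in a report is traceable to its run.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import __version__, fixtures, flexengine, graftlab, paratope, sitefinder, structio
from .config import RunConfig
from .flexengine import FluctuationProfile
from .structure import SASAProfile, Structure


# ---------------------------------------------------------------------------
# report plumbing
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path, cfg: RunConfig,
               calibration: float | None = None) -> None:
    header = [
        f"# flapkit {__version__}",
        f"# config_hash {cfg.config_hash}",
    ]
    if calibration is not None:
        header.append(f"# backend_calibration_A_per_mode {calibration:.6f}")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _write_summary(path: Path, cfg: RunConfig, payload: dict) -> None:
    payload = dict(payload)
    payload.update({"tool_version": __version__, "config_hash": cfg.config_hash,
                    "seed": cfg.seed})
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _echo_config(cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.yaml").write_text(cfg.resolved_yaml())


# ---------------------------------------------------------------------------
# backend factory
# ---------------------------------------------------------------------------

def make_backend(cfg: RunConfig, scaffolds: dict[str, Structure]
                 ) -> tuple[Callable[[Structure], FluctuationProfile], float | None]:
    """Build the fluctuation backend callable and its calibration.

    ENM: the calibration constant is taken from the config or computed
    once on the reference scaffold (median residue RMSF equal to the
    configured target), then applied to every structure of the run.

    Ensemble: profiles come from the configured multi-model PDB per
    scaffold id; structures without an ensemble (e.g. in-silico
    mutants) cannot be profiled by this backend.
    """
    b = cfg.backend
    if b.kind == "enm":
        cal = b.calibration
        if cal is None:
            ref_id = b.reference or next(iter(scaffolds))
            if ref_id not in scaffolds:
                raise ValueError(f"calibration reference {ref_id!r} not among scaffolds")
            ref_profile = flexengine.rmsf_from_enm(
                scaffolds[ref_id], cutoff=b.cutoff, weighting=b.weighting,
                contact_cutoff=b.contact_cutoff,
                calibration_target=b.calibration_target)
            cal = ref_profile.calibration

        def backend(s: Structure) -> FluctuationProfile:
            return flexengine.rmsf_from_enm(
                s, cutoff=b.cutoff, weighting=b.weighting,
                contact_cutoff=b.contact_cutoff, calibration=cal)

        return backend, cal

    ensembles = dict(b.ensembles)

    def backend(s: Structure) -> FluctuationProfile:
        if s.id not in ensembles:
            raise ValueError(
                f"no ensemble registered for structure {s.id!r}; the ensemble "
                "backend cannot profile in-silico mutants")
        ref, frames = structio.read_ensemble_coords(ensembles[s.id])
        ens = flexengine.Ensemble(reference=ref, frames=frames)
        return flexengine.rmsf_from_ensemble(ens)

    return backend, None


def _residue_sasa(cfg: RunConfig, s: Structure) -> SASAProfile:
    prof = structio.compute_sasa(s, probe=cfg.sasa.probe, n_points=cfg.sasa.n_points)
    if cfg.sasa.mode == "exposed":
        return prof
    # buried_delta: isolated-residue SASA minus in-context SASA
    from .structure import Chain

    values = {}
    for c, r in s.iter_residues():
        lone = Structure(id="res", chains=[Chain(id=c.id, residues=[r])])
        iso = structio.compute_sasa(lone, probe=cfg.sasa.probe,
                                    n_points=cfg.sasa.n_points)
        key = (c.id, r.number, r.icode)
        values[key] = iso.total - prof.values.get(key, 0.0)
    return SASAProfile(values=values, probe_radius=cfg.sasa.probe,
                       n_points=cfg.sasa.n_points)


# ---------------------------------------------------------------------------
# stage 1: scaffold scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    scaffolds: dict[str, Structure] = field(default_factory=dict)
    csa_sites: list[sitefinder.HexSite] = field(default_factory=list)
    funnel: dict[str, dict[str, int]] = field(default_factory=dict)
    calibration: float | None = None
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def total_funnel(self) -> dict[str, int]:
        out = {"enumerated": 0, "sa": 0, "constrained": 0, "csa": 0}
        for counts in self.funnel.values():
            for k in out:
                out[k] += counts[k]
        return out


def scan_scaffolds(cfg: RunConfig, out_dir: str | Path | None = None) -> ScanResult:
    """Run the site funnel (enumerate -> SA -> constrained -> CSA) over
    every scaffold; per-scaffold failures are isolated and recorded."""
    t0 = time.time()
    result = ScanResult()
    loaded: dict[str, Structure] = {}
    for path in cfg.scaffolds:
        try:
            s = structio.read_structure(path)
            loaded[s.id] = s
        except Exception as exc:
            result.failures[str(path)] = str(exc)
    result.scaffolds = loaded
    if not loaded:
        raise ValueError("no scaffold could be read")
    backend, calibration = make_backend(cfg, loaded)
    result.calibration = calibration

    all_rows = []
    for sid, s in loaded.items():
        try:
            pairs = structio.find_disulfides(s)
            ss = structio.assign_secondary_structure(
                s, disulfides=structio.disulfide_map(pairs))
            sasa = _residue_sasa(cfg, s)
            enumerated = sitefinder.enumerate_loop_hexapeptides(
                s, ss, mode=cfg.criteria.mode, flank_reach=cfg.criteria.flank_reach)
            sa = sitefinder.filter_solvent_accessible(enumerated, sasa, cfg.criteria)
            profile = backend(s)
            constrained, csa = sitefinder.filter_constrained(sa, profile, cfg.criteria)
            result.funnel[sid] = {
                "enumerated": len(enumerated), "sa": len(sa),
                "constrained": len(constrained), "csa": len(csa),
            }
            named = sitefinder.assign_site_names(csa)
            result.csa_sites.extend(named)
            flags = {
                "SA": {sitefinder.site_key(x) for x in sa},
                "constrained": {sitefinder.site_key(x) for x in constrained},
                "CSA": {sitefinder.site_key(x) for x in csa},
            }
            # report every enumerated site once, with the SA copy (which
            # carries the per-residue SASA) preferred and CSA sites named
            by_key = {sitefinder.site_key(x): x for x in enumerated}
            by_key.update({sitefinder.site_key(x): x for x in sa})
            by_key.update({sitefinder.site_key(x): x for x in constrained})
            by_key.update({sitefinder.site_key(x): x for x in named})
            all_rows.append(sitefinder.sites_to_dataframe(
                sorted(by_key.values(), key=lambda t: (t.chain_id, t.start, t.icode)),
                flags))
        except Exception as exc:
            result.failures[sid] = str(exc)

    if out_dir is not None:
        out = Path(out_dir)
        _echo_config(cfg, out)
        df = (pd.concat(all_rows, ignore_index=True)
              if all_rows else sitefinder.sites_to_dataframe([]))
        _write_tsv(df, out / "sites.tsv", cfg, calibration)
        _write_summary(out / "scan_summary.json", cfg, {
            "funnel_per_scaffold": result.funnel,
            "funnel_total": result.total_funnel,
            "failures": result.failures,
            "backend_calibration": calibration,
            "elapsed_s": round(time.time() - t0, 3),
        })
    return result


# ---------------------------------------------------------------------------
# stage 2: homo-hexapeptide profiling
# ---------------------------------------------------------------------------

@dataclass
class GAResult:
    profiles: list[graftlab.GAProfile] = field(default_factory=list)
    ga_sites: list[sitefinder.HexSite] = field(default_factory=list)
    calibration: float | None = None


def profile_ga(cfg: RunConfig, scan: ScanResult,
               out_dir: str | Path | None = None) -> GAResult:
    """20-homo-hexapeptide RMSF profiling of every CSA site; a site is a
    graft acceptor (GA) when all 20 grafted profiles stay constrained."""
    t0 = time.time()
    if not scan.csa_sites:
        raise ValueError("no CSA sites to profile; run the scaffold scan first")
    backend, calibration = make_backend(cfg, scan.scaffolds)
    if calibration is None and scan.calibration is None and cfg.backend.kind == "ensemble":
        raise ValueError("RMSF profiling of mutants needs the ENM backend")
    result = GAResult(calibration=calibration)
    rows = []
    for site in scan.csa_sites:
        host = scan.scaffolds[site.scaffold_id]
        prof = graftlab.profile_site(host, site, backend, cfg.criteria)
        result.profiles.append(prof)
        if prof.verdict == "GA":
            result.ga_sites.append(site)
        row = {"site": site.name, "scaffold": site.scaffold_id,
               "chain": site.chain_id, "start": site.start,
               "motif": site.motif, "ca1_ca6_dist": round(site.ca_dist, 3)}
        row.update({aa: prof.entries.get(aa, np.nan) for aa in graftlab.AA_ALPHABET})
        row["max_rmsf"] = (round(max(prof.entries.values()), 4)
                           if prof.entries else np.nan)
        row["verdict"] = prof.verdict or "incomplete"
        rows.append(row)
    if out_dir is not None:
        out = Path(out_dir)
        _write_tsv(pd.DataFrame(rows), out / "ga_profile.tsv", cfg, calibration)
        _write_summary(out / "ga_summary.json", cfg, {
            "n_csa": len(scan.csa_sites),
            "n_ga": len(result.ga_sites),
            "ga_sites": [s.name for s in result.ga_sites],
            "backend_calibration": calibration,
            "elapsed_s": round(time.time() - t0, 3),
        })
    return result


# ---------------------------------------------------------------------------
# stage 3: CDR hexapeptide extraction
# ---------------------------------------------------------------------------

@dataclass
class CDRResult:
    complex_spec: paratope.ComplexSpec | None = None
    contacts: dict[str, set[int]] = field(default_factory=dict)
    windows: list[paratope.CDRWindow] = field(default_factory=list)
    reports: list[paratope.DeltaGReport] = field(default_factory=list)

    @property
    def selected(self) -> list[paratope.DeltaGReport]:
        return [r for r in self.reports if r.selected]


def extract_cdr(cfg: RunConfig, out_dir: str | Path | None = None) -> CDRResult:
    """Contact mapping, CDR window enumeration and the alanine-
    hexapeptide binding-energy scan on the configured complex."""
    t0 = time.time()
    cx = cfg.complex
    if not cx.path:
        raise ValueError("no complex configured")
    s = structio.read_structure(cx.path)
    spec = paratope.ComplexSpec(
        structure=s, receptor_chains=cx.receptor_chains,
        ligand_chains=cx.ligand_chains,
        cdrs={cid: [paratope.CDRRange(*r) for r in ranges]
              for cid, ranges in cx.cdrs.items()},
        window_prefix=dict(cx.prefix))
    contacts = paratope.find_contact_residues(spec, cutoff=cfg.energy.contact_cutoff)
    windows = paratope.enumerate_cdr_windows(spec, contacts, require_contact=True)
    reports = paratope.alanine_hexapeptide_scan(
        spec, windows, cfg.energy, mode=cfg.selection.mode,
        top_k=cfg.selection.top_k, threshold=cfg.selection.threshold)
    result = CDRResult(complex_spec=spec, contacts=contacts,
                       windows=windows, reports=reports)
    if not any(contacts.values()):
        warnings.warn("empty interface: no CDR hexapeptide can be selected")
    if out_dir is not None:
        out = Path(out_dir)
        _echo_config(cfg, out)
        _write_tsv(paratope.scan_to_dataframe(reports), out / "cdr_scan.tsv", cfg)
        fasta = []
        for r in result.selected:
            fasta.append(f">{r.window.name} chain={r.window.chain_id} "
                         f"start={r.window.start} loss={r.loss:.4f}")
            fasta.append(r.window.sequence)
        (out / "selected_peptides.fasta").write_text(
            "\n".join(fasta) + ("\n" if fasta else ""))
        contact_rows = [{"chain": cid, "resnum": num}
                        for cid, nums in sorted(contacts.items())
                        for num in sorted(nums)]
        _write_tsv(pd.DataFrame(contact_rows, columns=["chain", "resnum"]),
                   out / "contact_map.tsv", cfg)
        _write_summary(out / "cdr_summary.json", cfg, {
            "n_windows": len(windows),
            "n_selected": len(result.selected),
            "selected": [r.window.name for r in result.selected],
            "longest_contact_runs": {
                cid: paratope.longest_contact_run(
                    nums, [res.number for res in s.chain(cid).residues])
                for cid, nums in contacts.items()},
            "elapsed_s": round(time.time() - t0, 3),
        })
    return result


# ---------------------------------------------------------------------------
# stage 4: design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignResult:
    designs: list[graftlab.GraftDesign] = field(default_factory=list)
    calibration: float | None = None


def design(cfg: RunConfig, ga: GAResult, cdr: CDRResult, scan: ScanResult,
           out_dir: str | Path | None = None,
           write_structures: bool = True) -> DesignResult:
    """Cross-product grafting of selected CDR hexapeptides into GA
    sites, with grafted-window RMSF and heavy-atom RMSD vs the source
    CDR conformation; designs are ranked by (RMSF, RMSD)."""
    t0 = time.time()
    if not ga.ga_sites:
        raise ValueError("no GA sites; nothing to design")
    if not cdr.selected:
        raise ValueError("no selected CDR hexapeptides; nothing to design")
    backend, calibration = make_backend(cfg, scan.scaffolds)
    peptides = [(r.window.name, r.window.sequence) for r in cdr.selected]
    designs = graftlab.build_designs(ga.ga_sites, peptides, scan.scaffolds,
                                     backend=backend)
    source = cdr.complex_spec.structure
    win_by_name = {r.window.name: r.window for r in cdr.selected}
    for d in designs:
        w = win_by_name[d.peptide_name]
        d.rmsd = round(graftlab.graft_rmsd(d.structure, d.site, source,
                                           w.chain_id, w.start), 4)
    designs.sort(key=lambda d: (d.mean_rmsf if d.mean_rmsf is not None else 1e9,
                                d.rmsd if d.rmsd is not None else 1e9, d.name))
    result = DesignResult(designs=designs, calibration=calibration)
    if out_dir is not None:
        out = Path(out_dir)
        _echo_config(cfg, out)
        _write_tsv(graftlab.designs_to_dataframe(designs, cfg.criteria),
                   out / "designs.tsv", cfg, calibration)
        if write_structures:
            pdb_dir = out / "designs"
            pdb_dir.mkdir(parents=True, exist_ok=True)
            for d in designs:
                structio.write_structure(
                    d.structure, pdb_dir / f"{d.name}.pdb",
                    remarks=[f"flapkit {__version__} design {d.name}",
                             f"config_hash {cfg.config_hash}"])
        _write_summary(out / "design_summary.json", cfg, {
            "n_designs": len(designs),
            "n_ga_sites": len(ga.ga_sites),
            "n_peptides": len(peptides),
            "backend_calibration": calibration,
            "elapsed_s": round(time.time() - t0, 3),
        })
    return result


# ---------------------------------------------------------------------------
# fixture set
# ---------------------------------------------------------------------------

def generate_fixture_set(out_dir: str | Path, seed: int = 0) -> dict:
    """Write the standard synthetic fixture set and a ready-to-run
    configuration: two hairpin scaffolds (clamped = immobilised loop,
    open = mobile loop), a helix, a linear peptide, the toy antibody-
    antigen complex, and a jittered ensemble of the clamped scaffold."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    specs = {
        "clamped_hairpin": fixtures.FixtureSpec(kind="clamped_hairpin", seed=seed),
        "hairpin": fixtures.FixtureSpec(kind="hairpin", seed=seed),
        "helix": fixtures.FixtureSpec(kind="helix", length=12, seed=seed),
        "linear_peptide": fixtures.FixtureSpec(
            kind="linear_peptide", length=6, sequence="GSSSSG", seed=seed),
        "toy_complex": fixtures.FixtureSpec(kind="toy_complex", seed=seed),
    }
    manifest: dict = {"seed": seed, "structures": {}}
    for name, spec in specs.items():
        s = fixtures.build_structure(spec)
        s.id = name
        structio.write_structure(s, out / f"{name}.pdb",
                                 remarks=[f"flapkit fixture {name} seed={seed}"])
        manifest["structures"][name] = fixtures.manifest(spec)

    ens_spec = fixtures.FixtureSpec(kind="clamped_hairpin", seed=seed,
                                    jitter={"all": 0.2})
    ens = fixtures.build_ensemble(ens_spec, frames=60)
    structio.write_ensemble(ens.reference, ens.frames,
                            out / "clamped_hairpin_ensemble.pdb",
                            remarks=[f"flapkit fixture ensemble seed={seed}"])
    manifest["ensemble"] = {"kind": "clamped_hairpin", "frames": 60,
                            "jitter_sigma_A": 0.2, "seed": seed}

    contacts = specs["toy_complex"].contact_positions
    cfg = {
        "seed": seed,
        "out_dir": str(out / "run"),
        "scaffolds": [str(out / "clamped_hairpin.pdb"), str(out / "hairpin.pdb")],
        # selection-funnel thresholds, all explicit (no hidden defaults)
        "criteria": {"sasa_min": 15.0, "rmsf_constrained": 1.5, "rmsf_csa": 1.0,
                     "mode": "windowed", "flank_reach": 2},
        "sasa": {"probe": 1.4, "n_points": 960, "mode": "exposed"},
        "backend": {"kind": "enm", "weighting": "contact", "cutoff": 7.5,
                    "contact_cutoff": 4.5, "calibration": None,
                    "calibration_target": 0.8, "reference": "clamped_hairpin"},
        "energy": {"contact_cutoff": 4.5, "pair_cutoff": 12.0,
                   "dielectric_scale": 4.0, "relax": "none", "solvation": False},
        "selection": {"mode": "rank", "top_k": 3, "threshold": 23.0},
        "complex": {
            "path": str(out / "toy_complex.pdb"),
            "receptor_chains": ["A"], "ligand_chains": ["B"],
            "prefix": {"B": "TH"},
            "cdrs": {"B": [["CDR-1", contacts[0] - 2, contacts[-1] + 2]]},
        },
    }
    import yaml

    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
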
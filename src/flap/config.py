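"""Run configuration: one structured file per run, no hidden defaults.

All selection thresholds of the design procedure live here in one
auditable place: the per-residue SASA floor (15 A^2), the constrained
and CSA RMSF ceilings (1.5 / 1.0 A), the interface contact cutoff
(4.5 A) and the alanine-scan selection rule (rank top-k by default,
absolute-loss threshold as the configurable alternative).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .energy import EnergyConfig
from .sitefinder import SiteCriteria


@dataclass
class BackendConfig:
    """Fluctuation backend choice and its calibration.

    The ENM thresholds are meaningful only relative to a calibration:
    ``calibration`` (A per mode unit) is either given explicitly or
    computed once on the ``reference`` scaffold so that its median
    residue RMSF equals ``calibration_target``, then reused for every
    structure in the run (one universal spring constant).
    """

    kind: str = "enm"                   # "enm" | "ensemble"
    weighting: str = "contact"          # "uniform" | "contact"
    cutoff: float = 7.5                 # A, Cα cutoff (uniform weighting)
    contact_cutoff: float = 4.5         # A, heavy-atom (contact weighting)
    calibration: float | None = None
    calibration_target: float = 0.8     # A, median residue RMSF of reference
    reference: str | None = None        # scaffold id; default first scaffold
    ensembles: dict[str, str] = field(default_factory=dict)  # id -> PDB path
    fit_exclude_window: bool = True     # ensemble superposition selection

    def __post_init__(self) -> None:
        if self.kind not in ("enm", "ensemble"):
            raise ValueError(f"unknown backend kind {self.kind!r}")
        if self.weighting not in ("uniform", "contact"):
            raise ValueError(f"unknown ENM weighting {self.weighting!r}")


@dataclass
class SelectionConfig:
    """Alanine-scan selection rule."""

    mode: str = "rank"        # "rank" | "threshold"
    top_k: int = 3
    threshold: float = 23.0   # score units, threshold mode only

    def __post_init__(self) -> None:
        if self.mode not in ("rank", "threshold"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class SasaConfig:
    probe: float = 1.4
    n_points: int = 960
    mode: str = "exposed"     # "exposed" | "buried_delta"

    def __post_init__(self) -> None:
        if self.mode not in ("exposed", "buried_delta"):
            raise ValueError(f"unknown SASA mode {self.mode!r}")


@dataclass
class ComplexConfig:
    path: str = ""
    receptor_chains: tuple[str, ...] = ()
    ligand_chains: tuple[str, ...] = ()
    prefix: dict[str, str] = field(default_factory=dict)
    cdrs: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "flap_run"
    scaffolds: list[str] = field(default_factory=list)       # PDB paths
    criteria: SiteCriteria = field(default_factory=SiteCriteria)
    sasa: SasaConfig = field(default_factory=SasaConfig)
    backend: BackendConfig = field(default_factory=BackendConfig)
    energy: EnergyConfig = field(default_factory=EnergyConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    complex: ComplexConfig = field(default_factory=ComplexConfig)

    # ---- serialisation -------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["complex"]["receptor_chains"] = list(self.complex.receptor_chains)
        d["complex"]["ligand_chains"] = list(self.complex.ligand_chains)
        d["complex"]["cdrs"] = {
            cid: [list(r) for r in ranges]
            for cid, ranges in self.complex.cdrs.items()
        }
        return d

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration; the output location is
        excluded so re-runs into different directories match."""
        d = self.to_dict()
        d.pop("out_dir", None)
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    known = {"seed", "out_dir", "scaffolds", "criteria", "sasa", "backend",
             "energy", "selection", "complex"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cx = dict(raw.get("complex") or {})
    if "receptor_chains" in cx:
        cx["receptor_chains"] = tuple(cx["receptor_chains"])
    if "ligand_chains" in cx:
        cx["ligand_chains"] = tuple(cx["ligand_chains"])
    if "cdrs" in cx:
        cx["cdrs"] = {
            cid: [(str(n), int(a), int(b)) for n, a, b in ranges]
            for cid, ranges in cx["cdrs"].items()
        }
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "flap_run")),
        scaffolds=[str(p) for p in raw.get("scaffolds", [])],
        criteria=SiteCriteria(**(raw.get("criteria") or {})),
        sasa=SasaConfig(**(raw.get("sasa") or {})),
        backend=BackendConfig(**(raw.get("backend") or {})),
        energy=EnergyConfig(**(raw.get("energy") or {})),
        selection=SelectionConfig(**(raw.get("selection") or {})),
        complex=ComplexConfig(**cx),
    )
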
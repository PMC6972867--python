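"""Shared fixtures: synthetic structures are built once per session
(the hairpin loop optimisation is cached) and treated as read-only."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from flap import fixtures, pipeline, structio
from flap.config import load_config

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def helix12():
    return fixtures.build_structure(fixtures.FixtureSpec(kind="helix", length=12))


@pytest.fixture(scope="session")
def hairpin():
    """Open-loop hairpin: strands 7 + 7, mobile 6-residue loop."""
    return fixtures.build_structure(fixtures.FixtureSpec(kind="hairpin"))


@pytest.fixture(scope="session")
def clamped_hairpin():
    """Disulfide-clamped hairpin: the immobilised-loop reference."""
    return fixtures.build_structure(fixtures.FixtureSpec(kind="clamped_hairpin"))


@pytest.fixture(scope="session")
def linear6():
    return fixtures.build_structure(
        fixtures.FixtureSpec(kind="linear_peptide", length=6, sequence="GSSSSG"))


@pytest.fixture(scope="session")
def toy_complex():
    """Toy antibody-antigen complex with a designed 6-run contact block."""
    return fixtures.build_structure(fixtures.FixtureSpec(kind="toy_complex"))


@pytest.fixture(scope="session")
def toy_complex4():
    """Variant with a 4-residue designed contact set."""
    return fixtures.build_structure(
        fixtures.FixtureSpec(kind="toy_complex",
                             contact_positions=(10, 11, 12, 13)))


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """The generated fixture set plus a full pipeline run over it."""
    root = tmp_path_factory.mktemp("fixture_set")
    pipeline.generate_fixture_set(root, seed=1)
    cfg = load_config(root / "config.yaml")
    scan = pipeline.scan_scaffolds(cfg, out_dir=cfg.out_dir)
    ga = pipeline.profile_ga(cfg, scan, out_dir=cfg.out_dir)
    cdr = pipeline.extract_cdr(cfg, out_dir=cfg.out_dir)
    designs = pipeline.design(cfg, ga, cdr, scan, out_dir=cfg.out_dir,
                              write_structures=False)
    return {"root": root, "cfg": cfg, "scan": scan, "ga": ga,
            "cdr": cdr, "designs": designs}


def reference_dssp(structure, tmp_path):
    """Independent 3-state secondary structure via mdtraj's DSSP."""
    import mdtraj

    path = tmp_path / f"{structure.id}_dssp.pdb"
    structio.write_structure(structure, path)
    traj = mdtraj.load(str(path))
    return "".join(mdtraj.compute_dssp(traj, simplified=True)[0])


def dense_gnm_oracle(K: np.ndarray) -> np.ndarray:
    """Brute-force pseudoinverse diagonal via full eigendecomposition,
    independent of the production pinvh path."""
    vals, vecs = np.linalg.eigh(K)
    keep = vals > 1e-9 * vals.max()
    return ((vecs[:, keep] ** 2) / vals[keep]).sum(axis=1)
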
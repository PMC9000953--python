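"""Shared fixtures: tiny hand-written structure files and synthetic inputs."""

from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
import pytest

from abcaxis.structure_io import Atom, StructureModel

# One glycine with N, CA, C — minimal valid PDB content.
THREE_ATOM_PDB = textwrap.dedent("""\
    ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
    ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
    ATOM      3  C   GLY A   1      10.729   6.768  -4.123  1.00  0.00           C
    END
""")

HEADER_ONLY_PDB = "HEADER    TEST ENTRY                              01-JAN-20   XXXX\nEND\n"


@pytest.fixture
def three_atom_pdb(tmp_path) -> Path:
    p = tmp_path / "gly.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p


@pytest.fixture
def header_only_pdb(tmp_path) -> Path:
    p = tmp_path / "empty.pdb"
    p.write_text(HEADER_ONLY_PDB)
    return p


def make_chain_model(n_residues: int = 30, chain: str = "A",
                     entry_id: str = "toy", skip: tuple[int, ...] = (),
                     rng: np.random.Generator | None = None) -> StructureModel:
    """CA-only chain with residues 1..n on a gentle curve; gaps via ``skip``."""
    rng = rng if rng is not None else np.random.default_rng(0)
    atoms = []
    for i in range(1, n_residues + 1):
        if i in skip:
            continue
        xyz = (3.8 * i + 0.1 * np.sin(i), 2.0 * np.cos(0.3 * i), 0.05 * i * i)
        atoms.append(Atom(chain, i, "", "ALA", "CA", "C",
                          tuple(float(v) for v in xyz), 1.0, ""))
    return StructureModel(id=entry_id, atoms=atoms)


@pytest.fixture
def chain_model() -> StructureModel:
    return make_chain_model()


def random_cloud(n: int, seed: int, scale: float = 10.0) -> np.ndarray:
    return np.random.default_rng(seed).uniform(-scale, scale, size=(n, 3))
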
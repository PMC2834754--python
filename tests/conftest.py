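"""Shared fixtures: synthetic complexes and their pipeline profiles.

Everything is generated programmatically; profiling a toy takes well under
a second, and session scoping keeps each variant profiled exactly once.
"""

from __future__ import annotations

import numpy as np
import pytest

from ppiface.structure import Atom, Structure
from ppiface.synthetic import ToyComplexSpec, build_toy_complex
from ppiface.pipeline import profile_complex


@pytest.fixture(scope="session")
def toys():
    """One built toy per kind, seed 7."""
    return {
        kind: build_toy_complex(ToyComplexSpec(kind=kind, seed=7))
        for kind in ("class_I_helix_groove", "class_I_strand",
                     "class_II_globular", "zipA_like_flat")
    }


@pytest.fixture(scope="session")
def toy_reports(toys):
    """Full pipeline reports for every toy kind."""
    out = {}
    for kind, toy in toys.items():
        out[kind] = profile_complex(
            toy.complex, toy.selection, toy.unbound,
            toy.ligand_complex, toy.ligand_selection)
    return out


def make_structure(coords, elements=None, chain_ids=None, names=None,
                   residue_seqs=None, residue_names=None, hetero=None):
    """Quick Structure from raw arrays, one atom per residue by default."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    elements = elements or ["C"] * n
    chain_ids = chain_ids or ["A"] * n
    names = names or ["CA"] * n
    residue_seqs = residue_seqs or list(range(1, n + 1))
    residue_names = residue_names or ["ALA"] * n
    hetero = hetero or [False] * n
    atoms = [
        Atom(serial=i + 1, name=names[i], element=elements[i],
             coords=coords[i], residue_name=residue_names[i],
             chain_id=chain_ids[i], residue_seq=residue_seqs[i],
             is_hetero=hetero[i])
        for i in range(n)
    ]
    return Structure(atoms)


@pytest.fixture
def slab_factory():
    """Factory for dense pseudo-atom slabs with optional carved cavities."""
    def build(carve=(), nx=16, ny=16, nz=5, spacing=2.5, radius=3.8,
              chain="A"):
        atoms = []
        k = 1
        for ix in range(nx):
            for iy in range(ny):
                for iz in range(nz):
                    p = np.array([ix * spacing, iy * spacing, iz * spacing])
                    if any(np.linalg.norm(p - np.asarray(c)) < radius
                           for c in carve):
                        continue
                    atoms.append(Atom(k, "CA", "C", p, "ALA", chain, k))
                    k += 1
        return Structure(atoms)
    return build
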
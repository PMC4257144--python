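"""Shared fixtures: synthetic peptides, injected-potential backends, tiny templates."""

from __future__ import annotations

import numpy as np
import pytest

from escapist.electrostatics import AtomPotentials
from escapist.features import EPDTemplate
from escapist.fixtures import PeptideSpec, generate_peptide

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def polyala10():
    return generate_peptide(PeptideSpec(sequence="A" * 10))


@pytest.fixture
def random_sequences():
    """Deterministic random 30-mer sequences over the 20 standard types."""
    rng = np.random.default_rng(2024)

    def make(n, length=30):
        return ["".join(rng.choice(list(AA20), size=length)) for _ in range(n)]

    return make


def make_injected_backend(base: dict[str, float], sigma: float = 0.0, seed: int = 0,
                          atoms=("N", "CA", "C", "CB")):
    """Backend callable assigning each atom a potential from a per-residue-type base
    value plus i.i.d. Gaussian noise.  Under this generative model the expected
    canonical EPD of the sorted pair (X, Y) is base[X] - base[Y] with SD sigma*sqrt(2),
    which gives every learning test an exact oracle."""
    rng = np.random.default_rng(seed)

    def backend(structure) -> AtomPotentials:
        values = {}
        for res in structure.iter_residues():
            for name in atoms:
                if res.has_atom(name):
                    noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
                    values[(res.chainId, res.seqIndex, name)] = base[res.aaType] + noise
        return AtomPotentials(values=values, backendName="injected")

    return backend


def make_fixed_potentials(structure, per_residue: dict[int, float],
                          atoms=("N", "CA", "C", "CB")) -> AtomPotentials:
    """AtomPotentials giving every atom of residue seqIndex i the value per_residue[i]."""
    values = {}
    for res in structure.iter_residues():
        if res.seqIndex not in per_residue:
            continue
        for name in atoms:
            if res.has_atom(name):
                values[(res.chainId, res.seqIndex, name)] = per_residue[res.seqIndex]
    return AtomPotentials(values=values, backendName="fixed")


def tiny_template(entries: dict[str, tuple[float, float, int]],
                  mode=("CB", "CB")) -> EPDTemplate:
    return EPDTemplate(mode=mode, entries=dict(entries),
                       provenance={"backend": "test"})
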
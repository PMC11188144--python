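"""Shared fixtures: small seeded sequences and communities."""

from __future__ import annotations

import numpy as np
import pytest

from guideasm.model import Read, ReferenceGenome
from guideasm.simulate import make_community, simulate_reads


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def mutate_subs(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only mutant (always to a different base)."""
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < rate)[0]:
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def tile_reads(template: str, read_length: int, step: int, prefix: str = "t") -> list:
    """Error-free reads tiling the template at a fixed stride."""
    return [
        Read(f"{prefix}{i}", template[p : p + read_length])
        for i, p in enumerate(range(0, len(template) - read_length + 1, step))
    ]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_community():
    """3 species x 30 kb, one decoy — shared by the cheaper end-to-end tests."""
    truth = make_community(
        seed=7, n_species=3, species_length=30_000, n_strains=2,
        n_decoys=1, abundance_decay=0.15, marker_length=300,
    )
    reads = simulate_reads(truth, total_pairs=6000, error_rate=0.005, seed=7)
    return truth, reads
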
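"""Shared fixtures: random small structures and pocket tables with known properties."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from apop.structure_io import ResidueId, StructureModel

# keep hypothesis runs reproducible in CI and on developer machines
settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


def random_structure(
    rng: np.random.Generator,
    n: int,
    box: float = 18.0,
    chain_id: str = "A",
) -> StructureModel:
    """Random Cα cloud in a box; small boxes keep the contact graph connected."""
    coords = rng.uniform(0.0, box, size=(n, 3))
    return StructureModel(
        residue_ids=[ResidueId(chain_id, i + 1) for i in range(n)],
        residue_names=["ALA"] * n,
        coords=coords,
        source_label=f"random n={n}",
    )


def random_connected_structure(
    rng: np.random.Generator, n: int, box: float = 18.0
) -> StructureModel:
    """Resample random clouds until the contact graph is connected.

    Proteins are connected chains; disconnected clouds have ambiguous global
    modes and are exercised separately in the disconnection tests.
    """
    from apop.gnm import build_kirchhoff, connected_components

    while True:
        model = random_structure(rng, n, box)
        if len(connected_components(build_kirchhoff(model))) == 1:
            return model


def random_chain_structure(
    rng: np.random.Generator, n: int, step: float = 3.8, min_sep: float = 3.0
) -> StructureModel:
    """Self-avoiding random walk with Cα virtual-bond steps.

    Closer to protein geometry than a uniform cloud: connected by
    construction, packing limited by an excluded-volume radius, and with the
    cleanly separated slow modes typical of chain molecules.
    """
    coords = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(200):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            candidate = coords[i - 1] + step * direction
            if i < 2 or np.linalg.norm(coords[: i - 1] - candidate, axis=1).min() >= min_sep:
                coords[i] = candidate
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError("self-avoiding walk got stuck")
    return StructureModel(
        residue_ids=[ResidueId("A", i + 1) for i in range(n)],
        residue_names=["ALA"] * n,
        coords=coords,
        source_label=f"chain n={n}",
    )


def nearest_neighbor_pocket(
    rng: np.random.Generator, coords: np.ndarray, size: int
) -> list[int]:
    """A spatially contiguous pocket: a random seed residue plus its nearest
    neighbors, mimicking the lining of one cavity."""
    seed_node = int(rng.integers(len(coords)))
    d = np.linalg.norm(coords - coords[seed_node], axis=1)
    return sorted(np.argsort(d)[:size].tolist())


def brute_force_kirchhoff(coords: np.ndarray, cutoff: float) -> np.ndarray:
    """Independent O(N²) double-loop contact Laplacian (test oracle)."""
    n = len(coords)
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = float(np.sqrt(((coords[i] - coords[j]) ** 2).sum()))
            if d <= cutoff:
                k[i, j] = -1.0
    for i in range(n):
        k[i, i] = -k[i].sum()
    return k


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


MINI_PDB = """\
ATOM      1  N   ALA A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  MET A   3       7.600   0.000   0.000  1.00  0.00           C
TER
HETATM    5  C1  LIG A 101      20.000  20.000  20.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
TER
ATOM      3  CA  LEU B   1       0.000   8.000   0.000  1.00  0.00           C
ATOM      4  CA  VAL B   2       3.800   8.000   0.000  1.00  0.00           C
TER
END
"""


@pytest.fixture
def mini_pdb_text() -> str:
    return MINI_PDB


@pytest.fixture
def two_chain_pdb_text() -> str:
    return TWO_CHAIN_PDB
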
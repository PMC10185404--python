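"""Deterministic synthetic structures and pocket sets for testing and demos.

These fixtures trade physical realism for auditable spectra: node topology
(which residues belong to which pocket) is always explicit in the spec, and
pseudo-randomness is confined to seeded coordinate jitter.  The
``multimer-ring`` kind places several chains around a central axis — each a
compact body plus a short linker reaching the axis — so that a central
cavity exists whose lining residues touch every chain and mediate all
inter-chain coupling.  The slow modes are then relative motions of whole
subunits about the center: the geometry in which ligand binding at a
central pocket most constrains global dynamics, mirroring the behavior of
central cavities in real multimeric assemblages.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pockets import Pocket, PocketSet, write_pocket_file
from .structure_io import ResidueId, StructureModel, mini_pdb_text

__all__ = ["PocketFixture", "FixtureSpec", "make_structure", "make_pockets", "multimer_ring_demo"]

_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
#: Residue names cycled through generated chains (identity is irrelevant to
#: the network; variety keeps fixture files realistic-looking).
_RES_CYCLE = ("ALA", "LEU", "GLY", "VAL", "SER", "THR", "ILE", "PHE")


@dataclass(frozen=True)
class PocketFixture:
    """Explicit pocket content for a fixture: id, residue tokens, H_p."""

    pocket_id: int
    residue_tokens: tuple[str, ...]
    hydrophobic_density: float


@dataclass(frozen=True)
class FixtureSpec:
    """Deterministic recipe for a synthetic structure + pockets.

    kind
        "path" (straight chain), "ring" (closed circle), "lattice" (cubic
        grid), or "multimer-ring" (n_chains chains arranged radially around
        the z axis, innermost residues lining a central cavity).
    spacing
        Consecutive-node distance in Å (Cα virtual-bond ≈ 3.8 Å).
    jitter
        Amplitude (Å) of seeded uniform coordinate noise; breaks exact
        geometric degeneracies without altering topology at default cutoff.
    """

    kind: str = "path"
    n_nodes: int = 10
    n_chains: int = 1
    spacing: float = 3.8
    jitter: float = 0.0
    inner_radius: float = 4.0  # multimer-ring: radius of the innermost node
    blob_radius: float = 15.0  # multimer-ring: radius of the chain-body center
    seed: int = 0
    pockets: tuple[PocketFixture, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in ("path", "ring", "lattice", "multimer-ring"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_nodes < 2 or self.n_chains < 1:
            raise ValueError("need n_nodes >= 2 and n_chains >= 1")


def _chain_template(spec: FixtureSpec) -> np.ndarray:
    """Per-chain coordinates before chain placement (chain lies along +x)."""
    n = spec.n_nodes
    if spec.kind == "path":
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * spec.spacing
    elif spec.kind == "ring":
        radius = n * spec.spacing / (2.0 * np.pi)
        theta = 2.0 * np.pi * np.arange(n) / n
        coords = np.stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.zeros(n)], axis=1
        )
    elif spec.kind == "lattice":
        side = int(np.ceil(n ** (1.0 / 3.0)))
        pts = [(i, j, k) for i in range(side) for j in range(side) for k in range(side)]
        coords = np.array(pts[:n], dtype=float) * spec.spacing
    else:
        # multimer-ring chain = two linker residues reaching toward the axis
        # plus a compact grid body at blob_radius.  Bodies of different
        # chains stay out of contact range, so inter-chain coupling runs
        # only through the central hub and the slow modes are relative
        # motions of whole bodies about the center.
        if n > 2 + 27:
            raise ValueError("multimer-ring supports at most 29 nodes per chain")
        coords = np.zeros((n, 3))
        coords[0] = (spec.inner_radius, 0.0, 0.0)
        coords[1] = (spec.inner_radius + 2.5, 0.0, 0.5)
        for i in range(2, n):
            j = i - 2
            a, b, c = j % 3, (j // 3) % 3, j // 9
            coords[i] = (
                spec.blob_radius + (a - 1) * spec.spacing,
                (b - 1) * spec.spacing,
                (c - 0.5) * spec.spacing,
            )
    return coords


def make_structure(spec: FixtureSpec) -> StructureModel:
    """Build the deterministic synthetic Cα model a spec describes.

    Identical specs (including seed) give identical coordinates, hence
    byte-identical PDB serializations.  Raises if two nodes fall within
    0.1 Å of each other (collapsed geometry).
    """
    rng = np.random.default_rng(spec.seed)
    template = _chain_template(spec)
    n_chains = spec.n_chains if spec.kind == "multimer-ring" else max(1, spec.n_chains)

    ids: list[ResidueId] = []
    names: list[str] = []
    blocks: list[np.ndarray] = []
    for c in range(n_chains):
        coords = template.copy()
        if spec.kind == "multimer-ring":
            angle = 2.0 * np.pi * c / n_chains
            rot = np.array(
                [
                    [np.cos(angle), -np.sin(angle), 0.0],
                    [np.sin(angle), np.cos(angle), 0.0],
                    [0.0, 0.0, 1.0],
                ]
            )
            coords = coords @ rot.T
        else:
            coords = coords + np.array([0.0, 0.0, c * 5.0 * spec.spacing])
        if spec.jitter > 0:
            coords = coords + rng.uniform(-spec.jitter, spec.jitter, size=coords.shape)
        chain_id = _CHAIN_IDS[c]
        for i in range(spec.n_nodes):
            ids.append(ResidueId(chain_id=chain_id, res_seq=i + 1))
            names.append(_RES_CYCLE[(c + i) % len(_RES_CYCLE)])
        blocks.append(coords)

    all_coords = np.vstack(blocks)
    diff = all_coords[:, None, :] - all_coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    if dist.min() < 0.1:
        raise ValueError(
            f"fixture geometry collapses two nodes to {dist.min():.3f} Å apart"
        )
    return StructureModel(
        residue_ids=ids,
        residue_names=names,
        coords=all_coords,
        source_label=f"synthetic:{spec.kind} seed={spec.seed}",
    )


def make_pockets(
    spec: FixtureSpec,
    model: StructureModel,
    out_dir: str | os.PathLike | None = None,
) -> PocketSet:
    """Materialize the spec's pockets; optionally write both on-disk formats.

    When ``out_dir`` is given, writes ``pockets.txt`` (neutral format) and a
    miniature Fpocket-style tree ``fixture_out/`` (info file + per-pocket
    Cα atom PDBs) encoding identical content, so both parsers can be
    exercised on the same ground truth.
    """
    if not spec.pockets:
        raise ValueError("fixture spec defines no pockets")
    pockets: list[Pocket] = []
    for pf in spec.pockets:
        residues = frozenset(ResidueId.from_token(t) for t in pf.residue_tokens)
        for rid in residues:
            if model.index_of(rid) is None:
                raise ValueError(
                    f"fixture pocket {pf.pocket_id} references residue {rid.token()} "
                    "absent from the generated model"
                )
        pockets.append(
            Pocket(
                pocket_id=pf.pocket_id,
                residues=residues,
                hydrophobic_density=pf.hydrophobic_density,
            )
        )
    pocket_set = PocketSet(pockets=pockets, source_kind="synthetic")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_pocket_file(pocket_set, out / "pockets.txt")
        _write_fpocket_style(pocket_set, model, out / "fixture_out")
    return pocket_set


def _write_fpocket_style(pocket_set: PocketSet, model: StructureModel, root: Path) -> None:
    """Emit a minimal Fpocket-layout directory mirroring a pocket set."""
    (root / "pockets").mkdir(parents=True, exist_ok=True)
    info_lines: list[str] = []
    for p in pocket_set:
        info_lines.append(f"Pocket {p.pocket_id} :")
        info_lines.append(f"\tScore : {0.5:.3f}")
        info_lines.append(f"\tLocal hydrophobic density Score : {p.hydrophobic_density}")
        info_lines.append("")
        node_indices = sorted(
            i for i in (model.index_of(r) for r in p.residues) if i is not None
        )
        sub = StructureModel(
            residue_ids=[model.residue_ids[i] for i in node_indices],
            residue_names=[model.residue_names[i] for i in node_indices],
            coords=model.coords[node_indices],
            source_label=f"pocket{p.pocket_id}",
        )
        (root / "pockets" / f"pocket{p.pocket_id}_atm.pdb").write_text(mini_pdb_text(sub))
    (root / "fixture_info.txt").write_text("\n".join(info_lines) + "\n")


def multimer_ring_demo(seed: int = 0) -> FixtureSpec:
    """The canonical demo assemblage: 4 chains × 15 residues, 4 pockets.

    Pocket 1 lines the central cavity (two innermost residues of every
    chain); pockets 2–4 sit on single chains.  Hydrophobic densities are
    fixed so the central pocket is *not* the most hydrophobic — its top rank
    must come from the dynamics term.
    """
    central = tuple(f"{c}:{i}" for c in "ABCD" for i in (1, 2))
    return FixtureSpec(
        kind="multimer-ring",
        n_nodes=15,
        n_chains=4,
        spacing=3.8,
        jitter=0.3,
        inner_radius=4.0,
        seed=seed,
        pockets=(
            PocketFixture(1, central, 9.0),
            PocketFixture(2, tuple(f"A:{i}" for i in range(8, 13)), 12.0),
            PocketFixture(3, tuple(f"B:{i}" for i in range(8, 13)), 5.0),
            PocketFixture(4, tuple(f"C:{i}" for i in range(5, 10)), 7.0),
        ),
    )
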
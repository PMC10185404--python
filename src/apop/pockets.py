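"""Candidate pockets: residue membership plus local hydrophobic density.

Two on-disk sources are supported.  The primary one is an Fpocket output
directory (per-pocket atom PDBs plus an info file carrying the
"Local hydrophobic density Score"); the second is a neutral plain-text
format that removes the Fpocket dependency for testing and for
user-supplied pockets.

Neutral pocket file grammar (version 1, whitespace-separated)::

    # comment / blank lines ignored
    <pocket_id> <hydrophobic_density> <residue> [<residue> ...]

where each residue token is ``chain:resSeq`` or ``chain:resSeq:icode``,
e.g. ``A:42`` or ``B:100:A``.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .errors import NoScorablePocketsError, PocketFormatError, PocketResolutionWarning
from .structure_io import ResidueId, StructureModel

__all__ = [
    "Pocket",
    "PocketSet",
    "PocketNodeMap",
    "parse_pocket_file",
    "write_pocket_file",
    "parse_fpocket_dir",
    "map_pockets_to_nodes",
]

#: Accepted spellings of the hydrophobic-density line in Fpocket info files,
#: lowercased, compared after collapsing runs of whitespace.  The field name
#: drifts slightly between Fpocket releases; extend here if a new variant
#: appears.
HYDROPHOBIC_DENSITY_KEYS = (
    "local hydrophobic density score",
    "local hydrophobic density",
    "mean local hydrophobic density",
)


@dataclass(frozen=True)
class Pocket:
    """One candidate pocket: id, lining residues, hydrophobic density H_p."""

    pocket_id: int
    residues: frozenset[ResidueId]
    hydrophobic_density: float

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"pocket {self.pocket_id} has no residues")


@dataclass
class PocketSet:
    """Ordered collection of pockets from one source."""

    pockets: list[Pocket]
    source_kind: str = "neutral-file"  # "fpocket" | "neutral-file" | "synthetic"

    def __post_init__(self) -> None:
        ids = [p.pocket_id for p in self.pockets]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PocketFormatError(f"duplicate pocket id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.pockets)

    def __iter__(self):
        return iter(self.pockets)

    def by_id(self, pocket_id: int) -> Pocket:
        for p in self.pockets:
            if p.pocket_id == pocket_id:
                return p
        raise KeyError(pocket_id)


@dataclass
class PocketNodeMap:
    """Resolution of pocket residues onto structure node indices.

    ``resolved`` maps pocket_id -> sorted node-index list; ids in
    ``unscorable`` resolved to fewer than two nodes and cannot be perturbed
    (a single node admits no pairwise spring).  Unscorable pockets are kept
    visible here rather than silently dropped.
    """

    resolved: dict[int, list[int]] = field(default_factory=dict)
    unscorable: set[int] = field(default_factory=set)

    def scorable_ids(self) -> list[int]:
        return [pid for pid in self.resolved if pid not in self.unscorable]


def parse_pocket_text(text: str, source: str = "<string>") -> PocketSet:
    """Parse the neutral pocket format from a string."""
    pockets: list[Pocket] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 3:
            raise PocketFormatError(
                f"{source}:{lineno}: expected 'pocket_id density residue...', got {raw!r}"
            )
        try:
            pid = int(parts[0])
            density = float(parts[1])
        except ValueError as exc:
            raise PocketFormatError(f"{source}:{lineno}: {exc}") from exc
        try:
            residues = frozenset(ResidueId.from_token(tok) for tok in parts[2:])
        except ValueError as exc:
            raise PocketFormatError(f"{source}:{lineno}: {exc}") from exc
        pockets.append(Pocket(pocket_id=pid, residues=residues, hydrophobic_density=density))
    return PocketSet(pockets=pockets, source_kind="neutral-file")


def parse_pocket_file(path: str | os.PathLike) -> PocketSet:
    """Read a neutral pocket-definition file (grammar in the module docstring)."""
    p = Path(path)
    return parse_pocket_text(p.read_text(), source=p.name)


def write_pocket_file(pocket_set: PocketSet, path: str | os.PathLike) -> None:
    """Write the neutral format; ``parse_pocket_file`` inverts this exactly."""
    lines = ["# pocket definitions v1: pocket_id hydrophobic_density residues..."]
    for p in pocket_set:
        toks = " ".join(r.token() for r in sorted(p.residues))
        lines.append(f"{p.pocket_id} {p.hydrophobic_density!r} {toks}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Fpocket output directory
# ---------------------------------------------------------------------------

_POCKET_HEADER = re.compile(r"^\s*Pocket\s+(\d+)\s*:?\s*$")


def _parse_info_densities(info_path: Path) -> dict[int, float]:
    """Extract pocket-id -> hydrophobic density from an Fpocket info file."""
    densities: dict[int, float] = {}
    current: int | None = None
    for raw in info_path.read_text().splitlines():
        m = _POCKET_HEADER.match(raw)
        if m:
            current = int(m.group(1))
            continue
        if ":" not in raw:
            continue
        key, _, value = raw.partition(":")
        key_norm = " ".join(key.split()).lower()
        if key_norm in HYDROPHOBIC_DENSITY_KEYS:
            if current is None:
                raise PocketFormatError(
                    f"{info_path.name}: density line before any 'Pocket N :' header: {raw!r}"
                )
            try:
                densities[current] = float(value.strip())
            except ValueError as exc:
                raise PocketFormatError(
                    f"{info_path.name}: unparseable density line {raw!r}"
                ) from exc
    return densities


def _residues_from_atom_pdb(path: Path) -> frozenset[ResidueId]:
    """Collapse the atoms of one pocket PDB file to their residue identities."""
    residues: set[ResidueId] = set()
    for line in path.read_text().splitlines():
        if not (line.startswith("ATOM") or line.startswith("HETATM")):
            continue
        if len(line) < 27:
            raise PocketFormatError(f"{path.name}: truncated atom record {line!r}")
        chain = line[21]
        try:
            res_seq = int(line[22:26])
        except ValueError as exc:
            raise PocketFormatError(f"{path.name}: bad residue number in {line!r}") from exc
        icode = line[26] if line[26].strip() else " "
        residues.add(ResidueId(chain_id=chain, res_seq=res_seq, insertion_code=icode))
    return frozenset(residues)


def parse_fpocket_dir(out_dir: str | os.PathLike) -> PocketSet:
    """Read an Fpocket output directory (``*_info.txt`` + ``pockets/pocketN_atm.pdb``).

    Pocket ids are Fpocket's 1-based pocket numbers; residues are the union
    of the residue identities of all atoms listed for each pocket;
    ``hydrophobic_density`` comes from that pocket's info block.
    """
    d = Path(out_dir)
    if not d.is_dir():
        raise PocketFormatError(f"not a directory: {d}")
    infos = sorted(d.glob("*_info.txt")) or sorted(d.glob("*info.txt"))
    if not infos:
        raise PocketFormatError(f"no *_info.txt file found in {d}")
    densities = _parse_info_densities(infos[0])

    pocket_dir = d / "pockets"
    atom_files = sorted(pocket_dir.glob("pocket*_atm.pdb")) if pocket_dir.is_dir() else []
    if not atom_files:
        raise PocketFormatError(f"no pockets/pocket*_atm.pdb files found in {d}")

    pockets: list[Pocket] = []
    for path in atom_files:
        m = re.match(r"pocket(\d+)_atm\.pdb$", path.name)
        if not m:
            continue
        pid = int(m.group(1))
        residues = _residues_from_atom_pdb(path)
        if not residues:
            raise PocketFormatError(f"{path.name}: no atom records")
        if pid not in densities:
            raise PocketFormatError(
                f"pocket {pid} has an atom file but no "
                f"'Local hydrophobic density Score' line in {infos[0].name}"
            )
        pockets.append(
            Pocket(pocket_id=pid, residues=residues, hydrophobic_density=densities[pid])
        )
    pockets.sort(key=lambda p: p.pocket_id)
    return PocketSet(pockets=pockets, source_kind="fpocket")


# ---------------------------------------------------------------------------
# Mapping pockets onto GNM nodes
# ---------------------------------------------------------------------------


def map_pockets_to_nodes(pockets: PocketSet, model: StructureModel) -> PocketNodeMap:
    """Resolve each pocket's residues to node indices in model order.

    Residues absent from the model (e.g. missing Cα, stripped ligand chain)
    are dropped with a warning; a pocket left with fewer than two resolved
    nodes is flagged unscorable.  Raises ``NoScorablePocketsError`` when no
    pocket at all can be scored.
    """
    node_map = PocketNodeMap()
    for pocket in pockets:
        indices: list[int] = []
        dropped: list[str] = []
        for rid in sorted(pocket.residues):
            idx = model.index_of(rid)
            if idx is None:
                dropped.append(rid.token())
            else:
                indices.append(idx)
        if dropped:
            warnings.warn(
                PocketResolutionWarning(
                    f"pocket {pocket.pocket_id}: {len(dropped)} residue(s) not in "
                    f"structure, dropped: {', '.join(dropped)}"
                ),
                stacklevel=2,
            )
        node_map.resolved[pocket.pocket_id] = sorted(indices)
        if len(indices) < 2:
            node_map.unscorable.add(pocket.pocket_id)
            warnings.warn(
                PocketResolutionWarning(
                    f"pocket {pocket.pocket_id} resolves to {len(indices)} node(s); "
                    "needs >= 2 to perturb — flagged unscorable"
                ),
                stacklevel=2,
            )
    if not node_map.scorable_ids():
        raise NoScorablePocketsError(
            "no pocket resolves to >= 2 structure nodes; check chain ids and numbering"
        )
    return node_map
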
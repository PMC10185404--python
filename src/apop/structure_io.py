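"""Read PDB files into the coarse-grained Cα node model used by the GNM.

Each retained node is one standard amino-acid residue with a Cα atom,
identified by (chain id, author residue number, insertion code).  Node order
is the order of first appearance in the source file and is stable across
runs, so downstream matrices index residues deterministically.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import BiopythonWarning
from Bio.PDB import PDBParser

__all__ = ["ResidueId", "StructureModel", "read_structure", "write_mini_pdb"]

#: Three-letter codes accepted as nodes.  MSE (selenomethionine) is common in
#: crystal structures and is mapped to MET; everything else is treated as a
#: ligand or solvent and ignored.
STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
RESNAME_ALIASES = {"MSE": "MET"}


@dataclass(frozen=True, order=True)
class ResidueId:
    """Author-numbering identity of one residue: chain, number, insertion code."""

    chain_id: str
    res_seq: int
    insertion_code: str = " "

    def token(self) -> str:
        """Render as ``chain:resSeq`` or ``chain:resSeq:icode``."""
        if self.insertion_code.strip():
            return f"{self.chain_id}:{self.res_seq}:{self.insertion_code}"
        return f"{self.chain_id}:{self.res_seq}"

    @classmethod
    def from_token(cls, token: str) -> "ResidueId":
        parts = token.strip().split(":")
        if len(parts) == 2:
            chain, seq = parts
            icode = " "
        elif len(parts) == 3:
            chain, seq, icode = parts
        else:
            raise ValueError(f"bad residue token {token!r}; expected chain:resSeq[:icode]")
        if not chain or len(icode) != 1:
            raise ValueError(f"bad residue token {token!r}")
        return cls(chain_id=chain, res_seq=int(seq), insertion_code=icode)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token()


@dataclass
class StructureModel:
    """Ordered Cα node list: residue identities, names, and coordinates (Å)."""

    residue_ids: list[ResidueId]
    residue_names: list[str]
    coords: np.ndarray  # shape (N, 3), Å, as read; GNM is rigid-motion invariant
    source_label: str = ""
    _index: dict[ResidueId, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.residue_ids), 3):
            raise ValueError("coords must be (N, 3) matching residue_ids")
        if len(self.residue_names) != len(self.residue_ids):
            raise ValueError("residue_names must match residue_ids")
        self._index = {}
        for i, rid in enumerate(self.residue_ids):
            if rid in self._index:
                raise ValueError(f"duplicate residue id {rid.token()}")
            self._index[rid] = i

    @property
    def n_nodes(self) -> int:
        return len(self.residue_ids)

    def __len__(self) -> int:
        return self.n_nodes

    def index_of(self, rid: ResidueId) -> int | None:
        """Node index for a residue id, or None if absent."""
        return self._index.get(rid)

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rid in self.residue_ids:
            seen.setdefault(rid.chain_id, None)
        return list(seen)

    def nodes(self) -> Iterator[tuple[ResidueId, str, np.ndarray]]:
        for i, rid in enumerate(self.residue_ids):
            yield rid, self.residue_names[i], self.coords[i]


def _select_ca(residue):
    """Pick one Cα from a (possibly disordered) residue.

    Altloc policy: highest occupancy wins; ties broken by altloc character
    order.  Returns None when the residue has no Cα at all.
    """
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        children = atom.disordered_get_list()
        children = sorted(
            children,
            key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
        )
        return children[0]
    return atom


def read_structure(
    pdb_source: str | os.PathLike | Path,
    chains: Iterable[str] | None = None,
    model_index: int = 0,
) -> StructureModel:
    """Parse PDB text or a PDB file into a Cα ``StructureModel``.

    Parameters
    ----------
    pdb_source
        Path to a PDB file, or a string containing PDB text (detected by the
        presence of a newline).
    chains
        Optional chain-id filter; all chains are kept when None.
    model_index
        Which MODEL block to read (0 = first); crystal structures have one.
    """
    from .errors import EmptyModelError, UnknownChainError

    if isinstance(pdb_source, str) and "\n" in pdb_source:
        handle: io.TextIOBase = io.StringIO(pdb_source)
        label = "<string>"
    else:
        path = Path(pdb_source)
        handle = open(path)
        label = path.name

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", BiopythonWarning)
        try:
            structure = parser.get_structure("s", handle)
        finally:
            handle.close()

    models = list(structure)
    if not models:
        raise EmptyModelError(f"no MODEL found in {label}")
    if model_index >= len(models):
        raise EmptyModelError(
            f"model index {model_index} out of range ({len(models)} models in {label})"
        )
    model = models[model_index]

    available = [c.id for c in model]
    chain_filter = set(chains) if chains is not None else None
    if chain_filter is not None:
        missing = sorted(chain_filter - set(available))
        if missing:
            raise UnknownChainError(
                f"chain(s) {missing} not in {label}; available chains: {sorted(available)}"
            )

    ids: list[ResidueId] = []
    seen: set[ResidueId] = set()
    names: list[str] = []
    xyz: list[np.ndarray] = []
    for chain in model:
        if chain_filter is not None and chain.id not in chain_filter:
            continue
        for residue in chain:
            hetflag, res_seq, icode = residue.id
            resname = residue.get_resname().strip()
            resname = RESNAME_ALIASES.get(resname, resname)
            if resname not in STANDARD_AA:
                continue
            if hetflag.strip() and hetflag != "H_MSE":
                continue
            atom = _select_ca(residue)
            if atom is None:
                continue
            rid = ResidueId(chain_id=str(chain.id), res_seq=int(res_seq),
                            insertion_code=icode if icode.strip() else " ")
            if rid in seen:
                continue  # duplicate author numbering; keep first appearance
            seen.add(rid)
            ids.append(rid)
            names.append(resname)
            xyz.append(np.asarray(atom.get_coord(), dtype=float))

    if not ids:
        flt = f" with chain filter {sorted(chain_filter)}" if chain_filter else ""
        raise EmptyModelError(f"empty model: no Cα nodes in {label}{flt}")

    kept = ",".join(sorted({r.chain_id for r in ids}))
    return StructureModel(
        residue_ids=ids,
        residue_names=names,
        coords=np.array(xyz, dtype=float),
        source_label=f"{label} model={model_index} chains={kept}",
    )


def mini_pdb_text(model: StructureModel) -> str:
    """Serialize a Cα-only model as PDB text at standard coordinate precision.

    Values outside [-999.999, 9999.999] cannot be represented in the
    fixed-width coordinate columns and raise ``ValueError``.
    """
    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    for rid, resname, xyz in model.nodes():
        if prev_chain is not None and rid.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = rid.chain_id
        serial += 1
        x, y, z = (float(v) for v in xyz)
        for v in (x, y, z):
            if not (-999.999 <= v <= 9999.999):
                raise ValueError(f"coordinate {v} not representable in PDB columns")
        if not (-999 <= rid.res_seq <= 9999):
            raise ValueError(f"residue number {rid.res_seq} not representable")
        if len(rid.chain_id) != 1:
            raise ValueError(f"chain id {rid.chain_id!r} must be one character")
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname:>3s} {rid.chain_id}"
            f"{rid.res_seq:4d}{rid.insertion_code:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
            f"{'C':>2s}"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_mini_pdb(model: StructureModel, path: str | os.PathLike) -> None:
    """Write a Cα-only PDB file that round-trips through :func:`read_structure`."""
    Path(path).write_text(mini_pdb_text(model))
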
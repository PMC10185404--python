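"""Pocket perturbation scoring: the allosteric-propensity ranking itself.

For each candidate pocket the network springs among *all* pairs of pocket
residues are set to a stiffer constant (default 10× the base γ, regardless
of pair distance), emulating the constraint a bound ligand imposes.  The
perturbed spectrum is recomputed, each unperturbed global mode is re-identified
among the perturbed modes by best eigenvector overlap, and the mean
percentage eigenvalue shift over the slowest modes measures how strongly the
pocket constrains global dynamics.  That dynamics score and the pocket's
local hydrophobic density are each standardized over the pocket population
(z-scores) and averaged with equal weight into the final score

    s_p = (z_p + z_h_p) / 2,

by which pockets are ranked (descending).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import (
    DegenerateVarianceWarning,
    ModeCountWarning,
    NoSignalError,
    PocketResolutionWarning,
)
from .gnm import GNMParameters, GNMSpectrum, KirchhoffMatrix, build_kirchhoff, decompose
from .pockets import PocketSet, map_pockets_to_nodes
from .structure_io import StructureModel

__all__ = [
    "ScoringParameters",
    "ModeMatching",
    "PerturbationResult",
    "PocketRanking",
    "perturb_pocket",
    "match_modes",
    "eigenvalue_shift",
    "score_pockets",
    "run_apop",
    "top_k_success",
]

#: Two competing overlaps closer than this are reported as a degeneracy flag.
DEGENERACY_TOL = 1e-6


@dataclass(frozen=True)
class ScoringParameters:
    """Perturbation strength and mode-window sizes.

    perturbed_gamma
        Spring constant (kcal mol⁻¹ Å⁻²) assigned to every pocket residue
        pair; default 10.0 against a base γ of 1.0.
    n_global
        Number of slowest unperturbed modes whose shifts are averaged
        (default 5).
    n_perturbed
        Number of slowest perturbed modes searched when re-identifying each
        global mode (default 15; clamped to the available mode count on
        small networks).
    """

    perturbed_gamma: float = 10.0
    n_global: int = 5
    n_perturbed: int = 15

    def __post_init__(self) -> None:
        if not self.perturbed_gamma > 0:
            raise ValueError("perturbed_gamma must be positive")
        if not (1 <= self.n_global <= self.n_perturbed):
            raise ValueError("need 1 <= n_global <= n_perturbed")


@dataclass
class ModeMatching:
    """Assignment of each unperturbed global mode to a distinct perturbed mode."""

    matched_indices: list[int]
    overlaps: list[float]
    degenerate: bool = False  # competing overlaps within DEGENERACY_TOL


@dataclass
class PerturbationResult:
    """Per-pocket outcome: matched modes and percentage eigenvalue shifts."""

    pocket_id: int
    n_resolved: int
    matched_mode_indices: list[int]
    per_mode_shift: np.ndarray  # percent, one per matched global mode
    mean_shift: float  # percent, mean over the matched global modes
    min_overlap: float  # quality flag: weakest overlap used in the matching
    degenerate_overlaps: bool = False


@dataclass
class PocketRanking:
    """Final table of pocket scores plus the population statistics used.

    ``table`` columns: pocket_id, n_residues, mean_shift_pct, z_dyn,
    hydrophobic_density, z_hyd, score, rank.  Scored rows come first, sorted
    by descending score; unscorable pockets follow with NaN score and rank.
    """

    table: pd.DataFrame
    mu: float
    sigma: float
    mu_h: float
    sigma_h: float
    parameters: dict = field(default_factory=dict)

    def rank_of(self, pocket_id: int) -> int | None:
        row = self.table[self.table["pocket_id"] == pocket_id]
        if row.empty or pd.isna(row["rank"].iloc[0]):
            return None
        return int(row["rank"].iloc[0])

    def to_csv_text(self) -> str:
        """Fixed 6-decimal CSV; byte-stable across runs for identical inputs."""

        def fmt(v: float) -> str:
            if pd.isna(v):
                return ""
            v = float(v)
            if v == 0.0:
                v = 0.0  # normalize -0.0
            return f"{v:.6f}"

        lines = ["pocket_id,n_residues,mean_shift_pct,z_dyn,hydrophobic_density,z_hyd,score,rank"]
        for _, r in self.table.iterrows():
            rank = "" if pd.isna(r["rank"]) else str(int(r["rank"]))
            lines.append(
                f"{int(r['pocket_id'])},{int(r['n_residues'])},"
                f"{fmt(r['mean_shift_pct'])},{fmt(r['z_dyn'])},"
                f"{fmt(r['hydrophobic_density'])},{fmt(r['z_hyd'])},"
                f"{fmt(r['score'])},{rank}"
            )
        return "\n".join(lines) + "\n"

    def write_csv(self, path) -> None:
        Path(path).write_text(self.to_csv_text())

    def to_json_dict(self, provenance: dict | None = None) -> dict:
        rows = []
        for _, r in self.table.iterrows():
            rows.append(
                {
                    "pocket_id": int(r["pocket_id"]),
                    "n_residues": int(r["n_residues"]),
                    "mean_shift_pct": None if pd.isna(r["mean_shift_pct"]) else float(r["mean_shift_pct"]),
                    "z_dyn": None if pd.isna(r["z_dyn"]) else float(r["z_dyn"]),
                    "hydrophobic_density": float(r["hydrophobic_density"]),
                    "z_hyd": None if pd.isna(r["z_hyd"]) else float(r["z_hyd"]),
                    "score": None if pd.isna(r["score"]) else float(r["score"]),
                    "rank": None if pd.isna(r["rank"]) else int(r["rank"]),
                }
            )
        return {
            "version": __version__,
            "parameters": self.parameters,
            "population": {
                "mean_shift": {"mu": self.mu, "sigma": self.sigma},
                "hydrophobic_density": {"mu": self.mu_h, "sigma": self.sigma_h},
            },
            "pockets": rows,
            "provenance": provenance or {},
        }

    def write_json(self, path, provenance: dict | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict(provenance), indent=2) + "\n")


def perturb_pocket(
    K: KirchhoffMatrix,
    pocket_nodes: Iterable[int],
    params: ScoringParameters | None = None,
    base_gamma: float = 1.0,
) -> KirchhoffMatrix:
    """Stiffen all pairwise springs within a pocket, distance notwithstanding.

    Every unordered pair of pocket nodes gets spring weight
    ``perturbed_gamma / base_gamma`` (in base-γ units) — set, not added, and
    inserted even between pairs beyond the contact cutoff.  The diagonal is
    recomputed so rows still sum to zero.
    """
    params = params or ScoringParameters()
    idx = np.asarray(sorted(set(int(i) for i in pocket_nodes)), dtype=int)
    if idx.size < 2:
        raise ValueError("pocket must resolve to at least two nodes")
    if idx.min() < 0 or idx.max() >= K.n_nodes:
        raise IndexError("pocket node index out of range")
    weight = params.perturbed_gamma / base_gamma
    m = K.matrix.copy()
    m[np.ix_(idx, idx)] = -weight
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, -m.sum(axis=1))
    return KirchhoffMatrix(matrix=m, model=K.model)


def _degenerate_clusters(eigenvalues: np.ndarray, rel_tol: float = 1e-8) -> list[list[int]]:
    """Group consecutive (sorted) eigenvalues closer than rel_tol × scale."""
    scale = max(float(np.abs(eigenvalues).max()), 1.0)
    clusters: list[list[int]] = [[0]]
    for i in range(1, len(eigenvalues)):
        if eigenvalues[i] - eigenvalues[i - 1] <= rel_tol * scale:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    return clusters


def match_modes(
    unperturbed: GNMSpectrum,
    perturbed: GNMSpectrum,
    params: ScoringParameters | None = None,
) -> ModeMatching:
    """Re-identify each slow unperturbed mode among the perturbed modes.

    Computes the |cosine| overlap block between the slowest ``n_global``
    unperturbed eigenvectors and the first ``n_perturbed`` perturbed ones
    (eigenvector sign is arbitrary, so the absolute inner product is used),
    then assigns greedily: the largest overlap in the block is fixed first,
    its row and column removed, and so on, yielding distinct matches.  Ties
    fall to the lower mode index (row-major argmax).

    Degenerate perturbed eigenvalues need special care: within a degenerate
    eigenvalue any orthonormal basis of its eigenspace is equally valid, so
    raw eigenvector overlaps are basis noise.  Perturbed modes are therefore
    grouped into numerically degenerate clusters, and a reference mode's
    overlap with a cluster is the norm of its projection onto the cluster
    subspace (orthogonalized against projections already consumed from that
    cluster).  Singleton clusters — the generic case — reduce exactly to the
    plain greedy rule above.  Any assignment that touched a multi-member
    cluster, or was decided by a near-tie, sets the ``degenerate`` flag.
    """
    params = params or ScoringParameters()
    n_global = min(params.n_global, unperturbed.n_modes, perturbed.n_modes)
    if n_global == 0:
        raise ValueError("no retained modes available for matching")
    if n_global < params.n_global:
        warnings.warn(
            ModeCountWarning(
                f"only {n_global} retained mode(s); n_global clamped from {params.n_global}"
            ),
            stacklevel=2,
        )
    n_pert = min(params.n_perturbed, perturbed.n_modes)

    u = unperturbed.eigenvectors[:, :n_global]
    v = perturbed.eigenvectors[:, :n_pert]
    clusters = _degenerate_clusters(perturbed.eigenvalues[:n_pert])

    if all(len(c) == 1 for c in clusters):
        overlap = np.abs(u.T @ v)  # unit vectors: |cos| = |dot|
        work = overlap.copy()
        assigned: dict[int, tuple[int, float]] = {}
        degenerate = False
        for _ in range(n_global):
            flat = int(np.argmax(work))
            m, n = divmod(flat, work.shape[1])
            tied = np.isclose(work, work[m, n], rtol=0.0, atol=DEGENERACY_TOL).sum()
            if tied > 1:
                degenerate = True
            assigned[m] = (n, float(overlap[m, n]))
            work[m, :] = -1.0
            work[:, n] = -1.0
        matched = [assigned[m][0] for m in range(n_global)]
        overlaps = [assigned[m][1] for m in range(n_global)]
        return ModeMatching(matched_indices=matched, overlaps=overlaps, degenerate=degenerate)

    return _match_modes_degenerate(u, v, clusters, n_global)


def _match_modes_degenerate(
    u: np.ndarray, v: np.ndarray, clusters: list[list[int]], n_global: int
) -> ModeMatching:
    """Cluster-aware greedy matching used when perturbed eigenvalues repeat."""
    # per-cluster subspace basis and already-consumed directions (subspace coords)
    bases = [v[:, c] for c in clusters]
    used: list[list[np.ndarray]] = [[] for _ in clusters]
    capacity = [len(c) for c in clusters]

    def effective(m: int, ci: int) -> tuple[float, np.ndarray]:
        p = bases[ci].T @ u[:, m]  # projection in subspace coordinates
        for d in used[ci]:
            p = p - (d @ p) * d
        return float(np.linalg.norm(p)), p

    assigned_rows: set[int] = set()
    rows_in_cluster: dict[int, list[int]] = {ci: [] for ci in range(len(clusters))}
    row_overlap: dict[int, float] = {}
    for _ in range(n_global):
        best = (-1.0, 0, 0)
        for m in range(n_global):
            if m in assigned_rows:
                continue
            for ci in range(len(clusters)):
                if capacity[ci] == 0:
                    continue
                val, _ = effective(m, ci)
                if val > best[0] + 0.0:
                    best = (val, m, ci)
        _, m, ci = best
        val, p = effective(m, ci)
        if val > 0:
            used[ci].append(p / np.linalg.norm(p))
        capacity[ci] -= 1
        assigned_rows.add(m)
        rows_in_cluster[ci].append(m)
        row_overlap[m] = min(val, 1.0)
    # within a cluster all eigenvalues are numerically equal, so member
    # indices are interchangeable; hand them out in ascending row order to
    # keep the null perturbation an exact identity
    result: dict[int, int] = {}
    for ci, rows in rows_in_cluster.items():
        for member, m in zip(clusters[ci], sorted(rows)):
            result[m] = member
    matched = [result[m] for m in range(n_global)]
    overlaps = [row_overlap[m] for m in range(n_global)]
    return ModeMatching(matched_indices=matched, overlaps=overlaps, degenerate=True)


def eigenvalue_shift(
    unperturbed: GNMSpectrum,
    perturbed: GNMSpectrum,
    matching: ModeMatching,
    params: ScoringParameters | None = None,
    pocket_id: int = -1,
    n_resolved: int = 0,
) -> PerturbationResult:
    """Percentage shift of each matched mode and their mean.

    Δλ_k = (λ_k^p − λ_k) / λ_k × 100 for matched pairs; the pocket's
    dynamics score is the arithmetic mean over the matched global modes.
    """
    del params  # window sizes already encoded in the matching
    k = len(matching.matched_indices)
    lam = unperturbed.eigenvalues[:k]
    lam_p = perturbed.eigenvalues[np.asarray(matching.matched_indices, dtype=int)]
    shifts = (lam_p - lam) / lam * 100.0
    return PerturbationResult(
        pocket_id=pocket_id,
        n_resolved=n_resolved,
        matched_mode_indices=list(matching.matched_indices),
        per_mode_shift=shifts,
        mean_shift=float(shifts.mean()),
        min_overlap=float(min(matching.overlaps)),
        degenerate_overlaps=matching.degenerate,
    )


def _population_z(values: np.ndarray, label: str) -> tuple[np.ndarray, float, float]:
    """Population z-scores (ddof=0); constant columns go to zero with a warning."""
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if sigma == 0.0:
        warnings.warn(
            DegenerateVarianceWarning(f"degenerate {label} variance; z-scores set to 0"),
            stacklevel=3,
        )
        return np.zeros_like(values), mu, 0.0
    return (values - mu) / sigma, mu, sigma


def score_pockets(
    results: Sequence[PerturbationResult],
    pockets: PocketSet,
    resolved_counts: dict[int, int] | None = None,
    parameters: dict | None = None,
) -> PocketRanking:
    """Standardize shifts and hydrophobic densities, combine, and rank.

    z-scores use the population (divide-by-P) standard deviation over the
    scored pockets only, so an unscorable pocket cannot distort the others.
    Final score is the equal-weight mean of the two z-scores; ties are broken
    by larger z_dyn, then smaller pocket_id.
    """
    if len(results) < 2:
        raise ValueError("scoring needs at least two perturbed pockets")
    by_id = {r.pocket_id: r for r in results}
    scored_ids = [p.pocket_id for p in pockets if p.pocket_id in by_id]

    shifts = np.array([by_id[i].mean_shift for i in scored_ids], dtype=float)
    dens = np.array([pockets.by_id(i).hydrophobic_density for i in scored_ids], dtype=float)
    if shifts.std(ddof=0) == 0.0 and dens.std(ddof=0) == 0.0:
        raise NoSignalError(
            "no discriminating signal: mean shifts and hydrophobic densities both constant"
        )
    z_dyn, mu, sigma = _population_z(shifts, "dynamics")
    z_hyd, mu_h, sigma_h = _population_z(dens, "hydrophobic-density")
    score = (z_dyn + z_hyd) / 2.0

    rows = []
    for j, pid in enumerate(scored_ids):
        rows.append(
            {
                "pocket_id": pid,
                "n_residues": by_id[pid].n_resolved,
                "mean_shift_pct": shifts[j],
                "z_dyn": z_dyn[j],
                "hydrophobic_density": dens[j],
                "z_hyd": z_hyd[j],
                "score": score[j],
            }
        )
    rows.sort(key=lambda r: (-r["score"], -r["z_dyn"], r["pocket_id"]))
    for rank, row in enumerate(rows, start=1):
        row["rank"] = rank

    # unscorable pockets: reported, never ranked, excluded from mu/sigma
    counts = resolved_counts or {}
    for p in pockets:
        if p.pocket_id in by_id:
            continue
        rows.append(
            {
                "pocket_id": p.pocket_id,
                "n_residues": counts.get(p.pocket_id, 0),
                "mean_shift_pct": np.nan,
                "z_dyn": np.nan,
                "hydrophobic_density": p.hydrophobic_density,
                "z_hyd": np.nan,
                "score": np.nan,
                "rank": np.nan,
            }
        )

    table = pd.DataFrame(
        rows,
        columns=[
            "pocket_id", "n_residues", "mean_shift_pct", "z_dyn",
            "hydrophobic_density", "z_hyd", "score", "rank",
        ],
    )
    return PocketRanking(
        table=table, mu=mu, sigma=sigma, mu_h=mu_h, sigma_h=sigma_h,
        parameters=parameters or {},
    )


def run_apop(
    model: StructureModel,
    pockets: PocketSet,
    gnm_params: GNMParameters | None = None,
    scoring_params: ScoringParameters | None = None,
) -> PocketRanking:
    """Full pipeline: contact matrix → spectrum → per-pocket perturbation → ranking.

    Deterministic for fixed inputs and parameters: the eigensolver is a dense
    symmetric decomposition with a fixed sign convention, and no step draws
    random numbers.
    """
    gnm_params = gnm_params or GNMParameters()
    scoring_params = scoring_params or ScoringParameters()

    K = build_kirchhoff(model, gnm_params)
    reference = decompose(K)
    node_map = map_pockets_to_nodes(pockets, model)

    results: list[PerturbationResult] = []
    for pocket in pockets:
        pid = pocket.pocket_id
        if pid in node_map.unscorable:
            continue
        nodes = node_map.resolved[pid]
        K_p = perturb_pocket(K, nodes, scoring_params, base_gamma=gnm_params.gamma)
        perturbed = decompose(K_p)
        matching = match_modes(reference, perturbed, scoring_params)
        results.append(
            eigenvalue_shift(
                reference, perturbed, matching, scoring_params,
                pocket_id=pid, n_resolved=len(nodes),
            )
        )

    counts = {pid: len(ix) for pid, ix in node_map.resolved.items()}
    params_doc = {
        "cutoff": gnm_params.cutoff,
        "gamma": gnm_params.gamma,
        "perturbed_gamma": scoring_params.perturbed_gamma,
        "n_global": scoring_params.n_global,
        "n_perturbed": scoring_params.n_perturbed,
        "n_nodes": model.n_nodes,
    }
    return score_pockets(results, pockets, resolved_counts=counts, parameters=params_doc)


def top_k_success(
    ranking: PocketRanking,
    known_allosteric_pocket_ids: Iterable[int],
    k: int = 3,
) -> bool:
    """True iff the best-ranked known pocket lands within the top *k*.

    When several pockets overlap the known site (common in multimers), the
    highest-ranking occurrence governs.  Known ids absent from the ranking
    (the pocket finder missed the site) count as failure, with a warning.
    """
    known = set(known_allosteric_pocket_ids)
    ranks = [r for pid in known if (r := ranking.rank_of(pid)) is not None]
    if not ranks:
        warnings.warn(
            PocketResolutionWarning(
                f"known pocket id(s) {sorted(known)} not present in the ranking"
            ),
            stacklevel=2,
        )
        return False
    return min(ranks) <= k


def hash_file(path) -> str:
    """SHA-256 of a file, for output provenance."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
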
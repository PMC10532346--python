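"""RMSD clustering, GNM dynamical domains and hybrid conformational sampling.

The hybrid sampler follows the ClustENM(D) recipe: starting from a
(relaxed) structure, each generation draws conformers as random linear
combinations of low-frequency ANM modes scaled to a target RMSD,
clusters the pool by pairwise RMSD with a UPGMA tree, keeps cluster
representatives, relaxes them through a pluggable hook, and repeats.
All randomness flows from one seeded generator, so runs are bit
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .enm import ElasticModel, ModeSet, build_hessian, solve_modes
from .ensemble import kabsch_superpose
from .structures import Structure

__all__ = [
    "RMSDTree", "DomainLabels", "HybridConfig", "HybridRun",
    "upgma_cluster", "cut_tree", "gnm_domains", "sample_conformers",
    "cluster_generation", "run_hybrid", "make_enm_relaxer",
]


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------

@dataclass
class RMSDTree:
    """Average-linkage (UPGMA) tree over ensemble members."""

    linkage: np.ndarray  # (M−1)×4 scipy linkage records
    labels: list[str]
    distances: np.ndarray  # original M×M matrix (kept for medoids)


def upgma_cluster(d: np.ndarray, labels: list[str] | None = None) -> RMSDTree:
    """UPGMA (average-linkage) agglomeration of a symmetric RMSD matrix.

    Ties are broken deterministically (lowest-index pair, the scipy
    nearest-neighbour chain convention).
    """
    d = np.asarray(d, float)
    m = d.shape[0]
    if d.shape != (m, m):
        raise ValueError("distance matrix must be square")
    if np.abs(d - d.T).max() > 1e-8:
        raise ValueError("distance matrix is not symmetric")
    if np.abs(np.diag(d)).max() > 1e-8:
        raise ValueError("distance matrix diagonal must be zero")
    labels = labels or [str(i) for i in range(m)]
    if m == 1:
        return RMSDTree(np.empty((0, 4)), labels, d.copy())
    z = sch.linkage(squareform(0.5 * (d + d.T), checks=False),
                    method="average")
    return RMSDTree(z, labels, d.copy())


def _medoid(members: list[int], d: np.ndarray) -> int:
    sub = d[np.ix_(members, members)]
    return members[int(np.argmin(sub.mean(axis=1)))]


def cut_tree(t: RMSDTree, cutoff: float | None = None,
             max_clusters: int | None = None
             ) -> tuple[list[list[int]], list[int]]:
    """Cut the UPGMA tree at a height (Å) or to at most ``max_clusters``.

    Returns the clusters (member index lists, ordered by first member)
    and one representative per cluster — the medoid, i.e. the member
    with the lowest mean RMSD to its co-members.
    """
    m = len(t.labels)
    if m == 1:
        return [[0]], [0]
    if cutoff is not None:
        if cutoff <= 0:
            raise ValueError("cutoff must be positive")
        assignment = sch.fcluster(t.linkage, t=cutoff, criterion="distance")
    elif max_clusters is not None:
        assignment = sch.fcluster(t.linkage, t=max_clusters,
                                  criterion="maxclust")
    else:
        raise ValueError("give either a cutoff or max_clusters")
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(assignment):
        clusters.setdefault(int(c), []).append(i)
    ordered = sorted(clusters.values(), key=lambda mem: mem[0])
    reps = [_medoid(mem, t.distances) for mem in ordered]
    return ordered, reps


# ---------------------------------------------------------------------------
# GNM dynamical domains
# ---------------------------------------------------------------------------

@dataclass
class DomainLabels:
    labels: np.ndarray
    n_domains: int
    modes_used: int


def _farthest_point_kmeans(x: np.ndarray, k: int,
                           max_iter: int = 200) -> np.ndarray:
    """Lloyd k-means with deterministic farthest-point seeding.

    The first centre is the point farthest from the data mean; each
    following centre is the point farthest from its nearest chosen
    centre.  No randomness, so results are reproducible and invariant
    to atom order up to label permutation for well-separated clusters.
    """
    n = x.shape[0]
    centers = [int(np.argmax(((x - x.mean(axis=0)) ** 2).sum(axis=1)))]
    dist = ((x - x[centers[0]]) ** 2).sum(axis=1)
    while len(centers) < k:
        nxt = int(np.argmax(dist))
        centers.append(nxt)
        dist = np.minimum(dist, ((x - x[nxt]) ** 2).sum(axis=1))
    c = x[centers].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            mask = labels == j
            if mask.any():
                c[j] = x[mask].mean(axis=0)
    return labels


def gnm_domains(gnm_modes: ModeSet, n_modes: int, n_domains: int) -> DomainLabels:
    """Dynamical domain decomposition by spectral clustering of GNM modes.

    Atoms are embedded in the row space of the first ``n_modes`` mode
    shapes, rows are normalised to the unit sphere, and clustered by
    deterministic k-means.  Regions moving in opposite directions in the
    slow modes end up in different domains; contiguity is not enforced.
    To include the zero mode, solve the GNM with ``skip_zeros=False``.
    """
    if gnm_modes.kind != "gnm":
        raise ValueError("domain decomposition expects GNM modes")
    if n_modes < 1 or n_modes > gnm_modes.n_modes:
        raise ValueError("n_modes out of range")
    x = gnm_modes.vectors[:, :n_modes].copy()
    n = x.shape[0]
    if n_domains > n:
        raise ValueError("more domains than atoms requested")
    norms = np.linalg.norm(x, axis=1)
    nz = norms > 1e-12
    x[nz] /= norms[nz, None]
    labels = _farthest_point_kmeans(x, n_domains)
    return DomainLabels(labels, int(len(np.unique(labels))), n_modes)


# ---------------------------------------------------------------------------
# Hybrid sampling
# ---------------------------------------------------------------------------

Relaxer = Callable[[Structure, np.random.Generator], Structure]


def identity_relaxer(s: Structure, rng: np.random.Generator) -> Structure:
    return s


def make_enm_relaxer(cutoff: float = 15.0, n_steps: int = 20,
                     step: float = 0.02) -> Relaxer:
    """Steepest descent on the ENM quadratic energy around each conformer.

    The rest lengths are the conformer's own contact distances, so the
    relaxer smooths local distortions introduced by the mode step
    without pulling the structure back to its parent.
    """

    def relax(s: Structure, rng: np.random.Generator) -> Structure:
        coords = s.coords
        model = ElasticModel(coords, cutoff=cutoff)
        from .enm import _contact_pairs
        pairs = _contact_pairs(coords, cutoff)
        rest = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]],
                              axis=1)
        x = coords.copy()
        for _ in range(n_steps):
            delta = x[pairs[:, 0]] - x[pairs[:, 1]]
            dist = np.linalg.norm(delta, axis=1)
            factor = (1.0 - rest / np.maximum(dist, 1e-9))[:, None]
            grad = np.zeros_like(x)
            np.add.at(grad, pairs[:, 0], factor * delta)
            np.add.at(grad, pairs[:, 1], -factor * delta)
            x -= step * grad
        out = s.copy()
        out.set_coords(x)
        return out

    return relax


@dataclass
class HybridConfig:
    """Parameters of a hybrid sampling run.

    ``max_clusters`` must have one entry per generation; a run with zero
    generations only relaxes the starting structure.
    """

    n_modes: int = 6
    n_generations: int = 5
    confs_per_parent: int = 50
    target_rmsd: float = 2.0
    max_clusters: list[int] = field(default_factory=lambda: [10, 20, 30, 40, 50])
    seed: int = 0
    cutoff: float = 15.0
    rmsd_mode: str = "exact"  # or "sampled": uniform(0.5·t, 1.5·t)
    relaxer: Relaxer = identity_relaxer

    def __post_init__(self) -> None:
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if len(self.max_clusters) < self.n_generations:
            raise ValueError("max_clusters needs one entry per generation")
        if self.rmsd_mode not in ("exact", "sampled"):
            raise ValueError("rmsd_mode must be 'exact' or 'sampled'")


@dataclass
class HybridRun:
    """Per-generation conformer sets with provenance."""

    generations: list[list[Structure]]
    manifest: pd.DataFrame
    provenance: dict

    def all_structures(self) -> list[Structure]:
        return [s for gen in self.generations for s in gen]

    def coords_trajectory(self) -> np.ndarray:
        return np.array([s.coords for s in self.all_structures()])


def sample_conformers(parent: Structure, ms: ModeSet, k: int,
                      target_rmsd: float, n_modes: int,
                      rng: np.random.Generator,
                      rmsd_mode: str = "exact") -> list[Structure]:
    """Draw conformers as random linear combinations of ANM modes.

    Mode coefficients are standard normal; the combined displacement is
    rescaled so each conformer sits exactly at ``target_rmsd`` from the
    parent (or at a uniform(0.5·t, 1.5·t) draw with ``rmsd_mode=
    'sampled'``), hence every displacement lies in the mode subspace.
    """
    if target_rmsd <= 0:
        raise ValueError("target_rmsd must be positive")
    if n_modes > ms.n_modes:
        raise ValueError("n_modes exceeds the available modes")
    if not ms.is_3d:
        raise ValueError("sampling requires 3D modes")
    n = len(parent)
    base = parent.coords
    u = ms.vectors[:, :n_modes]
    out = []
    for c in range(k):
        coeffs = rng.standard_normal(n_modes)
        disp = u @ coeffs
        norm = np.linalg.norm(disp)
        if norm == 0:
            continue
        amp = target_rmsd
        if rmsd_mode == "sampled":
            amp = float(rng.uniform(0.5 * target_rmsd, 1.5 * target_rmsd))
        scale = amp * np.sqrt(n) / norm
        conf = parent.copy()
        conf.title = f"{parent.title} conf {c}"
        conf.set_coords(base + scale * disp.reshape(n, 3))
        out.append(conf)
    return out


def _pairwise_rmsd_superposed(structs: list[Structure]) -> np.ndarray:
    m = len(structs)
    coords = [s.coords for s in structs]
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = kabsch_superpose(coords[j], coords[i]).rmsd
    return d


def _pairwise_rmsd_direct(structs: list[Structure]) -> np.ndarray:
    """Superposition-free pairwise RMSD via the Gram matrix (vectorised)."""
    x = np.array([s.coords.ravel() for s in structs])
    x -= x.mean(axis=0)  # reduce cancellation error in the Gram trick
    n = x.shape[1] // 3
    sq = (x ** 2).sum(axis=1)
    d2 = (sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)) / n
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.clip(d2, 0.0, None))
    return 0.5 * (d + d.T)


def cluster_generation(confs: list[Structure], max_clusters: int,
                       superpose: bool = False) -> list[Structure]:
    """UPGMA-cluster conformers by pairwise RMSD, keep medoids.

    At most ``max_clusters`` representatives are returned; when the pool
    is already small enough every conformer is kept.  Mode-sampled
    conformers carry no rigid-body displacement, so by default the RMSD
    is computed in their common frame (vectorised); pass ``superpose``
    for pools that are not pre-aligned.
    """
    if not confs:
        raise ValueError("no conformers to cluster")
    if max_clusters >= len(confs):
        return list(confs)
    d = (_pairwise_rmsd_superposed(confs) if superpose
         else _pairwise_rmsd_direct(confs))
    tree = upgma_cluster(d, [s.title for s in confs])
    _, reps = cut_tree(tree, max_clusters=max_clusters)
    return [confs[i] for i in reps]


def run_hybrid(parent: Structure, cfg: HybridConfig) -> HybridRun:
    """Run the full hybrid sampling loop.

    Generation 0 is the relaxed starting structure.  Each later
    generation re-solves the ANM on every current parent, draws
    ``confs_per_parent`` conformers at the target RMSD, pools them,
    clusters the pool down to that generation's ``max_clusters`` entry
    and relaxes the representatives.  A relaxer failure drops the
    conformer and the run continues.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    start = cfg.relaxer(parent.copy(), rng)
    start.title = parent.title or "start"
    generations = [[start]]
    rows.append({"generation": 0, "member": 0, "parent": -1,
                 "rmsd_to_parent": 0.0, "label": start.title})
    current = [start]
    for g in range(1, cfg.n_generations + 1):
        pool: list[Structure] = []
        parent_of: list[int] = []
        for pi, p in enumerate(current):
            model = ElasticModel(p.coords, cutoff=cfg.cutoff)
            hessian = build_hessian(model, sparse=len(p) > 600)
            modes = solve_modes(hessian, n_modes=cfg.n_modes, kind="anm")
            confs = sample_conformers(p, modes, cfg.confs_per_parent,
                                      cfg.target_rmsd, cfg.n_modes, rng,
                                      cfg.rmsd_mode)
            pool.extend(confs)
            parent_of.extend([pi] * len(confs))
        reps = cluster_generation(pool, cfg.max_clusters[g - 1])
        rep_idx = {id(s): i for i, s in enumerate(pool)}
        relaxed = []
        kept_parents = []
        for s in reps:
            try:
                relaxed.append(cfg.relaxer(s, rng))
                kept_parents.append(parent_of[rep_idx[id(s)]])
            except Exception:  # noqa: BLE001 - relaxer contract: drop & log
                continue
        if not relaxed:
            break
        for mi, (s, pi) in enumerate(zip(relaxed, kept_parents)):
            rmsd = kabsch_superpose(s.coords, current[pi].coords).rmsd
            rows.append({"generation": g, "member": mi, "parent": pi,
                         "rmsd_to_parent": rmsd, "label": s.title})
        generations.append(relaxed)
        current = relaxed
    manifest = pd.DataFrame(rows)
    provenance = {"seed": cfg.seed, "n_modes": cfg.n_modes,
                  "n_generations": cfg.n_generations,
                  "confs_per_parent": cfg.confs_per_parent,
                  "target_rmsd": cfg.target_rmsd,
                  "max_clusters": list(cfg.max_clusters),
                  "cutoff": cfg.cutoff, "rmsd_mode": cfg.rmsd_mode}
    return HybridRun(generations, manifest, provenance)
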
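"""Elastic network models: ANM Hessians, GNM Kirchhoff matrices, RTB.

An elastic network connects every pair of nodes within a distance cutoff
by a harmonic spring.  The ANM Hessian (3N×3N) yields directional normal
modes; the GNM Kirchhoff matrix (N×N) yields isotropic fluctuation
magnitudes.  The RTB model projects the Hessian into a basis of rigid
translations/rotations of atom blocks before diagonalisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg
import scipy.stats
from scipy.spatial import cKDTree

from .structures import Structure

__all__ = [
    "ElasticModel", "ModeSet", "BlockPartition", "gamma_value",
    "build_kirchhoff", "build_hessian", "solve_modes", "build_rtb_modes",
    "optimize_blocks", "mode_statistics", "cross_correlations",
]

GammaFunction = Callable[[int, int, float], float]


@dataclass
class ElasticModel:
    """Node coordinates plus spring topology parameters.

    ``gamma`` is a constant force constant or a pair function
    ``gamma(i, j, distance) -> force constant``.
    """

    coords: np.ndarray  # N×3 Å
    cutoff: float = 15.0
    gamma: float | GammaFunction = 1.0
    kind: str = "anm"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.kind not in ("anm", "gnm", "rtb"):
            raise ValueError(f"unknown model kind {self.kind!r}")

    def gamma_of(self, i: int, j: int, dist: float) -> float:
        g = self.gamma(i, j, dist) if callable(self.gamma) else float(self.gamma)
        if g < 0:
            raise ValueError(f"negative force constant for pair ({i}, {j})")
        return g


@dataclass
class ModeSet:
    """Eigenvectors (columns) with eigenvalues for one model kind.

    ``vectors`` is D×m with D = 3N for anm/rtb/pca/defvec and D = N for
    gnm.  ENM eigenvalues ascend; PCA variances descend.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    kind: str
    n_zero_skipped: int = 0
    source_atoms: Structure | None = None
    variances: np.ndarray | None = None

    @property
    def n_modes(self) -> int:
        return self.vectors.shape[1]

    @property
    def dim(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.dim if self.kind == "gnm" else self.dim // 3

    @property
    def is_3d(self) -> bool:
        return self.kind != "gnm"

    def vector_per_atom(self, k: int) -> np.ndarray:
        """Mode k reshaped to per-atom rows (N×3, or N×1 for GNM)."""
        v = self.vectors[:, k]
        return v[:, None] if self.kind == "gnm" else v.reshape(-1, 3)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-magnitude component of each mode is positive."""
    idx = np.abs(vectors).argmax(axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def gamma_value(kind: str = "uniform", n_residues: int | None = None,
                base: float = 1.0, ss_labels: np.ndarray | None = None,
                sequence_ids: np.ndarray | None = None,
                intra_ss_factor: float = 6.0,
                backbone_factor: float = 3.0) -> GammaFunction:
    """Build a spring-constant (gamma) function.

    ``uniform`` returns 1 for every pair.  ``ed`` returns the
    essential-dynamics-refined constant 2.9·ln(N) − 2.9 for N residues.
    ``structure_based`` multiplies ``base`` by ``intra_ss_factor`` for
    pairs in the same helix/strand element (``ss_labels``: per-atom
    element id, 0 = coil), by ``backbone_factor`` for (i, i±3/4)
    neighbours in sequence (``sequence_ids``), and by 1 otherwise.
    """
    if kind == "uniform":
        return lambda i, j, d: 1.0
    if kind == "ed":
        if n_residues is None or n_residues <= 1:
            raise ValueError("ed gamma requires a residue count > 1")
        g = 2.9 * math.log(n_residues) - 2.9
        return lambda i, j, d: g
    if kind == "structure_based":
        labels = None if ss_labels is None else np.asarray(ss_labels)
        seq = None if sequence_ids is None else np.asarray(sequence_ids)

        def gamma(i: int, j: int, d: float) -> float:
            mult = 1.0
            if labels is not None and labels[i] and labels[i] == labels[j]:
                mult = intra_ss_factor
            elif seq is not None and abs(int(seq[i]) - int(seq[j])) in (3, 4):
                mult = backbone_factor
            return base * mult

        return gamma
    raise ValueError(f"unknown gamma kind {kind!r}")


def _contact_pairs(coords: np.ndarray, cutoff: float) -> np.ndarray:
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    return pairs.reshape(-1, 2)


def build_kirchhoff(m: ElasticModel) -> np.ndarray:
    """GNM Kirchhoff matrix: Γ_ij = −γ_ij within cutoff, rows sum to zero."""
    n = m.coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    k = np.zeros((n, n))
    for i, j in _contact_pairs(m.coords, m.cutoff):
        d = float(np.linalg.norm(m.coords[i] - m.coords[j]))
        g = m.gamma_of(i, j, d)
        k[i, j] -= g
        k[j, i] -= g
        k[i, i] += g
        k[j, j] += g
    return k


def build_hessian(m: ElasticModel, sparse: bool = False
                  ) -> np.ndarray | scipy.sparse.csr_matrix:
    """ANM Hessian from pairwise dyadics −γ ΔΔᵀ/|Δ|² within the cutoff."""
    coords = m.coords
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    pairs = _contact_pairs(coords, m.cutoff)
    if sparse:
        h = scipy.sparse.lil_matrix((3 * n, 3 * n))
    else:
        h = np.zeros((3 * n, 3 * n))
    for i, j in pairs:
        delta = coords[j] - coords[i]
        d2 = float(delta @ delta)
        if d2 == 0.0:
            raise ValueError(f"coincident contact atoms {i} and {j}")
        g = m.gamma_of(i, j, math.sqrt(d2))
        block = (g / d2) * np.outer(delta, delta)
        si, sj = 3 * i, 3 * j
        h[si:si + 3, sj:sj + 3] -= block
        h[sj:sj + 3, si:si + 3] -= block
        h[si:si + 3, si:si + 3] += block
        h[sj:sj + 3, sj:sj + 3] += block
    return h.tocsr() if sparse else h


def solve_modes(matrix, n_modes: int = 20, zero_tol: float = 1e-6,
                skip_zeros: bool = True, kind: str = "anm",
                source_atoms: Structure | None = None) -> ModeSet:
    """Ascending eigenpairs of a symmetric ENM matrix.

    Eigenvalues below ``zero_tol`` times the largest computed eigenvalue
    are counted as rigid-body/zero modes and skipped by default (6 for a
    connected ANM, 1 for a connected GNM).  Requests beyond the available
    non-zero spectrum are truncated.
    """
    is_sparse = scipy.sparse.issparse(matrix)
    d = matrix.shape[0]
    if matrix.shape[0] != matrix.shape[1]:
        raise ValueError("matrix must be square")
    if is_sparse or d > 2000:
        # shift-invert around zero captures the low-frequency end cheaply
        mat = matrix.tocsc() if is_sparse else scipy.sparse.csc_matrix(matrix)
        k = min(d - 1, n_modes + 12)
        vals, vecs = scipy.sparse.linalg.eigsh(mat, k=k, sigma=-1e-4,
                                               which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
        scale = float(abs(vals).max()) if len(vals) else 1.0
    else:
        if not np.allclose(matrix, matrix.T, atol=1e-8):
            raise ValueError("matrix must be symmetric")
        vals, vecs = scipy.linalg.eigh(matrix)
        scale = float(abs(vals).max()) if len(vals) else 1.0
    tol = zero_tol * max(scale, 1e-300)
    zero_mask = vals < tol
    n_zero = int(zero_mask.sum())
    if skip_zeros:
        vals, vecs = vals[~zero_mask], vecs[:, ~zero_mask]
    take = min(n_modes, vecs.shape[1])
    return ModeSet(_fix_signs(vecs[:, :take]), np.maximum(vals[:take], 0.0),
                   kind=kind, n_zero_skipped=n_zero,
                   source_atoms=source_atoms)


# ---------------------------------------------------------------------------
# Rotating and translating blocks
# ---------------------------------------------------------------------------

@dataclass
class BlockPartition:
    """Block id per atom for the RTB projection."""

    labels: np.ndarray
    min_size: int = 1
    max_size: int = 10 ** 9

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def block_ids(self) -> np.ndarray:
        return np.unique(self.labels)


def _rtb_projection(coords: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Orthonormal 3N×K basis of rigid block translations and rotations."""
    n = coords.shape[0]
    columns = []
    for b in np.unique(labels):
        idx = np.flatnonzero(labels == b)
        if idx.size == 0:
            raise ValueError(f"empty block {b}")
        centroid = coords[idx].mean(axis=0)
        basis = []
        for ax in range(3):
            v = np.zeros((n, 3))
            v[idx, ax] = 1.0
            basis.append(v.ravel())
        if idx.size > 2:  # tiny blocks get translations only
            for ax in range(3):
                e = np.zeros(3)
                e[ax] = 1.0
                v = np.zeros((n, 3))
                v[idx] = np.cross(np.repeat([e], idx.size, axis=0),
                                  coords[idx] - centroid)
                basis.append(v.ravel())
        block = np.array(basis).T  # 3N × dof
        q, r = np.linalg.qr(block)
        keep = np.abs(np.diag(r)) > 1e-10
        columns.append(q[:, keep])
    return np.hstack(columns)


def build_rtb_modes(m: ElasticModel, part: BlockPartition,
                    n_modes: int = 20, zero_tol: float = 1e-6) -> ModeSet:
    """Solve the Hessian in the rigid-block subspace and back-project.

    Blocks of one or two atoms contribute translations only (their
    rotations are undefined or degenerate).  Back-projected eigenvectors
    are orthonormal because the projection basis is.
    """
    if part.labels.shape[0] != m.coords.shape[0]:
        raise ValueError("partition labels must cover every atom")
    h = build_hessian(m)
    p = _rtb_projection(m.coords, part.labels)
    reduced = p.T @ h @ p
    reduced = 0.5 * (reduced + reduced.T)
    vals, vecs = scipy.linalg.eigh(reduced)
    # scale the zero threshold by the full Hessian, not the reduced
    # spectrum, which is all-zero in the single-block limit
    scale = max(float(abs(vals).max()), float(abs(h.diagonal()).max()))
    tol = zero_tol * max(scale, 1e-300)
    nonzero = vals >= tol
    n_zero = int((~nonzero).sum())
    vals, vecs = vals[nonzero], vecs[:, nonzero]
    take = min(n_modes, vecs.shape[1])
    back = p @ vecs[:, :take]
    return ModeSet(_fix_signs(back), vals[:take], kind="rtb",
                   n_zero_skipped=n_zero)


def optimize_blocks(part: BlockPartition, coords: np.ndarray,
                    min_size: int, max_size: int) -> BlockPartition:
    """Split oversize blocks by spatial bisection and merge undersize ones
    into the block with the nearest centroid."""
    if min_size > max_size:
        raise ValueError("min_size must not exceed max_size")
    coords = np.asarray(coords, float)
    labels = part.labels.copy()
    next_label = int(labels.max()) + 1

    changed = True
    while changed:
        changed = False
        for b in np.unique(labels):
            idx = np.flatnonzero(labels == b)
            if idx.size > max_size:
                pts = coords[idx]
                centered = pts - pts.mean(axis=0)
                # split along the principal axis at the median projection
                _, _, vt = np.linalg.svd(centered, full_matrices=False)
                proj = centered @ vt[0]
                half = proj > np.median(proj)
                if not half.any() or half.all():
                    half = np.zeros(idx.size, dtype=bool)
                    half[idx.size // 2:] = True
                labels[idx[half]] = next_label
                next_label += 1
                changed = True
    changed = True
    while changed:
        changed = False
        ids = np.unique(labels)
        if ids.size == 1:
            break
        centroids = {b: coords[labels == b].mean(axis=0) for b in ids}
        for b in ids:
            idx = np.flatnonzero(labels == b)
            if 0 < idx.size < min_size:
                others = [o for o in np.unique(labels) if o != b]
                if not others:
                    break
                dists = [np.linalg.norm(centroids[b] - centroids[o])
                         for o in others]
                target = others[int(np.argmin(dists))]
                labels[idx] = target
                changed = True
                break
    # relabel consecutively, stable in first-occurrence order
    remap: dict[int, int] = {}
    for lab in labels:
        remap.setdefault(int(lab), len(remap))
    labels = np.array([remap[int(lab)] for lab in labels])
    return BlockPartition(labels, min_size, max_size)


# ---------------------------------------------------------------------------
# Mode statistics and correlations
# ---------------------------------------------------------------------------

def mode_statistics(ms: ModeSet, traverse_rmsd: float = 2.0) -> dict:
    """Collectivity, rank score, mean square fluctuations and the per-atom
    maximum traversal distance at the given RMSD amplitude.

    Collectivity κ = (1/N)·exp(−Σ p_i ln p_i) with p_i ∝ |u_i|²; κ is 1
    for a fully collective mode and 1/N for a single-atom mode.  The
    score ranks modes by eigenvalue and by 1−κ (both ascending) and
    averages the two ranks (lower = more interesting low-frequency,
    collective mode).
    """
    if ms.kind == "defvec":
        raise ValueError("statistics are not defined for deformation vectors")
    n = ms.n_atoms
    m = ms.n_modes
    kappa = np.zeros(m)
    msf = np.zeros(n)
    max_dist = np.zeros((m, n))
    for k in range(m):
        per_atom = ms.vector_per_atom(k)
        amp2 = (per_atom ** 2).sum(axis=1)
        total = amp2.sum()
        if total <= 0:
            raise ValueError(f"mode {k} has zero norm")
        p = amp2 / total
        nz = p > 0
        kappa[k] = np.exp(-(p[nz] * np.log(p[nz])).sum()) / n
        if ms.eigenvalues is not None and len(ms.eigenvalues) > k \
                and ms.eigenvalues[k] > 0:
            msf += amp2 / ms.eigenvalues[k]
        max_dist[k] = traverse_rmsd * np.sqrt(amp2) * np.sqrt(n)
    lam = np.asarray(ms.eigenvalues[:m], float)
    rank_lam = scipy.stats.rankdata(lam, method="ordinal")
    rank_kap = scipy.stats.rankdata(1.0 - kappa, method="ordinal")
    score = 0.5 * (rank_lam + rank_kap) / m
    return {"collectivity": kappa, "score": score, "msf": msf,
            "max_distance": max_dist.max(axis=0), "max_distance_per_mode": max_dist}


def cross_correlations(ms: ModeSet) -> dict[str, np.ndarray]:
    """Raw covariance and normalised orientational cross-correlations.

    C = Σ_k λ_k⁻¹ u_k u_kᵀ; for 3D modes the per-atom 3×3 blocks are
    traced down to an N×N matrix before normalising the diagonal to 1.
    """
    lam = np.asarray(ms.eigenvalues, float)
    if np.any(lam <= 0):
        raise ValueError("cross-correlations require strictly positive "
                         "eigenvalues (skip zero modes first)")
    v = ms.vectors
    cov_full = (v / lam) @ v.T
    if ms.is_3d:
        n = ms.n_atoms
        cov = cov_full.reshape(n, 3, n, 3)
        cov = np.einsum("iaja->ij", cov)
    else:
        cov = cov_full
    diag = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
    orientational = cov / np.outer(diag, diag)
    return {"covariance": cov, "orientational": orientational}
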
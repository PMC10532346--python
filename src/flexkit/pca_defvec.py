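"""Deformation vectors between structure pairs and PCA of ensembles.

The covariance matrix of a superposed ensemble is the average (divisor M)
of the outer products q qᵀ of the deformation vectors between each member
and the converged mean structure.  When 3N exceeds M the spectrum is
obtained through the M×M Gram matrix, which has the same non-zero
eigenvalues at a fraction of the memory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .ensemble import StructEnsemble, kabsch_superpose
from .enm import ModeSet, _fix_signs

__all__ = ["DeformationVector", "deformation_vector", "compute_pca"]


@dataclass
class DeformationVector:
    """3N displacement between two superposed conformations."""

    vector: np.ndarray  # (3N,)
    rmsd: float  # |q|/sqrt(N) over weighted atoms
    weights: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.vector.size // 3

    def unit(self) -> np.ndarray:
        norm = np.linalg.norm(self.vector)
        if norm == 0:
            raise ValueError("zero deformation vector has no direction")
        return self.vector / norm


def deformation_vector(a: np.ndarray, b: np.ndarray,
                       weights: np.ndarray | None = None) -> DeformationVector:
    """Deformation vector q = x_b − x_a after weighted Kabsch superposition.

    Rigid-body differences are removed by superposing ``b`` onto ``a``
    first, so a pure rotation/translation gives a zero vector and
    |q|/√N equals the superposed RMSD.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    res = kabsch_superpose(b, a, weights)
    q = (res.apply(b) - a)
    if weights is not None:
        q = q * (np.asarray(weights, float) > 0)[:, None]
    return DeformationVector(q.ravel(), res.rmsd, weights)


def _numerical_rank(descending_vals: np.ndarray) -> int:
    # relative cutoff for round-off directions, absolute floor (Å²) for
    # ensembles with no variance at all
    if len(descending_vals) == 0:
        return 0
    tol = max(1e-9 * descending_vals[0], 1e-20)
    return int((descending_vals > tol).sum())


def compute_pca(e: StructEnsemble, n_comps: int = 20) -> ModeSet:
    """Principal components of the occupancy-weighted ensemble covariance.

    Components are returned with descending variances; missing positions
    (weight 0) use pairwise-available averaging with per-entry effective
    member counts.  Raises if the ensemble mean did not converge.
    """
    if not e.converged:
        raise ValueError("ensemble mean has not converged; rebuild with more "
                         "iterations before PCA")
    m, n = e.n_members, e.n_atoms
    if m < 2:
        raise ValueError("PCA requires at least 2 ensemble members")
    w3 = np.repeat(e.weights, 3, axis=1)  # M × 3N
    dev = (e.coords - e.mean_coords[None]).reshape(m, 3 * n) * w3
    full_weights = bool(np.all(e.weights == 1.0))
    max_rank = min(3 * n, m - 1)
    if n_comps > max_rank:
        warnings.warn(f"n_comps truncated from {n_comps} to effective rank "
                      f"{max_rank}", stacklevel=2)
        n_comps = max_rank
    if full_weights and 3 * n > m:
        gram = dev @ dev.T / m
        vals, vecs = scipy.linalg.eigh(gram)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        vals = np.clip(vals, 0.0, None)
        keep = min(n_comps, _numerical_rank(vals))
        comps = dev.T @ vecs[:, :keep]
        norms = np.linalg.norm(comps, axis=0)
        nz = norms > 1e-12
        comps[:, nz] /= norms[nz]
        variances = vals[:keep]
    else:
        if full_weights:
            cov = dev.T @ dev / m
        else:
            eff = w3.T @ w3  # per-entry effective member count
            cov = (dev.T @ dev) / np.maximum(eff, 1.0)
        vals, vecs = scipy.linalg.eigh(cov)
        order = np.argsort(vals)[::-1]
        vals, vecs = np.clip(vals[order], 0.0, None), vecs[:, order]
        keep = min(n_comps, _numerical_rank(vals))
        comps = vecs[:, :keep]
        variances = vals[:keep]
    if keep < n_comps:
        warnings.warn(f"only {keep} components above numerical rank; "
                      f"{n_comps} requested", stacklevel=2)
    return ModeSet(_fix_signs(comps), variances.copy(), kind="pca",
                   source_atoms=e.reference_atoms, variances=variances)
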
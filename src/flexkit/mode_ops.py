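"""Mode editing, comparison, matching, landscape projection and traversal.

Editing operations change the atom basis of a mode set (restrict to a
selection, copy Cα vectors to all atoms of a residue, Schur-complement a
Hessian down to a subsystem, or interpolate vectors between node sets
with thin-plate splines).  Comparison covers cosine overlaps, the
root-weighted square inner product (RWSIP) and the covariance overlap,
with linear-assignment mode matching on top.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.interpolate import RBFInterpolator
from scipy.optimize import linear_sum_assignment

from .ensemble import StructEnsemble
from .enm import ModeSet, _fix_signs
from .structures import AtomSelection, Structure

__all__ = [
    "OverlapResult", "ProjectionResult", "ModeMatch", "slice_modes",
    "extend_modes", "reduce_hessian", "interpolate_modes_tps",
    "compare_modes", "match_modes", "project_ensemble", "traverse_mode",
]


# ---------------------------------------------------------------------------
# Editing
# ---------------------------------------------------------------------------

def slice_modes(ms: ModeSet, sel: AtomSelection,
                renormalize: bool = True) -> ModeSet:
    """Restrict mode vectors to the selected atoms.

    With ``renormalize`` (default) the sliced columns are rescaled to
    unit norm, the convention expected for overlap comparisons.
    """
    idx = np.asarray(sel.indices, dtype=int)
    if idx.size == 0:
        raise ValueError("cannot slice modes to an empty selection")
    if idx.max() >= ms.n_atoms:
        raise ValueError("selection indexes atoms beyond the mode set")
    if ms.is_3d:
        rows = (3 * idx[:, None] + np.arange(3)[None, :]).ravel()
    else:
        rows = idx
    vectors = ms.vectors[rows].copy()
    if renormalize:
        norms = np.linalg.norm(vectors, axis=0)
        if np.any(norms == 0):
            raise ValueError("a sliced mode vanished on this selection")
        vectors /= norms
    return ModeSet(vectors, ms.eigenvalues.copy(), ms.kind,
                   ms.n_zero_skipped, sel.to_structure(),
                   None if ms.variances is None else ms.variances.copy())


def _residue_key(atom) -> tuple:
    return (atom.chain_id, atom.resnum, atom.icode)


def extend_modes(ms: ModeSet, target: Structure,
                 renormalize: bool = False) -> ModeSet:
    """Copy per-residue Cα mode vectors to every atom of the target.

    Residues are matched by (chain, residue number, insertion code)
    against the mode set's source atoms; every target residue must have
    a source Cα.
    """
    if not ms.is_3d:
        raise ValueError("extension requires 3D modes")
    if ms.source_atoms is None:
        raise ValueError("mode set carries no source atoms to extend from")
    source_idx: dict[tuple, int] = {}
    for i, atom in enumerate(ms.source_atoms.atoms):
        source_idx.setdefault(_residue_key(atom), i)
    rows = []
    missing = []
    for atom in target.atoms:
        key = _residue_key(atom)
        if key in source_idx:
            rows.append(source_idx[key])
        else:
            missing.append(key)
    if missing:
        shown = ", ".join(f"{c}:{r}{ic}" for c, r, ic in missing[:10])
        raise ValueError(f"{len(missing)} target residues have no source "
                         f"Cα (first: {shown})")
    per_atom = ms.vectors.reshape(ms.n_atoms, 3, ms.n_modes)
    extended = per_atom[rows].reshape(3 * len(target), ms.n_modes).copy()
    if renormalize:
        extended /= np.linalg.norm(extended, axis=0)
    return ModeSet(extended, ms.eigenvalues.copy(), ms.kind,
                   ms.n_zero_skipped, target.copy(),
                   None if ms.variances is None else ms.variances.copy())


def reduce_hessian(h: np.ndarray, subsystem: AtomSelection | np.ndarray
                   ) -> np.ndarray:
    """Effective Hessian of a subsystem embedded in its environment.

    Vibrational subsystem analysis: H_eff = H_ss − H_se H_ee⁻¹ H_es, with
    a pseudoinverse when the environment block is singular.  The result
    is symmetrised and has the environment's softening folded in.
    """
    h = np.asarray(h, float)
    n3 = h.shape[0]
    if h.shape != (n3, n3) or n3 % 3:
        raise ValueError("Hessian must be 3N×3N")
    idx = subsystem.indices if isinstance(subsystem, AtomSelection) else subsystem
    idx = np.asarray(idx, dtype=int)
    dof_s = (3 * idx[:, None] + np.arange(3)[None, :]).ravel()
    if dof_s.size == n3:
        warnings.warn("subsystem covers the whole structure; Hessian "
                      "returned unchanged", stacklevel=2)
        return h.copy()
    dof_e = np.setdiff1d(np.arange(n3), dof_s)
    hss = h[np.ix_(dof_s, dof_s)]
    hse = h[np.ix_(dof_s, dof_e)]
    hee = h[np.ix_(dof_e, dof_e)]
    heff = hss - hse @ np.linalg.pinv(hee, hermitian=True) @ hse.T
    return 0.5 * (heff + heff.T)


def interpolate_modes_tps(source_nodes: np.ndarray, vectors: np.ndarray,
                          target_nodes: np.ndarray,
                          smoothing: float = 0.0) -> np.ndarray:
    """Thin-plate-spline interpolation of mode vectors onto new nodes.

    Each Cartesian displacement component is fitted with the 3D TPS
    kernel U(r) = r plus an affine term, which reproduces the data
    exactly at the source nodes (``smoothing`` adds an optional ridge
    for near-degenerate node sets).
    """
    source_nodes = np.asarray(source_nodes, float)
    target_nodes = np.asarray(target_nodes, float)
    p = source_nodes.shape[0]
    if p < 4:
        raise ValueError("need at least 4 source nodes")
    centered = source_nodes - source_nodes.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 3:
        raise ValueError("source nodes are coplanar; the affine term is "
                         "degenerate")
    vectors = np.asarray(vectors, float)
    m = vectors.shape[1] if vectors.ndim == 2 else 1
    values = vectors.reshape(p, 3 * m)
    interp = RBFInterpolator(source_nodes, values, kernel="linear",
                             degree=1, smoothing=smoothing)
    out = interp(target_nodes)  # N × 3m
    n = target_nodes.shape[0]
    return out.reshape(n, 3, m).reshape(3 * n, m)


# ---------------------------------------------------------------------------
# Comparison
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    """m1×m2 mode-comparison matrix plus per-row cumulative overlaps."""

    matrix: np.ndarray
    metric: str
    row_cumulative: np.ndarray
    value: float | None = None  # scalar for rwsip / cov_overlap
    diagonal_only: bool = False

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)


def _mode_weights(ms: ModeSet) -> np.ndarray:
    """Variance contribution of each mode: λ for PCA, 1/λ for ENMs."""
    if ms.kind == "pca":
        return np.asarray(ms.variances if ms.variances is not None
                          else ms.eigenvalues, float)
    lam = np.asarray(ms.eigenvalues, float)
    if np.any(lam <= 0):
        raise ValueError("ENM weights need strictly positive eigenvalues")
    return 1.0 / lam


def compare_modes(a: ModeSet, b: ModeSet, metric: str = "overlap",
                  diagonal_only: bool = False,
                  normalise: bool = True) -> OverlapResult:
    """Compare two mode sets living on the same atoms.

    ``overlap`` gives pairwise correlation cosines (absolute values when
    ``normalise`` is on, signed raw projection products otherwise);
    ``rwsip`` and ``cov_overlap`` additionally report the variance-
    weighted scalar subspace similarity in ``value``.
    """
    if a.dim != b.dim:
        raise ValueError(
            f"mode dimensionalities differ ({a.dim} vs {b.dim}); slice or "
            "extend one set first")
    va = a.vectors / np.linalg.norm(a.vectors, axis=0)
    vb = b.vectors / np.linalg.norm(b.vectors, axis=0)
    raw = va.T @ vb
    matrix = np.abs(raw) if normalise else raw
    if diagonal_only:
        k = min(a.n_modes, b.n_modes)
        matrix = np.diag(np.diag(matrix[:k, :k]))
    row_cum = np.minimum(np.sqrt((matrix ** 2).sum(axis=1)), 1.0)
    value = None
    if metric == "rwsip":
        wa, wb = _mode_weights(a), _mode_weights(b)
        k = min(len(wa), len(wb))
        num = float(np.einsum("i,j,ij->", wa, wb, raw ** 2))
        den = float((wa[:k] * wb[:k]).sum())
        value = float(np.sqrt(num / den))
    elif metric == "cov_overlap":
        wa, wb = _mode_weights(a), _mode_weights(b)
        total = wa.sum() + wb.sum()
        cross = float(np.einsum("i,j,ij->", np.sqrt(wa), np.sqrt(wb),
                                raw ** 2))
        inner = max((total - 2.0 * cross) / total, 0.0)
        value = float(1.0 - np.sqrt(inner))
    elif metric != "overlap":
        raise ValueError(f"unknown comparison metric {metric!r}")
    return OverlapResult(matrix, metric, row_cum, value, diagonal_only)


@dataclass
class ModeMatch:
    permutation: np.ndarray  # column index matched to each row mode
    reordered: ModeSet | None
    old_ids: np.ndarray


def match_modes(o: OverlapResult, b: ModeSet | None = None) -> ModeMatch:
    """Match modes by linear assignment maximising the summed squared overlap.

    Returns the permutation (column of ``o`` matched to each row) and,
    when the second mode set is given, that set reordered accordingly
    with the original mode indices kept in ``old_ids``.
    """
    cost = -(np.asarray(o.matrix, float) ** 2)
    rows, cols = linear_sum_assignment(cost)
    perm = np.full(o.matrix.shape[0], -1, dtype=int)
    perm[rows] = cols
    reordered = None
    if b is not None:
        take = perm[perm >= 0]
        reordered = ModeSet(b.vectors[:, take].copy(),
                            b.eigenvalues[take].copy(), b.kind,
                            b.n_zero_skipped, b.source_atoms,
                            None if b.variances is None
                            else b.variances[take].copy())
    return ModeMatch(perm, reordered, perm.copy())


# ---------------------------------------------------------------------------
# Projection and traversal
# ---------------------------------------------------------------------------

@dataclass
class ProjectionResult:
    coords: np.ndarray  # M × k
    scaling: str
    labels: list[str]
    mode_indices: list[int]


def project_ensemble(e: StructEnsemble, ms: ModeSet,
                     scaling: str = "norm",
                     modes: list[int] | None = None) -> ProjectionResult:
    """Project ensemble members onto mode vectors.

    Coordinates are dot products of member deformation vectors (from the
    converged mean) with the unit mode vectors; ``rmsd`` scaling divides
    by √N so axes read in Å RMSD.
    """
    if scaling not in ("norm", "rmsd"):
        raise ValueError("scaling must be 'norm' or 'rmsd'")
    if not e.converged:
        warnings.warn("projecting an unconverged ensemble against its "
                      "current mean", stacklevel=2)
    if not ms.is_3d:
        raise ValueError("projection requires 3D modes")
    if ms.n_atoms != e.n_atoms:
        raise ValueError("mode set and ensemble atom counts differ")
    modes = list(range(ms.n_modes)) if modes is None else list(modes)
    u = ms.vectors[:, modes]
    u = u / np.linalg.norm(u, axis=0)
    m, n = e.n_members, e.n_atoms
    dev = ((e.coords - e.mean_coords[None])
           * e.weights[:, :, None]).reshape(m, 3 * n)
    proj = dev @ u
    if scaling == "rmsd":
        proj = proj / np.sqrt(n)
    return ProjectionResult(proj, scaling, list(e.labels), modes)


def traverse_mode(s: Structure, mode: np.ndarray | ModeSet,
                  rmsd: float = 2.0, n_frames: int = 11,
                  direction: str = "both",
                  mode_index: int = 0) -> list[Structure]:
    """Generate conformations along a mode at amplitudes up to ± the RMSD.

    The end frames sit exactly at the requested RMSD from the input
    structure; ``direction`` picks both signs or a single branch.
    """
    if rmsd <= 0:
        raise ValueError("traversal rmsd must be positive")
    if direction not in ("both", "pos", "neg"):
        raise ValueError("direction must be both, pos or neg")
    vec = mode.vectors[:, mode_index] if isinstance(mode, ModeSet) else np.asarray(mode, float)
    n = len(s)
    if vec.size != 3 * n:
        raise ValueError("mode length does not match structure atoms")
    unit = vec / np.linalg.norm(vec)
    amp = rmsd * np.sqrt(n)
    if direction == "both":
        alphas = np.linspace(-amp, amp, n_frames)
    elif direction == "pos":
        alphas = np.linspace(0.0, amp, n_frames)
    else:
        alphas = np.linspace(0.0, -amp, n_frames)
    base = s.coords
    frames = []
    for t, alpha in enumerate(alphas):
        frame = s.copy()
        frame.title = f"{s.title} frame {t}"
        frame.set_coords(base + alpha * unit.reshape(n, 3))
        frames.append(frame)
    return frames
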
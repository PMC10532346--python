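"""Pairwise superposition and multi-structure ensemble construction.

The central object is :class:`StructEnsemble`: M conformations over N
matched reference positions, with 0/1 occupancy weights so that positions
missing in a member ("dummy atoms") never contribute to superposition,
means, fluctuations or PCA.  Chains are matched by id, file position, a
custom order dictionary, or automatically by sequence identity/coverage;
residues are mapped by global pairwise sequence alignment (Biopython).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .structures import AtomSelection, Structure, select_atoms

__all__ = [
    "ChainMatchSpec", "SuperpositionResult", "ResidueMapping",
    "StructEnsemble", "kabsch_superpose", "match_chains", "map_residues",
    "build_ensemble", "ensemble_statistics",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


def _chain_ca(chain: Structure) -> list:
    """Cα atoms of a chain (all atoms if the chain has no Cα)."""
    cas = [a for a in chain.atoms if a.name == "CA"]
    return cas if cas else list(chain.atoms)


def _chain_sequence(chain: Structure) -> str:
    return "".join(_THREE_TO_ONE.get(a.resname, "X") for a in _chain_ca(chain))


@dataclass
class ChainMatchSpec:
    """How chains of ensemble members are paired with the reference.

    ``scheme`` is one of ``same_id``, ``same_position``, ``auto`` or
    ``custom``.  For ``custom``, ``custom_orders`` maps a structure label
    (its title) to a chain-order string; the i-th characters of the
    reference order and the member order are paired.
    """

    scheme: str = "auto"
    custom_orders: dict[str, str] = field(default_factory=dict)
    seqid_cutoff: float = 0.5
    coverage_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if self.scheme not in ("same_id", "same_position", "auto", "custom"):
            raise ValueError(f"unknown chain-matching scheme {self.scheme!r}")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float
    n_matched: int
    degenerate: bool = False

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Weighted Kabsch superposition of ``mobile`` onto ``target``.

    Returns the proper rotation R and translation t minimising the
    weighted RMSD of ``R x + t`` to the target; reflections are excluded.
    Collinear (rank-deficient) point sets are solved but flagged.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and target must both be N×3")
    n = mobile.shape[0]
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, float)
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("all superposition weights are zero")
    if np.count_nonzero(weights) < 3:
        raise ValueError("need at least 3 weighted points")
    w = weights / wsum
    cm = w @ mobile
    ct = w @ target
    h = (mobile - cm).T @ ((target - ct) * w[:, None])
    u, sv, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ct - rot @ cm
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt((w * ((moved - target) ** 2).sum(axis=1)).sum()))
    degenerate = bool(sv[1] < 1e-10 * max(sv[0], 1e-300))
    return SuperpositionResult(rot, trans, rmsd,
                               int(np.count_nonzero(weights)), degenerate)


# ---------------------------------------------------------------------------
# Residue mapping
# ---------------------------------------------------------------------------

@dataclass
class ResidueMapping:
    """Matched Cα index pairs between two chains with alignment quality."""

    pairs: list[tuple[int, int]]
    identity: float
    coverage: float


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def map_residues(chain_a: Structure, chain_b: Structure,
                 method: str = "auto",
                 pairs: list[tuple[int, int]] | None = None) -> ResidueMapping:
    """Map Cα positions of ``chain_b`` onto ``chain_a``.

    ``auto`` (default) first tries matching residue numbers and falls
    back to sequence alignment when the chains share too few numbers;
    ``seqalign`` runs a global pairwise sequence alignment (match 1,
    mismatch −1, gap open −10, gap extend −0.5); ``custom`` accepts a
    precomputed index-pair list (e.g. from an external structural
    aligner).  Coverage is relative to ``chain_a``.
    """
    ca_a, ca_b = _chain_ca(chain_a), _chain_ca(chain_b)
    if not ca_a or not ca_b:
        raise ValueError("cannot map residues of an empty chain")
    if method == "auto":
        nums_a = {(a.resnum, a.icode): i for i, a in enumerate(ca_a)}
        nums_b = {(b.resnum, b.icode): j for j, b in enumerate(ca_b)}
        shared = sorted(nums_a.keys() & nums_b.keys(),
                        key=lambda k: nums_a[k])
        if (len(nums_a) == len(ca_a) and len(nums_b) == len(ca_b)
                and len(shared) >= 0.5 * min(len(ca_a), len(ca_b))):
            method, pairs = "custom", [(nums_a[k], nums_b[k])
                                       for k in shared]
        else:
            method = "seqalign"
    if method == "custom":
        if pairs is None:
            raise ValueError("custom mapping requires explicit pairs")
        matched = list(pairs)
        n_ident = sum(ca_a[i].resname == ca_b[j].resname for i, j in matched)
    elif method == "seqalign":
        seq_a, seq_b = _chain_sequence(chain_a), _chain_sequence(chain_b)
        aln = _make_aligner().align(seq_a, seq_b)[0]
        matched = []
        n_ident = 0
        for (a0, a1), (b0, b1) in zip(*aln.aligned):
            for i, j in zip(range(a0, a1), range(b0, b1)):
                matched.append((i, j))
                n_ident += seq_a[i] == seq_b[j]
    else:
        raise ValueError(f"unknown residue-mapping method {method!r}")
    n = len(matched)
    identity = n_ident / n if n else 0.0
    coverage = n / len(ca_a)
    return ResidueMapping(matched, identity, coverage)


# ---------------------------------------------------------------------------
# Chain matching
# ---------------------------------------------------------------------------

def _pairing_stats(a: Structure, b: Structure,
                   pairing: list[tuple[str, str]]) -> tuple[float, float]:
    """Composite score and whole-structure RMSD for a chain pairing."""
    scores = []
    coords_a, coords_b = [], []
    for ca_id, cb_id in pairing:
        mapping = map_residues(a.chain(ca_id), b.chain(cb_id))
        scores.append(mapping.identity * mapping.coverage)
        atoms_a = _chain_ca(a.chain(ca_id))
        atoms_b = _chain_ca(b.chain(cb_id))
        for i, j in mapping.pairs:
            coords_a.append(atoms_a[i].coords)
            coords_b.append(atoms_b[j].coords)
    if len(coords_a) < 3:
        return 0.0, np.inf
    res = kabsch_superpose(np.array(coords_b), np.array(coords_a))
    return float(np.mean(scores)), res.rmsd


def match_chains(a: Structure, b: Structure,
                 spec: ChainMatchSpec | None = None) -> list[tuple[str, str]]:
    """Pair chains of ``b`` with chains of reference ``a``.

    The ``auto`` scheme scores every candidate pairing by the mean
    per-chain (identity × coverage) among chain pairs passing the spec's
    cutoffs, breaking ties by lowest whole-structure RMSD and then by
    lexicographic order.
    """
    spec = spec or ChainMatchSpec()
    chains_a, chains_b = a.chain_ids, b.chain_ids
    if not chains_a or not chains_b:
        raise ValueError("both structures need at least one chain")
    if spec.scheme == "same_id":
        return [(c, c) for c in chains_a if c in chains_b]
    if spec.scheme == "same_position":
        return list(zip(chains_a, chains_b))
    if spec.scheme == "custom":
        order_a = spec.custom_orders.get(a.title, "".join(chains_a))
        try:
            order_b = spec.custom_orders[b.title]
        except KeyError:
            raise ValueError(f"no custom chain order for {b.title!r}") from None
        if sorted(order_a) != sorted(chains_a) or sorted(order_b) != sorted(chains_b):
            raise ValueError("custom chain order is not a permutation of the "
                             "structure's chains")
        return list(zip(order_a, order_b))
    # auto
    k = min(len(chains_a), len(chains_b))
    best: tuple | None = None
    for sub_a in itertools.combinations(chains_a, k):
        for perm_b in itertools.permutations(chains_b, k):
            pairing = list(zip(sub_a, perm_b))
            ok_pairs = []
            for ca_id, cb_id in pairing:
                m = map_residues(a.chain(ca_id), b.chain(cb_id))
                if (m.identity >= spec.seqid_cutoff
                        and m.coverage >= spec.coverage_cutoff):
                    ok_pairs.append((ca_id, cb_id))
            if not ok_pairs:
                continue
            score, rmsd = _pairing_stats(a, b, ok_pairs)
            # round before comparing so exact symmetry ties resolve by the
            # lexicographic pairing order, not by float noise
            key = (-round(score, 9), round(rmsd, 6), tuple(ok_pairs))
            if best is None or key < best[0]:
                best = (key, ok_pairs)
    return best[1] if best else []


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

@dataclass
class StructEnsemble:
    """M conformations × N matched atoms with 0/1 occupancy weights."""

    labels: list[str]
    coords: np.ndarray  # M×N×3
    weights: np.ndarray  # M×N in {0,1}
    reference_atoms: Structure
    msa: list[str]
    mean_coords: np.ndarray  # N×3
    rejected: dict[str, str] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_members(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def weighted_mean(self) -> np.ndarray:
        w = self.weights[:, :, None]
        denom = np.maximum(w.sum(axis=0), 1e-300)
        return (self.coords * w).sum(axis=0) / denom


def _superpose_members(coords: np.ndarray, weights: np.ndarray,
                       target: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for m in range(coords.shape[0]):
        res = kabsch_superpose(coords[m], target, weights[m])
        out[m] = res.apply(coords[m])
    return out


def iterative_superpose(coords: np.ndarray, weights: np.ndarray,
                        tol: float = 1e-4, max_iter: int = 100
                        ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Superpose members onto their running weighted mean until it converges.

    Returns (superposed coords, mean, converged flag).
    """
    w = weights[:, :, None]
    mean = (coords * w).sum(axis=0) / np.maximum(w.sum(axis=0), 1e-300)
    converged = False
    for _ in range(max_iter):
        coords = _superpose_members(coords, weights, mean)
        new_mean = (coords * w).sum(axis=0) / np.maximum(w.sum(axis=0), 1e-300)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if shift < tol:
            converged = True
            break
    return coords, mean, converged


def build_ensemble(structs: list[Structure], reference: int | Structure = 0,
                   spec: ChainMatchSpec | None = None,
                   cutoffs: dict | None = None,
                   occupancy_cutoff: float = 0.9,
                   trim_expr: str | None = None,
                   tol: float = 1e-4, max_iter: int = 100) -> StructEnsemble:
    """Build a matched, iteratively superposed ensemble.

    Each structure is matched to the reference chain-by-chain and
    residue-by-residue; reference Cα positions absent from a member
    become dummy atoms (weight 0) when the column occupancy stays at or
    above ``occupancy_cutoff``, otherwise the column is trimmed away.
    ``cutoffs`` may carry ``seqid``, ``coverage`` (per chain) and ``rmsd``
    (whole structure, Å); failing members are excluded with a logged
    reason.  Finally members are iteratively superposed onto the running
    occupancy-weighted mean until it moves less than ``tol`` Å.
    """
    if not structs:
        raise ValueError("no structures given")
    spec = spec or ChainMatchSpec()
    cutoffs = {"seqid": spec.seqid_cutoff, "coverage": spec.coverage_cutoff,
               "rmsd": None, **(cutoffs or {})}
    if isinstance(reference, Structure):
        ref = reference
    else:
        try:
            ref = structs[int(reference)]
        except (IndexError, TypeError) as exc:
            raise ValueError(f"invalid reference {reference!r}") from exc

    ref_ca = select_atoms(ref, "protein and name CA")
    ref_atoms = (ref_ca.to_structure() if len(ref_ca) else ref.copy())
    ref_chain_atoms = {cid: _chain_ca(ref_atoms.chain(cid))
                      for cid in ref_atoms.chain_ids}
    # column index of each reference Cα
    col_of: dict[tuple[str, int], int] = {}
    for idx, atom in enumerate(ref_atoms.atoms):
        col_of[(atom.chain_id, id(atom))] = idx
    ref_positions = {cid: [col_of[(cid, id(a))] for a in atoms]
                     for cid, atoms in ref_chain_atoms.items()}
    n_cols = len(ref_atoms)

    labels, rows_c, rows_w, rejected = [], [], [], {}
    for si, st in enumerate(structs):
        label = st.title or f"structure {si}"
        try:
            pairing = match_chains(ref_atoms, st, spec)
        except ValueError as exc:
            rejected[label] = str(exc)
            continue
        if not pairing:
            rejected[label] = "no chain pairing passed the cutoffs"
            continue
        coords = np.zeros((n_cols, 3))
        weights = np.zeros(n_cols)
        ok = True
        for ref_cid, mem_cid in pairing:
            mapping = map_residues(ref_atoms.chain(ref_cid), st.chain(mem_cid))
            if cutoffs["seqid"] is not None and mapping.identity < cutoffs["seqid"]:
                rejected[label] = (f"chain {mem_cid}: sequence identity "
                                   f"{mapping.identity:.2f} below cutoff")
                ok = False
                break
            if (cutoffs["coverage"] is not None
                    and mapping.coverage < cutoffs["coverage"]):
                rejected[label] = (f"chain {mem_cid}: coverage "
                                   f"{mapping.coverage:.2f} below cutoff")
                ok = False
                break
            mem_atoms = _chain_ca(st.chain(mem_cid))
            for i, j in mapping.pairs:
                col = ref_positions[ref_cid][i]
                coords[col] = mem_atoms[j].coords
                weights[col] = 1.0
        if not ok:
            continue
        if weights.sum() < 3:
            rejected[label] = "fewer than 3 matched atoms"
            continue
        sup = kabsch_superpose(coords, ref_atoms.coords, weights)
        if cutoffs.get("rmsd") is not None and sup.rmsd > cutoffs["rmsd"]:
            rejected[label] = f"RMSD to reference {sup.rmsd:.2f} above cutoff"
            continue
        labels.append(label)
        rows_c.append(sup.apply(coords))
        rows_w.append(weights)
    if not labels:
        lines = "; ".join(f"{k}: {v}" for k, v in rejected.items())
        raise ValueError(f"all members rejected ({lines})")

    coords = np.array(rows_c)
    weights = np.array(rows_w)
    # column filtering: occupancy cutoff, then optional trim selection
    occupancy = weights.mean(axis=0)
    keep = occupancy >= occupancy_cutoff
    if trim_expr:
        sel = select_atoms(ref_atoms, trim_expr)
        mask = np.zeros(n_cols, dtype=bool)
        mask[sel.indices] = True
        keep &= mask
    if not keep.any():
        raise ValueError("occupancy cutoff / trim selection removed all atoms")
    coords = coords[:, keep]
    weights = weights[:, keep]
    kept_atoms = Structure([a.copy() for a, k in zip(ref_atoms.atoms, keep) if k],
                           title=ref_atoms.title)

    coords, mean, converged = iterative_superpose(coords, weights, tol, max_iter)
    msa = []
    for m, label in enumerate(labels):
        row = "".join(
            _THREE_TO_ONE.get(a.resname, "X") if weights[m, i] else "-"
            for i, a in enumerate(kept_atoms.atoms))
        msa.append(row)
    return StructEnsemble(labels, coords, weights, kept_atoms, msa, mean,
                          rejected, converged)


def ensemble_statistics(e: StructEnsemble) -> dict[str, np.ndarray]:
    """Occupancy-weighted RMSD-to-mean, pairwise RMSD matrix and RMSF."""
    m, n = e.n_members, e.n_atoms
    mean = e.mean_coords
    rmsd_to_mean = np.zeros(m)
    for i in range(m):
        w = e.weights[i]
        d2 = ((e.coords[i] - mean) ** 2).sum(axis=1)
        rmsd_to_mean[i] = np.sqrt((w * d2).sum() / w.sum())
    pairwise = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            w = e.weights[i] * e.weights[j]
            res = kabsch_superpose(e.coords[j], e.coords[i], w)
            pairwise[i, j] = pairwise[j, i] = res.rmsd
    wsum = np.maximum(e.weights.sum(axis=0), 1e-300)
    dev2 = ((e.coords - mean[None]) ** 2).sum(axis=2)
    rmsf = np.sqrt((e.weights * dev2).sum(axis=0) / wsum)
    return {"rmsd_to_mean": rmsd_to_mean, "pairwise_rmsd": pairwise,
            "rmsf": rmsf}
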
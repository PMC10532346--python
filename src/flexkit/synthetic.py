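"""Deterministic synthetic structures for testing and demonstration.

All fixtures are Cα-only poly-alanine chains built from smooth analytic
curves, so inter-residue spacing and steric separation are controlled by
construction.  The ``pseudo_spike`` kind emulates a spike-like homotrimer:
three helical-coil protomers around a common axis, each with a terminal
"receptor-binding" lobe whose opening angle encodes 3-down / 1-up / 2-up
like states, plus optional per-chain missing residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import StructEnsemble, iterative_superpose
from .structures import Atom, Structure, write_structure

__all__ = ["SyntheticSpec", "make_structure", "make_mode_driven_ensemble",
           "spike_state_angles", "ensemble_from_members",
           "rigid_orthogonal_vectors"]

#: Named receptor-binding-lobe states of the pseudo-spike: per-chain
#: opening angles in degrees.
_SPIKE_STATES = {
    "3down": (0.0, 0.0, 0.0),
    "1up": (30.0, 0.0, 0.0),
    "1up1i": (30.0, 15.0, 0.0),
    "2up": (30.0, 30.0, 0.0),
    "3up": (30.0, 30.0, 30.0),
}


def spike_state_angles(name: str) -> tuple[float, float, float]:
    """Per-chain lobe opening angles (degrees) of a named spike state."""
    try:
        return _SPIKE_STATES[name]
    except KeyError:
        raise ValueError(f"unknown spike state {name!r}; options: "
                         f"{sorted(_SPIKE_STATES)}") from None


@dataclass
class SyntheticSpec:
    """Recipe for a deterministic synthetic structure.

    ``state`` holds per-chain lobe opening angles in degrees (pseudo
    spike only); ``missing`` lists residue numbers omitted per chain.
    """

    kind: str = "coil"
    n_res: int = 50
    chains: str = "A"
    res_start: int = 1
    missing: dict[str, list[int]] = field(default_factory=dict)
    state: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("coil", "helix", "dumbbell", "pseudo_spike"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n_res < 2:
            raise ValueError("need at least 2 residues")


_CA_SPACING = 3.8  # Å between consecutive residues


def _helix_curve(n: int, radius: float, rise: float,
                 phase: float = 0.0) -> np.ndarray:
    lateral = np.sqrt(_CA_SPACING ** 2 - rise ** 2)
    theta = 2.0 * np.arcsin(lateral / (2.0 * radius))
    t = np.arange(n)
    return np.stack([radius * np.cos(phase + theta * t),
                     radius * np.sin(phase + theta * t),
                     rise * t], axis=1)


def _alpha_helix(n: int) -> np.ndarray:
    # ideal Cα helix: radius 2.3 Å, rise 1.5 Å, 100° per residue
    t = np.arange(n)
    ang = np.deg2rad(100.0) * t
    return np.stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * t], axis=1)


def _confined_walk(n: int, rng: np.random.Generator,
                   centers: np.ndarray) -> np.ndarray:
    """Self-avoiding 3.8 Å-step walk confined near per-residue centres.

    Confinement produces compact, globular (well-connected) chains; the
    clash threshold relaxes from 3.4 towards 3.0 Å only if the walk gets
    stuck, so non-bonded atoms always stay at least 3 Å apart.
    """
    pts = [centers[0] + np.array([0.0, 0.0, 0.0])]
    direction = np.array([1.0, 0.0, 0.0])
    i = 1
    while i < n:
        radius = max(2.6 * (min(i + 1, n) ** (1.0 / 3.0)), 6.0)
        placed = False
        for attempt in range(600):
            clash = 3.4 if attempt < 300 else 3.0 + 0.4 * (600 - attempt) / 300
            pull = centers[i] - pts[-1]
            pull_norm = np.linalg.norm(pull)
            pull_w = 0.9 * max(pull_norm / radius - 0.6, 0.0)
            step = (0.5 * direction + rng.standard_normal(3)
                    + pull_w * pull / max(pull_norm, 1e-9))
            step /= np.linalg.norm(step)
            cand = pts[-1] + _CA_SPACING * step
            if len(pts) > 1:
                d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
                if d.min() < clash:
                    continue
            direction = step
            pts.append(cand)
            placed = True
            break
        if not placed:  # extremely unlikely; restart from a fresh direction
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            continue
        i += 1
    return np.array(pts)


def _coil_curve(n: int, seed: int) -> np.ndarray:
    """Compact globular random coil with fixed 3.8 Å steps."""
    rng = np.random.default_rng(seed)
    centers = np.zeros((n, 3))
    return _confined_walk(n, rng, centers)


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _dumbbell(n: int, seed: int) -> np.ndarray:
    """Two compact globular lobes whose walk migrates between centres.

    The lobes sit ~24 Å apart, close enough for a thin band of
    inter-lobe contacts at typical ENM cutoffs, so the slowest mode is
    an inter-lobe hinge/twist rather than a floppy zero mode.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    centers = np.zeros((n, 3))
    centers[half:] = np.array([36.0, 0.0, 0.0])
    return _confined_walk(n, rng, centers)


def _pseudo_spike_chain(resnums: np.ndarray, angle_deg: float,
                        chain_phase: float) -> np.ndarray:
    n = len(resnums)
    # pitch ≈ 12 Å keeps adjacent turns inside a 15 Å elastic-network
    # cutoff, so each protomer is a stiff tube rather than a loose coil
    curve = _helix_curve(n, radius=8.0, rise=0.9)
    # place the protomer off-axis so the three copies form a trimer whose
    # chains stay within elastic-network contact range of each other
    curve = curve + np.array([14.0, 0.0, 0.0])
    # terminal quarter is the mobile lobe; rotate it rigidly about the
    # hinge atom, tilting outward from the trimer axis ("opening")
    hinge = int(0.75 * n)
    if angle_deg and hinge < n - 1:
        pivot = curve[hinge]
        axis = np.array([0.0, 1.0, 0.0])  # horizontal tangent direction
        rot = _rotation_about_axis(axis, angle_deg)
        curve[hinge + 1:] = (curve[hinge + 1:] - pivot) @ rot.T + pivot
    rot_chain = _rotation_about_axis(np.array([0.0, 0.0, 1.0]),
                                     np.rad2deg(chain_phase))
    return curve @ rot_chain.T


def make_structure(spec: SyntheticSpec) -> Structure:
    """Build the deterministic Cα-only structure described by ``spec``.

    Consecutive residues are 3.8 Å apart and non-bonded atoms stay at
    least ~3 Å apart by construction; the same spec and seed always
    yield bit-identical coordinates.
    """
    chains = list(spec.chains)
    atoms: list[Atom] = []
    serial = 1
    for ci, cid in enumerate(chains):
        resnums = np.arange(spec.res_start, spec.res_start + spec.n_res)
        if spec.kind == "coil":
            coords = _coil_curve(spec.n_res, spec.seed + 977 * ci)
        elif spec.kind == "helix":
            coords = _alpha_helix(spec.n_res)
        elif spec.kind == "dumbbell":
            coords = _dumbbell(spec.n_res, spec.seed + 977 * ci)
        else:
            angle = spec.state[ci] if ci < len(spec.state) else 0.0
            coords = _pseudo_spike_chain(resnums, angle,
                                         2.0 * np.pi * ci / len(chains))
        if spec.kind != "pseudo_spike" and ci > 0:
            coords = coords + np.array([0.0, 40.0 * ci, 0.0])
        omit = set(spec.missing.get(cid, ()))
        for rn, xyz in zip(resnums, coords):
            if int(rn) in omit:
                continue
            atoms.append(Atom(serial=serial, name="CA", altloc="",
                              resname="ALA", chain_id=cid, resnum=int(rn),
                              icode="", coords=np.array(xyz, float),
                              element="C"))
            serial += 1
    title = f"{spec.kind} fixture"
    if spec.kind == "pseudo_spike" and spec.state:
        title += " " + "/".join(f"{a:g}" for a in spec.state)
    return Structure(atoms, title=title)


def ensemble_from_members(members: list[Structure], tol: float = 1e-6,
                          max_iter: int = 200) -> StructEnsemble:
    """Assemble identically-indexed structures into a converged ensemble.

    All members must share the same atom list (as produced by
    :func:`make_mode_driven_ensemble`); this skips chain matching and
    goes straight to iterative superposition.
    """
    coords = np.array([s.coords for s in members])
    weights = np.ones(coords.shape[:2])
    coords, mean, converged = iterative_superpose(coords, weights, tol,
                                                  max_iter)
    ref = members[0].copy()
    msa = ["A" * coords.shape[1]] * len(members)
    return StructEnsemble([s.title for s in members], coords, weights,
                          ref, msa, mean, {}, converged)


#: Study-set composition emulating a deposited spike-variant ensemble:
#: 24 structures over 7 lobe states (label, per-chain opening angles °,
#: member count).  States differ by at least one full 30° lobe opening,
#: i.e. several Å of backbone RMSD at the default protomer size.
SPIKE_SET_STATES: list[tuple[str, tuple[float, float, float], int]] = [
    ("3down", (0.0, 0.0, 0.0), 6),
    ("1upA", (30.0, 0.0, 0.0), 4),
    ("1upB", (0.0, 30.0, 0.0), 3),
    ("1upC", (0.0, 0.0, 30.0), 2),
    ("2upAB", (30.0, 30.0, 0.0), 4),
    ("2upBC", (0.0, 30.0, 30.0), 3),
    ("3up", (30.0, 30.0, 30.0), 2),
]

#: Chain-labelling conventions cycled over the study set, emulating the
#: mixed deposition conventions (reference convention first).
SPIKE_SET_ORDERS = ("BAC", "BCA", "ABC")


def make_spike_study_set(n_res: int = 150, noise: float = 0.3,
                         seed: int = 11
                         ) -> tuple[list[Structure], dict[str, str],
                                    list[str]]:
    """Deterministic 24-member pseudo-spike study set with mixed chain orders.

    Members are drawn from :data:`SPIKE_SET_STATES` with isotropic
    per-coordinate noise (Å); the chain at geometric position k of member
    m is labelled ``order[k]`` with orders cycling through
    :data:`SPIKE_SET_ORDERS`, so ensemble building requires the custom
    chain-order dictionary that is returned alongside.  Also returns the
    ground-truth state label per member.
    """
    rng = np.random.default_rng(seed)
    members: list[Structure] = []
    orders: dict[str, str] = {}
    truth: list[str] = []
    idx = 0
    for name, angles, count in SPIKE_SET_STATES:
        base = make_structure(SyntheticSpec(
            kind="pseudo_spike", n_res=n_res, chains="ABC", res_start=1,
            state=angles))
        for _ in range(count):
            member = base.copy()
            member.set_coords(base.coords
                              + noise * rng.standard_normal((len(base), 3)))
            order = SPIKE_SET_ORDERS[idx % len(SPIKE_SET_ORDERS)]
            for atom in member.atoms:
                atom.chain_id = order["ABC".index(atom.chain_id)]
            member._invalidate()
            member.title = f"{name}_{idx:02d}"
            orders[member.title] = order
            members.append(member)
            truth.append(name)
            idx += 1
    return members, orders, truth


def rigid_orthogonal_vectors(base: Structure, k: int,
                             seed: int = 0) -> list[np.ndarray]:
    """Random orthonormal 3N vectors orthogonal to rigid-body motions.

    Superposition removes the rigid-body part of any displacement, so
    planted conformational directions must live in the internal-motion
    subspace for an ensemble analysis to recover them exactly.
    """
    coords = base.coords
    n = coords.shape[0]
    rng = np.random.default_rng(seed)
    centered = coords - coords.mean(axis=0)
    rigid = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        rigid.append(t.ravel())
        e = np.zeros(3)
        e[ax] = 1.0
        rigid.append(np.cross(np.broadcast_to(e, (n, 3)), centered).ravel())
    basis = np.array(rigid).T
    q, _ = np.linalg.qr(basis)
    proj = np.eye(3 * n) - q @ q.T
    out: list[np.ndarray] = []
    while len(out) < k:
        v = proj @ rng.standard_normal(3 * n)
        for u in out:
            v -= (u @ v) * u
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            continue
        out.append(v / norm)
    return out


def make_mode_driven_ensemble(base: Structure, planted_vectors: list,
                              variances: list, m: int,
                              noise_rmsd: float = 0.0, seed: int = 0,
                              outdir: str | Path | None = None
                              ) -> tuple[list[Structure], pd.DataFrame]:
    """Draw an ensemble displaced along planted orthonormal directions.

    Member i is ``base + Σ_j a_ij v_j + ε`` with ``a_ij ~ N(0, var_j)``
    and isotropic noise ``ε`` of RMSD ``noise_rmsd``.  Returns the
    member structures and the ground-truth amplitude table; with
    ``outdir`` each member is also written as a PDB file next to a
    ``ground_truth.csv``.
    """
    n = len(base)
    vecs = np.array([np.asarray(v, float).ravel() for v in planted_vectors])
    if vecs.shape[1] != 3 * n:
        raise ValueError("planted vectors must have length 3N")
    gram = vecs @ vecs.T
    if not np.allclose(gram, np.eye(len(vecs)), atol=1e-8):
        raise ValueError("planted vectors must be orthonormal")
    variances = np.asarray(variances, float)
    if len(variances) != len(vecs):
        raise ValueError("one variance per planted vector required")
    rng = np.random.default_rng(seed)
    base_coords = base.coords
    members, rows = [], []
    sigma = noise_rmsd / np.sqrt(3.0)  # per-coordinate σ giving RMSD ≈ noise
    for i in range(m):
        amps = rng.standard_normal(len(vecs)) * np.sqrt(variances)
        disp = (amps @ vecs).reshape(n, 3)
        if noise_rmsd > 0:
            disp = disp + sigma * rng.standard_normal((n, 3))
        member = base.copy()
        member.title = f"member_{i:04d}"
        member.set_coords(base_coords + disp)
        members.append(member)
        rows.append({"member": member.title,
                     **{f"a{j}": amps[j] for j in range(len(vecs))}})
    truth = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for member in members:
            write_structure(member, outdir / f"{member.title}.pdb")
        truth.to_csv(outdir / "ground_truth.csv", index=False)
    return members, truth
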
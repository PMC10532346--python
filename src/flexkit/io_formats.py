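"""Readers and writers for mode and ensemble exchange formats.

Covers the plain-text NMD format consumed by mode-visualisation tools,
per-mode vector directories with a CSV metadata table (optionally
mirrored to SQLite), compressed named-array ensemble archives, FASTA
alignments and multi-model PDB trajectories.
"""

from __future__ import annotations

import sqlite3
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .enm import ModeSet
from .ensemble import StructEnsemble
from .structures import Atom, Structure, write_structure

__all__ = [
    "write_nmd", "read_nmd", "write_modes_dir", "read_modes_dir",
    "write_ensemble_npz", "read_ensemble_npz", "write_msa_fasta",
    "write_trajectory_pdb",
]


# ---------------------------------------------------------------------------
# NMD
# ---------------------------------------------------------------------------

def _mode_scale(ms: ModeSet, k: int, raw_eigenvalues: bool) -> float:
    lam = float(ms.eigenvalues[k]) if len(ms.eigenvalues) > k else 1.0
    if raw_eigenvalues:
        return lam
    if ms.kind == "pca":
        return float(np.sqrt(max(lam, 0.0)))
    return float(np.sqrt(1.0 / lam)) if lam > 0 else 1.0


def write_nmd(ms: ModeSet, s: Structure, path: str | Path,
              raw_eigenvalues: bool = False) -> Path:
    """Write modes and their structure as an NMD file.

    Mode scales follow the √variance convention (√λ for PCA, √(1/λ) for
    ENMs); ``raw_eigenvalues`` stores the eigenvalue itself instead.
    GNM mode sets have no 3D vectors and are rejected — write a
    mode-shape CSV for those instead.
    """
    if not ms.is_3d:
        raise ValueError("NMD requires 3D modes; write GNM mode shapes as "
                         "CSV instead")
    if ms.n_atoms != len(s):
        raise ValueError("mode set and structure atom counts differ")
    path = Path(path)
    fmt = "%.6f"
    lines = [f"title {s.title or 'flexkit modes'}"]
    lines.append("atomnames " + " ".join(a.name for a in s.atoms))
    lines.append("resnames " + " ".join(a.resname for a in s.atoms))
    lines.append("resids " + " ".join(str(a.resnum) for a in s.atoms))
    lines.append("chainids " + " ".join(a.chain_id or "_" for a in s.atoms))
    lines.append("betas " + " ".join(f"{a.bfactor:.2f}" for a in s.atoms))
    lines.append("coordinates "
                 + " ".join(fmt % v for v in s.coords.ravel()))
    for k in range(ms.n_modes):
        scale = _mode_scale(ms, k, raw_eigenvalues)
        lines.append(f"mode {k + 1} {scale:.6g} "
                     + " ".join(fmt % v for v in ms.vectors[:, k]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_nmd(path: str | Path) -> tuple[Structure, ModeSet]:
    """Parse an NMD file back into a structure-lite and a mode set.

    Unknown records are ignored with a warning; the returned eigenvalues
    are the stored per-mode scales (see :func:`write_nmd`).
    """
    path = Path(path)
    records: dict[str, list[str]] = {}
    modes: list[tuple[int, float, np.ndarray]] = []
    title = path.stem
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        key, _, rest = line.partition(" ")
        if key == "title":
            title = rest.strip()
        elif key == "mode":
            parts = rest.split()
            idx = int(parts[0])
            scale = float(parts[1])
            vec = np.array([float(v) for v in parts[2:]])
            modes.append((idx, scale, vec))
        elif key in ("atomnames", "resnames", "resids", "chainids",
                     "betas", "coordinates"):
            records[key] = rest.split()
        else:
            warnings.warn(f"ignoring unknown NMD record {key!r}",
                          stacklevel=2)
    if "coordinates" not in records:
        raise ValueError(f"{path.name}: missing coordinates record")
    coords = np.array([float(v) for v in records["coordinates"]])
    if coords.size % 3:
        raise ValueError(f"{path.name}: coordinates record truncated")
    n = coords.size // 3
    coords = coords.reshape(n, 3)

    def col(key: str, default: str) -> list[str]:
        vals = records.get(key, [default] * n)
        if len(vals) != n:
            raise ValueError(f"{path.name}: record {key!r} has {len(vals)} "
                             f"entries for {n} atoms")
        return vals

    atoms = [Atom(serial=i + 1, name=nm, altloc="", resname=rn,
                  chain_id=(cid if cid != "_" else ""), resnum=int(ri),
                  icode="", coords=coords[i], bfactor=float(b), element="")
             for i, (nm, rn, ri, cid, b) in enumerate(zip(
                 col("atomnames", "CA"), col("resnames", "ALA"),
                 col("resids", "1"), col("chainids", "A"),
                 col("betas", "0.0")))]
    structure = Structure(atoms, title=title)
    if not modes:
        raise ValueError(f"{path.name}: no mode records")
    modes.sort(key=lambda t: t[0])
    vectors = np.column_stack([vec for _, _, vec in modes])
    if vectors.shape[0] != 3 * n:
        raise ValueError(f"{path.name}: mode length does not match "
                         "coordinates")
    scales = np.array([scale for _, scale, _ in modes])
    return structure, ModeSet(vectors, scales, kind="anm",
                              source_atoms=structure)


# ---------------------------------------------------------------------------
# Per-mode vector directories
# ---------------------------------------------------------------------------

def write_modes_dir(ms: ModeSet, stats: dict | None, directory: str | Path,
                    overwrite: bool = False, sqlite_mirror: bool = False
                    ) -> Path:
    """Write one ``vec.<k>`` text file per mode plus a metadata table.

    Each vector file has one ``x y z`` line per atom (one value per line
    for GNM modes) at 9+ significant digits.  Metadata (eigenvalue,
    collectivity, score, enabled flag, relative path) is written as
    ``modes.csv``, with an optional SQLite mirror.
    """
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(f"{directory} is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)
    stats = stats or {}
    collectivity = stats.get("collectivity", np.full(ms.n_modes, np.nan))
    score = stats.get("score", np.full(ms.n_modes, np.nan))
    rows = []
    for k in range(ms.n_modes):
        name = f"vec.{k + 1}"
        per_atom = ms.vector_per_atom(k)
        with open(directory / name, "w") as fh:
            for row in per_atom:
                fh.write(" ".join(f"{v:.12e}" for v in row) + "\n")
        rows.append({"mode": k + 1,
                     "eigenvalue": float(ms.eigenvalues[k]),
                     "collectivity": float(collectivity[k]),
                     "score": float(score[k]),
                     "enabled": 1,
                     "path": name})
    meta = pd.DataFrame(rows)
    meta.to_csv(directory / "modes.csv", index=False)
    if sqlite_mirror:
        with sqlite3.connect(directory / "modes.sqlite") as con:
            meta.to_sql("modes", con, if_exists="replace", index=False)
    return directory


def read_modes_dir(directory: str | Path, kind: str = "anm",
                   include_disabled: bool = True
                   ) -> tuple[ModeSet, pd.DataFrame]:
    """Read a per-mode vector directory written by :func:`write_modes_dir`."""
    directory = Path(directory)
    meta_path = directory / "modes.csv"
    if not meta_path.exists():
        raise FileNotFoundError(f"no modes.csv in {directory}")
    meta = pd.read_csv(meta_path)
    if not include_disabled:
        meta = meta[meta["enabled"] != 0]
    vectors = []
    n_atoms = None
    for _, row in meta.iterrows():
        data = np.loadtxt(directory / row["path"], ndmin=2)
        if n_atoms is None:
            n_atoms = data.shape[0]
        elif data.shape[0] != n_atoms:
            raise ValueError(f"inconsistent atom counts across mode files "
                             f"in {directory}")
        vectors.append(data.ravel())
    if not vectors:
        raise ValueError(f"no mode files listed in {meta_path}")
    mat = np.column_stack(vectors)
    return (ModeSet(mat, meta["eigenvalue"].to_numpy(float), kind=kind),
            meta.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Ensemble archives, FASTA, trajectories
# ---------------------------------------------------------------------------

def write_ensemble_npz(e: StructEnsemble, path: str | Path,
                       fasta: bool = True) -> Path:
    """Compressed named-array ensemble archive (plus optional MSA FASTA)."""
    path = Path(path)
    np.savez_compressed(
        path, coords=e.coords, weights=e.weights,
        labels=np.array(e.labels, dtype=object), mean=e.mean_coords,
        msa=np.array(e.msa, dtype=object),
        resnums=np.array([a.resnum for a in e.reference_atoms.atoms]),
        chain_ids=np.array([a.chain_id for a in e.reference_atoms.atoms],
                           dtype=object),
        resnames=np.array([a.resname for a in e.reference_atoms.atoms],
                          dtype=object),
        names=np.array([a.name for a in e.reference_atoms.atoms],
                       dtype=object))
    if fasta:
        write_msa_fasta(e, path.with_suffix(".fasta"))
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_ensemble_npz(path: str | Path) -> StructEnsemble:
    data = np.load(Path(path), allow_pickle=True)
    coords = data["coords"]
    atoms = [Atom(serial=i + 1, name=str(nm), altloc="", resname=str(rn),
                  chain_id=str(cid), resnum=int(ri), icode="",
                  coords=coords[0, i].astype(float), element="")
             for i, (nm, rn, ri, cid) in enumerate(zip(
                 data["names"], data["resnames"], data["resnums"],
                 data["chain_ids"]))]
    ref = Structure(atoms, title=Path(path).stem)
    weights = data["weights"]
    mean = data["mean"]
    return StructEnsemble([str(x) for x in data["labels"]], coords, weights,
                          ref, [str(x) for x in data["msa"]], mean)


def write_msa_fasta(e: StructEnsemble, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for label, row in zip(e.labels, e.msa):
            fh.write(f">{label}\n{row}\n")
    return path


def write_trajectory_pdb(structs: list[Structure], path: str | Path) -> Path:
    """Multi-model PDB of a conformer trajectory."""
    path = Path(path)
    chunks = []
    for i, s in enumerate(structs, start=1):
        tmp = path.with_suffix(f".model{i}.tmp")
        write_structure(s, tmp, format="pdb")
        body = tmp.read_text().splitlines()
        tmp.unlink()
        body = [ln for ln in body if not ln.startswith(("END", "TITLE"))]
        chunks.append(f"MODEL     {i:4d}")
        chunks.extend(body)
        chunks.append("ENDMDL")
    chunks.append("END")
    path.write_text("\n".join(chunks) + "\n")
    return path
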
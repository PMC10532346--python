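"""Atomic structures: parsing, writing, atom selection and biological assemblies.

Structures are stored as a flat, ordered list of atom records with cached
numpy views for fast vectorised selection.  Parsing goes through gemmi so
both PDB and PDBx/mmCIF dialects yield identical records; writing is done
with explicit fixed-column (PDB) or ``atom_site`` loop (mmCIF) emitters so
the output is reproducible byte-for-byte.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom", "AssemblyOp", "AtomSelection", "Structure", "ParseError",
    "SelectionError", "parse_structure", "write_structure", "select_atoms",
    "build_assemblies", "PROTEIN_RESNAMES", "NUCLEIC_RESNAMES",
]


class ParseError(ValueError):
    """Raised when a structure file cannot be interpreted."""


class SelectionError(ValueError):
    """Raised on a malformed or unknown selection expression."""


#: Residue names treated as protein by the selection language.
PROTEIN_RESNAMES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
    TRP TYR VAL MSE SEC PYL ASX GLX UNK""".split()
)

#: Residue names treated as nucleic acid by the selection language.
NUCLEIC_RESNAMES = frozenset(
    "A C G U I T DA DC DG DT DI DU".split()
)


@dataclass
class Atom:
    serial: int
    name: str
    altloc: str
    resname: str
    chain_id: str
    resnum: int
    icode: str
    coords: np.ndarray  # (3,) Å
    occupancy: float = 1.0
    bfactor: float = 0.0
    element: str = ""
    hetero: bool = False

    def copy(self) -> "Atom":
        return Atom(self.serial, self.name, self.altloc, self.resname,
                    self.chain_id, self.resnum, self.icode,
                    np.array(self.coords, dtype=float), self.occupancy,
                    self.bfactor, self.element, self.hetero)


@dataclass
class AssemblyOp:
    """One rigid-body operator of a biological-assembly definition."""

    rotation: np.ndarray  # 3x3, orthonormal
    translation: np.ndarray  # (3,) Å
    target_chains: list[str]
    assembly_id: int = 1

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        rtr = self.rotation.T @ self.rotation
        if not np.allclose(rtr, np.eye(3), atol=1e-6):
            raise ValueError("assembly rotation is not orthonormal")


class Structure:
    """Ordered collection of atom records with hierarchy-style views."""

    def __init__(self, atoms: list[Atom], title: str = "",
                 assembly_ops: list[AssemblyOp] | None = None):
        self.atoms = list(atoms)
        self.title = title
        self.assembly_ops = list(assembly_ops or [])
        self._arrays: dict[str, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"<Structure {self.title!r} with {len(self)} atoms>"

    # -- cached column views -------------------------------------------------

    def _invalidate(self) -> None:
        self._arrays = None

    @property
    def arrays(self) -> dict[str, np.ndarray]:
        if self._arrays is None:
            a = self.atoms
            self._arrays = {
                "name": np.array([x.name for x in a], dtype=object),
                "resname": np.array([x.resname for x in a], dtype=object),
                "chain": np.array([x.chain_id for x in a], dtype=object),
                "resnum": np.array([x.resnum for x in a], dtype=int),
                "element": np.array([x.element for x in a], dtype=object),
                "hetero": np.array([x.hetero for x in a], dtype=bool),
            }
        return self._arrays

    @property
    def coords(self) -> np.ndarray:
        """N×3 coordinate array (a copy; mutate via :meth:`set_coords`)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate shape {xyz.shape} does not match "
                             f"{len(self.atoms)} atoms")
        for atom, row in zip(self.atoms, xyz):
            atom.coords = row.copy()

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain identifiers in file order."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def chain(self, chain_id: str) -> "Structure":
        return Structure([a for a in self.atoms if a.chain_id == chain_id],
                         title=f"{self.title}:{chain_id}")

    def residues(self) -> list[tuple[str, int, str, str]]:
        """Ordered distinct (chain, resnum, icode, resname) tuples."""
        seen: dict[tuple, None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.resnum, a.icode, a.resname), None)
        return list(seen)

    def copy(self) -> "Structure":
        return Structure([a.copy() for a in self.atoms], self.title,
                         [AssemblyOp(op.rotation.copy(), op.translation.copy(),
                                     list(op.target_chains), op.assembly_id)
                          for op in self.assembly_ops])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.copy()
        out.set_coords(self.coords @ np.asarray(rotation, float).T
                       + np.asarray(translation, float))
        return out


@dataclass
class AtomSelection:
    """Sorted atom indices into a parent structure."""

    parent: Structure
    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size:
            if np.any(np.diff(self.indices) <= 0):
                raise ValueError("selection indices must be strictly increasing")
            if self.indices[0] < 0 or self.indices[-1] >= len(self.parent):
                raise ValueError("selection index out of range")

    def __len__(self) -> int:
        return int(self.indices.size)

    def to_structure(self) -> Structure:
        atoms = [self.parent.atoms[i].copy() for i in self.indices]
        return Structure(atoms, title=f"{self.parent.title} ({self.expression})")

    @property
    def coords(self) -> np.ndarray:
        return self.parent.coords[self.indices]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _structure_from_gemmi(st: gemmi.Structure, altloc_policy: str) -> Structure:
    atoms: list[Atom] = []
    seen_altloc: set[tuple] = set()
    if len(st) == 0:
        raise ParseError("structure contains no models")
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                altloc = at.altloc if at.altloc not in ("", "\x00") else ""
                if altloc and altloc_policy == "first":
                    key = (chain.name, res.seqid.num, res.seqid.icode,
                           at.name)
                    if key in seen_altloc:
                        continue
                    seen_altloc.add(key)
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    altloc=altloc,
                    resname=res.name,
                    chain_id=chain.name,
                    resnum=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    bfactor=at.b_iso,
                    element=at.element.name,
                    hetero=het,
                ))
    ops: list[AssemblyOp] = []
    for i, assem in enumerate(st.assemblies, start=1):
        for gen in assem.generators:
            chains = list(gen.chains) or [c.name for c in model]
            for op in gen.operators:
                tr = op.transform
                ops.append(AssemblyOp(
                    rotation=np.array(tr.mat.tolist()),
                    translation=np.array(tr.vec.tolist()),
                    target_chains=chains,
                    assembly_id=i,
                ))
    return Structure(atoms, title=st.name or "", assembly_ops=ops)


def parse_structure(path: str | Path, altloc_policy: str = "first") -> Structure:
    """Parse a PDB or PDBx/mmCIF file into a :class:`Structure`.

    Parameters
    ----------
    path:
        File to read; the dialect is detected from extension and content.
    altloc_policy:
        ``"first"`` keeps only the first-listed alternate location of each
        atom (deterministic atom counts); ``"all"`` keeps every record.
    """
    if altloc_policy not in ("first", "all"):
        raise ValueError("altloc_policy must be 'first' or 'all'")
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path.name}: {exc}") from exc
    st.setup_entities()
    out = _structure_from_gemmi(st, altloc_policy)
    if len(out) == 0:
        raise ParseError(f"{path.name} contains no atoms")
    if not out.title:
        out.title = path.stem
    return out


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_H36_UPPER = string.digits + string.ascii_uppercase
_H36_LOWER = string.digits + string.ascii_lowercase


def _hybrid36(value: int, width: int = 5) -> str:
    """Encode a serial number in hybrid-36 (plain decimal while it fits)."""
    if value < 10 ** width:
        return str(value).rjust(width)
    value -= 10 ** width
    span = 26 * 36 ** (width - 1)
    for digits, offset in ((_H36_UPPER, 0), (_H36_LOWER, span)):
        if value < offset + span:
            v = value - offset + 10 * 36 ** (width - 1)
            out = ""
            while v:
                out = digits[v % 36] + out
                v //= 36
            return out.rjust(width)
    raise ValueError(f"serial {value} too large for hybrid-36 width {width}")


def _pdb_atom_name(name: str, element: str) -> str:
    # element symbols start in column 13 unless the name needs 4 characters
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return name.ljust(4)
    return (" " + name).ljust(4)


def _write_pdb(s: Structure, path: Path) -> None:
    lines = []
    if s.title:
        lines.append("TITLE     " + s.title[:70])
    for i, a in enumerate(s.atoms, start=1):
        if len(a.chain_id) > 1:
            raise ValueError(
                f"chain id {a.chain_id!r} is wider than one character; "
                "write mmCIF instead")
        record = "HETATM" if a.hetero else "ATOM  "
        lines.append(
            f"{record}{_hybrid36(i)} {_pdb_atom_name(a.name, a.element)}"
            f"{(a.altloc or ' ')[:1]}{a.resname:>3s} {a.chain_id or ' '}"
            f"{a.resnum:4d}{(a.icode or ' ')[:1]}   "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _cif_quote(v: str) -> str:
    if v == "":
        return "."
    if any(c in v for c in " '\"") :
        return f'"{v}"'
    return v


def _write_mmcif(s: Structure, path: Path) -> None:
    lines = [f"data_{(s.title or 'flexkit').replace(' ', '_')}", "#", "loop_"]
    cols = ["group_PDB", "id", "label_atom_id", "label_alt_id",
            "label_comp_id", "auth_asym_id", "auth_seq_id",
            "pdbx_PDB_ins_code", "Cartn_x", "Cartn_y", "Cartn_z",
            "occupancy", "B_iso_or_equiv", "type_symbol",
            "label_asym_id", "label_seq_id"]
    lines += [f"_atom_site.{c}" for c in cols]
    for i, a in enumerate(s.atoms, start=1):
        rec = "HETATM" if a.hetero else "ATOM"
        lines.append(" ".join([
            rec, str(i), _cif_quote(a.name), a.altloc or ".",
            _cif_quote(a.resname), _cif_quote(a.chain_id or "."),
            str(a.resnum), a.icode or "?",
            f"{a.coords[0]:.3f}", f"{a.coords[1]:.3f}", f"{a.coords[2]:.3f}",
            f"{a.occupancy:.2f}", f"{a.bfactor:.2f}",
            a.element or "?", _cif_quote(a.chain_id or "."), str(a.resnum),
        ]))
    lines.append("#")
    path.write_text("\n".join(lines) + "\n")


def write_structure(s: Structure | AtomSelection, path: str | Path,
                    format: str | None = None) -> Path:
    """Write a structure (or selection) as PDB or mmCIF.

    ``format`` defaults from the file extension (``.cif`` → mmCIF, else PDB).
    PDB serials beyond 99999 are written in hybrid-36.
    """
    if isinstance(s, AtomSelection):
        s = s.to_structure()
    path = Path(path)
    if format is None:
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    if format == "pdb":
        _write_pdb(s, path)
    elif format == "mmcif":
        _write_mmcif(s, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Selection mini-language
# ---------------------------------------------------------------------------

_KEYWORDS = {"and", "or", "not", "protein", "nucleic", "hetero", "ca",
             "name", "chain", "resnum", "resname", "element", "to"}


def _tokenize(expr: str) -> list[str]:
    out: list[str] = []
    token = ""
    for ch in expr:
        if ch in "()":
            if token:
                out.append(token)
                token = ""
            out.append(ch)
        elif ch.isspace():
            if token:
                out.append(token)
                token = ""
        else:
            token += ch
    if token:
        out.append(token)
    return out


class _SelParser:
    """Recursive-descent parser producing a boolean mask over atoms.

    Grammar::

        expr   := and_e ('or' and_e)*
        and_e  := unary ('and' unary)*
        unary  := 'not' unary | '(' expr ')' | predicate
        pred   := protein | nucleic | hetero | ca
                | (name|chain|resname|element) value+
                | resnum (INT | INT 'to' INT)+
    """

    def __init__(self, tokens: list[str], s: Structure):
        self.tokens = tokens
        self.pos = 0
        self.s = s
        self.arr = s.arrays
        self.n = len(s)

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.take()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.take()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.unary()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("missing closing parenthesis")
            return mask
        return self.predicate()

    def _values(self) -> list[str]:
        vals: list[str] = []
        while True:
            tok = self.peek()
            if tok is None or tok in _KEYWORDS or tok in "()":
                break
            vals.append(self.take())
        if not vals:
            raise SelectionError("keyword expects at least one value")
        return vals

    def _resnum_mask(self) -> np.ndarray:
        resnum = self.arr["resnum"]
        mask = np.zeros(self.n, dtype=bool)
        items = 0
        while True:
            tok = self.peek()
            if tok is None or tok in "()" or (tok in _KEYWORDS):
                break
            tok = self.take()
            try:
                lo = int(tok)
            except ValueError as exc:
                raise SelectionError(f"resnum expects integers, got {tok!r}") from exc
            if self.peek() == "to":
                self.take()
                hi_tok = self.take()
                try:
                    hi = int(hi_tok)
                except ValueError as exc:
                    raise SelectionError(
                        f"resnum range end must be an integer, got {hi_tok!r}") from exc
                mask |= (resnum >= lo) & (resnum <= hi)
            else:
                mask |= resnum == lo
            items += 1
        if items == 0:
            raise SelectionError("resnum expects at least one value")
        return mask

    def predicate(self) -> np.ndarray:
        tok = self.take()
        arr = self.arr
        if tok == "protein":
            return np.isin(arr["resname"], list(PROTEIN_RESNAMES))
        if tok == "nucleic":
            return np.isin(arr["resname"], list(NUCLEIC_RESNAMES))
        if tok == "hetero":
            return arr["hetero"].copy()
        if tok == "ca":
            return (np.isin(arr["resname"], list(PROTEIN_RESNAMES))
                    & (arr["name"] == "CA"))
        if tok == "name":
            return np.isin(arr["name"], self._values())
        if tok == "chain":
            return np.isin(arr["chain"], self._values())
        if tok == "resname":
            return np.isin(arr["resname"], self._values())
        if tok == "element":
            return np.isin(arr["element"], self._values())
        if tok == "resnum":
            return self._resnum_mask()
        raise SelectionError(f"unknown keyword {tok!r}")


def select_atoms(s: Structure | AtomSelection, expr: str) -> AtomSelection:
    """Evaluate a selection expression and return the matching atoms.

    Selecting on a selection intersects with it, so chained selections
    compose. See :class:`_SelParser` for the grammar.
    """
    if isinstance(s, AtomSelection):
        inner = select_atoms(s.parent, expr)
        idx = np.intersect1d(s.indices, inner.indices)
        return AtomSelection(s.parent, idx,
                             f"({s.expression}) and ({expr})")
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelParser(tokens, s).parse()
    return AtomSelection(s, np.flatnonzero(mask), expr)


# ---------------------------------------------------------------------------
# Biological assemblies
# ---------------------------------------------------------------------------

def build_assemblies(s: Structure) -> list[Structure]:
    """Apply recorded assembly operators, one output structure per assembly.

    Chain ids are disambiguated deterministically: copy ``k`` (1-based) of
    chain ``X`` is named ``X`` for the first copy and ``X2``, ``X3``, … for
    subsequent copies.  Without assembly records the input is returned
    unchanged (flagged via ``title``).
    """
    if not s.assembly_ops:
        out = s.copy()
        out.title = (out.title + " (no assembly records)").strip()
        return [out]
    by_assembly: dict[int, list[AssemblyOp]] = {}
    for op in s.assembly_ops:
        by_assembly.setdefault(op.assembly_id, []).append(op)
    results = []
    for aid in sorted(by_assembly):
        atoms: list[Atom] = []
        copy_count: dict[str, int] = {}
        for op in by_assembly[aid]:
            chain_map: dict[str, str] = {}
            for cid in op.target_chains:
                k = copy_count.get(cid, 0) + 1
                copy_count[cid] = k
                chain_map[cid] = cid if k == 1 else f"{cid}{k}"
            for a in s.atoms:
                if a.chain_id not in chain_map:
                    continue
                b = a.copy()
                b.coords = op.rotation @ a.coords + op.translation
                b.chain_id = chain_map[a.chain_id]
                atoms.append(b)
        results.append(Structure(atoms, title=f"{s.title} assembly {aid}"))
    return results
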
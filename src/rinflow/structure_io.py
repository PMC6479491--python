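"""Structure and ensemble I/O, atom selections, frame validation.

Coordinates are stored in Angstrom throughout; times in picoseconds.
PDB reading/writing is delegated to :mod:`biotite.structure.io.pdb` behind
the package's own :class:`StructureModel` / :class:`TrajectoryEnsemble`
containers.  Multi-model PDB is the mandatory ensemble dialect; per-frame
timestamps are carried in ``REMARK   6 TIME_PS MODEL <i> <t>`` header lines
and default to ``0, stride, 2*stride, ...`` when absent.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "StructureModel",
    "TrajectoryEnsemble",
    "AtomSelection",
    "PDBParseError",
    "SelectionError",
    "read_pdb",
    "write_pdb",
    "read_ensemble",
    "write_ensemble",
    "select",
    "BACKBONE_ATOM_NAMES",
]

# ---------------------------------------------------------------------------
# constants

#: Default backbone atom names (amide N, Calpha, carbonyl C and O).
BACKBONE_ATOM_NAMES: tuple[str, ...] = ("N", "CA", "C", "O")

WATER_RESNAMES = {"HOH", "WAT", "SOL", "TIP3", "TIP3P", "SPC", "H2O"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # common tautomer / protonation variants
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "MSE",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "HSD": "H", "HSE": "H", "HSP": "H", "HID": "H", "HIE": "H",
    "HIP": "H", "CYX": "C", "MSE": "M",
}

_TIME_REMARK = re.compile(
    r"^REMARK\s+6\s+TIME_PS\s+MODEL\s+(\d+)\s+([-+0-9.eE]+)"
)


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class SelectionError(ValueError):
    """Raised on an invalid selection expression."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Atom:
    """One atom of a structure model.

    ``residue_index`` is the package-internal 0-based sequential index;
    ``res_seq`` / ``insertion_code`` preserve the author numbering used in
    all user-facing reports.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    res_seq: int = 0
    insertion_code: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        if not self.element:
            self.element = _infer_element(self.name)


@dataclass
class Residue:
    """Derived grouping of atoms sharing (chain, residue index)."""

    index: int
    chain_id: str
    name: str
    res_seq: int
    insertion_code: str
    atom_indices: np.ndarray
    hetero: bool

    @property
    def label(self) -> str:
        """Author-numbered label in one-letter style, e.g. ``Y314``."""
        one = THREE_TO_ONE.get(self.name, "X")
        icode = self.insertion_code.strip()
        return f"{one}{self.res_seq}{icode}"


@dataclass
class StructureModel:
    """An ordered list of atoms with derived residue grouping."""

    atoms: list[Atom]
    residues: list[Residue] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serial numbers within a model")
        if not self.residues:
            self.residues = self._group_residues()

    def _group_residues(self) -> list[Residue]:
        residues: list[Residue] = []
        seen: dict[int, int] = {}
        for i, atom in enumerate(self.atoms):
            ridx = atom.residue_index
            if ridx not in seen:
                seen[ridx] = len(residues)
                residues.append(
                    Residue(
                        index=ridx,
                        chain_id=atom.chain_id,
                        name=atom.residue_name,
                        res_seq=atom.res_seq,
                        insertion_code=atom.insertion_code,
                        atom_indices=np.array([i], dtype=int),
                        hetero=atom.hetero,
                    )
                )
            else:
                res = residues[seen[ridx]]
                res.atom_indices = np.append(res.atom_indices, i)
        return residues

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Copy of the model with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            Atom(a.serial, a.name, a.element, a.residue_index, a.residue_name,
                 a.chain_id, coords[i].copy(), a.res_seq, a.insertion_code,
                 a.hetero)
            for i, a in enumerate(self.atoms)
        ]
        return StructureModel(atoms)


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames over a fixed topology."""

    topology: StructureModel
    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    times: np.ndarray  # (n_frames,), ps

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} differs from "
                f"topology atom count {self.topology.n_atoms}"
            )
        if len(self.times) != len(self.frames):
            raise ValueError("times length must equal number of frames")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_model(self, index: int) -> StructureModel:
        """Topology with the coordinates of one frame."""
        return self.topology.with_coords(self.frames[index])


@dataclass
class AtomSelection:
    """An ordered, duplicate-free set of atom indices with a label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("selection contains duplicate indices")

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# element inference / biotite conversion


def _infer_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _model_from_atom_array(arr: struc.AtomArray, include_water: bool) -> StructureModel:
    if not include_water:
        keep = ~np.isin(arr.res_name, list(WATER_RESNAMES))
        arr = arr[keep]
    if arr.array_length() == 0:
        raise PDBParseError("no atoms after filtering (empty structure)")
    atoms: list[Atom] = []
    ridx = -1
    prev_key = None
    for i in range(arr.array_length()):
        key = (arr.chain_id[i], arr.res_id[i], arr.ins_code[i], arr.res_name[i])
        if key != prev_key:
            ridx += 1
            prev_key = key
        element = str(arr.element[i]).strip()
        atoms.append(
            Atom(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                element=element or _infer_element(str(arr.atom_name[i])),
                residue_index=ridx,
                residue_name=str(arr.res_name[i]),
                chain_id=str(arr.chain_id[i]) or "A",
                position=arr.coord[i],
                res_seq=int(arr.res_id[i]),
                insertion_code=str(arr.ins_code[i]),
                hetero=bool(arr.hetero[i]),
            )
        )
    return StructureModel(atoms)


def _atom_array_from_model(model: StructureModel, coords: np.ndarray | None = None) -> struc.AtomArray:
    n = model.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = model.coords if coords is None else np.asarray(coords, dtype=float)
    arr.chain_id = np.array([a.chain_id for a in model.atoms], dtype="U4")
    arr.res_id = np.array([a.res_seq for a in model.atoms], dtype=int)
    arr.ins_code = np.array([a.insertion_code for a in model.atoms], dtype="U1")
    arr.res_name = np.array([a.residue_name for a in model.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in model.atoms], dtype="U6")
    arr.element = np.array([a.element for a in model.atoms], dtype="U2")
    arr.hetero = np.array([a.hetero for a in model.atoms], dtype=bool)
    return arr


# ---------------------------------------------------------------------------
# reading / writing


def _prevalidate_pdb_text(text: str) -> None:
    """Check coordinate fields of ATOM/HETATM records, naming bad lines."""
    has_atoms = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            has_atoms = True
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi].strip()
                try:
                    float(fld)
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field {fld!r} on line {lineno}"
                    ) from None
    if not has_atoms:
        raise PDBParseError("no ATOM/HETATM records found (empty or non-PDB file)")


def read_pdb(path, include_water: bool = False) -> StructureModel:
    """Read the first model of a PDB file.

    Alternate locations are resolved to the highest occupancy (ties: first
    listed); water residues are excluded unless ``include_water`` is set.
    """
    with open(path) as fh:
        text = fh.read()
    _prevalidate_pdb_text(text)
    pdb = PDBFile.read(io.StringIO(text))
    try:
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # occupancy column may be absent
        arr = pdb.get_structure(model=1, altloc="first")
        del exc
    return _model_from_atom_array(arr, include_water)


def read_ensemble(path, stride_ps: float = 1.0, include_water: bool = False) -> TrajectoryEnsemble:
    """Read a multi-model PDB as a trajectory ensemble.

    One frame per MODEL block.  Frame times come from
    ``REMARK   6 TIME_PS MODEL <i> <t>`` lines when present, otherwise
    ``0, stride_ps, 2*stride_ps, ...``.
    """
    with open(path) as fh:
        text = fh.read()
    _prevalidate_pdb_text(text)
    pdb = PDBFile.read(io.StringIO(text))
    try:
        try:
            stack = pdb.get_structure(altloc="occupancy")
        except struc.BadStructureError:
            stack = pdb.get_structure(altloc="first")
    except Exception as exc:
        # biotite names the offending model on atom-count mismatches;
        # re-raise under the package's error type.
        raise PDBParseError(str(exc)) from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    model = _model_from_atom_array(stack[0], include_water)
    if not include_water:
        keep = ~np.isin(stack.res_name, list(WATER_RESNAMES))
        coords = stack.coord[:, keep, :]
    else:
        coords = stack.coord
    n_frames = coords.shape[0]

    remark_times: dict[int, float] = {}
    for line in text.splitlines():
        m = _TIME_REMARK.match(line)
        if m:
            remark_times[int(m.group(1))] = float(m.group(2))
    if len(remark_times) == n_frames:
        times = np.array([remark_times[i + 1] for i in range(n_frames)])
    else:
        times = np.arange(n_frames, dtype=float) * stride_ps
    return TrajectoryEnsemble(topology=model, frames=coords, times=times)


def write_pdb(model: StructureModel, path) -> None:
    """Write a single-model PDB file."""
    pdb = PDBFile()
    pdb.set_structure(_atom_array_from_model(model))
    pdb.write(str(path))


def write_ensemble(ensemble: TrajectoryEnsemble, path) -> None:
    """Write a multi-model PDB with per-frame time remarks."""
    arrays = [
        _atom_array_from_model(ensemble.topology, ensemble.frames[i])
        for i in range(ensemble.n_frames)
    ]
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    buf = io.StringIO()
    pdb.write(buf)
    remarks = "".join(
        f"REMARK   6 TIME_PS MODEL {i + 1} {t:.6g}\n"
        for i, t in enumerate(ensemble.times)
    )
    with open(path, "w") as fh:
        fh.write(remarks)
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# selection mini-grammar
#
#   expr    := term ("or" term)*
#   term    := factor ("and" factor)*
#   factor  := "not" factor | "(" expr ")" | primary
#   primary := backbone | calpha | heavy | sidechain | protein | ligand
#            | water | all | resid <n|n-m> ... | chain <id> ... | name <nm> ...

_KEYWORDS = {"backbone", "calpha", "heavy", "sidechain", "protein", "ligand",
             "water", "all"}
_LIST_HEADS = {"resid", "chain", "name"}
_OPERATORS = {"and", "or", "not", "(", ")"}


def _tokenize(expression: str) -> list[str]:
    return expression.replace("(", " ( ").replace(")", " ) ").split()


class _SelParser:
    def __init__(self, tokens: list[str], model: StructureModel,
                 backbone_atoms: tuple[str, ...]):
        self.tokens = tokens
        self.pos = 0
        self.model = model
        self.backbone_atoms = backbone_atoms

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
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.primary()

    def primary(self) -> np.ndarray:
        tok = self.take()
        low = tok.lower()
        if low in _KEYWORDS:
            return self._keyword_mask(low)
        if low in _LIST_HEADS:
            args = []
            while (nxt := self.peek()) is not None and \
                    nxt.lower() not in _OPERATORS | _KEYWORDS | _LIST_HEADS:
                args.append(self.take())
            if not args:
                raise SelectionError(f"{low!r} requires at least one argument")
            return self._list_mask(low, args)
        raise SelectionError(f"unknown selection token {tok!r}")

    def _keyword_mask(self, kw: str) -> np.ndarray:
        atoms = self.model.atoms
        n = len(atoms)
        mask = np.zeros(n, dtype=bool)
        for i, a in enumerate(atoms):
            is_water = a.residue_name in WATER_RESNAMES
            is_protein = a.residue_name in STANDARD_AA
            if kw == "all":
                mask[i] = True
            elif kw == "protein":
                mask[i] = is_protein
            elif kw == "water":
                mask[i] = is_water
            elif kw == "ligand":
                mask[i] = a.hetero and not is_water and a.residue_name not in STANDARD_AA
            elif kw == "calpha":
                mask[i] = is_protein and a.name == "CA"
            elif kw == "backbone":
                mask[i] = is_protein and a.name in self.backbone_atoms
            elif kw == "heavy":
                mask[i] = a.element != "H"
            elif kw == "sidechain":
                mask[i] = (is_protein and a.element != "H"
                           and a.name not in self.backbone_atoms
                           and a.name != "OXT")
        return mask

    def _list_mask(self, head: str, args: list[str]) -> np.ndarray:
        atoms = self.model.atoms
        if head == "resid":
            wanted: set[int] = set()
            for arg in args:
                m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", arg)
                if not m:
                    raise SelectionError(f"bad resid token {arg!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) else lo
                wanted.update(range(lo, hi + 1))
            return np.array([a.res_seq in wanted for a in atoms])
        if head == "chain":
            return np.array([a.chain_id in set(args) for a in atoms])
        # name list
        names = {a.upper() for a in args}
        return np.array([a.name.upper() in names for a in atoms])


def select(model: StructureModel, expression: str,
           within: AtomSelection | None = None,
           backbone_atoms: tuple[str, ...] = BACKBONE_ATOM_NAMES) -> AtomSelection:
    """Evaluate a selection expression on a model.

    ``resid`` uses author (PDB) numbering.  ``within`` restricts the result
    to a previous selection, making nested selection monotone by
    construction.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelParser(tokens, model, backbone_atoms).parse()
    indices = np.flatnonzero(mask)
    if within is not None:
        indices = indices[np.isin(indices, within.indices)]
    return AtomSelection(indices=indices, label=expression)
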
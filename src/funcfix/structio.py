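"""Structure and alignment I/O with a uniform coordinate/residue model.

Reading goes through :mod:`gemmi` (PDB and mmCIF); alignments go through
:mod:`Bio.SeqIO`. The in-memory model is deliberately small: atoms with
coordinates, residues with both author numbering and a contiguous 1-based
``seq_index`` along each polymer chain, and hetero groups (ligands, ions,
waters) kept apart from the polymer. All downstream mask, triage and
ensemble computations run on this model, never on library internals.

Conventions
-----------
* ``seq_index`` is assigned 1..n per chain in file order, ignoring gaps in
  author numbering. Fixed-position output uses this sequential numbering
  (the convention inverse-folding backends consume); ``auth_seq_id`` is
  preserved for human-readable reports.
* Alternate conformers: only the highest-occupancy conformer of each atom
  is kept.
* Multi-model files yield the first model from :func:`read_structure`;
  use :func:`read_models` to obtain every model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
from Bio import SeqIO


class StructioError(ValueError):
    """Raised for unreadable or structurally invalid input files."""


class EmptyStructureError(StructioError):
    """Raised when a file contains no polymer residues."""


#: Water residue names never treated as ligands.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O", "TIP", "SOL"})

#: Standard 3-letter -> 1-letter amino acid table; anything else maps to X.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_AA3 = frozenset(THREE_TO_ONE)


@dataclass
class Atom:
    """A single atom: label, element and Cartesian coordinates in Å.

    ``bfactor`` doubles as the per-residue pLDDT channel when the file is a
    predicted model (the predictor convention of storing confidence in the
    B-factor column).
    """

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructioError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.element:
            raise StructioError(f"atom {self.name!r}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    """One residue (polymer) or hetero group (ligand/ion/water)."""

    chain_id: str
    auth_seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    seq_index: int | None = None  # 1-based along the polymer chain; None for hetero
    is_hetero: bool = False

    def heavy_coords(self) -> np.ndarray:
        """(k, 3) array of non-hydrogen atom coordinates."""
        pts = [a.coords for a in self.atoms if not a.is_hydrogen]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not found in {self.chain_id}:{self.auth_seq_id}:{self.res_name}")

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.res_name, "X")


@dataclass
class Chain:
    """An ordered polymer chain."""

    id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def ca_coords(self) -> np.ndarray:
        """(n, 3) Cα coordinates in seq_index order; raises if any Cα missing."""
        pts = []
        for r in self.residues:
            try:
                pts.append(r.atom("CA").coords)
            except KeyError:
                raise StructioError(
                    f"chain {self.id}: residue {r.auth_seq_id} ({r.res_name}) has no CA atom"
                ) from None
        return np.array(pts, dtype=float).reshape(-1, 3)


@dataclass
class Structure:
    """Polymer chains plus hetero groups, as read from one model."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    hetero_groups: list[Residue] = field(default_factory=list)

    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(
            f"chain {chain_id!r} not found; available chains: {', '.join(self.chain_ids()) or '(none)'}"
        )

    def residue_at(self, chain_id: str, seq_index: int) -> Residue:
        chain = self.get_chain(chain_id)
        if not 1 <= seq_index <= len(chain):
            raise KeyError(f"chain {chain_id}: seq_index {seq_index} out of range 1..{len(chain)}")
        return chain.residues[seq_index - 1]

    def n_atoms(self) -> int:
        n = sum(len(r.atoms) for c in self.chains for r in c)
        return n + sum(len(r.atoms) for r in self.hetero_groups)


# ---------------------------------------------------------------------------
# structure reading
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    return "pdb"


def _read_gemmi(path: Path, format: str) -> gemmi.Structure:
    try:
        if format == "pdb":
            return gemmi.read_pdb(str(path))
        if format == "mmcif":
            return gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        return gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructioError(f"cannot parse {path} as {format}: {exc}") from exc


def _best_altloc(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy conformer per atom name (ties: first seen)."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for at in res:
        key = at.name
        if key not in best:
            best[key] = at
            order.append(key)
        elif at.occ > best[key].occ:
            best[key] = at
    return [best[k] for k in order]


def _convert_model(model: gemmi.Model, struct_id: str) -> Structure:
    out = Structure(id=struct_id)
    for gchain in model:
        chain = Chain(id=gchain.name)
        seq_index = 0
        for gres in gchain:
            atoms = []
            for gat in _best_altloc(gres):
                elem = gat.element.name or gat.name[:1]
                atoms.append(
                    Atom(name=gat.name, element=elem,
                         coords=np.array([gat.pos.x, gat.pos.y, gat.pos.z]),
                         occupancy=gat.occ, bfactor=gat.b_iso)
                )
            het_flag = gres.het_flag
            is_het = het_flag == "H" or (het_flag not in ("A", "H") and gres.name not in _AA3)
            res = Residue(
                chain_id=gchain.name,
                auth_seq_id=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
                res_name=gres.name,
                atoms=atoms,
                is_hetero=is_het,
            )
            if is_het:
                out.hetero_groups.append(res)
            else:
                seq_index += 1
                res.seq_index = seq_index
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    return out


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB/mmCIF file into a :class:`Structure` (first model only).

    Polymer residues get ``seq_index`` 1..n per chain in file order; hetero
    groups (ligands, ions, waters) are kept in ``hetero_groups``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown structure format {format!r}; use pdb, mmcif or auto")
    st = _read_gemmi(path, format)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models found")
    out = _convert_model(st[0], st.name or path.stem)
    if not out.chains:
        raise EmptyStructureError(f"{path}: no polymer residues found")
    return out


def read_models(path: str | Path, format: str = "auto") -> list[Structure]:
    """Read every model of a (multi-model) PDB/mmCIF file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)
    st = _read_gemmi(path, format)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models found")
    models = [_convert_model(m, f"{st.name or path.stem}") for m in st]
    for i, m in enumerate(models, start=1):
        if not m.chains:
            raise EmptyStructureError(f"{path}: model {i} has no polymer residues")
    return models


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as a single-model PDB file."""
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gchain.add_residue(_to_gemmi_residue(res, het=False))
        model.add_chain(gchain)
    # hetero groups are appended on their own chains, grouped by chain id
    het_by_chain: dict[str, list[Residue]] = {}
    for res in structure.hetero_groups:
        het_by_chain.setdefault(res.chain_id, []).append(res)
    for cid, residues in het_by_chain.items():
        gchain = gemmi.Chain(cid)
        for res in residues:
            gchain.add_residue(_to_gemmi_residue(res, het=True))
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _to_gemmi_residue(res: Residue, het: bool) -> gemmi.Residue:
    gres = gemmi.Residue()
    gres.name = res.res_name
    gres.seqid = gemmi.SeqId(res.auth_seq_id, res.icode or " ")
    gres.het_flag = "H" if het else "A"
    for at in res.atoms:
        gat = gemmi.Atom()
        gat.name = at.name
        gat.element = gemmi.Element(at.element)
        gat.pos = gemmi.Position(*at.coords)
        gat.occ = at.occupancy
        gat.b_iso = at.bfactor
        gres.add_atom(gat)
    return gres


def extract_sequence(structure: Structure, chain: str) -> str:
    """One-letter sequence of a polymer chain in ``seq_index`` order.

    Residues without a standard one-letter mapping become ``X``.
    """
    return "".join(r.one_letter for r in structure.get_chain(chain))


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class Msa:
    """A multiple sequence alignment with a designated parent/query row."""

    rows: list[str]
    ids: list[str]
    parent_row: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise StructioError("alignment has no rows")
        width = len(self.rows[0])
        for i, row in enumerate(self.rows):
            if len(row) != width:
                raise StructioError(
                    f"alignment row {i} ({self.ids[i]!r}) has length {len(row)}, expected {width}"
                )
        if not 0 <= self.parent_row < len(self.rows):
            raise StructioError(f"parent_row {self.parent_row} out of range")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def parent_sequence(self) -> str:
        """Ungapped parent sequence."""
        return self.rows[self.parent_row].replace("-", "").replace(".", "")

    def parent_columns(self) -> list[int]:
        """Alignment column index of each ungapped parent position."""
        return [j for j, c in enumerate(self.rows[self.parent_row]) if c not in "-."]


def read_msa(path: str | Path, format: str = "auto") -> Msa:
    """Read an aligned FASTA or A3M alignment.

    A3M lowercase insertion columns (and ``.`` gaps) are removed so every
    row aligns to the query columns. ``parent_row`` defaults to row 0.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "a3m" if path.suffix.lower() == ".a3m" else "aligned-fasta"
    if format not in ("aligned-fasta", "a3m"):
        raise ValueError(f"unknown MSA format {format!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise StructioError(f"{path}: no sequences found")
    rows, ids = [], []
    for rec in records:
        seq = str(rec.seq)
        if format == "a3m":
            seq = "".join(c for c in seq if not (c.islower() or c == "."))
        rows.append(seq.upper())
        ids.append(rec.id)
    return Msa(rows=rows, ids=ids, parent_row=0)
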
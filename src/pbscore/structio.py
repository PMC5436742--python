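"""Structure data model and PDB I/O.

A deliberately small hierarchical model (chains -> residues -> atoms) plus the
crystal cell, with gemmi doing the fixed-width PDB parsing/writing underneath.
All coordinates are orthogonal Angstroms; fractional coordinates appear only
inside symmetry application (see :mod:`pbscore.assembler`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

from . import config

WATER_NAMES = {"HOH", "WAT", "DOD"}

# 3-letter -> 1-letter for chain sequence extraction; MEN (N4-methyl
# asparagine, present in APC beta subunits) is treated as an ASN variant.
AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MEN": "N", "MSE": "M",
}
AA1TO3 = {v: k for k, v in reversed(list(AA3TO1.items()))}


class StructureError(ValueError):
    """Raised for malformed or unusable structural input."""


@dataclasses.dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray            # shape (3,), orthogonal Å
    occ: float = 1.0
    b: float = 0.0
    het: bool = False

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.pos.copy(), self.occ,
                    self.b, self.het)


@dataclasses.dataclass
class Residue:
    name: str
    seqnum: int
    icode: str = ""
    atoms: list[Atom] = dataclasses.field(default_factory=list)
    #: template residue this one was threaded from (modelling provenance)
    source_seqnum: int | None = None

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def is_het(self) -> bool:
        return any(a.het for a in self.atoms)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def copy(self) -> "Residue":
        return Residue(self.name, self.seqnum, self.icode,
                       [a.copy() for a in self.atoms], self.source_seqnum)


@dataclasses.dataclass
class Chain:
    id: str
    residues: list[Residue] = dataclasses.field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def residue(self, seqnum: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.seqnum == seqnum and r.icode == icode:
                return r
        return None

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)

    def sequence(self) -> str:
        """One-letter sequence from ATOM records (waters/ligands skipped)."""
        return "".join(AA3TO1[r.name] for r in self.residues
                       if r.name in AA3TO1)

    def copy(self) -> "Chain":
        return Chain(self.id, [r.copy() for r in self.residues])


@dataclasses.dataclass
class CrystalCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    space_group: str = "P 1"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise StructureError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise StructureError("cell angles must be in (0, 180)")

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c,
                              self.alpha, self.beta, self.gamma)


@dataclasses.dataclass
class StructureModel:
    chains: list[Chain] = dataclasses.field(default_factory=list)
    cell: CrystalCell | None = None
    meta: dict = dataclasses.field(default_factory=dict)

    def chain(self, cid: str) -> Chain:
        for c in self.chains:
            if c.id == cid:
                return c
        raise KeyError(f"no chain {cid!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    @property
    def atoms(self) -> list[Atom]:
        return [a for c in self.chains for a in c.atoms]

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)

    def copy(self) -> "StructureModel":
        return StructureModel([c.copy() for c in self.chains],
                              dataclasses.replace(self.cell) if self.cell else None,
                              dict(self.meta))

    def validate(self) -> None:
        seen_chains: set[str] = set()
        for ch in self.chains:
            if ch.id in seen_chains:
                raise StructureError(f"duplicate chain id {ch.id!r}")
            seen_chains.add(ch.id)
            keys = set()
            for r in ch.residues:
                for a in r.atoms:
                    if not np.all(np.isfinite(a.pos)):
                        raise StructureError("non-finite coordinates")
                    k = (ch.id, r.seqnum, r.icode, a.name)
                    if k in keys:
                        raise StructureError(f"duplicate atom {k}")
                    keys.add(k)


@dataclasses.dataclass
class Ligand:
    chain_id: str
    resname: str
    seqnum: int
    atoms: list[Atom]
    bonds: set[tuple[int, int]]   # index pairs into atoms, i < j

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)

    def atom_index(self, name: str) -> int | None:
        for i, a in enumerate(self.atoms):
            if a.name == name:
                return i
        return None


# ---------------------------------------------------------------------------
# PDB I/O

def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one atom per name: highest occupancy, ties broken toward 'A'."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name, alts in by_name.items():
        alts.sort(key=lambda a: (-a.occ, a.altloc or "A"))
        out.append(alts[0])
    return out


def read_pdb(path: str | Path) -> StructureModel:
    """Read a PDB file into a StructureModel.

    Altlocs are resolved to the highest-occupancy conformer (tie -> 'A');
    waters are retained (flag via ``Residue.is_water``).  The dummy P1
    1x1x1 cell gemmi uses for cell-less files is treated as "no cell".
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise StructureError(f"{path}: no atoms")
    model = StructureModel()
    g = st[0]
    for gch in g:
        chain = Chain(gch.name)
        for gres in gch:
            res = Residue(gres.name, gres.seqid.num,
                          gres.seqid.icode.strip())
            het = gres.het_flag == "H"
            for ga in _resolve_altlocs(gres):
                res.atoms.append(Atom(ga.name, ga.element.name.upper(),
                                      np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                                      ga.occ, ga.b_iso, het))
            chain.residues.append(res)
        model.chains.append(chain)
    cell = st.cell
    if cell.a > 1.0 or cell.b > 1.0 or cell.c > 1.0:
        model.cell = CrystalCell(cell.a, cell.b, cell.c, cell.alpha,
                                 cell.beta, cell.gamma,
                                 st.spacegroup_hm or "P 1")
    model.validate()
    return model


def to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "pbscore"
    if model.cell is not None:
        st.cell = model.cell.to_gemmi()
        st.spacegroup_hm = model.cell.space_group
    gm = gemmi.Model("1")
    for ch in model.chains:
        gch = gemmi.Chain(ch.id)
        for r in ch.residues:
            gr = gemmi.Residue()
            gr.name = r.name
            gr.seqid = gemmi.SeqId(r.seqnum, r.icode or " ")
            gr.het_flag = "H" if (r.is_het or r.is_water
                                  or r.name not in AA3TO1) else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occ
                ga.b_iso = a.b
                gr.add_atom(ga)
            gch.add_residue(gr)
        gm.add_chain(gch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write fixed-width PDB (ATOM/HETATM/TER; CRYST1 when a cell is set)."""
    model.validate()
    natoms = len(model.atoms)
    if natoms > 99999:
        raise StructureError(f"{natoms} atoms exceed the PDB serial limit")
    st = to_gemmi(model)
    Path(path).write_text(st.make_pdb_string())


def extract_ligands(model: StructureModel,
                    resnames: Iterable[str]) -> list[Ligand]:
    """Pull het residues matching ``resnames``, with distance-inferred bonds.

    Bonds are inferred between C/N/O/S heavy-atom pairs at <= 1.8 Å
    (inclusive); the result is symmetric by construction.
    """
    wanted = set(resnames)
    out = []
    for ch in model.chains:
        for r in ch.residues:
            if r.name in wanted:
                lig = Ligand(ch.id, r.name, r.seqnum,
                             [a.copy() for a in r.atoms], set())
                lig.bonds = infer_bonds(lig.atoms)
                out.append(lig)
    return out


def infer_bonds(atoms: list[Atom],
                cutoff: float = config.BOND_INFER_CUTOFF) -> set[tuple[int, int]]:
    bondable = {"C", "N", "O", "S"}
    xyz = np.array([a.pos for a in atoms])
    bonds: set[tuple[int, int]] = set()
    for i in range(len(atoms)):
        if atoms[i].element not in bondable:
            continue
        d = np.linalg.norm(xyz[i + 1:] - xyz[i], axis=1)
        for off in np.nonzero(d <= cutoff)[0]:
            j = i + 1 + int(off)
            if atoms[j].element in bondable:
                bonds.add((i, j))
    return bonds


# ---------------------------------------------------------------------------
# Fractional <-> orthogonal transforms

def frac_orth_transforms(cell: CrystalCell) -> tuple[np.ndarray, np.ndarray]:
    """Return (orth, frac) 3x3 matrices for the cell.

    Standard crystallographic convention: *a* along x, *b* in the xy plane.
    ``orth @ frac == I`` to 1e-10.  Offsets are zero (PDB scale convention).
    """
    gc = cell.to_gemmi()
    if gc.volume <= 1e-6:
        raise StructureError("degenerate cell (zero volume)")
    orth = np.array(gc.orth.mat.tolist())
    frac = np.array(gc.frac.mat.tolist())
    return orth, frac


def write_chain_fasta(model: StructureModel, path: str | Path) -> None:
    """Export each chain's ATOM-derived sequence as wrapped FASTA."""
    lines = []
    for ch in model.chains:
        seq = ch.sequence()
        if not seq:
            continue
        lines.append(f">{ch.id}")
        lines.extend(seq[i:i + 60] for i in range(0, len(seq), 60))
    Path(path).write_text("\n".join(lines) + "\n")
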
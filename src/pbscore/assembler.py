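"""Trimer assembly: P321 symmetry expansion, threading, variant building.

The biological allophycocyanin unit is a trimer of αβ heterodimers generated
from the one-heterodimer asymmetric unit by the crystallographic 3-fold of
space group P321.  Minor-subunit variants (APC_1..APC_3) are built by
substituting threaded homolog chains (alphaII, beta18, the PB domain of the
core-membrane linker) into trimer slots, and the small core linker is placed
by template superposition.  Homology modelling is deliberately replaced by
deterministic backbone threading (substituted residues truncated to CB) and
molecular-dynamics relaxation by explicit clash reporting.
"""

from __future__ import annotations

import dataclasses
import string
import warnings

import gemmi
import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from . import config
from .seqkit import PairwiseAlignment, SequenceRecord, GAP
from .structio import (AA1TO3, AA3TO1, Atom, Chain, Residue, StructureModel,
                       StructureError, frac_orth_transforms)

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")


class AssemblyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Symmetry operators

@dataclasses.dataclass
class SymmetryOperator:
    """A crystallographic operator in the fractional frame."""

    rotation: np.ndarray        # 3x3
    translation: np.ndarray     # 3-vector

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymmetryOperator":
        op = gemmi.Op(triplet)
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        return cls(rot, tran)

    def compose(self, other: "SymmetryOperator") -> "SymmetryOperator":
        return SymmetryOperator(self.rotation @ other.rotation,
                                self.rotation @ other.translation
                                + self.translation)

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=tol)
                and np.allclose(self.translation % 1.0, 0.0, atol=tol))


#: The 3-fold rotation subgroup of P321 about the crystallographic c axis.
P321_THREEFOLD: tuple[str, str, str] = ("x,y,z", "-y,x-y,z", "-x+y,-x,z")


def threefold_operators() -> list[SymmetryOperator]:
    return [SymmetryOperator.from_triplet(t) for t in P321_THREEFOLD]


def _check_closure(ops: list[SymmetryOperator]) -> None:
    for a in ops:
        for b in ops:
            c = a.compose(b)
            if not any(np.allclose(c.rotation, o.rotation, atol=1e-6)
                       and np.allclose((c.translation - o.translation) % 1.0,
                                       0.0, atol=1e-6)
                       or np.allclose((c.translation - o.translation) % 1.0,
                                      1.0, atol=1e-6)
                       for o in ops):
                warnings.warn("symmetry operators do not close into a group")
                return


def expand_trimer(asu: StructureModel,
                  operators: list[SymmetryOperator] | None = None,
                  ) -> StructureModel:
    """Apply symmetry operators to every asymmetric-unit chain.

    Each chain is fractionalized, rotated/translated, and orthogonalized
    back.  Copies are relabeled A, B, ... in (operator, chain) order, so a
    two-chain αβ asymmetric unit yields α at A/C/E and β at B/D/F.
    """
    if asu.cell is None:
        raise AssemblyError("symmetry expansion requires a crystal cell")
    ops = operators if operators is not None else threefold_operators()
    _check_closure(ops)
    orth, frac = frac_orth_transforms(asu.cell)
    labels = string.ascii_uppercase
    n_chains = len(asu.chains)
    if len(ops) * n_chains > len(labels):
        raise AssemblyError("too many chains to relabel")
    out = StructureModel(cell=dataclasses.replace(asu.cell))
    for i, op in enumerate(ops):
        for j, chain in enumerate(asu.chains):
            copy = chain.copy()
            copy.id = labels[i * n_chains + j]
            for res in copy.residues:
                for atom in res.atoms:
                    f = frac @ atom.pos
                    atom.pos = orth @ (op.rotation @ f + op.translation)
            out.chains.append(copy)
    out.meta["operators"] = [(op.rotation.tolist(), op.translation.tolist())
                             for op in ops]
    out.meta["source_chains"] = asu.chain_ids
    return out


# ---------------------------------------------------------------------------
# Rigid superposition (Kabsch)

@dataclasses.dataclass
class Transform:
    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def apply_to_chain(self, chain: Chain) -> None:
        for res in chain.residues:
            for atom in res.atoms:
                atom.pos = self.rotation @ atom.pos + self.translation


def superpose(mobile: np.ndarray, target: np.ndarray,
              ) -> tuple[Transform, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns the proper-rotation transform carrying *mobile* onto *target*
    and the residual RMSD.  Requires >= 3 non-collinear points.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2:
        raise AssemblyError("superpose needs equal-shape (n, 3) arrays")
    if len(mobile) < 3:
        raise AssemblyError("superpose needs at least 3 points")
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    m0, t0 = mobile - mc, target - tc
    if (np.linalg.matrix_rank(m0, tol=1e-8) < 2
            or np.linalg.matrix_rank(t0, tol=1e-8) < 2):
        raise AssemblyError("superpose: points are collinear")
    rot, _ = Rotation.align_vectors(t0, m0)
    rmat = rot.as_matrix()
    transform = Transform(rmat, tc - rmat @ mc)
    resid = transform.apply(mobile) - target
    rmsd = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return transform, rmsd


def chain_rmsd(a: Chain, b: Chain, atom_names=("CA",)) -> float:
    """RMSD between same-named atoms of two chains after superposition."""
    pa, pb = _paired_coords(a, b, atom_names)
    _, rmsd = superpose(pa, pb)
    return rmsd


def _paired_coords(a: Chain, b: Chain, atom_names=BACKBONE_ATOMS,
                   ) -> tuple[np.ndarray, np.ndarray]:
    index_b = {(r.seqnum, at.name): at.pos for r in b.residues
               for at in r.atoms if at.name in atom_names}
    pa, pb = [], []
    for r in a.residues:
        for at in r.atoms:
            if at.name in atom_names and (r.seqnum, at.name) in index_b:
                pa.append(at.pos)
                pb.append(index_b[(r.seqnum, at.name)])
    if len(pa) < 3:
        raise AssemblyError(
            f"chains {a.id}/{b.id}: fewer than 3 shared atoms to pair")
    return np.array(pa), np.array(pb)


# ---------------------------------------------------------------------------
# Backbone threading

@dataclasses.dataclass
class ThreadingReport:
    target_id: str
    template_id: str
    n_modeled: int
    n_identical: int
    unmodeled: list[int]        # target positions opposite template gaps
    deleted_template: list[int]  # template seqnums opposite target gaps


def thread_subunit(template_chain: Chain, target_seq: SequenceRecord,
                   aln: PairwiseAlignment) -> tuple[Chain, ThreadingReport]:
    """Thread a homolog sequence onto a template backbone.

    *aln* must align the template chain's ATOM-derived sequence (row a) to
    the target sequence (row b).  Aligned positions keep the template
    backbone (N, CA, C, O, CB); identical residues keep the full side
    chain; substituted residues are truncated to CB (Gly: no CB).  Target
    residues opposite template gaps (e.g. the PB loop) are left unmodeled
    and reported; template residues opposite target gaps are deleted.
    Residues are renumbered 1..len(target).
    """
    tmpl_residues = [r for r in template_chain.residues if r.name in AA3TO1]
    tmpl_seq = "".join(AA3TO1[r.name] for r in tmpl_residues)
    if aln.seq_a != tmpl_seq:
        raise AssemblyError("alignment row a does not match template chain")
    if aln.seq_b != target_seq.residues:
        raise AssemblyError("alignment row b does not match target sequence")
    out = Chain(template_chain.id)
    report = ThreadingReport(target_seq.id, template_chain.id, 0, 0, [], [])
    ti = bi = 0
    for col_a, col_b in zip(aln.row_a, aln.row_b):
        if col_a != GAP and col_b != GAP:
            tmpl_res = tmpl_residues[ti]
            ti += 1
            bi += 1
            identical = AA3TO1[tmpl_res.name] == col_b
            new = Residue(tmpl_res.name if identical else AA1TO3[col_b], bi,
                          source_seqnum=tmpl_res.seqnum)
            for atom in tmpl_res.atoms:
                keep = identical or (atom.name in BACKBONE_ATOMS
                                     and not (col_b == "G"
                                              and atom.name == "CB"))
                if keep:
                    new.atoms.append(atom.copy())
            out.residues.append(new)
            report.n_modeled += 1
            report.n_identical += identical
        elif col_a != GAP:                  # target gap: delete template res
            report.deleted_template.append(tmpl_residues[ti].seqnum)
            ti += 1
        else:                               # template gap: unmodeled target
            bi += 1
            report.unmodeled.append(bi)
    return out, report


# ---------------------------------------------------------------------------
# Trimer variants

@dataclasses.dataclass
class TrimerSpec:
    variant: str
    slots: dict[str, str]

    @classmethod
    def for_variant(cls, variant: str) -> "TrimerSpec":
        if variant not in config.TRIMER_COMPOSITIONS:
            raise AssemblyError(f"unknown trimer variant {variant!r}")
        return cls(variant, dict(config.TRIMER_COMPOSITIONS[variant]))


@dataclasses.dataclass
class TrimerModel:
    structure: StructureModel
    spec: TrimerSpec
    provenance: list[str] = dataclasses.field(default_factory=list)


def build_trimer(base: StructureModel, spec: TrimerSpec,
                 subunit_library: dict[str, Chain] | None = None,
                 ) -> TrimerModel:
    """Build a trimer variant by slot substitution on an APC base.

    *base* is the symmetry-expanded (αβ)3 with chains A–F (alpha at A/C/E,
    beta at B/D/F).  Substituted slots are replaced by the library chain
    after backbone superposition onto the displaced chain; unsubstituted
    chains are untouched.  A linker slot (G) is taken from the library
    as-is — place it first with :func:`place_linker`.
    """
    subunit_library = subunit_library or {}
    base_kinds = {"A": "alpha", "B": "beta", "C": "alpha", "D": "beta",
                  "E": "alpha", "F": "beta"}
    structure = StructureModel(cell=base.cell, meta=dict(base.meta))
    provenance = []
    for label in sorted(spec.slots):
        kind = spec.slots[label]
        if label == "G":
            if kind not in subunit_library:
                raise AssemblyError(f"no library chain for linker {kind!r}")
            linker = subunit_library[kind].copy()
            linker.id = "G"
            structure.chains.append(linker)
            provenance.append(f"G <- {kind} (pre-placed linker)")
            continue
        displaced = base.chain(label)
        if kind == base_kinds[label]:
            structure.chains.append(displaced.copy())
            provenance.append(f"{label}: base {kind}")
            continue
        if kind not in subunit_library:
            raise AssemblyError(f"no library chain for subunit {kind!r}")
        sub = subunit_library[kind].copy()
        # pair backbone atoms via threading provenance (template seqnums)
        index = {(r.seqnum, a.name): a.pos for r in displaced.residues
                 for a in r.atoms if a.name in ("N", "CA", "C")}
        pa, pb = [], []
        for r in sub.residues:
            key_num = r.source_seqnum if r.source_seqnum is not None \
                else r.seqnum
            for a in r.atoms:
                if a.name in ("N", "CA", "C") and (key_num, a.name) in index:
                    pa.append(a.pos)
                    pb.append(index[(key_num, a.name)])
        if len(pa) < 3:
            raise AssemblyError(f"slot {label}: cannot pair library chain "
                                f"{kind!r} with the displaced chain")
        transform, rmsd = superpose(np.array(pa), np.array(pb))
        transform.apply_to_chain(sub)
        sub.id = label
        structure.chains.append(sub)
        provenance.append(f"{label} <- {kind} (backbone rmsd onto "
                          f"displaced {base_kinds[label]}: {rmsd:.3f} A)")
    return TrimerModel(structure, spec, provenance)


def place_linker(trimer: StructureModel, template_complex: StructureModel,
                 linker_chain_id: str) -> tuple[StructureModel, float]:
    """Place a linker into the trimer channel by template superposition.

    The template complex (a homologous trimer plus its linker chain) is
    superposed onto the target trimer using CA atoms of chains paired by
    id, and the resulting transform carries the template linker into the
    target frame, where it is added as chain G.
    """
    pairs_m, pairs_t = [], []
    unmatched = []
    for tch in template_complex.chains:
        if tch.id == linker_chain_id:
            continue
        try:
            target_chain = trimer.chain(tch.id)
        except KeyError:
            unmatched.append(tch.id)
            continue
        try:
            pm, pt = _paired_coords(tch, target_chain, ("CA",))
        except AssemblyError:
            unmatched.append(tch.id)
            continue
        pairs_m.append(pm)
        pairs_t.append(pt)
    if not pairs_m:
        raise AssemblyError(
            f"linker placement: no template chain maps onto the trimer "
            f"(unmatched: {unmatched})")
    transform, rmsd = superpose(np.vstack(pairs_m), np.vstack(pairs_t))
    try:
        linker = template_complex.chain(linker_chain_id).copy()
    except KeyError as exc:
        raise AssemblyError(f"template has no chain "
                            f"{linker_chain_id!r}") from exc
    transform.apply_to_chain(linker)
    linker.id = "G"
    out = StructureModel([c.copy() for c in trimer.chains], trimer.cell,
                         dict(trimer.meta))
    out.chains.append(linker)
    return out, rmsd


# ---------------------------------------------------------------------------
# Clash detection

@dataclasses.dataclass
class ClashReport:
    pairs: list[tuple[tuple, tuple, float]]

    @property
    def count(self) -> int:
        return len(self.pairs)


def _atom_table(model: StructureModel):
    rows = []
    for ch in model.chains:
        for ri, res in enumerate(ch.residues):
            for atom in res.atoms:
                rows.append((ch.id, ri, res.seqnum, res.name, atom))
    return rows


def _excluded(a_row, b_row) -> bool:
    cid_a, ri_a, num_a, name_a, atom_a = a_row
    cid_b, ri_b, num_b, name_b, atom_b = b_row
    if cid_a == cid_b and ri_a == ri_b:
        return True                      # intra-residue (bonded / 1-3)
    if cid_a == cid_b and abs(ri_a - ri_b) == 1:
        # peptide link and its 1-3 neighbours
        backbone = {"N", "CA", "C", "O"}
        if atom_a.name in backbone and atom_b.name in backbone:
            return True
    # disulfides and chromophore thioether
    names = {atom_a.name, atom_b.name}
    if names == {"SG"}:
        return True
    if "SG" in names and ("CYC" in (name_a, name_b)):
        return True
    return False


def count_clashes(model: StructureModel,
                  cutoff_scale: float = config.CLASH_CUTOFF_SCALE,
                  ) -> ClashReport:
    """All non-bonded inter-residue heavy-atom pairs closer than
    cutoff_scale x (r_vdw_i + r_vdw_j)."""
    rows = [r for r in _atom_table(model) if r[4].element != "H"]
    if not rows:
        return ClashReport([])
    xyz = np.array([r[4].pos for r in rows])
    radii = np.array([config.VDW_RADII.get(r[4].element, 1.8) for r in rows])
    max_cut = cutoff_scale * 2 * radii.max()
    tree = cKDTree(xyz)
    pairs = []
    for i, j in tree.query_pairs(max_cut):
        d = float(np.linalg.norm(xyz[i] - xyz[j]))
        if d >= cutoff_scale * (radii[i] + radii[j]):
            continue
        if _excluded(rows[i], rows[j]):
            continue
        ra, rb = rows[i], rows[j]
        pairs.append(((ra[0], ra[2], ra[3], ra[4].name),
                      (rb[0], rb[2], rb[3], rb[4].name), d))
    pairs.sort()
    return ClashReport(pairs)


def relieve_clashes(model: StructureModel,
                    cutoff_scale: float = config.CLASH_CUTOFF_SCALE,
                    max_rounds: int = 20) -> tuple[StructureModel, int]:
    """Greedy side-chain clash relief: iteratively drop the clashing
    side-chain atom farthest from its CB.  Backbone atoms never move."""
    out = model.copy()
    removed = 0
    protected = set(BACKBONE_ATOMS)
    for _ in range(max_rounds):
        report = count_clashes(out, cutoff_scale)
        candidates = []
        for a_ref, b_ref, d in report.pairs:
            for cid, seqnum, resname, atom_name in (a_ref, b_ref):
                if atom_name in protected or resname == "CYC":
                    continue
                res = out.chain(cid).residue(seqnum)
                if res is None:
                    continue
                cb = res.atom("CB")
                atom = res.atom(atom_name)
                if atom is None:
                    continue
                dist_cb = (np.linalg.norm(atom.pos - cb.pos)
                           if cb is not None else 0.0)
                candidates.append((dist_cb, cid, seqnum, atom_name))
        if not candidates:
            break
        _, cid, seqnum, atom_name = max(candidates)
        res = out.chain(cid).residue(seqnum)
        res.atoms = [a for a in res.atoms if a.name != atom_name]
        removed += 1
    return out, removed
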
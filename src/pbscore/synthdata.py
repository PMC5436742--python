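"""Synthetic fixtures with planted, recomputable ground truth.

Each generator emulates the statistical/geometric structure one pipeline
stage assumes — C3-symmetric assemblies, dimers with known buried area or
planted hydrogen bonds/salt bridges, four-ring tetrapyrrole mimics with
controlled methine dihedrals, and sequence pairs with controlled identity —
so every stage is testable without any downloaded data.  All generators take
explicit integer seeds; there is no hidden global randomness.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from . import config
from .seqkit import SequenceRecord, write_fasta
from .structio import (Atom, Chain, CrystalCell, Ligand, Residue,
                       StructureModel, infer_bonds, write_pdb)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FixtureError(ValueError):
    pass


@dataclasses.dataclass
class FixtureBundle:
    """Structures + sequences + a map of planted truth values."""

    structures: dict[str, StructureModel] = dataclasses.field(default_factory=dict)
    sequences: dict[str, list[SequenceRecord]] = dataclasses.field(default_factory=dict)
    truth: dict = dataclasses.field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, model in self.structures.items():
            write_pdb(model, outdir / f"{name}.pdb")
        for name, recs in self.sequences.items():
            write_fasta(recs, outdir / f"{name}.fasta")
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=1))


# ---------------------------------------------------------------------------
# C3-symmetric assemblies

def make_random_chain(n_atoms: int, seed: int, chain_id: str = "A",
                      center: np.ndarray | None = None,
                      spread: float = 5.0) -> Chain:
    """A chain of CA-only pseudo-residues at seeded random positions."""
    rng = np.random.default_rng(seed)
    center = np.zeros(3) if center is None else np.asarray(center, float)
    chain = Chain(chain_id)
    for i in range(n_atoms):
        pos = center + rng.uniform(-spread, spread, 3)
        chain.residues.append(
            Residue("ALA", i + 1, "", [Atom("CA", "C", pos)]))
    return chain


def _rotation_about(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(degrees) * axis).as_matrix()


def make_c3_assembly(seed_chain: Chain, axis=(0.0, 0.0, 1.0),
                     seed: int = 0) -> StructureModel:
    """Three chains related by exact 120/240 degree rotations about *axis*.

    The rotation axis passes through the origin.  Chain ids are A, B, C and
    the applied operators are recorded in ``model.meta["operators"]``.  A
    hexagonal P321 cell is attached when the axis is z, so the assembly can
    also exercise crystallographic symmetry expansion.
    """
    coords = seed_chain.coords()
    if len(coords) < 3:
        raise FixtureError("seed chain needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise FixtureError("seed chain atoms are collinear")
    model = StructureModel()
    ops = []
    for k, cid in enumerate("ABC"):
        rot = _rotation_about(axis, 120.0 * k)
        ops.append(rot)
        ch = seed_chain.copy()
        ch.id = cid
        for res in ch.residues:
            for a in res.atoms:
                a.pos = rot @ a.pos
        model.chains.append(ch)
    model.meta["operators"] = ops
    if np.allclose(np.asarray(axis, float) / np.linalg.norm(axis),
                   [0, 0, 1]):
        extent = float(np.abs(coords).max()) * 4 + 20
        model.cell = CrystalCell(extent, extent, extent, 90, 90, 120,
                                 "P 3 2 1")
    return model


# ---------------------------------------------------------------------------
# SASA fixtures with closed-form truth

def sphere_area(radius: float, probe: float = config.PROBE_RADIUS) -> float:
    return 4.0 * math.pi * (radius + probe) ** 2


def two_sphere_sasa(radius: float, separation: float,
                    probe: float = config.PROBE_RADIUS) -> float:
    """Exposed area of each of two equal spheres (spherical-cap formula)."""
    big_r = radius + probe
    if separation >= 2 * big_r:
        return sphere_area(radius, probe)
    cap_h = big_r - separation / 2.0
    return 4.0 * math.pi * big_r ** 2 - 2.0 * math.pi * big_r * cap_h


def make_sasa_fixture(kind: str, radius: float = 1.4,
                      separation: float = 3.0,
                      probe: float = config.PROBE_RADIUS,
                      ) -> tuple[StructureModel, dict]:
    """Single-atom / two-atom / dimer fixtures with closed-form SASA truth.

    Atoms are oxygen-like so that the pinned radius table (O = 1.40 Å)
    matches the default *radius*; other radii are honoured through the
    ``radii`` override of the SASA routine.
    """
    if radius <= 0 or separation <= 0 or probe < 0:
        raise FixtureError("radius and separation must be positive")

    def one_atom_chain(cid: str, pos) -> Chain:
        return Chain(cid, [Residue("HOH" if False else "UNX", 1, "",
                                   [Atom("O", "O", np.asarray(pos, float),
                                         het=True)])])

    truth: dict = {"radius": radius, "probe": probe}
    model = StructureModel()
    if kind == "single-atom":
        model.chains.append(one_atom_chain("A", (0, 0, 0)))
        truth["sasa"] = sphere_area(radius, probe)
    elif kind in ("two-atom", "contact-dimer", "disjoint-dimer"):
        if kind == "disjoint-dimer":
            separation = max(separation, 2 * (radius + probe) + 1.0)
        if separation < 1e-9:
            raise FixtureError("overlapping identical centers")
        model.chains.append(one_atom_chain("A", (0, 0, 0)))
        model.chains.append(one_atom_chain("B", (separation, 0, 0)))
        per_atom = two_sphere_sasa(radius, separation, probe)
        truth["separation"] = separation
        truth["sasa_per_atom"] = per_atom
        big_r = radius + probe
        cap_h = max(big_r - separation / 2.0, 0.0)
        truth["buried_area"] = 2.0 * math.pi * big_r * cap_h
    else:
        raise FixtureError(f"unknown SASA fixture kind {kind!r}")
    return model, truth


# ---------------------------------------------------------------------------
# Planted hydrogen bonds and salt bridges

def _ser_donor(resnum: int, base: np.ndarray) -> Residue:
    # OG donor at *base*, CB antecedent straight above (angle 180 to an
    # acceptor below) with margin over the 90 degree criterion.
    return Residue("SER", resnum, "", [
        Atom("CB", "C", base + np.array([0.0, 0.0, 1.43])),
        Atom("OG", "O", base.copy()),
    ])


def _gly_acceptor(resnum: int, pos: np.ndarray) -> Residue:
    return Residue("GLY", resnum, "", [
        Atom("C", "C", pos + np.array([0.0, 1.23, 0.0])),
        Atom("O", "O", pos.copy()),
    ])


def make_hbond_dimer(n_hbonds: int, n_bridges: int, seed: int = 0,
                     n_decoys: int = 2) -> tuple[StructureModel, dict]:
    """Two chains with planted donor–acceptor pairs and charged pairs.

    Planted hydrogen bonds (Ser OG -> backbone O) sit at 2.7–3.2 Å with an
    antecedent angle of ~180°; planted salt bridges (Lys NZ — Glu OE1) at
    3.6–3.9 Å, outside the H-bond window so the two truths stay disjoint.
    Decoy polar pairs violate the distance criteria with margin (>= 3.8 Å).
    Units are spaced 10 Å apart so pairs cannot cross-talk.
    """
    if n_hbonds < 0 or n_bridges < 0:
        raise FixtureError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    chain_x, chain_y = Chain("X"), Chain("Y")
    resnum = 0
    x0 = 0.0
    truth_hb, truth_sb = [], []

    for _ in range(n_hbonds):
        resnum += 1
        d = rng.uniform(2.7, 3.2)
        base = np.array([x0, 0.0, 0.0])
        chain_x.residues.append(_ser_donor(resnum, base))
        chain_y.residues.append(_gly_acceptor(resnum,
                                              base + np.array([0, 0, -d])))
        truth_hb.append({"donor_res": resnum, "acceptor_res": resnum,
                         "distance": d})
        x0 += 10.0

    for _ in range(n_bridges):
        resnum += 1
        d = rng.uniform(3.6, 3.9)
        base = np.array([x0, 0.0, 0.0])
        chain_x.residues.append(Residue("LYS", resnum, "", [
            Atom("CE", "C", base + np.array([0.0, 0.0, 1.48])),
            Atom("NZ", "N", base.copy()),
        ]))
        chain_y.residues.append(Residue("GLU", resnum, "", [
            Atom("CD", "C", base + np.array([0.0, 1.25, -d])),
            Atom("OE1", "O", base + np.array([0.0, 0.0, -d])),
        ]))
        truth_sb.append({"basic_res": resnum, "acidic_res": resnum,
                         "distance": d})
        x0 += 10.0

    for _ in range(n_decoys):
        resnum += 1
        d = rng.uniform(4.3, 5.0)   # fails both criteria with margin
        base = np.array([x0, 0.0, 0.0])
        chain_x.residues.append(_ser_donor(resnum, base))
        chain_y.residues.append(_gly_acceptor(resnum,
                                              base + np.array([0, 0, -d])))
        x0 += 10.0

    model = StructureModel([chain_x, chain_y])
    truth = {"n_hbonds": n_hbonds, "n_bridges": n_bridges,
             "hbonds": truth_hb, "salt_bridges": truth_sb}
    return model, truth


def make_polar_pair(distance: float) -> StructureModel:
    """One Ser OG -> backbone O pair at exactly *distance* (boundary probe)."""
    cx = Chain("X", [_ser_donor(1, np.zeros(3))])
    cy = Chain("Y", [_gly_acceptor(1, np.array([0.0, 0.0, -distance]))])
    return StructureModel([cx, cy])


# ---------------------------------------------------------------------------
# Parametric bilin (open-chain tetrapyrrole) mimic

RING_ATOMS = {r: [f"C1{r}", f"C2{r}", f"C3{r}", f"C4{r}", f"N{r}"]
              for r in "ABCD"}
BRIDGE_NAMES = {"AB": "CHB", "BC": "CHC", "CD": "CHD"}
_BOND = 1.4
_RING_ANGLE = 108.0
_EXO_ANGLE = 126.0


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF internal-coordinate placement of atom d bonded to c."""
    ang, tor = np.deg2rad(angle), np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([-math.cos(ang),
                          math.cos(tor) * math.sin(ang),
                          math.sin(tor) * math.sin(ang)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def make_bilin_fixture(bridge_config, seed: int = 0,
                       ) -> tuple[Ligand, dict]:
    """Four planar five-membered rings joined by methine bridges.

    *bridge_config* is three (zn, sa) pairs for bridges A–B, B–C, C–D with
    zn in {"Z", "E"} and sa in {"syn", "anti"}.  Double-bond dihedrals are
    placed near 0° (Z) or 180° (E); single-bond dihedrals near ±30° (syn)
    or ±150° (anti), signs and small jitter drawn from *seed*.  The mimic
    carries standard phycocyanobilin-style atom names (N A–D, C1–C4, CHB/
    CHC/CHD bridge carbons, CAA thioether carbon on ring A) and is returned
    under a seeded random rigid motion.
    """
    bridge_config = list(bridge_config)
    if len(bridge_config) != 3:
        raise FixtureError("need exactly three bridge configurations")
    for zn, sa in bridge_config:
        if zn not in ("Z", "E") or sa not in ("syn", "anti"):
            raise FixtureError(f"bad bridge configuration ({zn}, {sa})")
    rng = np.random.default_rng(seed)

    pos: dict[str, np.ndarray] = {}
    # Ring A: regular pentagon in the xy plane, order C1A C2A C3A C4A NA.
    r_penta = _BOND / (2.0 * math.sin(math.pi / 5.0))
    for k, name in enumerate(RING_ATOMS["A"]):
        th = 2.0 * math.pi * k / 5.0
        pos[name] = np.array([r_penta * math.cos(th),
                              r_penta * math.sin(th), 0.0])
    # Thioether carbon on C3A, in plane, pointing outward.
    pos["CAA"] = _place_atom(pos["C1A"], pos["C2A"], pos["C3A"],
                             _BOND, _EXO_ANGLE, 180.0)

    dihedrals = {}
    prev = "A"
    for (zn, sa), nxt in zip(bridge_config, "BCD"):
        bridge = BRIDGE_NAMES[prev + nxt]
        jit = rng.uniform(-5.0, 5.0, 2)
        sign = rng.choice([-1.0, 1.0], 2)
        tau_double = (0.0 if zn == "Z" else 180.0) + jit[0]
        tau_single = sign[1] * ((30.0 if sa == "syn" else 150.0) + jit[1])
        c2, c3, c4 = (pos[f"C2{prev}"], pos[f"C3{prev}"], pos[f"C4{prev}"])
        pos[bridge] = _place_atom(c2, c3, c4, _BOND, _EXO_ANGLE, 180.0)
        # Double-bond torsion: C3(prev)-C4(prev)-CH-C1(next)
        pos[f"C1{nxt}"] = _place_atom(c3, c4, pos[bridge],
                                      _BOND, _EXO_ANGLE, tau_double)
        # Single-bond torsion: C4(prev)-CH-C1(next)-N(next)
        pos[f"N{nxt}"] = _place_atom(c4, pos[bridge], pos[f"C1{nxt}"],
                                     _BOND, _EXO_ANGLE, tau_single)
        # Complete the planar pentagon of the next ring.
        pos[f"C4{nxt}"] = _place_atom(pos[bridge], pos[f"C1{nxt}"],
                                      pos[f"N{nxt}"], _BOND, _RING_ANGLE,
                                      180.0)
        pos[f"C3{nxt}"] = _place_atom(pos[f"C1{nxt}"], pos[f"N{nxt}"],
                                      pos[f"C4{nxt}"], _BOND, _RING_ANGLE,
                                      0.0)
        pos[f"C2{nxt}"] = _place_atom(pos[f"N{nxt}"], pos[f"C4{nxt}"],
                                      pos[f"C3{nxt}"], _BOND, _RING_ANGLE,
                                      0.0)
        dihedrals[prev + nxt] = (tau_double, tau_single)
        prev = nxt

    # Seeded rigid motion so fixtures never sit in a special frame.
    rot = Rotation.random(random_state=np.random.RandomState(seed)).as_matrix()
    shift = rng.uniform(-20, 20, 3)
    atoms = [Atom(name, "N" if name.startswith("N") else "C",
                  rot @ p + shift, het=True)
             for name, p in pos.items()]
    lig = Ligand("L", "CYC", 1, atoms, set())
    lig.bonds = infer_bonds(lig.atoms)

    class_string = ("".join(zn for zn, _ in bridge_config)
                    + "".join(sa[0] for _, sa in bridge_config))
    truth = {"classes": [(zn, sa) for zn, sa in bridge_config],
             "class_string": class_string,
             "syn_anti": "".join(sa[0] for _, sa in bridge_config).upper(),
             "dihedrals": dihedrals}
    return lig, truth


def bilin_to_model(lig: Ligand) -> StructureModel:
    """Wrap a bilin ligand as a one-residue het chain."""
    res = Residue(lig.resname, lig.seqnum, "",
                  [a.copy() for a in lig.atoms])
    return StructureModel([Chain(lig.chain_id, [res])])


# ---------------------------------------------------------------------------
# Sequence pairs with controlled identity and one insertion block

def _conservative_choices() -> dict[str, list[str]]:
    """Non-identical substitutions with the highest BLOSUM62 similarity.

    Mutating to similar residues mimics real homolog divergence and keeps
    the planted alignment optimal under realignment, so the planted
    identity is recoverable.
    """
    from Bio.Align import substitution_matrices
    mat = substitution_matrices.load("BLOSUM62")
    table: dict[str, list[str]] = {}
    for a in AMINO_ACIDS:
        scored = sorted(((mat[a, b], b) for b in AMINO_ACIDS if b != a),
                        reverse=True)
        best = scored[0][0]
        table[a] = [b for s, b in scored if s >= min(best, 1)]
    return table


_CONSERVATIVE: dict[str, list[str]] | None = None


def make_homolog(seq: str, target_identity: float, insertion_len: int = 0,
                 seed: int = 0, rec_id: str = "synth_homolog",
                 ) -> tuple[SequenceRecord, dict]:
    """Derive a homolog with planted identity and one insertion block.

    The homolog copies *seq* with ``round((1-p)*len)`` conservative
    substitutions at distinct positions, then one contiguous insertion of
    *insertion_len* random residues at an interior position.
    """
    global _CONSERVATIVE
    if not 0 <= target_identity <= 1:
        raise FixtureError("target_identity must be in [0, 1]")
    length = len(seq)
    if insertion_len < 0 or length < 10:
        raise FixtureError("need insertion_len >= 0 and length >= 10")
    if _CONSERVATIVE is None:
        _CONSERVATIVE = _conservative_choices()
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    seq_b = np.array(list(seq))
    n_mut = round((1.0 - target_identity) * length)
    sites = rng.choice(length, size=n_mut, replace=False)
    for i in sites:
        choices = _CONSERVATIVE[seq[i]]
        seq_b[i] = choices[rng.integers(len(choices))]
    b_list = list(seq_b)
    ins_pos = None
    if insertion_len:
        ins_pos = int(rng.integers(5, length - 5))
        block = rng.choice(aa, size=insertion_len)
        b_list[ins_pos:ins_pos] = list(block)
    # the planted (construction) alignment: one gap block in row a
    row_a = seq[:ins_pos] + "-" * insertion_len + seq[ins_pos:] \
        if insertion_len else seq
    truth = {"identity": (length - n_mut) / length,
             "n_substitutions": int(n_mut),
             "insertion_len": insertion_len, "insertion_pos": ins_pos,
             "row_a": row_a, "row_b": "".join(b_list)}
    return SequenceRecord(rec_id, "protein", "".join(b_list)), truth


def make_sequence_pair(length: int, target_identity: float,
                       insertion_len: int = 0, seed: int = 0,
                       ) -> tuple[SequenceRecord, SequenceRecord, dict]:
    """A random protein pair with planted identity and one insertion.

    By construction the pre-realignment identity equals the target within
    1/length; *truth* records the exact planted values.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    seq_a = "".join(rng.choice(aa, size=length))
    rec_b, truth = make_homolog(seq_a, target_identity, insertion_len,
                                seed + 1, rec_id=f"synth_b_{seed}")
    rec_a = SequenceRecord(f"synth_a_{seed}", "protein", seq_a)
    return rec_a, rec_b, truth


# ---------------------------------------------------------------------------
# A heterodimer-like asymmetric unit for end-to-end runs

_BACKBONE_OFFSETS = {
    "N": np.array([-1.20, 0.60, 0.00]),
    "CA": np.zeros(3),
    "C": np.array([1.25, 0.60, 0.00]),
    "O": np.array([1.35, 1.83, 0.00]),
    "CB": np.array([-0.20, -1.00, 1.05]),
}


def _curve_chain(cid: str, sequence: str, start_num: int,
                 center: np.ndarray, seed: int) -> Chain:
    """A compact helical pseudo-backbone (N, CA, C, O, CB per residue)."""
    rng = np.random.default_rng(seed)
    from .structio import AA1TO3
    chain = Chain(cid)
    n = len(sequence)
    for i, letter in enumerate(sequence):
        th = 2.0 * math.pi * i / 10.0
        ca = center + np.array([4.5 * math.cos(th), 4.5 * math.sin(th),
                                1.5 * (i - n / 2) / 1.0 * 0.45])
        res = Residue(AA1TO3[letter], start_num + i, "")
        for name, off in _BACKBONE_OFFSETS.items():
            if name == "CB" and letter == "G":
                continue
            res.atoms.append(Atom(name, name[0],
                                  ca + off + rng.normal(0, 0.02, 3)))
        chain.residues.append(res)
    return chain


def make_asu_fixture(seed: int = 0, n_res: int = 30,
                     ) -> tuple[StructureModel, dict]:
    """A two-chain heterodimer-like asymmetric unit with bilin chromophores.

    Chains A (alpha-like) and B (beta-like) are compact pseudo-helices
    offset from the crystallographic z axis so that C3 expansion produces a
    ring of three touching heterodimers.  Each chain carries a Cys at
    residue 81 whose SG sits 1.8 Å from the CAA thioether carbon of an
    attached ZZZ-asa bilin.  A hexagonal P321 cell is included.
    """
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS.replace("C", "")))
    seqs = {}
    for cid in "AB":
        letters = list(rng.choice(aa, size=n_res))
        letters[11] = "C"            # residue 81 of numbering 70..
        seqs[cid] = "".join(letters)
    center_a = np.array([13.0, 0.0, 6.0])
    center_b = np.array([13.0, 3.0, -6.0])
    chain_a = _curve_chain("A", seqs["A"], 70, center_a, seed + 1)
    chain_b = _curve_chain("B", seqs["B"], 70, center_b, seed + 2)

    model = StructureModel([chain_a, chain_b])
    config_bilin = [("Z", "anti"), ("Z", "syn"), ("Z", "anti")]
    for cid, chain in (("A", chain_a), ("B", chain_b)):
        cys = chain.residue(81)
        cb = cys.atom("CB").pos
        sg = cb + np.array([0.0, -1.1, 1.4])
        cys.atoms.append(Atom("SG", "S", sg))
        lig, _ = make_bilin_fixture(config_bilin, seed=seed + ord(cid))
        anchor = next(a for a in lig.atoms if a.name == "CAA")
        shift = (sg + np.array([0.0, -1.2, 1.3])) - anchor.pos
        res = Residue("CYC", 201, "")
        for a in lig.atoms:
            res.atoms.append(Atom(a.name, a.element, a.pos + shift, het=True))
        chain.residues.append(res)

    extent = 60.0
    model.cell = CrystalCell(extent, extent, 40.0, 90, 90, 120, "P 3 2 1")
    truth = {"sequences": seqs, "cys_position": 81,
             "bilin_class": "ZZZasa", "first_resnum": 70}
    return model, truth
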
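"""Phycocyanobilin geometry: rings, bridge dihedrals, binding sites.

The open-chain tetrapyrrole chromophore of allophycocyanin has four
five-membered, nitrogen-containing rings (A–D) joined by methine bridges.
The syn/anti pattern of the three single-bond bridge dihedrals — ASA in the
α/β subunits versus SSA in the PB domain of the core-membrane linker — is
the geometric determinant of the spectral tuning of the terminal emitter,
and is corroborated by the ring A–D centroid distance.  Torsion-atom
convention per bridge X→Y: double bond (C3X, C4X, CHm, C1Y), single bond
(C4X, CHm, C1Y, NY); a bridge is Z / syn when the respective |dihedral| is
<= 90° (inclusive), E / anti otherwise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import config
from .seqkit import PairwiseAlignment, map_aligned_position
from .structio import AA3TO1, Ligand, StructureModel


class BilinError(ValueError):
    pass


@dataclasses.dataclass
class ChromophoreGeometry:
    ligand: Ligand
    rings: dict[str, list[str]]                # label -> atom names
    bridge_dihedrals: list[tuple[float, float]]  # (double, single) per bridge
    conformation: str                          # e.g. "ZZZasa"
    ring_AD_distance: float

    @property
    def syn_anti(self) -> str:
        """Three-letter syn/anti summary, e.g. 'ASA' or 'SSA'."""
        return self.conformation[3:].upper()


@dataclasses.dataclass
class BindingSite:
    ligand: Ligand
    residues: list[tuple[str, int, str, float]]  # chain, resnum, name, dmin
    covalent_cys: tuple[str, int] | None


# ---------------------------------------------------------------------------
# Ring identification

def _ring_sets_by_name(ligand: Ligand) -> dict[str, list[int]] | None:
    """Standard phycocyanobilin naming: ring X = C1X..C4X + NX."""
    out = {}
    for label in "ABCD":
        names = [f"C1{label}", f"C2{label}", f"C3{label}", f"C4{label}",
                 f"N{label}"]
        idx = [ligand.atom_index(n) for n in names]
        if any(i is None for i in idx):
            return None
        out[label] = idx
    return out


def _adjacency(ligand: Ligand) -> dict[int, set[int]]:
    adj: dict[int, set[int]] = {i: set() for i in range(len(ligand.atoms))}
    for i, j in ligand.bonds:
        adj[i].add(j)
        adj[j].add(i)
    return adj


def _five_cycles(adj: dict[int, set[int]]) -> list[list[int]]:
    """All simple 5-cycles (as ordered vertex lists), deduplicated."""
    cycles = set()
    out = []
    for start in adj:
        stack = [(start, [start])]
        while stack:
            node, path = stack.pop()
            for nxt in adj[node]:
                if nxt == start and len(path) == 5:
                    key = frozenset(path)
                    if key not in cycles:
                        cycles.add(key)
                        out.append(path)
                elif nxt not in path and len(path) < 5:
                    stack.append((nxt, path + [nxt]))
    return out


def _rings_by_connectivity(ligand: Ligand) -> dict[str, list[int]]:
    adj = _adjacency(ligand)
    elements = [a.element for a in ligand.atoms]
    rings = [c for c in _five_cycles(adj)
             if any(elements[i] == "N" for i in c)]
    if len(rings) != 4:
        raise BilinError(f"expected 4 five-membered N-containing rings, "
                         f"found {len(rings)}")
    ring_of = {}
    for k, ring in enumerate(rings):
        for i in ring:
            ring_of[i] = k
    # ring adjacency through a single bridge atom
    neighbors: dict[int, set[int]] = {k: set() for k in range(4)}
    for i, a_ring in ring_of.items():
        for j in adj[i]:
            if j in ring_of:
                continue
            for k in adj[j]:
                if k in ring_of and ring_of[k] != a_ring:
                    neighbors[a_ring].add(ring_of[k])
                    neighbors[ring_of[k]].add(a_ring)
    terminals = [k for k, nb in neighbors.items() if len(nb) == 1]
    if len(terminals) != 2:
        raise BilinError("bilin rings do not form a simple chain")

    def exocyclic_carbons(k: int) -> int:
        ring = set(rings[k])
        return sum(1 for i in ring for j in adj[i]
                   if j not in ring_of and elements[j] == "C"
                   and not any(r in ring_of and ring_of[r] != k
                               for r in adj[j]))

    # Ring A anchors the thioether: the terminal ring carrying an exocyclic
    # (non-bridge) carbon; tie broken toward the lower ring index.
    start = max(terminals, key=lambda k: (exocyclic_carbons(k), -k))
    order = [start]
    while len(order) < 4:
        nxt = [k for k in neighbors[order[-1]] if k not in order]
        order.append(nxt[0])
    return {label: rings[k] for label, k in zip("ABCD", order)}


def identify_rings(ligand: Ligand) -> dict[str, list[int]]:
    """Locate the four pyrrole-like rings, labeled A–D along the chain.

    Standard phycocyanobilin atom names are used when present; otherwise
    rings are found by cycle detection and ordered by connectivity from the
    thioether-bearing terminal ring.
    """
    if not ligand.bonds:
        raise BilinError("ligand has no bonds (CONECT absent and none "
                         "inferred)")
    named = _ring_sets_by_name(ligand)
    if named is not None:
        return named
    return _rings_by_connectivity(ligand)


# ---------------------------------------------------------------------------
# Torsions and classification

def torsion(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
            p4: np.ndarray) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in degrees, in (-180, 180]."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(b2 / np.linalg.norm(b2), n1)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


def _bridge_atoms(ligand: Ligand, rings: dict[str, list[int]],
                  ring_x: str, ring_y: str) -> tuple[int, int, int, int, int]:
    """Resolve (C3X, C4X, CHm, C1Y, NY) indices for one bridge."""
    adj = _adjacency(ligand)
    set_x, set_y = set(rings[ring_x]), set(rings[ring_y])
    elements = [a.element for a in ligand.atoms]
    for m in adj:
        if m in set_x or m in set_y:
            continue
        nx = [i for i in adj[m] if i in set_x]
        ny = [i for i in adj[m] if i in set_y]
        if nx and ny:
            c4 = nx[0]
            c1 = ny[0]
            c3_opts = [i for i in adj[c4]
                       if i in set_x and elements[i] == "C"]
            n_opts = [i for i in adj[c1]
                      if i in set_y and elements[i] == "N"]
            if not c3_opts or not n_opts:
                raise BilinError(
                    f"bridge {ring_x}-{ring_y}: missing reference atom")
            return c3_opts[0], c4, m, c1, n_opts[0]
    raise BilinError(f"no methine bridge between rings {ring_x} and "
                     f"{ring_y}")


def classify_conformation(ligand: Ligand,
                          rings: dict[str, list[int]] | None = None,
                          boundary: float = config.DIHEDRAL_CLASS_BOUNDARY,
                          ) -> ChromophoreGeometry:
    """Classify the three methine bridges and measure the A–D distance.

    Per bridge: Z when |double-bond dihedral| <= boundary else E; syn when
    |single-bond dihedral| <= boundary else anti.  The class string is the
    three Z/E letters followed by the three s/a letters ('ZZZasa' is the
    canonical α-subunit conformation, 'ZZZssa' the PB-domain one).
    """
    if rings is None:
        rings = identify_rings(ligand)
    xyz = ligand.coords()
    dihedrals: list[tuple[float, float]] = []
    letters_ze, letters_sa = [], []
    for rx, ry in (("A", "B"), ("B", "C"), ("C", "D")):
        c3, c4, m, c1, n = _bridge_atoms(ligand, rings, rx, ry)
        tau_d = torsion(xyz[c3], xyz[c4], xyz[m], xyz[c1])
        tau_s = torsion(xyz[c4], xyz[m], xyz[c1], xyz[n])
        dihedrals.append((tau_d, tau_s))
        letters_ze.append("Z" if abs(tau_d) <= boundary else "E")
        letters_sa.append("s" if abs(tau_s) <= boundary else "a")
    centroid = {lab: xyz[rings[lab]].mean(axis=0) for lab in ("A", "D")}
    dist_ad = float(np.linalg.norm(centroid["A"] - centroid["D"]))
    names = {lab: [ligand.atoms[i].name for i in idx]
             for lab, idx in rings.items()}
    return ChromophoreGeometry(ligand, names, dihedrals,
                               "".join(letters_ze) + "".join(letters_sa),
                               dist_ad)


# ---------------------------------------------------------------------------
# Binding sites

def binding_site(model: StructureModel, ligand: Ligand,
                 cutoff: float = config.BINDING_SITE_CUTOFF,
                 covalent_cutoff: float = config.COVALENT_CYS_CUTOFF,
                 ) -> BindingSite:
    """Protein residues with any heavy atom within *cutoff* of the ligand.

    The covalent cysteine is any Cys whose SG lies within the thioether
    cutoff of a ligand carbon.
    """
    lig_xyz = ligand.coords()
    lig_carbon = np.array([a.element == "C" for a in ligand.atoms])
    residues = []
    covalent = None
    cov_d = np.inf
    for ch in model.chains:
        for res in ch.residues:
            if res.name not in AA3TO1:
                continue
            heavy = [a for a in res.atoms if a.element != "H"]
            if not heavy:
                continue
            d = np.linalg.norm(
                np.array([a.pos for a in heavy])[:, None, :]
                - lig_xyz[None, :, :], axis=2)
            dmin = float(d.min())
            if dmin <= cutoff:
                residues.append((ch.id, res.seqnum, res.name, dmin))
            if res.name == "CYS":
                sg = res.atom("SG")
                if sg is not None and lig_carbon.any():
                    d_sg = float(np.linalg.norm(
                        lig_xyz[lig_carbon] - sg.pos, axis=1).min())
                    if d_sg <= covalent_cutoff and d_sg < cov_d:
                        covalent = (ch.id, res.seqnum)
                        cov_d = d_sg
    residues.sort(key=lambda r: (r[0], r[1]))
    return BindingSite(ligand, residues, covalent)


def compare_sites(site_a: BindingSite, site_b: BindingSite,
                  aln: PairwiseAlignment, first_resnum_a: int = 1,
                  first_resnum_b: int = 1) -> pd.DataFrame:
    """Residue-by-residue conservation table between two binding sites.

    *aln* aligns the chain-a sequence to the chain-b sequence;
    ``first_resnum_*`` anchor the chains' residue numbering to sequence
    position 1.  Unaligned residues are reported as unmapped.
    """
    b_index = {num: name for _, num, name, _ in site_b.residues}
    rows = []
    for cid, num, name, dmin in site_a.residues:
        pos_a = num - first_resnum_a + 1
        try:
            mapped = map_aligned_position(aln, pos_a)
        except Exception:
            rows.append({"resnum_a": num, "resname_a": name,
                         "resnum_b": None, "residue_b": None,
                         "same_type": False, "both_in_site": False,
                         "mapped": False})
            continue
        if mapped.pos_b is None:
            rows.append({"resnum_a": num, "resname_a": name,
                         "resnum_b": None, "residue_b": None,
                         "same_type": False, "both_in_site": False,
                         "mapped": False})
            continue
        num_b = mapped.pos_b + first_resnum_b - 1
        rows.append({"resnum_a": num, "resname_a": name,
                     "resnum_b": num_b, "residue_b": mapped.residue_b,
                     "same_type": AA3TO1.get(name) == mapped.residue_b,
                     "both_in_site": num_b in b_index,
                     "mapped": True})
    return pd.DataFrame(rows, columns=["resnum_a", "resname_a", "resnum_b",
                                       "residue_b", "same_type",
                                       "both_in_site", "mapped"])
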
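"""Protein–protein interface characterization of trimer models.

Buried solvent-accessible surface area (Shrake–Rupley with a deterministic
golden-spiral point set), heavy-atom hydrogen bonds and salt bridges, and a
per-chain-pair comparative report for the four allophycocyanin trimer
variants.  All criteria are hydrogen-free: the underlying crystal structure
(2.3 Å) carries no hydrogens, so donors/acceptors are judged on heavy-atom
distance plus the antecedent–donor–acceptor angle.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import config
from .structio import Atom, StructureModel, StructureError, AA3TO1

# ---------------------------------------------------------------------------
# Donor / acceptor / charged-group chemistry (heavy-atom tables)

BACKBONE_DONOR = ("N", "CA")          # donor, antecedent
BACKBONE_ACCEPTOR = ("O", "OXT")

SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "SER": {"OG": "CB"}, "THR": {"OG1": "CB"}, "TYR": {"OH": "CZ"},
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "ASN": {"ND2": "CG"}, "GLN": {"NE2": "CD"},
    "TRP": {"NE1": "CD1"}, "CYS": {"SG": "CB"},
    "MEN": {"ND2": "CG"},             # N4-methyl-Asn, ASN variant
}
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",), "GLN": ("OE1",),
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"), "MEN": ("OD1",),
}
BASIC_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"), "HIS": ("ND1", "NE2"),
}
ACIDIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"),
}


@dataclasses.dataclass
class SasaResult:
    per_atom: np.ndarray
    atom_refs: list[tuple[str, int, str, str]]   # chain, resnum, resname, atom
    params: dict

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())

    def per_chain(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (cid, *_), v in zip(self.atom_refs, self.per_atom):
            out[cid] = out.get(cid, 0.0) + float(v)
        return out

    def per_residue(self) -> dict[tuple[str, int], float]:
        out: dict[tuple[str, int], float] = {}
        for (cid, num, *_), v in zip(self.atom_refs, self.per_atom):
            out[(cid, num)] = out.get((cid, num), 0.0) + float(v)
        return out


@dataclasses.dataclass
class HBond:
    donor: tuple[str, int, str, str]
    acceptor: tuple[str, int, str, str]
    distance: float


@dataclasses.dataclass
class SaltBridge:
    basic: tuple[str, int, str, str]
    acidic: tuple[str, int, str, str]
    distance: float


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def _select_atoms(model: StructureModel, chains: Iterable[str] | None,
                  include_waters: bool, include_ligands: bool,
                  ) -> tuple[list[tuple[str, int, str, str]], np.ndarray,
                             list[Atom]]:
    wanted = None if chains is None else set(chains)
    refs, atoms = [], []
    for ch in model.chains:
        if wanted is not None and ch.id not in wanted:
            continue
        for res in ch.residues:
            if res.is_water and not include_waters:
                continue
            if res.name not in AA3TO1 and not res.is_water \
                    and not include_ligands:
                continue
            for a in res.atoms:
                if a.element == "H":
                    continue
                refs.append((ch.id, res.seqnum, res.name, a.name))
                atoms.append(a)
    xyz = (np.array([a.pos for a in atoms])
           if atoms else np.empty((0, 3)))
    return refs, xyz, atoms


def shrake_rupley(model: StructureModel,
                  chains: Iterable[str] | None = None,
                  probe: float = config.PROBE_RADIUS,
                  n_points: int = config.SASA_N_POINTS,
                  radii: dict[str, float] | None = None,
                  include_waters: bool = False,
                  include_ligands: bool = True) -> SasaResult:
    """Per-atom solvent-accessible surface area by sphere-point sampling.

    Occlusion is computed against all atoms of the selected subset only.
    The point set is a fixed golden spiral, so results are deterministic
    for a given ``n_points``.
    """
    radii_table = dict(config.VDW_RADII)
    if radii:
        radii_table.update(radii)
    refs, xyz, atoms = _select_atoms(model, chains, include_waters,
                                     include_ligands)
    params = {"probe": probe, "n_points": n_points,
              "radii_set": "chothia+overrides" if radii else "chothia"}
    if not atoms:
        return SasaResult(np.zeros(0), [], params)
    try:
        rads = np.array([radii_table[a.element] for a in atoms])
    except KeyError as exc:
        raise StructureError(f"no vdW radius for element {exc}") from exc
    big_r = rads + probe
    sphere = _golden_spiral(n_points)
    tree = cKDTree(xyz)
    areas = np.zeros(len(atoms))
    max_r = big_r.max()
    for i in range(len(atoms)):
        neighbors = [j for j in tree.query_ball_point(xyz[i],
                                                      big_r[i] + max_r)
                     if j != i]
        pts = xyz[i] + big_r[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d = np.linalg.norm(xyz[j] - xyz[i])
            if d >= big_r[i] + big_r[j]:
                continue
            accessible &= (np.linalg.norm(pts - xyz[j], axis=1)
                           >= big_r[j])
            if not accessible.any():
                break
        frac = accessible.sum() / n_points
        areas[i] = frac * 4.0 * np.pi * big_r[i] ** 2
    return SasaResult(areas, refs, params)


def buried_area(model: StructureModel, chain_set_1: Sequence[str],
                chain_set_2: Sequence[str], **sasa_kwargs) -> float:
    """Half the SASA lost on association of two disjoint chain sets."""
    s1, s2 = set(chain_set_1), set(chain_set_2)
    if s1 & s2:
        raise StructureError(f"overlapping chain sets {sorted(s1 & s2)}")
    a1 = shrake_rupley(model, chains=s1, **sasa_kwargs).total
    a2 = shrake_rupley(model, chains=s2, **sasa_kwargs).total
    a12 = shrake_rupley(model, chains=s1 | s2, **sasa_kwargs).total
    return (a1 + a2 - a12) / 2.0


# ---------------------------------------------------------------------------
# Hydrogen bonds / salt bridges

def _polar_inventory(model: StructureModel, chains: set[str],
                     include_waters: bool = False):
    """Collect (ref, pos, antecedent_pos|None) donors and (ref, pos)
    acceptors for the selected chains."""
    donors, acceptors = [], []
    for ch in model.chains:
        if ch.id not in chains:
            continue
        for res in ch.residues:
            if res.is_water and not include_waters:
                continue
            is_protein = res.name in AA3TO1
            if is_protein:
                table = SIDECHAIN_DONORS.get(res.name, {})
                d_atoms = dict(table)
                if res.name != "PRO":
                    d_atoms[BACKBONE_DONOR[0]] = BACKBONE_DONOR[1]
                a_names = set(BACKBONE_ACCEPTOR) | set(
                    SIDECHAIN_ACCEPTORS.get(res.name, ()))
                for a in res.atoms:
                    ref = (ch.id, res.seqnum, res.name, a.name)
                    if a.name in d_atoms:
                        ante = res.atom(d_atoms[a.name])
                        donors.append((ref, a.pos,
                                       ante.pos if ante else None))
                    if a.name in a_names:
                        acceptors.append((ref, a.pos))
            else:
                # chromophores / het groups: every N or O is polar, the
                # antecedent is the nearest bonded heavy atom.
                heavy = [a for a in res.atoms if a.element != "H"]
                for a in heavy:
                    if a.element not in ("N", "O"):
                        continue
                    ref = (ch.id, res.seqnum, res.name, a.name)
                    others = [b for b in heavy if b is not a]
                    ante = (min(others,
                                key=lambda b: np.linalg.norm(b.pos - a.pos))
                            if others else None)
                    donors.append((ref, a.pos,
                                   ante.pos if ante is not None else None))
                    acceptors.append((ref, a.pos))
    return donors, acceptors


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def find_hbonds(model: StructureModel, chain_set_1: Sequence[str],
                chain_set_2: Sequence[str],
                max_dist: float = config.HBOND_DIST,
                min_angle: float = config.HBOND_MIN_ANGLE,
                include_waters: bool = False) -> list[HBond]:
    """Heavy-atom hydrogen bonds across two disjoint chain sets.

    Criterion: donor–acceptor distance <= *max_dist* (inclusive) and
    antecedent–donor–acceptor angle >= *min_angle*; a donor without a
    resolvable antecedent passes the angle test by default.
    """
    s1, s2 = set(chain_set_1), set(chain_set_2)
    if s1 & s2:
        raise StructureError(f"overlapping chain sets {sorted(s1 & s2)}")
    out = []
    for da_set, ac_set in ((s1, s2), (s2, s1)):
        donors, _ = _polar_inventory(model, da_set, include_waters)
        _, acceptors = _polar_inventory(model, ac_set, include_waters)
        for dref, dpos, ante in donors:
            for aref, apos in acceptors:
                d = float(np.linalg.norm(dpos - apos))
                if d > max_dist:
                    continue
                if ante is not None and _angle(ante, dpos, apos) < min_angle:
                    continue
                out.append(HBond(dref, aref, d))
    out.sort(key=lambda h: (h.donor, h.acceptor))
    return out


def find_salt_bridges(model: StructureModel, chain_set_1: Sequence[str],
                      chain_set_2: Sequence[str],
                      max_dist: float = config.SALTBRIDGE_DIST,
                      ) -> list[SaltBridge]:
    """Basic–acidic contacts across two disjoint chain sets.

    One bridge per residue pair, at the minimum-distance atom pair;
    distance <= *max_dist* inclusive.  The C-terminal carboxylate (OXT)
    counts as acidic.
    """
    s1, s2 = set(chain_set_1), set(chain_set_2)
    if s1 & s2:
        raise StructureError(f"overlapping chain sets {sorted(s1 & s2)}")

    def groups(chains, table, extra_oxt):
        rows = []
        for ch in model.chains:
            if ch.id not in chains:
                continue
            for res in ch.residues:
                names = set(table.get(res.name, ()))
                if extra_oxt and res.name in AA3TO1:
                    names.add("OXT")
                for a in res.atoms:
                    if a.name in names:
                        rows.append(((ch.id, res.seqnum, res.name, a.name),
                                     a.pos))
        return rows

    best: dict[tuple, SaltBridge] = {}
    for basic_set, acidic_set in ((s1, s2), (s2, s1)):
        basics = groups(basic_set, BASIC_ATOMS, extra_oxt=False)
        acidics = groups(acidic_set, ACIDIC_ATOMS, extra_oxt=True)
        for bref, bpos in basics:
            for aref, apos in acidics:
                d = float(np.linalg.norm(bpos - apos))
                if d > max_dist:
                    continue
                key = (bref[:2], aref[:2])
                if key not in best or d < best[key].distance:
                    best[key] = SaltBridge(bref, aref, d)
    return sorted(best.values(), key=lambda s: (s.basic, s.acidic))


# ---------------------------------------------------------------------------
# Comparative report

def interface_report(structure: StructureModel, label: str = "",
                     chains: Sequence[str] | None = None,
                     min_area: float = 1e-6,
                     **sasa_kwargs) -> pd.DataFrame:
    """Per-chain-pair buried area, H-bond and salt-bridge counts.

    Returns a tidy frame (model, chain_i, chain_j, area, n_hbonds,
    n_bridges); pairs with no buried area and no contacts are omitted.
    """
    ids = list(chains) if chains is not None else structure.chain_ids
    solo = {cid: shrake_rupley(structure, chains=[cid], **sasa_kwargs).total
            for cid in ids}
    rows = []
    for i, ci in enumerate(ids):
        for cj in ids[i + 1:]:
            pair = shrake_rupley(structure, chains=[ci, cj],
                                 **sasa_kwargs).total
            area = (solo[ci] + solo[cj] - pair) / 2.0
            hb = find_hbonds(structure, [ci], [cj])
            sb = find_salt_bridges(structure, [ci], [cj])
            if area <= min_area and not hb and not sb:
                continue
            rows.append({"model": label, "chain_i": ci, "chain_j": cj,
                         "area": area, "n_hbonds": len(hb),
                         "n_bridges": len(sb)})
    return pd.DataFrame(rows, columns=["model", "chain_i", "chain_j",
                                       "area", "n_hbonds", "n_bridges"])
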
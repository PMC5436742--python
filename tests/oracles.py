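"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different route from the implementation it
verifies: exhaustive enumeration for alignment scores, the quaternion
eigenvalue method for superposition, regex translation for motif scans,
gemmi for torsions, and naive O(n^2) scans for contact detectors.
"""

from __future__ import annotations

import itertools
import re

import gemmi
import numpy as np


def brute_force_global_score(a: str, b: str, matrix, gap_open: float,
                             gap_extend: float) -> float:
    """Maximum global alignment score by exhaustive enumeration.

    A gap run of length L costs gap_open + (L-1)*gap_extend (the
    convention of Biopython's open/extend scores).  Feasible for len <= 8.
    """
    best = -np.inf

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + matrix[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if last == "a" else gap_open
            rec(i + 1, j, score - cost, "a")
        if j < len(b):
            cost = gap_extend if last == "b" else gap_open
            rec(i, j + 1, score - cost, "b")

    rec(0, 0, 0.0, "m")
    return float(best)


def quaternion_superpose_rmsd(mobile: np.ndarray,
                              target: np.ndarray) -> float:
    """RMSD after optimal rigid superposition, quaternion eigen method."""
    x = mobile - mobile.mean(axis=0)
    y = target - target.mean(axis=0)
    sxx, sxy, sxz = (x[:, 0] @ y[:, 0], x[:, 0] @ y[:, 1], x[:, 0] @ y[:, 2])
    syx, syy, syz = (x[:, 1] @ y[:, 0], x[:, 1] @ y[:, 1], x[:, 1] @ y[:, 2])
    szx, szy, szz = (x[:, 2] @ y[:, 0], x[:, 2] @ y[:, 1], x[:, 2] @ y[:, 2])
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(k).max()
    e0 = (x ** 2).sum() + (y ** 2).sum()
    msd = max((e0 - 2.0 * lam) / len(x), 0.0)
    return float(np.sqrt(msd))


def prosite_to_regex(pattern: str) -> str:
    """Translate a PROSITE-subset pattern into a python regex."""
    parts = []
    for token in pattern.strip().rstrip(".").split("-"):
        m = re.match(r"^(?:([A-Za-z])|\[([A-Za-z]+)\]|\{([A-Za-z]+)\})"
                     r"(?:\((\d+)\))?$", token)
        letter, inc, exc, rep = m.groups()
        if letter:
            piece = "." if letter.upper() == "X" else letter.upper()
        elif inc:
            piece = f"[{inc.upper()}]"
        else:
            piece = f"[^{exc.upper()}]"
        parts.append(piece * int(rep or 1))
    return "".join(parts)


def regex_scan(seq: str, pattern: str) -> list[tuple[int, int, str]]:
    """All (possibly overlapping) matches as 1-based (start, end, match)."""
    rx = re.compile("(?=(" + prosite_to_regex(pattern) + "))")
    return [(m.start() + 1, m.start() + len(m.group(1)), m.group(1))
            for m in rx.finditer(seq)]


def gemmi_torsion(p1, p2, p3, p4) -> float:
    pts = [gemmi.Position(*p) for p in (p1, p2, p3, p4)]
    return float(np.degrees(gemmi.calculate_dihedral(*pts)))


def naive_contact_pairs(coords_a: np.ndarray, coords_b: np.ndarray,
                        cutoff: float) -> set[tuple[int, int]]:
    out = set()
    for i, j in itertools.product(range(len(coords_a)), range(len(coords_b))):
        if np.linalg.norm(coords_a[i] - coords_b[j]) <= cutoff:
            out.add((i, j))
    return out
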
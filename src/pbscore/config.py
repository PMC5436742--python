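"""Pinned numerical conventions and parameter defaults.

Every cutoff used by the analysis stages lives here so that a report can
echo the exact convention it was computed under.  All distance cutoffs are
inclusive (a pair *at* the cutoff is counted).
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# van der Waals radii (Å), Chothia-style united-heavy-atom set.
# Used for both SASA (plus probe) and clash detection (sum scaled).
VDW_RADII: dict[str, float] = {
    "H": 1.00,
    "C": 1.87,
    "N": 1.65,
    "O": 1.40,
    "S": 1.85,
    "P": 1.90,
    "SE": 1.90,
    "FE": 1.47,
    "MG": 1.18,
    "ZN": 1.39,
}

# SASA sampling
PROBE_RADIUS = 1.4          # Å, water probe
SASA_N_POINTS = 960         # golden-spiral points per atom

# Interface detection (heavy-atom criteria; the 2.3 Å structure has no H)
HBOND_DIST = 3.5            # Å, donor–acceptor
HBOND_MIN_ANGLE = 90.0      # degrees, antecedent–donor–acceptor
SALTBRIDGE_DIST = 4.0       # Å, basic N — acidic O
CLASH_CUTOFF_SCALE = 0.7    # clash when d < scale * (r_i + r_j)
BOND_INFER_CUTOFF = 1.8     # Å, covalent bond inference between C/N/O/S
COVALENT_CYS_CUTOFF = 2.0   # Å, Cys SG — chromophore carbon thioether
BINDING_SITE_CUTOFF = 4.0   # Å, residue inclusion around a chromophore

# Bilin conformational windows (degrees, inclusive toward Z / syn)
DIHEDRAL_CLASS_BOUNDARY = 90.0

# Alignment defaults (global Needleman–Wunsch, affine gaps)
ALIGN_MATRIX = "BLOSUM62"
GAP_OPEN = 10.0
GAP_EXTEND = 0.5

# PROSITE-style phosphosite patterns scanned by default:
# protein kinase C and casein kinase 2 consensus sites.
PHOSPHOSITE_PATTERNS: dict[str, str] = {
    "PKC_PHOSPHO_SITE": "[ST]-x-[RK]",
    "CK2_PHOSPHO_SITE": "[ST]-x(2)-[DE]",
}

# Trimer slot composition per variant: chain label -> subunit kind.
# alpha-type subunits sit at A/C/E, beta-type at B/D/F, the core linker at G.
TRIMER_COMPOSITIONS: dict[str, dict[str, str]] = {
    "APC":   {"A": "alpha", "B": "beta", "C": "alpha", "D": "beta",
              "E": "alpha", "F": "beta"},
    "APC_1": {"A": "alpha", "B": "beta", "C": "alpha", "D": "beta",
              "E": "alpha", "F": "beta", "G": "Lc"},
    "APC_2": {"A": "alphaII", "B": "beta", "C": "alpha", "D": "beta",
              "E": "alpha", "F": "beta", "G": "Lc"},
    "APC_3": {"A": "PB", "B": "beta", "C": "alpha", "D": "beta",
              "E": "alpha", "F": "beta18"},
}
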
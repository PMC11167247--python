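"""Shared physicochemical reference tables.

All tables are plain dicts so callers can copy-and-override them through
config; nothing here is read from disk.
"""

from __future__ import annotations

# Van der Waals radii (Å), Bondi-style element values. Unknown elements fall
# back to DEFAULT_VDW_RADIUS with a warning at parse time.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_VDW_RADIUS: float = 1.70

# Black & Mould normalised hydrophobicity scale (0..1), shifted so Gly = 0.
# Apolar residues are positive, polar/charged residues negative; the default
# hydrophobic patch cutoff of 0.09 operates on this shifted scale.
_BLACK_MOULD = {
    "A": 0.616, "R": 0.000, "N": 0.236, "D": 0.028, "C": 0.680,
    "Q": 0.251, "E": 0.043, "G": 0.501, "H": 0.165, "I": 0.943,
    "L": 0.943, "K": 0.283, "M": 0.738, "F": 1.000, "P": 0.711,
    "S": 0.359, "T": 0.450, "W": 0.878, "Y": 0.880, "V": 0.825,
}
HYDROPHOBICITY_SCALE: dict[str, float] = {
    aa: round(v - _BLACK_MOULD["G"], 3) for aa, v in _BLACK_MOULD.items()
}
HYDROPHOBICITY_SCALE["X"] = 0.0

# EMBOSS pKa convention for titratable side chains and free termini.
EMBOSS_PKA: dict[str, float] = {
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
    "N_term": 8.6, "C_term": 3.6,
}
ACIDIC = frozenset("DECY")
BASIC = frozenset("HKR")

# Formal side-chain charges (e) at formulation pH ~6 used for the Coulombic
# surface potential. His carries a small fractional positive charge.
FORMAL_CHARGES_PH6: dict[str, float] = {
    "D": -1.0, "E": -1.0, "K": +1.0, "R": +1.0, "H": +0.1,
}

# Side-chain atom on which the formal charge is placed; falls back to CA,
# then to the residue's first atom (covers one-bead toy structures).
CHARGE_SITE_ATOM: dict[str, str] = {
    "D": "CG", "E": "CD", "K": "NZ", "R": "CZ", "H": "NE2",
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # selenomethionine maps to M (documented nonstandard mapping)
    "MSE": "M",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}

CDR_REGIONS = frozenset(
    {"CDR-H1", "CDR-H2", "CDR-H3", "CDR-L1", "CDR-L2", "CDR-L3"}
)
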
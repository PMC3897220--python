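"""Per-residue scales and physicochemical constants.

Everything here is a published constant: the Kyte–Doolittle hydropathy
scale, the Vihinen B-factor-derived flexibility index, the Bjellqvist
pKa set used by ProtParam-style isoelectric-point calculations, and
residue charge conventions at pH 7.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 canonical one-letter codes, alphabetical."""

#: Kyte & Doolittle (1982) hydropathy index.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Vihinen et al. (1994) normalized flexibility index (window-9 averages of
#: normalized B-factors). Low = rigid, high = flexible.
VIHINEN_FLEXIBILITY = {
    "A": 0.984, "C": 0.906, "D": 1.068, "E": 1.094, "F": 0.915,
    "G": 1.031, "H": 0.950, "I": 0.927, "K": 1.102, "L": 0.935,
    "M": 0.952, "N": 1.048, "P": 1.049, "Q": 1.037, "R": 1.008,
    "S": 1.046, "T": 0.997, "V": 0.931, "W": 0.904, "Y": 0.929,
}

#: Amino acids ordered from most rigid to most flexible on the Vihinen scale
#: (the x-axis convention of composition-profile plots).
VIHINEN_ORDER = sorted(AMINO_ACIDS, key=VIHINEN_FLEXIBILITY.__getitem__)

#: Integer residue charges at pH 7 used for the mean-net-charge axis of the
#: charge–hydropathy plot (His treated as neutral, termini excluded).
CHARGE_PH7 = {"K": 1, "R": 1, "D": -1, "E": -1}

#: Bjellqvist pKa values as used by ProtParam. Side-chain groups:
PKA_POSITIVE_SIDE = {"K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE_SIDE = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
PKA_CTERMINAL = 3.55
#: N-terminal alpha-amino pKa depends on the first residue.
PKA_NTERMINAL = {
    "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
    "T": 6.82, "V": 7.44, "E": 7.7, "G": 7.5,
}
PKA_NTERMINAL_DEFAULT = 7.5


def normalized(scale: dict[str, float]) -> dict[str, float]:
    """Min–max normalize a per-residue scale to [0, 1]."""
    lo, hi = min(scale.values()), max(scale.values())
    return {aa: (v - lo) / (hi - lo) for aa, v in scale.items()}
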
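"""Amino-acid property tables used by the descriptor families.

Contents:

* the three property scales of Chou's pseudo-amino-acid composition
  (hydrophobicity, hydrophilicity, side-chain mass);
* the Grantham (1974) amino-acid difference matrix;
* a physicochemical distance matrix derived in-package from the three
  z-scored property scales (Euclidean over standardized properties,
  rescaled to [0, 1]) — the second distance matrix of the
  quasi-sequence-order descriptors;
* the seven attribute / three group partitions behind the
  composition-transition-distribution descriptors.
"""

from __future__ import annotations

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

# Chou's PAAC property scales (original, un-standardized values).
HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}
HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}


def standardize_scale(scale: dict[str, float]) -> dict[str, float]:
    """Z-score a property scale over the 20 residues (population SD)."""
    vals = np.array([scale[a] for a in AA])
    mu = vals.mean()
    sd = np.sqrt(((vals - mu) ** 2).mean())
    return {a: (scale[a] - mu) / sd for a in AA}


# Grantham amino-acid difference matrix (upper triangle of the published
# table; row residue, then {column residue: distance}).
_GRANTHAM_TRIANGLE = {
    "S": {"R": 110, "L": 145, "P": 74, "T": 58, "A": 99, "V": 124, "G": 56,
          "I": 142, "F": 155, "Y": 144, "C": 112, "H": 89, "Q": 68, "N": 46,
          "K": 121, "D": 65, "E": 80, "M": 135, "W": 177},
    "R": {"L": 102, "P": 103, "T": 71, "A": 112, "V": 96, "G": 125, "I": 97,
          "F": 97, "Y": 77, "C": 180, "H": 29, "Q": 43, "N": 86, "K": 26,
          "D": 96, "E": 54, "M": 91, "W": 101},
    "L": {"P": 98, "T": 92, "A": 96, "V": 32, "G": 138, "I": 5, "F": 22,
          "Y": 36, "C": 198, "H": 99, "Q": 113, "N": 153, "K": 107, "D": 172,
          "E": 138, "M": 15, "W": 61},
    "P": {"T": 38, "A": 27, "V": 68, "G": 42, "I": 95, "F": 114, "Y": 110,
          "C": 169, "H": 77, "Q": 76, "N": 91, "K": 103, "D": 108, "E": 93,
          "M": 87, "W": 147},
    "T": {"A": 58, "V": 69, "G": 59, "I": 89, "F": 103, "Y": 92, "C": 149,
          "H": 47, "Q": 42, "N": 65, "K": 78, "D": 85, "E": 65, "M": 81,
          "W": 128},
    "A": {"V": 64, "G": 60, "I": 94, "F": 113, "Y": 112, "C": 195, "H": 86,
          "Q": 91, "N": 111, "K": 106, "D": 126, "E": 107, "M": 84, "W": 148},
    "V": {"G": 109, "I": 29, "F": 50, "Y": 55, "C": 192, "H": 84, "Q": 96,
          "N": 133, "K": 97, "D": 152, "E": 121, "M": 21, "W": 88},
    "G": {"I": 135, "F": 153, "Y": 147, "C": 159, "H": 98, "Q": 87, "N": 80,
          "K": 127, "D": 94, "E": 98, "M": 127, "W": 184},
    "I": {"F": 21, "Y": 33, "C": 198, "H": 94, "Q": 109, "N": 149, "K": 102,
          "D": 168, "E": 134, "M": 10, "W": 61},
    "F": {"Y": 22, "C": 205, "H": 100, "Q": 116, "N": 158, "K": 102,
          "D": 177, "E": 140, "M": 28, "W": 40},
    "Y": {"C": 194, "H": 83, "Q": 99, "N": 143, "K": 85, "D": 160, "E": 122,
          "M": 36, "W": 37},
    "C": {"H": 174, "Q": 154, "N": 139, "K": 202, "D": 154, "E": 170,
          "M": 196, "W": 215},
    "H": {"Q": 24, "N": 68, "K": 32, "D": 81, "E": 40, "M": 87, "W": 115},
    "Q": {"N": 46, "K": 53, "D": 61, "E": 29, "M": 101, "W": 130},
    "N": {"K": 94, "D": 23, "E": 42, "M": 142, "W": 174},
    "K": {"D": 101, "E": 56, "M": 95, "W": 110},
    "D": {"E": 45, "M": 160, "W": 181},
    "E": {"M": 126, "W": 152},
    "M": {"W": 67},
}


def grantham_matrix(normalize: bool = True) -> np.ndarray:
    """The symmetric 20x20 Grantham difference matrix, A..Y order.

    With ``normalize=True`` entries are divided by the matrix maximum (215)
    so both quasi-sequence-order distance matrices live on [0, 1].
    """
    m = np.zeros((20, 20))
    for a, row in _GRANTHAM_TRIANGLE.items():
        for b, d in row.items():
            m[AA_INDEX[a], AA_INDEX[b]] = d
            m[AA_INDEX[b], AA_INDEX[a]] = d
    if normalize:
        m = m / m.max()
    return m


def physchem_distance_matrix() -> np.ndarray:
    """Physicochemical distance matrix from the three z-scored PAAC scales.

    d(a, b) is the Euclidean distance between residues in the standardized
    (hydrophobicity, hydrophilicity, side-chain-mass) space, rescaled so the
    largest pairwise distance is 1.
    """
    scales = [
        standardize_scale(HYDROPHOBICITY),
        standardize_scale(HYDROPHILICITY),
        standardize_scale(SIDE_CHAIN_MASS),
    ]
    pts = np.array([[s[a] for s in scales] for a in AA])
    diff = pts[:, None, :] - pts[None, :, :]
    m = np.sqrt((diff ** 2).sum(axis=2))
    return m / m.max()


# Composition-transition-distribution attribute partitions: seven
# physicochemical attributes, each splitting the alphabet into three groups
# (Dubchak-style tables, as used by the standard descriptor packages).
CTD_ATTRIBUTES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}
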
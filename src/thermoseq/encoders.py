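"""Integer token encodings feeding the model's two sequence channels.

Composition channel: each residue maps to 1 + its rank in the alphabetical
one-letter order (A=1, C=2, ..., Y=20).

Physicochemical channel: each residue maps to the index of its property
group — hydrophobic (V,I,L,F,M,W,Y,C)=1, negatively charged (D,E)=2,
positively charged (R,K,H)=3, conformational (G,P)=4, polar (N,Q,S)=5,
other (A,T)=6.

Token 0 is reserved for right padding in both channels and is masked out by
the embedding layer downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tables import AA, AA_INDEX

#: Maximum sequence length; matches the dataset length filter, so accepted
#: sequences are never truncated.
DEFAULT_LMAX = 1500

PHYS_GROUPS = {
    "hydrophobic": "VILFMWYC",
    "negative": "DE",
    "positive": "RKH",
    "conformation": "GP",
    "polarity": "NQS",
    "other": "AT",
}
_PHYS_CODE = {
    ch: code
    for code, members in enumerate(PHYS_GROUPS.values(), start=1)
    for ch in members
}
_COMP_DECODE = {i + 1: a for a, i in AA_INDEX.items()}


@dataclass
class EncodedPair:
    """The two fixed-length token arrays for one sequence."""

    id: str
    comp_tokens: np.ndarray
    phys_tokens: np.ndarray
    true_length: int

    def __post_init__(self) -> None:
        self.comp_tokens = np.asarray(self.comp_tokens, dtype=np.int64)
        self.phys_tokens = np.asarray(self.phys_tokens, dtype=np.int64)
        if self.comp_tokens.shape != self.phys_tokens.shape:
            raise ValueError("channel arrays must share one padded length")


def _check(seq: str, lmax: int) -> str:
    seq = seq.upper()
    if len(seq) > lmax:
        raise ValueError(f"sequence length {len(seq)} exceeds Lmax={lmax}")
    bad = set(seq) - set(AA)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return seq


def encode_composition(seq: str, lmax: int = DEFAULT_LMAX) -> np.ndarray:
    """Alphabetical-rank tokens (A=1 .. Y=20), right-padded with 0."""
    seq = _check(seq, lmax)
    out = np.zeros(lmax, dtype=np.int64)
    for i, ch in enumerate(seq):
        out[i] = AA_INDEX[ch] + 1
    return out


def encode_physicochemical(seq: str, lmax: int = DEFAULT_LMAX) -> np.ndarray:
    """Property-group tokens (1..6), right-padded with 0."""
    seq = _check(seq, lmax)
    out = np.zeros(lmax, dtype=np.int64)
    for i, ch in enumerate(seq):
        out[i] = _PHYS_CODE[ch]
    return out


def decode_composition(tokens: np.ndarray) -> str:
    """Invert :func:`encode_composition`, stripping padding."""
    return "".join(_COMP_DECODE[t] for t in np.asarray(tokens) if t != 0)


def encode_pair(seq: str, lmax: int = DEFAULT_LMAX, id: str = "") -> EncodedPair:
    """Build both channel encodings for one sequence."""
    return EncodedPair(
        id=id,
        comp_tokens=encode_composition(seq, lmax),
        phys_tokens=encode_physicochemical(seq, lmax),
        true_length=len(seq),
    )
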
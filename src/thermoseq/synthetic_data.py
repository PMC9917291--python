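"""Synthetic labeled corpora and feature tables for exercising the pipeline.

Sequences are residue-i.i.d. draws from class-specific composition
profiles.  The positive (thermophilic-like) profile up-weights the
hydrophobic, charged and aromatic residues {V,I,L,F,M,W,Y,C,D,E,R,K,H}
relative to the negative profile, with ``signal_strength`` scaling the
log-fold enrichment; ``signal_strength=0`` makes the classes
indistinguishable.  Lengths follow a lognormal law clipped to
``[min_len, max_len]``.  Everything is deterministic under the
``GeneratorSpec`` seed.

No positional motifs are injected; the generator exercises every
computation but does not emulate protein evolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tables import AA
from .io import LABEL_MESOPHILIC, LABEL_THERMOPHILIC, ProteinRecord

#: Residues enriched in the positive class: hydrophobic + charged + aromatic.
ENRICHED_RESIDUES = "VILFMWYCDERKH"


def _default_profiles(signal_strength: float) -> tuple[np.ndarray, np.ndarray]:
    neg = np.full(20, 1 / 20)
    bias = np.array([0.5 if a in ENRICHED_RESIDUES else -0.5 for a in AA])
    pos = neg * np.exp(signal_strength * bias)
    pos /= pos.sum()
    return pos, neg


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic corpus generator."""

    n_pos: int = 400
    n_neg: int = 400
    length_meanlog: float = 4.7  # median length ~110 residues
    length_sdlog: float = 0.35
    min_len: int = 40
    max_len: int = 1500
    signal_strength: float = 1.0
    pos_profile: np.ndarray | None = None
    neg_profile: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 31:
            raise ValueError(
                "min_len must be >= 31 (lag-based descriptors need length > 30)"
            )
        if self.max_len > 1500:
            raise ValueError("max_len must be <= 1500 (dataset length filter)")
        pos, neg = _default_profiles(self.signal_strength)
        if self.pos_profile is None:
            self.pos_profile = pos
        if self.neg_profile is None:
            self.neg_profile = neg
        for name, prof in (("pos_profile", self.pos_profile),
                           ("neg_profile", self.neg_profile)):
            prof = np.asarray(prof, dtype=float)
            if prof.shape != (20,) or abs(prof.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be a 20-simplex vector")


def _sample_length(rng: np.random.Generator, spec: GeneratorSpec) -> int:
    L = int(round(rng.lognormal(spec.length_meanlog, spec.length_sdlog)))
    return int(np.clip(L, spec.min_len, spec.max_len))


def generate_corpus(spec: GeneratorSpec) -> list[ProteinRecord]:
    """Draw a labeled corpus of ``n_pos + n_neg`` records.

    Positives carry an OGT sampled uniformly in [60, 95] degrees C,
    negatives in [5, 37], so the corpus also exercises the
    temperature-based class-assignment rules.
    """
    rng = np.random.default_rng(spec.seed)
    residues = np.array(list(AA))
    records: list[ProteinRecord] = []
    for label, profile, n, prefix in (
        (LABEL_THERMOPHILIC, spec.pos_profile, spec.n_pos, "tp"),
        (LABEL_MESOPHILIC, spec.neg_profile, spec.n_neg, "mp"),
    ):
        for i in range(n):
            L = _sample_length(rng, spec)
            seq = "".join(rng.choice(residues, size=L, p=profile))
            ogt = (rng.uniform(60.0, 95.0) if label == LABEL_THERMOPHILIC
                   else rng.uniform(5.0, 37.0))
            records.append(
                ProteinRecord(f"{prefix}{i:05d}", seq, label=label,
                              ogt=float(round(ogt, 1)))
            )
    return records


def generate_feature_table(
    n: int,
    p: int,
    n_informative: int,
    seed: int,
    effect_size: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Gaussian feature matrix with a known informative subset.

    Informative columns are class-shifted normals (Cohen's d =
    ``effect_size``); the rest are shared N(0, 1) noise.  Returns
    ``(X, y, feature_names, informative_names)``.
    """
    if n_informative > p:
        raise ValueError("n_informative must be <= p")
    if n < 2 or p < 1:
        raise ValueError("need n >= 2 samples and p >= 1 features")
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[n // 2:] = 1
    rng.shuffle(y)
    X = rng.standard_normal((n, p))
    informative_idx = rng.choice(p, size=n_informative, replace=False)
    for j in informative_idx:
        X[:, j] += effect_size * y
    names = [f"f{j:03d}" for j in range(p)]
    informative = sorted(names[j] for j in informative_idx)
    return X, y, names, informative
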
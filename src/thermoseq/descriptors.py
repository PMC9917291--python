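"""Six families of sequence-derived biological descriptors (797 features).

The full panel concatenates, in fixed order:

========  ===============================================  ====
family    description                                      dim
========  ===============================================  ====
AAC       amino-acid composition                             20
DPC       dipeptide composition                             400
CTD       composition / transition / distribution           147
QSO       quasi-sequence-order descriptors                  100
PAAC      pseudo-amino-acid composition                      50
APAAC     amphiphilic pseudo-amino-acid composition          80
========  ===============================================  ====

All descriptors are deterministic functions of the sequence.  The lag-based
families (QSO, PAAC, APAAC) need sequences longer than their lag (30 by
default), so the full panel requires length >= 31.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _tables
from ._tables import AA, AA_INDEX
from .io import ProteinRecord

FAMILIES = ("aac", "dpc", "ctd", "qso", "paac", "apaac")
FAMILY_DIMS = {"aac": 20, "dpc": 400, "ctd": 147, "qso": 100, "paac": 50, "apaac": 80}
TOTAL_FEATURES = 797

MIN_FULL_PANEL_LENGTH = 31
MAX_SEQUENCE_LENGTH = 1500


@dataclass
class FeatureVector:
    """Named descriptor values for one sequence."""

    id: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _validate(seq: str, min_len: int = 1) -> str:
    seq = seq.upper()
    if len(seq) < min_len:
        raise ValueError(
            f"sequence too short: length {len(seq)} < required {min_len}"
        )
    bad = set(seq) - set(AA)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    return seq


def _counts(seq: str) -> np.ndarray:
    counts = np.zeros(20)
    for ch in seq:
        counts[AA_INDEX[ch]] += 1
    return counts


def aac(seq: str, id: str = "") -> FeatureVector:
    """Amino-acid composition: frequency of the 20 residues, A..Y order."""
    seq = _validate(seq, 1)
    vals = _counts(seq) / len(seq)
    return FeatureVector(id, [f"AAC.{a}" for a in AA], vals)


def dpc(seq: str, id: str = "") -> FeatureVector:
    """Dipeptide composition over the L-1 overlapping windows (400 values)."""
    seq = _validate(seq, 2)
    vals = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        vals[AA_INDEX[a] * 20 + AA_INDEX[b]] += 1
    vals /= len(seq) - 1
    names = [f"DPC.{a}{b}" for a, b in itertools.product(AA, repeat=2)]
    return FeatureVector(id, names, vals)


def ctd(seq: str, id: str = "") -> FeatureVector:
    """Composition-transition-distribution descriptors (147 values).

    For each of seven physicochemical attributes the residues fall into
    three groups.  Composition is the three group fractions; transition the
    frequency of adjacent residue pairs crossing each group pair (either
    order, over L-1 windows); distribution the relative chain positions
    (percent of L) of the first, 25%-th, 50%-th, 75%-th and last occurrence
    of each group, zero for absent groups.
    """
    seq = _validate(seq, 1)
    L = len(seq)
    comp_names, comp_vals = [], []
    tran_names, tran_vals = [], []
    dist_names, dist_vals = [], []
    for attr, groups in _tables.CTD_ATTRIBUTES.items():
        lookup = {
            ch: g for g, members in enumerate(groups) for ch in members
        }
        cls = np.array([lookup[ch] for ch in seq])
        # composition
        for g in range(3):
            comp_names.append(f"CTD.C.{attr}.G{g + 1}")
            comp_vals.append(float((cls == g).sum()) / L)
        # transition
        pair_counts = {(0, 1): 0, (0, 2): 0, (1, 2): 0}
        for a, b in zip(cls, cls[1:]):
            key = (min(a, b), max(a, b))
            if a != b:
                pair_counts[key] += 1
        for (g1, g2), c in pair_counts.items():
            tran_names.append(f"CTD.T.{attr}.G{g1 + 1}{g2 + 1}")
            tran_vals.append(c / (L - 1) if L > 1 else 0.0)
        # distribution
        for g in range(3):
            pos = np.flatnonzero(cls == g) + 1  # 1-based chain positions
            n = len(pos)
            if n == 0:
                picks = [0.0] * 5
            else:
                idx = [0,
                       max(int(np.ceil(0.25 * n)) - 1, 0),
                       max(int(np.ceil(0.50 * n)) - 1, 0),
                       max(int(np.ceil(0.75 * n)) - 1, 0),
                       n - 1]
                picks = [pos[i] / L * 100.0 for i in idx]
            for q, v in zip(("first", "25", "50", "75", "100"), picks):
                dist_names.append(f"CTD.D.{attr}.G{g + 1}.{q}")
                dist_vals.append(v)
    return FeatureVector(
        id,
        comp_names + tran_names + dist_names,
        np.array(comp_vals + tran_vals + dist_vals),
    )


def _socn(seq: str, matrix: np.ndarray, nlag: int) -> np.ndarray:
    """Sequence-order coupling numbers tau_d = sum_i dist(r_i, r_{i+d})^2."""
    idx = np.array([AA_INDEX[c] for c in seq])
    return np.array(
        [float((matrix[idx[:-d], idx[d:]] ** 2).sum()) for d in range(1, nlag + 1)]
    )


def qso(seq: str, nlag: int = 30, w: float = 0.1, id: str = "") -> FeatureVector:
    """Quasi-sequence-order descriptors under two distance matrices.

    For each matrix: 20 composition-type values f_r / (sum f + w sum tau)
    and nlag sequence-order values w tau_d / (sum f + w sum tau), where
    tau_d is the d-lag coupling number (sum of squared inter-residue
    distances).  With the default nlag=30 the result has 2*(20+30)=100
    entries.  Frequencies are normalized (sum f = 1).
    """
    seq = _validate(seq, 1)
    if len(seq) <= nlag:
        raise ValueError(f"sequence too short for nlag={nlag} (length {len(seq)})")
    freqs = _counts(seq) / len(seq)
    names: list[str] = []
    vals: list[float] = []
    matrices = {
        "physchem": _tables.physchem_distance_matrix(),
        "grantham": _tables.grantham_matrix(),
    }
    for mname, matrix in matrices.items():
        tau = _socn(seq, matrix, nlag)
        denom = freqs.sum() + w * tau.sum()
        for a, f in zip(AA, freqs):
            names.append(f"QSO.{mname}.{a}")
            vals.append(f / denom)
        for d, t in enumerate(tau, start=1):
            names.append(f"QSO.{mname}.lag{d}")
            vals.append(w * t / denom)
    return FeatureVector(id, names, np.array(vals))


def _paac_scales() -> list[dict[str, float]]:
    return [
        _tables.standardize_scale(_tables.HYDROPHOBICITY),
        _tables.standardize_scale(_tables.HYDROPHILICITY),
        _tables.standardize_scale(_tables.SIDE_CHAIN_MASS),
    ]


def paac(seq: str, lam: int = 30, w: float = 0.05, id: str = "") -> FeatureVector:
    """Chou's pseudo-amino-acid composition (20 + lam values).

    theta_j averages, over positions i, the mean squared difference of the
    three standardized property scales between residues i and i+j.  The
    first 20 entries are f_u / (sum f + w sum theta); the last lam are
    w theta_j / (sum f + w sum theta).  All 50 entries sum to 1.
    """
    seq = _validate(seq, 1)
    if len(seq) <= lam:
        raise ValueError(f"sequence too short for lambda={lam} (length {len(seq)})")
    scales = _paac_scales()
    prof = np.array([[s[c] for c in seq] for s in scales])  # (3, L)
    L = prof.shape[1]
    theta = np.array(
        [float(((prof[:, j:] - prof[:, :-j]) ** 2).mean(axis=0).mean())
         for j in range(1, lam + 1)]
    )
    freqs = _counts(seq) / L
    denom = freqs.sum() + w * theta.sum()
    names = [f"PAAC.{a}" for a in AA] + [f"PAAC.lambda{j}" for j in range(1, lam + 1)]
    vals = np.concatenate([freqs / denom, w * theta / denom])
    return FeatureVector(id, names, vals)


def apaac(seq: str, lam: int = 30, w: float = 0.05, id: str = "") -> FeatureVector:
    """Amphiphilic pseudo-amino-acid composition (20 + 2*lam values).

    The hydrophobicity and hydrophilicity correlations are kept separate:
    for lag j, tau uses the mean product h(r_i) * h(r_{i+j}) of each
    standardized scale, giving two pseudo components per lag.  Entries sum
    to 1, though individual pseudo components may be negative (the
    correlation is a product, not a squared difference).
    """
    seq = _validate(seq, 1)
    if len(seq) <= lam:
        raise ValueError(f"sequence too short for lambda={lam} (length {len(seq)})")
    hb, hl, _ = _paac_scales()
    h1 = np.array([hb[c] for c in seq])
    h2 = np.array([hl[c] for c in seq])
    L = len(seq)
    names = [f"APAAC.{a}" for a in AA]
    tau: list[float] = []
    for j in range(1, lam + 1):
        tau.append(float((h1[:-j] * h1[j:]).mean()))
        tau.append(float((h2[:-j] * h2[j:]).mean()))
        names.append(f"APAAC.H1.lag{j}")
        names.append(f"APAAC.H2.lag{j}")
    tau_arr = np.array(tau)
    freqs = _counts(seq) / L
    denom = freqs.sum() + w * tau_arr.sum()
    vals = np.concatenate([freqs / denom, w * tau_arr / denom])
    return FeatureVector(id, names, vals)


_FAMILY_FUNCS = {
    "aac": lambda s: aac(s),
    "dpc": lambda s: dpc(s),
    "ctd": lambda s: ctd(s),
    "qso": lambda s: qso(s),
    "paac": lambda s: paac(s),
    "apaac": lambda s: apaac(s),
}


def featurize(
    record: ProteinRecord | str,
    families: Sequence[str] = FAMILIES,
) -> FeatureVector:
    """Compute the concatenated descriptor panel for one record.

    With all six families this is the 797-feature panel in fixed order
    AAC, DPC, CTD, QSO, PAAC, APAAC.  The sequence must be 31..1500
    residues long (lag preconditions of QSO/PAAC/APAAC; upstream length
    filter).  Family errors propagate with the family named.
    """
    if isinstance(record, str):
        record = ProteinRecord("", record)
    seq = record.sequence
    full = set(families) & {"qso", "paac", "apaac"}
    min_len = MIN_FULL_PANEL_LENGTH if full else 2
    if len(seq) < min_len:
        raise ValueError(
            f"record {record.id!r}: length {len(seq)} below the minimum "
            f"{min_len} required by the lag-based families (QSO/PAAC/APAAC "
            f"need length > 30)"
        )
    if len(seq) > MAX_SEQUENCE_LENGTH:
        raise ValueError(
            f"record {record.id!r}: length {len(seq)} exceeds the "
            f"{MAX_SEQUENCE_LENGTH}-residue limit"
        )
    names: list[str] = []
    vals: list[np.ndarray] = []
    for fam in FAMILIES:
        if fam not in families:
            continue
        try:
            fv = _FAMILY_FUNCS[fam](seq)
        except ValueError as exc:
            raise ValueError(f"record {record.id!r}, family {fam}: {exc}") from exc
        names.extend(fv.names)
        vals.append(fv.values)
    return FeatureVector(record.id, names, np.concatenate(vals))


def feature_names(families: Sequence[str] = FAMILIES) -> list[str]:
    """The stable feature-name list for a family selection."""
    probe = "ACDEFGHIKLMNPQRSTVWY" * 2  # length 40 covers every lag default
    return featurize(ProteinRecord("probe", probe), families).names


class ProteinFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn transformer mapping sequences to the descriptor panel.

    Parameters
    ----------
    families : tuple of str
        Subset of ``("aac", "dpc", "ctd", "qso", "paac", "apaac")`` to
        compute, in canonical order.

    The transformer is stateless; ``fit`` only validates parameters.
    """

    def __init__(self, families: Sequence[str] = FAMILIES):
        self.families = families

    def fit(self, X, y=None):
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown descriptor families: {sorted(unknown)}")
        self.feature_names_ = feature_names(self.families)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X: Iterable[ProteinRecord | str]) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        rows = [featurize(x, self.families).values for x in X]
        return np.vstack(rows) if rows else np.empty((0, self.n_features_out_))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
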
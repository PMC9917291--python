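"""Descriptor-family tests against independent, naive oracle implementations.

The oracles below recompute each descriptor with plain Python loops,
straight from the definitions, sharing nothing with the package
implementation except the published property tables.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoseq import _tables
from thermoseq.descriptors import (
    FAMILIES,
    FAMILY_DIMS,
    ProteinFeaturizer,
    aac,
    apaac,
    ctd,
    dpc,
    feature_names,
    featurize,
    paac,
    qso,
)
from thermoseq.io import ProteinRecord

from conftest import AA, random_sequence

sequences = st.text(alphabet=AA, min_size=31, max_size=80)


# ---------------------------------------------------------------- oracles
def oracle_aac(seq):
    return {a: seq.count(a) / len(seq) for a in AA}


def oracle_ctd_composition(seq, groups):
    return [sum(seq.count(c) for c in g) / len(seq) for g in groups]


def oracle_ctd_transition(seq, groups):
    cls = {c: i for i, g in enumerate(groups) for c in g}
    pairs = [(cls[a], cls[b]) for a, b in zip(seq, seq[1:])]
    out = []
    for g1, g2 in ((0, 1), (0, 2), (1, 2)):
        out.append(sum(1 for p in pairs if set(p) == {g1, g2}) / (len(seq) - 1))
    return out


def oracle_ctd_distribution(seq, groups):
    out = []
    for g in groups:
        pos = [i + 1 for i, c in enumerate(seq) if c in g]
        if not pos:
            out.extend([0.0] * 5)
            continue
        n = len(pos)
        for frac in (None, 0.25, 0.50, 0.75, 1.0):
            if frac is None:
                p = pos[0]
            else:
                p = pos[max(math.ceil(frac * n) - 1, 0)]
            out.append(p / len(seq) * 100)
    return out


def oracle_qso_block(seq, matrix, nlag, w):
    dist = {(a, b): matrix[_tables.AA_INDEX[a], _tables.AA_INDEX[b]]
            for a in AA for b in AA}
    tau = [sum(dist[(seq[i], seq[i + d])] ** 2 for i in range(len(seq) - d))
           for d in range(1, nlag + 1)]
    freqs = [seq.count(a) / len(seq) for a in AA]
    denom = sum(freqs) + w * sum(tau)
    return [f / denom for f in freqs] + [w * t / denom for t in tau]


def oracle_paac(seq, lam, w):
    scales = [
        _tables.standardize_scale(_tables.HYDROPHOBICITY),
        _tables.standardize_scale(_tables.HYDROPHILICITY),
        _tables.standardize_scale(_tables.SIDE_CHAIN_MASS),
    ]
    theta = []
    for j in range(1, lam + 1):
        vals = []
        for i in range(len(seq) - j):
            vals.append(
                sum((s[seq[i]] - s[seq[i + j]]) ** 2 for s in scales) / 3
            )
        theta.append(sum(vals) / len(vals))
    freqs = [seq.count(a) / len(seq) for a in AA]
    denom = sum(freqs) + w * sum(theta)
    return [f / denom for f in freqs] + [w * t / denom for t in theta]


def oracle_apaac(seq, lam, w):
    hb = _tables.standardize_scale(_tables.HYDROPHOBICITY)
    hl = _tables.standardize_scale(_tables.HYDROPHILICITY)
    tau = []
    for j in range(1, lam + 1):
        n = len(seq) - j
        tau.append(sum(hb[seq[i]] * hb[seq[i + j]] for i in range(n)) / n)
        tau.append(sum(hl[seq[i]] * hl[seq[i + j]] for i in range(n)) / n)
    freqs = [seq.count(a) / len(seq) for a in AA]
    denom = sum(freqs) + w * sum(tau)
    return [f / denom for f in freqs] + [w * t / denom for t in tau]


# ------------------------------------------------------------------ tests
class TestAAC:
    def test_homopolymer(self):
        fv = aac("AAAA")
        assert fv.as_dict()["AAC.A"] == 1.0
        assert fv.values.sum() == pytest.approx(1.0)

    def test_uniform_quartet(self):
        vals = aac("ACDG").as_dict()
        for a in "ACDG":
            assert vals[f"AAC.{a}"] == 0.25

    def test_permutation_invariant(self, rng):
        seq = random_sequence(rng, 60)
        shuffled = "".join(rng.permutation(list(seq)))
        np.testing.assert_array_equal(aac(seq).values, aac(shuffled).values)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aac("")


class TestDPC:
    def test_homopolymer(self):
        assert dpc("AAA").as_dict()["DPC.AA"] == 1.0

    def test_enumerated_windows(self):
        # "ACAC" has windows AC, CA, AC
        vals = dpc("ACAC").as_dict()
        assert vals["DPC.AC"] == pytest.approx(2 / 3)
        assert vals["DPC.CA"] == pytest.approx(1 / 3)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            dpc("A")


class TestCTD:
    def test_homopolymer_composition_and_transitions(self):
        fv = ctd("G" * 20).as_dict()
        for attr, groups in _tables.CTD_ATTRIBUTES.items():
            g = next(i for i, grp in enumerate(groups) if "G" in grp) + 1
            assert fv[f"CTD.C.{attr}.G{g}"] == 1.0
            for pair in ("G12", "G13", "G23"):
                assert fv[f"CTD.T.{attr}.{pair}"] == 0.0

    def test_composition_partitions_to_one(self, rng):
        fv = ctd(random_sequence(rng, 75)).as_dict()
        for attr in _tables.CTD_ATTRIBUTES:
            total = sum(fv[f"CTD.C.{attr}.G{g}"] for g in (1, 2, 3))
            assert total == pytest.approx(1.0)

    def test_matches_naive_oracle_on_random_sequences(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(31, 120)))
            fv = ctd(seq)
            expected = []
            for attr, groups in _tables.CTD_ATTRIBUTES.items():
                expected.extend(oracle_ctd_composition(seq, groups))
            for attr, groups in _tables.CTD_ATTRIBUTES.items():
                expected.extend(oracle_ctd_transition(seq, groups))
            for attr, groups in _tables.CTD_ATTRIBUTES.items():
                expected.extend(oracle_ctd_distribution(seq, groups))
            np.testing.assert_allclose(fv.values, expected, atol=1e-12)


class TestQSO:
    def test_nonnegative_and_finite(self, rng):
        vals = qso(random_sequence(rng, 50)).values
        assert np.all(vals >= 0) and np.all(np.isfinite(vals))

    def test_w_zero_reduces_to_frequencies(self, rng):
        seq = random_sequence(rng, 45)
        fv = qso(seq, w=0.0)
        freqs = aac(seq).values
        np.testing.assert_allclose(fv.values[:20], freqs, atol=1e-12)
        np.testing.assert_allclose(fv.values[50:70], freqs, atol=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="nlag"):
            qso("ACDEF" * 6)  # length 30 == nlag

    def test_matches_naive_oracle(self, rng):
        seq = random_sequence(rng, 64)
        fv = qso(seq)
        expected = (
            oracle_qso_block(seq, _tables.physchem_distance_matrix(), 30, 0.1)
            + oracle_qso_block(seq, _tables.grantham_matrix(), 30, 0.1)
        )
        np.testing.assert_allclose(fv.values, expected, atol=1e-12)


class TestPAAC:
    def test_homopolymer_reduces_to_aac(self):
        fv = paac("A" * 40)
        assert np.all(fv.values[20:] == 0.0)
        np.testing.assert_allclose(fv.values[:20], aac("A" * 40).values)

    def test_sums_to_one(self, rng):
        for _ in range(5):
            seq = random_sequence(rng, int(rng.integers(31, 100)))
            assert paac(seq).values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_naive_oracle(self, rng):
        seq = random_sequence(rng, 55)
        np.testing.assert_allclose(paac(seq).values, oracle_paac(seq, 30, 0.05),
                                   atol=1e-12)


class TestAPAAC:
    def test_sums_to_one(self, rng):
        for _ in range(5):
            seq = random_sequence(rng, int(rng.integers(31, 100)))
            assert apaac(seq).values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_naive_oracle_on_random_sequences(self, rng):
        for _ in range(20):
            seq = random_sequence(rng, int(rng.integers(31, 90)))
            np.testing.assert_allclose(
                apaac(seq).values, oracle_apaac(seq, 30, 0.05), atol=1e-6
            )

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="lambda"):
            apaac("ACDEF" * 6)


class TestFeaturize:
    @pytest.mark.parametrize("family,dim", list(FAMILY_DIMS.items()))
    def test_family_dimensions(self, family, dim, rng):
        fv = featurize(random_sequence(rng, 100), families=(family,))
        assert len(fv) == dim

    def test_full_panel_is_797(self, rng):
        fv = featurize(random_sequence(rng, 100))
        assert len(fv) == 797
        assert len(fv.names) == len(set(fv.names))

    def test_family_order_fixed(self, rng):
        names = featurize(random_sequence(rng, 100)).names
        prefixes = [n.split(".")[0] for n in names]
        boundaries = [prefixes.index(f.upper()) for f in FAMILIES]
        assert boundaries == sorted(boundaries)

    def test_short_sequence_error_names_lag_families(self):
        with pytest.raises(ValueError, match="QSO/PAAC/APAAC"):
            featurize(ProteinRecord("p", "ACDEF" * 5))

    def test_too_long_rejected(self):
        with pytest.raises(ValueError, match="1500"):
            featurize("A" * 1501)

    def test_names_stable_across_calls(self, rng):
        seq1, seq2 = random_sequence(rng, 60), random_sequence(rng, 200)
        assert featurize(seq1).names == featurize(seq2).names == feature_names()

    def test_deterministic(self, rng):
        seq = random_sequence(rng, 80)
        np.testing.assert_array_equal(featurize(seq).values, featurize(seq).values)


@settings(max_examples=25, deadline=None)
@given(seq=sequences)
def test_composition_families_sum_to_one(seq):
    """AAC, DPC, PAAC and APAAC are all normalized to unit sum."""
    assert aac(seq).values.sum() == pytest.approx(1.0, abs=1e-9)
    assert dpc(seq).values.sum() == pytest.approx(1.0, abs=1e-9)
    assert paac(seq).values.sum() == pytest.approx(1.0, abs=1e-9)
    assert apaac(seq).values.sum() == pytest.approx(1.0, abs=1e-9)


class TestProteinFeaturizer:
    def test_transform_matrix_shape(self, rng):
        seqs = [random_sequence(rng, 50) for _ in range(3)]
        feat = ProteinFeaturizer().fit(seqs)
        X = feat.transform(seqs)
        assert X.shape == (3, 797)
        assert list(feat.get_feature_names_out()) == feature_names()

    def test_family_subset(self, rng):
        feat = ProteinFeaturizer(families=("aac", "dpc")).fit([])
        X = feat.transform([random_sequence(rng, 40)])
        assert X.shape == (1, 420)

    def test_unknown_family_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            ProteinFeaturizer(families=("aac", "bogus")).fit([])
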
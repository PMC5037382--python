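"""Encoder unit and property tests: AAC, RAAC, acACS, combined."""

import statistics
from collections import Counter

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from acpkit import (
    CANONICAL_ALPHABET,
    ChemicalShiftScale,
    EncoderConfig,
    PeptideDataset,
    PeptideRecord,
    acacs_theta,
    encode_aac,
    encode_acacs,
    encode_combined,
    encode_raac,
    reduce_sequence,
    shift_profile,
    standardize_scale,
)

peptides = st.text(alphabet=CANONICAL_ALPHABET, min_size=1, max_size=50)


def rec(seq: str) -> PeptideRecord:
    return PeptideRecord("t", seq)


# ---------------------------------------------------------------------------
# AAC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,expected_nonzero",
    [
        ("AAAA", {"A": 1.0}),
        ("GLFG", {"G": 0.5, "L": 0.25, "F": 0.25}),
        ("ACDEFGHIKLMNPQRSTVWY", {aa: 0.05 for aa in CANONICAL_ALPHABET}),
    ],
)
def test_aac_hand_counted_examples(seq, expected_nonzero):
    vec = encode_aac(rec(seq))
    for i, aa in enumerate(CANONICAL_ALPHABET):
        assert vec[i] == pytest.approx(expected_nonzero.get(aa, 0.0), abs=1e-15)


@given(seq=peptides)
def test_aac_matches_counter_oracle_and_sums_to_one(seq):
    vec = encode_aac(rec(seq))
    counts = Counter(seq)
    expected = [counts[aa] / len(seq) for aa in CANONICAL_ALPHABET]
    assert np.allclose(vec, expected)
    assert abs(vec.sum() - 1.0) < 1e-12


@given(seq=peptides)
def test_aac_invariant_under_sequence_permutation(seq):
    shuffled = "".join(sorted(seq))
    assert np.array_equal(encode_aac(rec(seq)), encode_aac(rec(shuffled)))


# ---------------------------------------------------------------------------
# reduced alphabet / RAAC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,expected",
    [
        ("RDENQKH", "1111111"),
        ("LIVAMF", "222222"),
        ("STYW", "3333"),
        ("PGC", "456"),
    ],
)
def test_reduce_sequence_hydropathy_groups(seq, expected):
    assert reduce_sequence(rec(seq)) == expected


def test_raac_single_dipeptide():
    by_l = encode_raac(rec("RK"), normalization="by_L")
    assert by_l[0] == pytest.approx(0.5)  # (1,1) is the first feature
    assert by_l.sum() == pytest.approx(0.5)
    by_l1 = encode_raac(rec("RK"), normalization="by_L_minus_1")
    assert by_l1[0] == pytest.approx(1.0)


def test_raac_enumerated_overlapping_dipeptides():
    # "RLRL" reduces to "2121"... no: R->1, L->2 so "1212": pairs 12, 21, 12.
    vec = encode_raac(rec("RLRL"), normalization="by_L_minus_1")
    assert vec[(1 - 1) * 6 + (2 - 1)] == pytest.approx(2 / 3)
    assert vec[(2 - 1) * 6 + (1 - 1)] == pytest.approx(1 / 3)
    assert vec.sum() == pytest.approx(1.0)


def test_raac_is_order_sensitive_where_aac_is_not():
    a, b = rec("RLRL"), rec("RRLL")
    assert np.array_equal(encode_aac(a), encode_aac(b))
    assert not np.array_equal(encode_raac(a), encode_raac(b))


def test_raac_length_one_errors():
    with pytest.raises(ValueError, match="length >= 2"):
        encode_raac(rec("G"))


@given(seq=st.text(alphabet=CANONICAL_ALPHABET, min_size=2, max_size=50))
def test_raac_matches_pair_count_oracle(seq):
    reduced = reduce_sequence(rec(seq))
    pair_counts = Counter(zip(reduced, reduced[1:]))
    vec = encode_raac(rec(seq), normalization="by_L")
    L = len(seq)
    for i in range(1, 7):
        for j in range(1, 7):
            expected = pair_counts[(str(i), str(j))] / L
            assert vec[(i - 1) * 6 + (j - 1)] == pytest.approx(expected)
    assert vec.sum() == pytest.approx((L - 1) / L, abs=1e-12)


# ---------------------------------------------------------------------------
# chemical-shift scale and acACS
# ---------------------------------------------------------------------------

def test_standardize_scale_mean_zero_unit_variance(toy_scale):
    std = standardize_scale(toy_scale)
    for atom in std.atoms:
        col = std.column(atom)
        assert abs(col.mean()) < 1e-9
        assert abs(col.std() - 1.0) < 1e-9
    assert std.standardized


def test_standardize_scale_idempotent(toy_scale):
    once = standardize_scale(toy_scale)
    twice = standardize_scale(once)
    for atom in once.atoms:
        assert np.allclose(once.column(atom), twice.column(atom), atol=1e-12)


def test_standardize_degenerate_scale_errors():
    flat = ChemicalShiftScale(
        values={"HA": {aa: 4.5 for aa in CANONICAL_ALPHABET}}
    )
    with pytest.raises(ValueError, match="zero variance"):
        standardize_scale(flat)


def test_shift_profile_lookup(toy_scale):
    poly_a = shift_profile(rec("AAAAAA"), toy_scale, "HA")
    assert poly_a.shape == (6,)
    assert np.all(poly_a == poly_a[0])
    gk = shift_profile(rec("GK"), toy_scale, "HA")
    assert gk.tolist() == [toy_scale.values["HA"]["G"], toy_scale.values["HA"]["K"]]


def test_shift_profile_unknown_atom_errors(toy_scale):
    with pytest.raises(KeyError, match="CA13"):
        shift_profile(rec("GK"), toy_scale, "CA13")


def theta_brute(series, d):
    terms = [(series[p] - series[p + d]) ** 2 for p in range(len(series) - d)]
    return sum(terms) / len(terms)


@pytest.mark.parametrize(
    "series,d,expected",
    [
        ([3.0, 3.0, 3.0, 3.0], 1, 0.0),
        ([0.0, 1.0, 0.0, 1.0], 1, 1.0),
        ([0.0, 1.0, 0.0, 1.0], 2, 0.0),
    ],
)
def test_theta_hand_computed(series, d, expected):
    assert acacs_theta(np.array(series), d) == pytest.approx(expected)


@given(
    series=st.lists(
        st.floats(min_value=-5, max_value=5, allow_nan=False), min_size=2, max_size=30
    ),
    d=st.integers(min_value=1, max_value=5),
)
def test_theta_matches_bruteforce_and_is_reversal_invariant(series, d):
    if len(series) <= d:
        with pytest.raises(ValueError, match="shorter than lag"):
            acacs_theta(np.array(series), d)
        return
    got = acacs_theta(np.array(series), d)
    assert got == pytest.approx(theta_brute(series, d))
    assert got >= 0.0
    # mathematically reversal-invariant; float summation order differs
    rev = acacs_theta(np.array(series[::-1]), d)
    assert rev == pytest.approx(got, rel=1e-12, abs=1e-12)


def test_theta_autocov_form_zero_on_constant():
    assert acacs_theta(np.full(8, 2.5), 3, form="autocov") == pytest.approx(0.0)


def test_acacs_dimension_arithmetic(four_atom_scale):
    vec = encode_acacs(rec("ACDEFGHIKL"), scale=four_atom_scale, lambda_max=5)
    assert vec.shape == (20,)
    two = encode_acacs(
        rec("ACDEFGHIKL"), scale=four_atom_scale, lambda_max=3, atoms=("HA", "N15")
    )
    assert two.shape == (6,)


def test_acacs_zero_on_homopolymer(four_atom_scale):
    vec = encode_acacs(rec("LLLLLLLLLL"), scale=four_atom_scale, lambda_max=5)
    assert np.allclose(vec, 0.0)


def test_acacs_bruteforce_oracle_gkgk(toy_scale):
    """θ(1), θ(2) for 'GKGK' on the N15 toy scale, recomputed by hand."""
    raw = [toy_scale.values["N15"][aa] for aa in CANONICAL_ALPHABET]
    mu = statistics.fmean(raw)
    sd = statistics.pstdev(raw)
    g = (toy_scale.values["N15"]["G"] - mu) / sd
    k = (toy_scale.values["N15"]["K"] - mu) / sd
    series = [g, k, g, k]
    expected = [theta_brute(series, 1), theta_brute(series, 2)]
    got = encode_acacs(rec("GKGK"), scale=toy_scale, lambda_max=2, atoms=("N15",))
    assert np.allclose(got, expected)


def test_acacs_preconditions(four_atom_scale):
    with pytest.raises(ValueError, match="length >= 6"):
        encode_acacs(rec("ACDEF"), scale=four_atom_scale, lambda_max=5)
    with pytest.raises(ValueError, match="non-empty"):
        encode_acacs(rec("ACDEFGH"), scale=four_atom_scale, atoms=())
    toy = ChemicalShiftScale(
        values={"HA": {aa: float(i) for i, aa in enumerate(CANONICAL_ALPHABET)}}
    )
    with pytest.raises(KeyError, match="N15"):
        encode_acacs(rec("ACDEFGH"), scale=toy, lambda_max=2, atoms=("HA", "N15"))


def test_scale_tsv_roundtrip(tmp_path, toy_scale):
    path = tmp_path / "scale.tsv"
    toy_scale.to_tsv(path)
    back = ChemicalShiftScale.from_tsv(path)
    assert back.atoms == toy_scale.atoms
    for atom in toy_scale.atoms:
        assert np.allclose(back.column(atom), toy_scale.column(atom))
    assert back.provenance == toy_scale.provenance


def test_packaged_default_scale_loads_and_standardizes():
    scale = ChemicalShiftScale.default()
    assert scale.atoms == ("HA", "HN", "N15", "CA13")
    std = standardize_scale(scale)
    for atom in std.atoms:
        assert abs(std.column(atom).mean()) < 1e-9


# ---------------------------------------------------------------------------
# combined encoding
# ---------------------------------------------------------------------------

def test_combined_dimension_sum(tiny_labeled_dataset, four_atom_scale):
    matrix = encode_combined(
        tiny_labeled_dataset, EncoderConfig(lambda_max=5), scale=four_atom_scale
    )
    assert matrix.shape == (4, 20 + 36 + 20)
    assert matrix.feature_names[0] == "aac:A"
    assert matrix.feature_names[20] == "raac:1-1"
    assert matrix.feature_names[56] == "acacs:HA:d1"
    assert matrix.encoder_meta["lambda_max"] == 5


def test_combined_single_part_matches_rowwise_encoder(tiny_labeled_dataset):
    matrix = encode_combined(tiny_labeled_dataset, EncoderConfig(parts=("AAC",)))
    for i, record in enumerate(tiny_labeled_dataset):
        assert np.array_equal(matrix.X[i], encode_aac(record))


def test_combined_part_reordering_permutes_blocks_not_values(
    tiny_labeled_dataset, four_atom_scale
):
    ab = encode_combined(
        tiny_labeled_dataset, EncoderConfig(parts=("AAC", "RAAC")),
        scale=four_atom_scale,
    )
    ba = encode_combined(
        tiny_labeled_dataset, EncoderConfig(parts=("RAAC", "AAC")),
        scale=four_atom_scale,
    )
    assert ba.feature_names == ab.feature_names[20:] + ab.feature_names[:20]
    assert np.array_equal(ba.X[:, 36:], ab.X[:, :20])
    assert np.array_equal(ba.X[:, :36], ab.X[:, 20:])


def test_combined_error_names_failing_record(four_atom_scale):
    ds = PeptideDataset(
        [PeptideRecord("ok", "ACDEFGHIKL"), PeptideRecord("shorty", "ACD")]
    )
    with pytest.raises(ValueError, match="shorty"):
        encode_combined(ds, EncoderConfig(lambda_max=5), scale=four_atom_scale)


def test_encoders_are_deterministic(tiny_labeled_dataset, four_atom_scale):
    cfg = EncoderConfig()
    a = encode_combined(tiny_labeled_dataset, cfg, scale=four_atom_scale)
    b = encode_combined(tiny_labeled_dataset, cfg, scale=four_atom_scale)
    assert np.array_equal(a.X, b.X)
    assert a.feature_names == b.feature_names
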
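import pytest
from hypothesis import HealthCheck, settings

from acpkit import CANONICAL_ALPHABET, ChemicalShiftScale, PeptideDataset, PeptideRecord

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def toy_scale() -> ChemicalShiftScale:
    """Small explicit scale (two atoms) with simple, distinct values.

    HA runs 0..19 over the canonical alphabet; N15 is a shuffled-looking
    quadratic so that the two atoms are not affinely related.
    """
    ha = {aa: float(i) for i, aa in enumerate(CANONICAL_ALPHABET)}
    n15 = {aa: float((7 * i + 3) % 20) for i, aa in enumerate(CANONICAL_ALPHABET)}
    return ChemicalShiftScale(
        values={"HA": ha, "N15": n15}, provenance="toy test scale"
    )


@pytest.fixture
def four_atom_scale() -> ChemicalShiftScale:
    """Explicit scale covering all four atoms (for dimension checks)."""
    values = {}
    for k, atom in enumerate(("HA", "HN", "N15", "CA13")):
        values[atom] = {
            aa: float((i + 3 * k) % 20 + k)
            for i, aa in enumerate(CANONICAL_ALPHABET)
        }
    return ChemicalShiftScale(values=values, provenance="toy four-atom scale")


@pytest.fixture
def tiny_labeled_dataset() -> PeptideDataset:
    return PeptideDataset(
        [
            PeptideRecord("p1", "GLFDIVKKVVGALG", label="positive"),
            PeptideRecord("p2", "KWKLFKKIEKVGQN", label="positive"),
            PeptideRecord("n1", "ASTTSEQNDAGSHP", label="negative"),
            PeptideRecord("n2", "DDEESSTTNNQQHH", label="negative"),
        ]
    )
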
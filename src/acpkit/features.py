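"""Sequence feature encoders: AAC, reduced-alphabet dipeptides, acACS.

Three complementary fixed-length representations of a peptide:

* **AAC** — the 20-vector of amino-acid occurrence frequencies ``n_i / L``.
* **RAAC** — dipeptide frequencies over a 6-letter hydropathy reduction of
  the alphabet (strongly hydrophilic/polar; strongly hydrophobic; weakly
  hydrophilic or hydrophobic; and the singletons P, G, C), giving 6x6 = 36
  features.  The literal normalization divides dipeptide counts by the
  sequence length ``L`` (so the vector sums to ``(L-1)/L``); dividing by
  ``L-1`` is available as an option.
* **acACS** — autocovariance-style descriptors of the per-residue reference
  NMR chemical-shift profile (atoms ¹Hα, ¹H_N, ¹⁵N, ¹³Cα).  For each atom
  the residue sequence is mapped to a numeric series via a standardized
  shift scale, and a correlation factor θ(d) is computed for each lag
  d = 1..λ.  The default θ is the mean squared lagged difference
  ``θ(d) = (1/(L-d)) Σ_p (s_p - s_{p+d})²``; a centered autocovariance form
  is available via ``acacs_form="autocov"``.  Both vanish on homopolymers.

Encoders are deterministic and purely per-record, so encoding an entire
dataset never mixes information between records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import CANONICAL_ALPHABET, PeptideDataset, PeptideRecord

#: Fixed atom ordering used everywhere (selection preserves this order).
ATOM_ORDER = ("HA", "HN", "N15", "CA13")

_RESIDUE_INDEX = {aa: i for i, aa in enumerate(CANONICAL_ALPHABET)}


# ---------------------------------------------------------------------------
# chemical-shift scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChemicalShiftScale:
    """Per-residue reference chemical shifts (ppm) for up to four atom types.

    ``values`` maps an atom tag from :data:`ATOM_ORDER` to a residue -> shift
    mapping covering all 20 canonical residues with finite values.
    """

    values: Mapping[str, Mapping[str, float]]
    provenance: str = ""
    standardized: bool = False

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("scale must define at least one atom")
        for atom, table in self.values.items():
            if atom not in ATOM_ORDER:
                raise ValueError(f"unknown atom tag {atom!r}; expected {ATOM_ORDER}")
            missing = [aa for aa in CANONICAL_ALPHABET if aa not in table]
            if missing:
                raise ValueError(f"atom {atom}: missing residues {missing}")
            vals = np.array([table[aa] for aa in CANONICAL_ALPHABET], dtype=float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"atom {atom}: non-finite shift value")

    @property
    def atoms(self) -> tuple[str, ...]:
        return tuple(a for a in ATOM_ORDER if a in self.values)

    def column(self, atom: str) -> np.ndarray:
        """The 20 shifts for ``atom`` in canonical residue order."""
        if atom not in self.values:
            raise KeyError(f"atom {atom!r} not in scale (has {self.atoms})")
        return np.array(
            [self.values[atom][aa] for aa in CANONICAL_ALPHABET], dtype=float
        )

    @classmethod
    def from_tsv(cls, path) -> "ChemicalShiftScale":
        """Read a scale TSV: optional ``#provenance:`` line, then a header
        ``residue<TAB>HA<TAB>HN<TAB>N15<TAB>CA13`` (any atom subset) and 20
        data rows."""
        provenance = ""
        header: list[str] | None = None
        rows: dict[str, list[float]] = {}
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                if line.startswith("#"):
                    if line.lower().startswith("#provenance:"):
                        provenance = line.split(":", 1)[1].strip()
                    continue
                parts = line.split("\t")
                if header is None:
                    if parts[0] != "residue":
                        raise ValueError(
                            "scale TSV header must start with 'residue'"
                        )
                    header = parts[1:]
                    continue
                rows[parts[0].strip().upper()] = [float(v) for v in parts[1:]]
        if header is None:
            raise ValueError("scale TSV has no header line")
        values = {
            atom: {aa: rows[aa][j] for aa in rows} for j, atom in enumerate(header)
        }
        return cls(values=values, provenance=provenance)

    def to_tsv(self, path) -> None:
        atoms = self.atoms
        lines = [f"#provenance: {self.provenance}"]
        lines.append("residue\t" + "\t".join(atoms))
        for aa in CANONICAL_ALPHABET:
            vals = "\t".join(repr(float(self.values[a][aa])) for a in atoms)
            lines.append(f"{aa}\t{vals}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def default(cls) -> "ChemicalShiftScale":
        """The packaged reference scale (see its provenance header)."""
        ref = resources.files("acpkit.data").joinpath(
            "chemical_shifts_synthetic_default.tsv"
        )
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def standardize_scale(scale: ChemicalShiftScale) -> ChemicalShiftScale:
    """Z-score each atom's 20 shifts to mean 0, unit (population) variance.

    Idempotent; raises on a degenerate atom whose 20 values are all equal.
    """
    new_values: dict[str, dict[str, float]] = {}
    for atom in scale.atoms:
        vals = scale.column(atom)
        sd = float(np.std(vals))
        if sd < 1e-15:
            raise ValueError(f"atom {atom}: zero variance, cannot standardize")
        z = (vals - float(np.mean(vals))) / sd
        new_values[atom] = dict(zip(CANONICAL_ALPHABET, z.tolist()))
    provenance = scale.provenance
    if not scale.standardized:
        provenance = (provenance + "; standardized").lstrip("; ")
    return ChemicalShiftScale(
        values=new_values, provenance=provenance, standardized=True
    )


# ---------------------------------------------------------------------------
# reduced alphabet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReducedAlphabet:
    """Ordered partition of the 20 residues into 6 groups, indexed 1..6."""

    groups: tuple[frozenset, ...]

    def __post_init__(self) -> None:
        if len(self.groups) != 6:
            raise ValueError("reduced alphabet must have exactly 6 groups")
        union: set[str] = set()
        for g in self.groups:
            if union & g:
                raise ValueError("reduced-alphabet groups must be disjoint")
            union |= set(g)
        if union != set(CANONICAL_ALPHABET):
            raise ValueError("groups must partition the 20 canonical residues")

    @property
    def mapping(self) -> dict[str, int]:
        return {aa: i + 1 for i, g in enumerate(self.groups) for aa in g}


#: Hydropathy partition: strongly hydrophilic/polar, strongly hydrophobic,
#: weakly hydrophilic/hydrophobic, then the singletons P, G, C.
DEFAULT_REDUCED_ALPHABET = ReducedAlphabet(
    groups=(
        frozenset("RDENQKH"),
        frozenset("LIVAMF"),
        frozenset("STYW"),
        frozenset("P"),
        frozenset("G"),
        frozenset("C"),
    )
)


def reduce_sequence(
    record: PeptideRecord, alphabet: ReducedAlphabet = DEFAULT_REDUCED_ALPHABET
) -> str:
    """Map a sequence position-wise to its group-index string, e.g. 'PGC'->'456'."""
    mapping = alphabet.mapping
    try:
        return "".join(str(mapping[aa]) for aa in record.sequence)
    except KeyError as exc:  # unreachable with a valid partition; defensive
        raise ValueError(
            f"record {record.id!r}: residue {exc.args[0]!r} not covered by alphabet"
        ) from exc


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

AAC_FEATURE_NAMES = tuple(f"aac:{aa}" for aa in CANONICAL_ALPHABET)
RAAC_FEATURE_NAMES = tuple(
    f"raac:{i}-{j}" for i, j in product(range(1, 7), range(1, 7))
)


def encode_aac(record: PeptideRecord) -> np.ndarray:
    """Amino-acid composition: frequencies n_i / L in fixed alphabetical order."""
    counts = np.zeros(20)
    for aa in record.sequence:
        counts[_RESIDUE_INDEX[aa]] += 1
    return counts / len(record.sequence)


def encode_raac(
    record: PeptideRecord,
    alphabet: ReducedAlphabet = DEFAULT_REDUCED_ALPHABET,
    normalization: str = "by_L",
) -> np.ndarray:
    """36-vector of reduced-alphabet dipeptide frequencies.

    Adjacent (overlapping) group-index pairs are counted and divided by L
    (``"by_L"``, the literal definition; sums to (L-1)/L) or by L-1
    (``"by_L_minus_1"``; sums to 1).  Requires L >= 2.
    """
    if normalization not in ("by_L", "by_L_minus_1"):
        raise ValueError(f"unknown RAAC normalization {normalization!r}")
    L = len(record.sequence)
    if L < 2:
        raise ValueError(
            f"record {record.id!r}: RAAC needs length >= 2, got {L}"
        )
    reduced = reduce_sequence(record, alphabet)
    counts = np.zeros((6, 6))
    for a, b in zip(reduced, reduced[1:]):
        counts[int(a) - 1, int(b) - 1] += 1
    denom = L if normalization == "by_L" else L - 1
    return counts.ravel() / denom


def shift_profile(
    record: PeptideRecord, scale: ChemicalShiftScale, atom: str
) -> np.ndarray:
    """Per-position chemical-shift series s(1..L) for one atom (table lookup)."""
    if atom not in scale.values:
        raise KeyError(f"atom {atom!r} not in scale (has {scale.atoms})")
    table = scale.values[atom]
    return np.array([table[aa] for aa in record.sequence], dtype=float)


def acacs_theta(series: np.ndarray, lag: int, form: str = "msd") -> float:
    """Correlation factor θ(d) of a shift series at lag ``d = lag``.

    ``"msd"`` (default): mean squared lagged difference
    ``(1/(L-d)) Σ (s_p - s_{p+d})²``.  ``"autocov"``: centered lagged
    autocovariance ``(1/(L-d)) Σ (s_p - s̄)(s_{p+d} - s̄)``.  Either form is
    0 for a constant series.
    """
    if form not in ("msd", "autocov"):
        raise ValueError(f"unknown acACS form {form!r}")
    series = np.asarray(series, dtype=float)
    L = series.size
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if L <= lag:
        raise ValueError(f"sequence shorter than lag+1 (L={L}, lag={lag})")
    head, tail = series[:-lag], series[lag:]
    if form == "msd":
        return float(np.mean((head - tail) ** 2))
    centered = series - series.mean()
    return float(np.mean(centered[:-lag] * centered[lag:]))


def acacs_feature_names(
    atoms: Sequence[str], lambda_max: int
) -> tuple[str, ...]:
    ordered = tuple(a for a in ATOM_ORDER if a in atoms)
    return tuple(
        f"acacs:{atom}:d{d}" for atom in ordered for d in range(1, lambda_max + 1)
    )


def encode_acacs(
    record: PeptideRecord,
    scale: ChemicalShiftScale | None = None,
    lambda_max: int = 5,
    atoms: Sequence[str] = ATOM_ORDER,
    form: str = "msd",
) -> np.ndarray:
    """acACS descriptor: θ(1..λ) per selected atom, atoms in fixed order.

    The scale is standardized first (idempotent), so descriptors are
    comparable across atoms.  Requires L >= λ + 1.
    """
    if not atoms:
        raise ValueError("atom set must be non-empty")
    unknown = [a for a in atoms if a not in ATOM_ORDER]
    if unknown:
        raise ValueError(f"unknown atom tag {unknown[0]!r}; expected {ATOM_ORDER}")
    if lambda_max < 1:
        raise ValueError("lambda_max must be >= 1")
    L = len(record.sequence)
    if L <= lambda_max:
        raise ValueError(
            f"record {record.id!r}: acACS with lambda={lambda_max} needs "
            f"length >= {lambda_max + 1}, got {L}"
        )
    scale = scale if scale is not None else ChemicalShiftScale.default()
    missing = [a for a in atoms if a not in scale.values]
    if missing:
        raise KeyError(f"atom {missing[0]!r} not in scale (has {scale.atoms})")
    scale = standardize_scale(scale)
    ordered = tuple(a for a in ATOM_ORDER if a in atoms)
    out = np.empty(len(ordered) * lambda_max)
    k = 0
    for atom in ordered:
        series = shift_profile(record, scale, atom)
        for d in range(1, lambda_max + 1):
            out[k] = acacs_theta(series, d, form=form)
            k += 1
    return out


# ---------------------------------------------------------------------------
# combined encoding of a dataset
# ---------------------------------------------------------------------------

PART_NAMES = ("AAC", "RAAC", "acACS")
_PART_CANON = {p.lower(): p for p in PART_NAMES}


@dataclass(frozen=True)
class EncoderConfig:
    """Which encoders to run and with what parameters."""

    parts: tuple[str, ...] = PART_NAMES
    lambda_max: int = 5
    atoms: tuple[str, ...] = ATOM_ORDER
    raac_normalization: str = "by_L"
    acacs_form: str = "msd"
    scale_file: str | None = None

    def __post_init__(self) -> None:
        canon = tuple(_PART_CANON.get(str(p).lower()) for p in self.parts)
        if not canon or any(c is None for c in canon):
            raise ValueError(
                f"parts must be a non-empty subset of {PART_NAMES}, got {self.parts}"
            )
        if len(set(canon)) != len(canon):
            raise ValueError("duplicate encoder part")
        object.__setattr__(self, "parts", canon)
        object.__setattr__(self, "atoms", tuple(self.atoms))

    def resolve_scale(self) -> ChemicalShiftScale:
        if self.scale_file is not None:
            return ChemicalShiftScale.from_tsv(self.scale_file)
        return ChemicalShiftScale.default()


@dataclass
class EncodedMatrix:
    """Named feature vectors for a peptide set, with encoder provenance."""

    ids: list[str]
    feature_names: list[str]
    X: np.ndarray
    encoder_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape != (len(self.ids), len(self.feature_names)):
            raise ValueError(
                f"shape mismatch: X is {self.X.shape}, expected "
                f"({len(self.ids)}, {len(self.feature_names)})"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.X, index=self.ids, columns=self.feature_names)

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.index.name = "id"
        frame.to_csv(path, sep="\t")

    def rows(self, indices: Iterable[int]) -> "EncodedMatrix":
        idx = list(indices)
        return EncodedMatrix(
            ids=[self.ids[i] for i in idx],
            feature_names=list(self.feature_names),
            X=self.X[idx],
            encoder_meta=dict(self.encoder_meta),
        )


def encode_combined(
    dataset: PeptideDataset,
    config: EncoderConfig | None = None,
    scale: ChemicalShiftScale | None = None,
    alphabet: ReducedAlphabet = DEFAULT_REDUCED_ALPHABET,
) -> EncodedMatrix:
    """Encode every record with the selected parts, concatenated in order.

    Feature names are prefixed by encoder (``aac:G``, ``raac:1-2``,
    ``acacs:N15:d3``).  Any record failing a sub-encoder precondition raises
    an error naming that record.
    """
    config = config or EncoderConfig()
    needs_acacs = "acACS" in config.parts
    if needs_acacs:
        scale = scale if scale is not None else config.resolve_scale()
        scale = standardize_scale(scale)

    names: list[str] = []
    for part in config.parts:
        if part == "AAC":
            names.extend(AAC_FEATURE_NAMES)
        elif part == "RAAC":
            names.extend(RAAC_FEATURE_NAMES)
        else:
            names.extend(acacs_feature_names(config.atoms, config.lambda_max))

    rows = []
    for rec in dataset:
        blocks = []
        for part in config.parts:
            if part == "AAC":
                blocks.append(encode_aac(rec))
            elif part == "RAAC":
                blocks.append(
                    encode_raac(rec, alphabet, config.raac_normalization)
                )
            else:
                blocks.append(
                    encode_acacs(
                        rec,
                        scale=scale,
                        lambda_max=config.lambda_max,
                        atoms=config.atoms,
                        form=config.acacs_form,
                    )
                )
        rows.append(np.concatenate(blocks) if blocks else np.empty(0))

    meta = {
        "parts": config.parts,
        "lambda_max": config.lambda_max,
        "atoms": tuple(a for a in ATOM_ORDER if a in config.atoms),
        "raac_normalization": config.raac_normalization,
        "acacs_form": config.acacs_form,
        "scale_provenance": scale.provenance if needs_acacs else None,
    }
    X = np.vstack(rows) if rows else np.empty((0, len(names)))
    return EncodedMatrix(
        ids=dataset.ids, feature_names=names, X=X, encoder_meta=meta
    )
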
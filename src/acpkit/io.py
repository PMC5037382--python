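"""FASTA input/output for labeled peptide datasets.

Peptide sets are carried as :class:`PeptideDataset` objects: ordered
collections of validated :class:`PeptideRecord` entries over the 20
canonical amino-acid letters, each optionally tagged ``positive``
(anticancer) or ``negative``.  Class labels travel out-of-band, either by
reading one FASTA file per class or through a two-column ``id<TAB>label``
TSV, mirroring the class-separated benchmark files this kind of predictor
is trained on.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_ALPHABET)
#: IUPAC ambiguity / non-standard one-letter codes handled by the
#: ``ambiguous`` policies; anything else in a sequence is always an error.
AMBIGUOUS_CODES = frozenset("BJOUXZ")

LABELS = ("positive", "negative")


class FastaError(ValueError):
    """Malformed FASTA text (bad header, duplicate or empty id)."""


class AlphabetError(ValueError):
    """A sequence contains a character outside the canonical 20 letters."""


@dataclass(frozen=True)
class PeptideRecord:
    """One identified peptide sequence with an optional class label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("record id must be a non-empty string")
        if not self.sequence:
            raise AlphabetError(f"record {self.id!r}: sequence must be non-empty")
        bad = [c for c in self.sequence if c not in _CANONICAL_SET]
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: non-canonical residue {bad[0]!r} "
                f"(alphabet is {CANONICAL_ALPHABET})"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValueError(
                f"record {self.id!r}: label must be one of {LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideDataset:
    """Ordered collection of peptide records with unique ids."""

    records: list[PeptideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FastaError(f"duplicate record id {rec.id!r} in dataset")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    @property
    def n_pos(self) -> int:
        return sum(1 for r in self.records if r.label == "positive")

    @property
    def n_neg(self) -> int:
        return sum(1 for r in self.records if r.label == "negative")

    def with_labels(self, mapping: Mapping[str, str]) -> "PeptideDataset":
        """Return a copy with labels attached from an id -> label mapping."""
        missing = [r.id for r in self.records if r.id not in mapping]
        if missing:
            raise KeyError(f"no label for record id(s): {', '.join(missing[:5])}")
        return PeptideDataset(
            [replace(r, label=mapping[r.id]) for r in self.records]
        )

    def subset(self, indices: Iterable[int]) -> "PeptideDataset":
        return PeptideDataset([self.records[i] for i in indices])


def _as_text_handle(source) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def read_fasta(
    source,
    label: str | None = None,
    ambiguous: str = "strict",
) -> PeptideDataset:
    """Read a FASTA file (path or text handle) into a :class:`PeptideDataset`.

    Sequences are upper-cased and whitespace-stripped.  ``label``, if given,
    is attached to every record.  ``ambiguous`` controls the handling of the
    non-canonical codes B, J, O, U, X, Z:

    - ``"strict"`` (default): raise :class:`AlphabetError` naming the record;
    - ``"drop-record"``: silently omit records containing such codes;
    - ``"delete-residue"``: remove the offending characters.

    Characters outside both the canonical alphabet and the ambiguity codes
    are always an error.
    """
    if ambiguous not in ("strict", "drop-record", "delete-residue"):
        raise ValueError(f"unknown ambiguous-residue policy {ambiguous!r}")
    handle, owned = _as_text_handle(source)
    try:
        text = handle.read()
    finally:
        if owned:
            handle.close()

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaError(
                f"line {lineno}: expected FASTA header ('>') before sequence data"
            )
        break

    records: list[PeptideRecord] = []
    for title, seq in SeqIO.FastaIO.SimpleFastaParser(_stdio.StringIO(text)):
        rec_id = title.split()[0] if title.split() else ""
        if not rec_id:
            raise FastaError("FASTA header with empty id ('>' line has no name)")
        sequence = "".join(seq.split()).upper()
        bad = sorted(set(sequence) - _CANONICAL_SET)
        if bad:
            hard_bad = [c for c in bad if c not in AMBIGUOUS_CODES]
            if hard_bad:
                raise AlphabetError(
                    f"record {rec_id!r}: invalid character {hard_bad[0]!r}"
                )
            if ambiguous == "strict":
                raise AlphabetError(
                    f"record {rec_id!r}: ambiguous residue {bad[0]!r} "
                    "(policy 'strict'; see ambiguous= options)"
                )
            if ambiguous == "drop-record":
                continue
            sequence = "".join(c for c in sequence if c in _CANONICAL_SET)
            if not sequence:
                raise AlphabetError(
                    f"record {rec_id!r}: empty sequence after deleting "
                    "ambiguous residues"
                )
        records.append(PeptideRecord(id=rec_id, sequence=sequence, label=label))
    return PeptideDataset(records)


def write_fasta(dataset: PeptideDataset, sink) -> None:
    """Write a non-empty dataset as wrapped FASTA (path or text handle)."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in dataset
    ]
    if hasattr(sink, "write"):
        SeqIO.write(seq_records, sink, "fasta")
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            SeqIO.write(seq_records, fh, "fasta")


def read_labels(source) -> dict[str, str]:
    """Read a two-column ``id<TAB>label`` TSV (no header) into a dict."""
    handle, owned = _as_text_handle(source)
    try:
        mapping: dict[str, str] = {}
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"label TSV line {lineno}: expected 2 tab-separated columns"
                )
            rec_id, lab = parts[0].strip(), parts[1].strip()
            if lab not in LABELS:
                raise ValueError(
                    f"label TSV line {lineno}: label must be one of {LABELS}"
                )
            if rec_id in mapping:
                raise ValueError(f"label TSV line {lineno}: duplicate id {rec_id!r}")
            mapping[rec_id] = lab
        return mapping
    finally:
        if owned:
            handle.close()


def write_labels(dataset: PeptideDataset, sink) -> None:
    """Write ``id<TAB>label`` rows for every labeled record."""
    lines = [f"{r.id}\t{r.label}\n" for r in dataset if r.label is not None]
    if hasattr(sink, "write"):
        sink.writelines(lines)
    else:
        Path(sink).write_text("".join(lines), encoding="utf-8")


def concat_datasets(*datasets: PeptideDataset) -> PeptideDataset:
    """Concatenate datasets (ids must stay globally unique)."""
    records: list[PeptideRecord] = []
    for ds in datasets:
        records.extend(ds.records)
    return PeptideDataset(records)
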
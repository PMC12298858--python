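"""Reading, writing and validating barcode sequence datasets.

Sequences are normalised to an uppercase IUPAC DNA alphabet (U mapped to T)
on ingestion so every downstream comparison operates in one canonical space.
Records carry their provenance (``field`` specimen vs ``reference`` accession)
together with optional species/genus annotations and the survey sampling unit
they were collected in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO

from .errors import FastaParseError, ValidationError

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

SOURCES = ("field", "reference")


def normalize_sequence(seq: str) -> str:
    """Canonicalise a raw sequence string: strip, uppercase, RNA U -> T."""
    s = seq.strip().upper().replace("U", "T")
    bad = set(s) - IUPAC_DNA
    if bad:
        raise ValidationError(
            f"sequence contains non-IUPAC characters: {sorted(bad)}"
        )
    if not s:
        raise ValidationError("empty sequence")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence with provenance and optional annotations."""

    id: str
    sequence: str
    source: str  # "field" | "reference"
    species_name: Optional[str] = None
    genus: Optional[str] = None
    sampling_unit: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValidationError(f"unknown source {self.source!r}")
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


class Dataset:
    """An ordered collection of :class:`SequenceRecord` with unique ids."""

    def __init__(self, records: Iterable[SequenceRecord]):
        self.records: list[SequenceRecord] = list(records)
        self._by_id: dict[str, SequenceRecord] = {}
        for rec in self.records:
            if rec.id in self._by_id:
                raise ValidationError(f"duplicate record id {rec.id!r}")
            self._by_id[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, rec_id: str) -> SequenceRecord:
        return self._by_id[rec_id]

    def __contains__(self, rec_id: str) -> bool:
        return rec_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def counts_by_source(self) -> dict[str, int]:
        out = {s: 0 for s in SOURCES}
        for r in self.records:
            out[r.source] += 1
        return out

    def counts_by_genus(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            key = r.genus or ""
            out[key] = out.get(key, 0) + 1
        return out

    def subset(self, ids: Iterable[str]) -> "Dataset":
        wanted = set(ids)
        return Dataset(r for r in self.records if r.id in wanted)

    def merge(self, other: "Dataset") -> "Dataset":
        return Dataset(list(self.records) + list(other.records))


def read_fasta(
    path: str | Path,
    source: str = "field",
    annotations: str | Path | None = None,
) -> Dataset:
    """Read a FASTA file (and optional annotation TSV) into a :class:`Dataset`.

    The annotation table is a TSV with a header row and columns
    ``id, species_name, genus, sampling_unit`` (all but ``id`` optional);
    its ids must be a subset of the FASTA ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # Biopython signals malformed input this way
        first = path.read_text().split("\n", 1)[0]
        raise FastaParseError(
            f"{path}: not parseable as FASTA (first line: {first!r}): {exc}"
        ) from exc
    if not parsed:
        # distinguish empty file from one with no '>' header
        text = path.read_text()
        if text.strip():
            first = text.strip().splitlines()[0]
            raise FastaParseError(
                f"{path}: no FASTA records; first line is {first!r}"
            )
    for seqrec in parsed:
        if seqrec.id in seen:
            raise ValidationError(f"{path}: duplicate record id {seqrec.id!r}")
        seen.add(seqrec.id)
        records.append(
            SequenceRecord(id=seqrec.id, sequence=str(seqrec.seq), source=source)
        )
    dataset = Dataset(records)
    if annotations is not None:
        dataset = _join_annotations(dataset, Path(annotations))
    return dataset


def _join_annotations(dataset: Dataset, table_path: Path) -> Dataset:
    table = pd.read_csv(table_path, sep="\t", dtype=str)
    if "id" not in table.columns:
        raise ValidationError(f"{table_path}: annotation table lacks 'id' column")
    orphans = sorted(set(table["id"]) - set(dataset.ids))
    if orphans:
        raise ValidationError(
            f"{table_path}: annotation ids absent from FASTA: {orphans}"
        )
    ann = table.set_index("id")
    updated = []
    for rec in dataset:
        if rec.id in ann.index:
            row = ann.loc[rec.id]
            kwargs = {}
            for col in ("species_name", "genus", "sampling_unit"):
                if col in ann.columns and pd.notna(row[col]) and str(row[col]).strip():
                    kwargs[col] = str(row[col]).strip()
            rec = replace(rec, **kwargs)
        updated.append(rec)
    return Dataset(updated)


def write_fasta(dataset: Dataset, path: str | Path, width: int = 70) -> None:
    """Write a dataset to FASTA. Round-trips ids and sequences exactly."""
    if len(dataset) == 0:
        raise ValidationError("refusing to write an empty dataset")
    path = Path(path)
    with path.open("w") as fh:
        for rec in dataset:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_annotations(dataset: Dataset, path: str | Path) -> None:
    """Write the annotation TSV (id, species_name, genus, sampling_unit)."""
    rows = [
        {
            "id": r.id,
            "species_name": r.species_name or "",
            "genus": r.genus or "",
            "sampling_unit": r.sampling_unit or "",
        }
        for r in dataset
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class RejectionReport:
    """Ids rejected by a filter, with the offending lengths."""

    rejected: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rejected)


def length_sanity_filter(
    dataset: Dataset, min_len: int = 400, max_len: int = 1200
) -> tuple[Dataset, RejectionReport]:
    """Keep records whose length lies in [min_len, max_len].

    A crude stand-in for marker-region verification: full-length fungal ITS
    amplicons fall in a predictable size window, so records far outside it
    are fragments or off-target products.
    """
    if not (0 < min_len < max_len):
        raise ValidationError(f"invalid length bounds [{min_len}, {max_len}]")
    kept, report = [], RejectionReport()
    for rec in dataset:
        if min_len <= len(rec) <= max_len:
            kept.append(rec)
        else:
            report.rejected[rec.id] = len(rec)
    if not kept:
        warnings.warn("length filter rejected every record", stacklevel=2)
    return Dataset(kept), report
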
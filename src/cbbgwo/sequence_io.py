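"""Reading, labelling and cleaning of protein sequence datasets.

FASTA input is parsed with Biopython; class labels come from a two-column
TSV (``id<TAB>label``).  Cleaning applies, in a fixed order, the filters a
tripeptide-composition pipeline needs: drop empty sequences, drop sequences
shorter than ``min_length`` residues (the default of 20 keeps length-20
sequences), drop exact duplicate sequences keeping the first occurrence,
and -- under the strict alphabet policy -- drop sequences containing
residues outside the 20-letter canonical amino-acid alphabet.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)

#: residues that occur in real databases but are outside the canonical 20
AMBIGUOUS_AA = frozenset("BJOUXZ")


class FastaParseError(ValueError):
    """Raised when a file is not parseable as FASTA."""


@dataclass(frozen=True)
class ProteinRecord:
    """One (optionally labelled) amino-acid sequence."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PreprocessReport:
    """Tally of records removed by each cleaning filter."""

    n_input: int = 0
    n_removed_short: int = 0
    n_removed_duplicate: int = 0
    n_removed_invalid: int = 0
    n_kept: int = 0
    removed_ids: list[tuple[str, str]] = field(default_factory=list)

    def _check(self) -> None:
        total = (self.n_kept + self.n_removed_short
                 + self.n_removed_duplicate + self.n_removed_invalid)
        if self.n_input != total:
            raise ValueError(
                f"inconsistent report: n_input={self.n_input} != {total}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input": self.n_input,
            "n_removed_short": self.n_removed_short,
            "n_removed_duplicate": self.n_removed_duplicate,
            "n_removed_invalid": self.n_removed_invalid,
            "n_kept": self.n_kept,
            "removed_ids": [list(t) for t in self.removed_ids],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a FASTA file into unlabelled :class:`ProteinRecord` objects.

    Wrapped sequence lines are concatenated, whitespace stripped and
    residues upper-cased; record order is preserved.  A record with an
    empty sequence, or non-FASTA content before the first ``>`` header,
    raises :class:`FastaParseError`.
    """
    path = Path(path)
    with open(path) as handle:
        # Biopython tolerates leading junk; reject it explicitly.
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: content before first '>' header")
                break
        handle.seek(0)
        records = []
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).replace(" ", "").upper()
            if not seq:
                raise FastaParseError(f"{path}: empty sequence for '{rec.id}'")
            records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA (60-column wrap, Biopython writer)."""
    seq_records = [SeqRecord(Seq(r.sequence), id=r.id, description="")
                   for r in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_label_table(path: str | Path) -> pd.DataFrame:
    """Read an ``id<TAB>label`` TSV with a header row."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"id", "label"}
    if not expected.issubset(table.columns):
        raise ValueError(f"label table must have columns {sorted(expected)}, "
                         f"got {list(table.columns)}")
    return table[["id", "label"]]


def write_label_table(records: Iterable[ProteinRecord],
                      path: str | Path) -> None:
    rows = [(r.id, r.label) for r in records]
    pd.DataFrame(rows, columns=["id", "label"]).to_csv(
        path, sep="\t", index=False)


def attach_labels(records: Sequence[ProteinRecord],
                  labels: pd.DataFrame,
                  ) -> tuple[list[ProteinRecord], list[str]]:
    """Attach class labels to records from an (id, label) table.

    Returns the labelled records (input order) and the ids of records
    absent from the table, which are dropped.  A duplicate id in the label
    table, or an empty intersection of ids, is an error: the table must
    give exactly one class per id.
    """
    if labels["id"].duplicated().any():
        dupes = labels.loc[labels["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids in label table: {dupes}")
    mapping = dict(zip(labels["id"], labels["label"]))
    labelled, unlabelled = [], []
    for rec in records:
        if rec.id in mapping:
            labelled.append(ProteinRecord(rec.id, rec.sequence,
                                          mapping[rec.id]))
        else:
            unlabelled.append(rec.id)
    if records and not labelled:
        raise ValueError("no record id matches the label table")
    return labelled, unlabelled


def preprocess(records: Sequence[ProteinRecord],
               min_length: int = 20,
               alphabet_policy: str = "strict",
               ) -> tuple[list[ProteinRecord], PreprocessReport]:
    """Clean a labelled dataset for tripeptide-composition encoding.

    Filters are applied in a fixed, documented order:

    1. records with a missing/empty sequence (counted as invalid),
    2. records shorter than ``min_length`` residues (length == min_length
       is kept),
    3. exact duplicate sequences -- first occurrence by input order wins,
       labels are ignored for the comparison,
    4. under ``alphabet_policy="strict"``, records containing any residue
       outside the 20-letter canonical alphabet.

    The operation is idempotent: re-running it on its own output removes
    nothing.
    """
    if min_length < 3:
        raise ValueError("min_length must be >= 3 (one tripeptide window)")
    if alphabet_policy not in ("strict", "permissive"):
        raise ValueError(f"unknown alphabet_policy {alphabet_policy!r}")

    report = PreprocessReport(n_input=len(records))
    kept: list[ProteinRecord] = []
    seen_sequences: set[str] = set()
    for rec in records:
        if not rec.sequence:
            report.n_removed_invalid += 1
            report.removed_ids.append((rec.id, "empty"))
            continue
        if len(rec.sequence) < min_length:
            report.n_removed_short += 1
            report.removed_ids.append((rec.id, "short"))
            continue
        if rec.sequence in seen_sequences:
            report.n_removed_duplicate += 1
            report.removed_ids.append((rec.id, "duplicate"))
            continue
        if (alphabet_policy == "strict"
                and not _CANONICAL_SET.issuperset(rec.sequence)):
            report.n_removed_invalid += 1
            report.removed_ids.append((rec.id, "invalid_residue"))
            continue
        seen_sequences.add(rec.sequence)
        kept.append(rec)
    report.n_kept = len(kept)
    report._check()
    if not kept:
        raise ValueError("empty dataset after preprocessing")
    ids = [r.id for r in kept]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids after preprocessing")
    return kept, report
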
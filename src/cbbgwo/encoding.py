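"""Tripeptide-composition (TPC) encoding of protein sequences.

A sequence of length ``L`` has ``L - 2`` overlapping tripeptide windows.
The TPC vector holds, for each of the 20^3 = 8000 possible tripeptides
over the canonical alphabet, its window count divided by ``L - 2``.  With
a fully canonical sequence the entries therefore sum to one.

The tripeptide -> index map is lexicographic over the fixed residue order
``ACDEFGHIKLMNPQRSTVWY`` and is exposed 1-based ("AAA" -> 1, "YYY" ->
8000) so that reported feature indices are stable across runs; internal
arrays are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_io import CANONICAL_AA, ProteinRecord

N_FEATURES = 20 ** 3

_AA_TO_ORD = {aa: i for i, aa in enumerate(CANONICAL_AA)}

#: all 8000 tripeptide strings in index order (position k holds index k+1)
TRIPEPTIDES: tuple[str, ...] = tuple(
    a + b + c for a in CANONICAL_AA for b in CANONICAL_AA for c in CANONICAL_AA
)


def tripeptide_index(tripeptide: str, alphabet_policy: str = "strict") -> int:
    """Map a 3-residue string to its 1-based feature index in [1, 8000].

    In permissive mode a tripeptide containing a non-canonical residue
    returns 0, the "unindexed" sentinel.
    """
    if len(tripeptide) != 3:
        raise ValueError(f"need exactly 3 residues, got {tripeptide!r}")
    try:
        r1, r2, r3 = (_AA_TO_ORD[aa] for aa in tripeptide.upper())
    except KeyError:
        if alphabet_policy == "permissive":
            return 0
        raise ValueError(
            f"non-canonical residue in tripeptide {tripeptide!r}") from None
    return 400 * r1 + 20 * r2 + r3 + 1


def index_to_tripeptide(index: int) -> str:
    """Inverse of :func:`tripeptide_index` (1-based index -> string)."""
    if not 1 <= index <= N_FEATURES:
        raise ValueError(f"index {index} outside [1, {N_FEATURES}]")
    return TRIPEPTIDES[index - 1]


@dataclass(frozen=True)
class TpcVector:
    """8000-dimensional tripeptide frequency vector of one sequence."""

    values: np.ndarray
    source_id: str
    length: int

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"TPC vector must have {N_FEATURES} entries")


def encode_sequence(sequence: str,
                    alphabet_policy: str = "strict",
                    source_id: str = "") -> TpcVector:
    """Encode one amino-acid sequence as tripeptide frequencies.

    Counts each of the ``L - 2`` overlapping windows and divides by
    ``L - 2``.  In permissive mode, windows containing a non-canonical
    residue contribute to no count but the denominator stays ``L - 2``,
    so the entries may sum to less than one (documented deviation from
    strict normalisation).
    """
    sequence = sequence.upper()
    length = len(sequence)
    if length < 3:
        raise ValueError("no tripeptide window: sequence shorter than 3")
    codes = np.array([_AA_TO_ORD.get(aa, -1) for aa in sequence],
                     dtype=np.int64)
    if alphabet_policy == "strict" and (codes < 0).any():
        bad = sorted({aa for aa in sequence if aa not in _AA_TO_ORD})
        raise ValueError(f"non-canonical residues {bad} in strict mode")
    idx = 400 * codes[:-2] + 20 * codes[1:-1] + codes[2:]
    valid = (codes[:-2] >= 0) & (codes[1:-1] >= 0) & (codes[2:] >= 0)
    counts = np.bincount(idx[valid], minlength=N_FEATURES)
    values = counts.astype(np.float64) / (length - 2)
    return TpcVector(values=values, source_id=source_id, length=length)


@dataclass
class FeatureMatrix:
    """Stacked TPC vectors: one row per sequence, 8000 columns.

    ``labels`` is the parallel class vector and ``ids`` the parallel
    sequence identifiers; ``feature_names`` are the tripeptide strings in
    column order.
    """

    values: np.ndarray
    labels: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(f"feature matrix must be n x {N_FEATURES}")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must match row count")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ids length must match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return TRIPEPTIDES

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=list(TRIPEPTIDES))
        frame.insert(0, "label", self.labels)
        frame.insert(0, "id", self.ids)
        return frame

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path)
        values = frame[list(TRIPEPTIDES)].to_numpy(dtype=np.float64)
        return cls(values=values, labels=frame["label"].to_numpy(),
                   ids=frame["id"].astype(str).tolist())


def encode_dataset(records: Sequence[ProteinRecord],
                   alphabet_policy: str = "strict") -> FeatureMatrix:
    """Encode preprocessed records into a :class:`FeatureMatrix`."""
    if not records:
        raise ValueError("cannot encode an empty record list")
    rows = np.empty((len(records), N_FEATURES), dtype=np.float64)
    labels = []
    for k, rec in enumerate(records):
        try:
            rows[k] = encode_sequence(rec.sequence, alphabet_policy).values
        except ValueError as exc:
            raise ValueError(f"record {rec.id!r}: {exc}") from exc
        labels.append(rec.label)
    return FeatureMatrix(values=rows, labels=np.array(labels),
                         ids=[r.id for r in records])


@dataclass(frozen=True)
class FeatureSummary:
    """Population statistics over all entries of a feature matrix."""

    mean: float
    median: float
    standard_deviation: float
    variance: float

    def __post_init__(self) -> None:
        for name in ("mean", "median", "standard_deviation", "variance"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")


def summarize_features(matrix: FeatureMatrix,
                       per_feature: bool = False):
    """Summarise matrix entries (population statistics, ddof=0).

    With ``per_feature=True`` additionally returns a DataFrame of
    column-wise statistics.
    """
    flat = matrix.values.ravel()
    if flat.size == 0:
        raise ValueError("empty feature matrix")
    summary = FeatureSummary(
        mean=float(flat.mean()),
        median=float(np.median(flat)),
        standard_deviation=float(flat.std()),
        variance=float(flat.var()),
    )
    if not per_feature:
        return summary
    cols = matrix.values
    table = pd.DataFrame({
        "tripeptide": list(TRIPEPTIDES),
        "mean": cols.mean(axis=0),
        "median": np.median(cols, axis=0),
        "standard_deviation": cols.std(axis=0),
        "variance": cols.var(axis=0),
    })
    return summary, table
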
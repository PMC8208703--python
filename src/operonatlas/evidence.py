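"""Transcription-signal evidence and UTR biotype agreement.

ML2 is the mean, over the base positions of an annotation, of the maximum
log2 expression signal across all conditions at that position.  Signals are
taken as-is; no normalization is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .model import Interval, ModelError
from .utrs import UTR


@dataclass
class SignalMatrix:
    """Per-position log2 signal for a set of conditions.

    ``plus`` has shape (n_conditions, L) for positions 1..L; ``minus`` is
    optional and used for minus-strand annotations when present, otherwise
    the signal is treated as unstranded.
    """

    plus: np.ndarray
    minus: Optional[np.ndarray] = None
    conditions: tuple = ()

    def __post_init__(self) -> None:
        self.plus = np.asarray(self.plus, dtype=float)
        if self.plus.ndim != 2 or self.plus.shape[0] < 1:
            raise ModelError("signal matrix must be 2-D with >= 1 condition")
        if not np.all(np.isfinite(self.plus)):
            raise ModelError("signal values must be finite")
        if self.minus is not None:
            self.minus = np.asarray(self.minus, dtype=float)
            if self.minus.shape != self.plus.shape:
                raise ModelError("plus/minus signal shapes differ")

    @property
    def length(self) -> int:
        return self.plus.shape[1]

    def values_for(self, interval: Interval) -> np.ndarray:
        if interval.start < 1 or interval.end > self.length:
            raise ModelError(
                f"annotation [{interval.start}, {interval.end}] outside signal range 1..{self.length}"
            )
        mat = self.plus if (interval.strand == "+" or self.minus is None) else self.minus
        return mat[:, interval.start - 1 : interval.end]


def compute_ml2(annotation: Interval, signal: SignalMatrix) -> float:
    """Mean over positions of the per-position maximum across conditions."""
    values = signal.values_for(annotation)
    return float(values.max(axis=0).mean())


@dataclass(frozen=True)
class Ml2Summary:
    exceeded_by_90pct: float  # 10th percentile of ML2 across the set
    median: float
    n: int
    percentile_method: str = "linear interpolation"


def ml2_percentiles(annotations: Iterable[Interval], signal: SignalMatrix) -> Ml2Summary:
    """The ML2 value exceeded by 90 % of annotations, and the median."""
    values = np.array([compute_ml2(a, signal) for a in annotations])
    if values.size == 0:
        raise ModelError("cannot summarize an empty annotation set")
    p10, p50 = np.percentile(values, [10, 50], method="linear")
    return Ml2Summary(float(p10), float(p50), int(values.size))


def read_signal_tsv(path, length: int) -> SignalMatrix:
    """Ingest a (strand, position, condition, value) TSV as a SignalMatrix.

    Missing (position, condition) cells are filled with 0.
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"strand", "position", "condition", "value"}
    if not needed <= set(df.columns):
        raise ModelError(f"{path}: signal TSV needs columns {sorted(needed)}")
    conditions = tuple(sorted(df["condition"].unique()))
    cidx = {c: i for i, c in enumerate(conditions)}
    arrays = {}
    for strand in ("+", "-"):
        sub = df[df["strand"] == strand]
        if sub.empty:
            continue
        mat = np.zeros((len(conditions), length))
        mat[
            sub["condition"].map(cidx).to_numpy(),
            sub["position"].to_numpy(dtype=int) - 1,
        ] = sub["value"].to_numpy(dtype=float)
        arrays[strand] = mat
    if "+" not in arrays:
        raise ModelError(f"{path}: no plus-strand signal")
    return SignalMatrix(plus=arrays["+"], minus=arrays.get("-"), conditions=conditions)


AGREEMENT_COLUMNS = ("agree", "five_prime", "three_prime", "internal", "both_5p_3p", "no_overlap")


@dataclass
class AgreementTable:
    """Counts of biotype agreement between two UTR collections.

    Rows are source UTR classes.  Each source UTR is counted exactly once:
    in ``agree`` when it overlaps a same-strand target of its own class, in
    ``both_5p_3p`` when it overlaps both a 5' and a 3' target but none of its
    own class, otherwise in the column of the class(es) it overlaps, or in
    ``no_overlap``.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            0, index=list(("five_prime", "three_prime", "internal")), columns=list(AGREEMENT_COLUMNS)
        )
    )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def biotype_agreement(source_utrs: Iterable[UTR], target_utrs: Iterable[UTR]) -> AgreementTable:
    """Classify each source UTR by its same-strand overlaps with targets."""
    targets = list(target_utrs)
    out = AgreementTable()
    tbl = out.table
    for s in source_utrs:
        overlapped = {
            t.utr_class
            for t in targets
            if t.interval.strand == s.interval.strand and s.interval.overlap_bp(t.interval) > 0
        }
        if s.utr_class in overlapped:
            col = "agree"
        elif {"five_prime", "three_prime"} <= overlapped:
            col = "both_5p_3p"
        elif overlapped:
            col = sorted(overlapped)[0]
        else:
            col = "no_overlap"
        tbl.loc[s.utr_class, col] += 1
    return out
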
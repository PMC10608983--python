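"""Bucketed 1H NMR data tables.

A *bucket* (or bin) is a fixed-width chemical-shift interval over which
spectral intensity has been integrated; each bucket is one predictor
variable of the classification problem.  The convention throughout the
package is a half-open interval [low_ppm, high_ppm) labelled
``"low-high"`` with two decimals (e.g. ``"5.18-5.19"``), a width of
0.01 ppm for real data, and columns ordered by *descending* ppm — the
direction in which NMR spectra are conventionally drawn.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Bucket",
    "BucketTable",
    "AnnotationMap",
    "parse_bucket_label",
    "read_bucket_table",
    "write_bucket_table",
    "read_annotation_map",
    "write_annotation_map",
    "ppm_to_hz",
    "hz_to_ppm",
]

#: regular expression a bucket column header must match: two decimal
#: numbers (decimal point required) joined by "-"
_BUCKET_RE = re.compile(r"^\s*(\d+\.\d+)-(\d+\.\d+)\s*$")

_DELIMITERS = (",", ";", "\t")


class BucketParseError(ValueError):
    """A column header could not be parsed as a ppm interval."""


@dataclass(frozen=True, order=True)
class Bucket:
    """Half-open chemical-shift interval [low_ppm, high_ppm)."""

    low_ppm: float
    high_ppm: float

    def __post_init__(self) -> None:
        if not self.high_ppm - self.low_ppm > 0:
            raise ValueError(
                f"bucket width must be positive, got [{self.low_ppm}, {self.high_ppm})"
            )

    @property
    def width_ppm(self) -> float:
        return self.high_ppm - self.low_ppm

    @property
    def center_ppm(self) -> float:
        return 0.5 * (self.low_ppm + self.high_ppm)

    @property
    def label(self) -> str:
        return f"{self.low_ppm:.2f}-{self.high_ppm:.2f}"

    def __contains__(self, ppm: float) -> bool:
        return self.low_ppm <= ppm < self.high_ppm


def parse_bucket_label(label: str) -> Bucket:
    """Parse a ``"low-high"`` header token into a :class:`Bucket`.

    Both endpoints must be decimal numbers with an explicit decimal
    point; anything else (``"5.18-519"``, stray text, reversed bounds)
    raises :class:`BucketParseError` naming the offending token.
    """
    m = _BUCKET_RE.match(label)
    if m is None:
        raise BucketParseError(f"cannot parse bucket column {label!r} as 'low-high' ppm interval")
    low, high = float(m.group(1)), float(m.group(2))
    if not high > low:
        raise BucketParseError(f"bucket column {label!r} has non-positive width")
    return Bucket(low, high)


def ppm_to_hz(delta_ppm: float, frequency_mhz: float) -> float:
    """Convert a chemical-shift difference to Hz.

    At a proton frequency of ``frequency_mhz`` MHz, 1 ppm corresponds to
    ``frequency_mhz`` Hz; a 0.01 ppm bucket at 400 MHz is exactly 4 Hz
    wide.
    """
    if not frequency_mhz > 0:
        raise ValueError(f"spectrometer frequency must be positive, got {frequency_mhz}")
    return delta_ppm * frequency_mhz


def hz_to_ppm(delta_hz: float, frequency_mhz: float) -> float:
    """Inverse of :func:`ppm_to_hz`."""
    if not frequency_mhz > 0:
        raise ValueError(f"spectrometer frequency must be positive, got {frequency_mhz}")
    return delta_hz / frequency_mhz


@dataclass
class BucketTable:
    """Samples x buckets intensity matrix with class labels.

    Invariants enforced at construction: matching shapes, unique sample
    ids, finite non-negative intensities, and buckets sorted by strictly
    descending ppm with pairwise disjoint intervals.
    """

    intensities: np.ndarray
    sample_ids: list[str]
    class_labels: list[str]
    buckets: list[Bucket]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.class_labels = [str(c) for c in self.class_labels]
        self.buckets = list(self.buckets)
        n, p = self.intensities.shape if self.intensities.ndim == 2 else (0, 0)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-d samples x buckets matrix")
        if n == 0:
            raise ValueError("a BucketTable must contain at least one sample")
        if len(self.sample_ids) != n or len(self.class_labels) != n:
            raise ValueError(
                f"row count mismatch: {n} intensity rows, {len(self.sample_ids)} sample ids, "
                f"{len(self.class_labels)} class labels"
            )
        if len(self.buckets) != p:
            raise ValueError(f"column count mismatch: {p} columns, {len(self.buckets)} buckets")
        if len(set(self.sample_ids)) != n:
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities contain missing or non-finite values")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        for a, b in zip(self.buckets, self.buckets[1:]):
            if b.high_ppm > a.low_ppm + 1e-9:
                raise ValueError(
                    f"buckets must be disjoint and sorted by descending ppm; "
                    f"{a.label} is followed by {b.label}"
                )

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_buckets(self) -> int:
        return self.intensities.shape[1]

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.buckets]

    @property
    def classes(self) -> list[str]:
        """Distinct class labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.class_labels:
            seen.setdefault(c)
        return list(seen)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.class_labels:
            counts[c] = counts.get(c, 0) + 1
        return counts

    def column(self, label: str) -> np.ndarray:
        return self.intensities[:, self.labels.index(label)]

    def select(self, labels: Sequence[str]) -> "BucketTable":
        """Subset of bucket columns, in descending-ppm order."""
        idx = [self.labels.index(l) for l in labels]
        idx.sort()
        return BucketTable(
            self.intensities[:, idx],
            list(self.sample_ids),
            list(self.class_labels),
            [self.buckets[i] for i in idx],
        )

    def to_dataframe(self, label_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.labels)
        df.insert(0, label_column, self.class_labels)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str = "class", id_column: str = "sample_id"
    ) -> "BucketTable":
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found")
        if id_column in df.columns:
            ids = df[id_column].astype(str).tolist()
        else:
            ids = [str(i) for i in df.index]
        bucket_cols = [c for c in df.columns if c not in (label_column, id_column)]
        buckets = [parse_bucket_label(str(c)) for c in bucket_cols]
        values = df[bucket_cols].to_numpy()
        if values.dtype == object or not np.issubdtype(values.dtype, np.number):
            raise ValueError("bucket columns contain non-numeric values")
        return cls(values.astype(np.float64), ids, df[label_column].astype(str).tolist(), buckets)


# ----------------------------------------------------------------------
# delimited-text I/O


def _sniff_delimiter(header_line: str) -> str:
    present = [d for d in _DELIMITERS if d in header_line]
    if not present:
        raise ValueError("could not detect a delimiter (expected comma, semicolon or tab)")
    if len(present) > 1:
        names = {",": "comma", ";": "semicolon", "\t": "tab"}
        raise ValueError(
            "ambiguous delimiter: header contains " + " and ".join(names[d] for d in present)
        )
    return present[0]


def read_bucket_table(
    path: str | Path,
    label_column: str = "class",
    *,
    id_column: str = "sample_id",
    transpose: bool = False,
    delimiter: str | None = None,
) -> BucketTable:
    """Read a delimited bucket table.

    The expected layout is one row per sample with an id column, a class
    label column, and one column per bucket headed ``"low-high"`` in
    ppm.  ``transpose=True`` accepts the other dialect (buckets as
    rows).  The delimiter is auto-detected among comma/semicolon/tab
    unless given explicitly; mixed delimiters are rejected.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = delimiter or _sniff_delimiter(header.rstrip("\n"))
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, engine="python")
    if transpose:
        df = df.set_index(df.columns[0]).T.reset_index(names=id_column)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path.name}")
    first = df.columns[0]
    ids = df[first].tolist() if first != label_column else [str(i) for i in df.index]
    bucket_cols = [c for c in df.columns if c not in (first, label_column, id_column)]
    buckets = [parse_bucket_label(str(c)) for c in bucket_cols]
    raw = df[bucket_cols].to_numpy()
    if (raw == "").any():
        rows, cols = np.nonzero(raw == "")
        raise ValueError(
            f"missing values, e.g. sample {ids[rows[0]]!r} bucket {bucket_cols[cols[0]]!r}"
        )
    try:
        values = raw.astype(np.float64)
    except ValueError as exc:
        raise ValueError(f"non-numeric intensity value: {exc}") from exc
    return BucketTable(values, ids, df[label_column].tolist(), buckets)


def write_bucket_table(
    table: BucketTable,
    path: str | Path,
    *,
    label_column: str = "class",
    delimiter: str = ",",
) -> Path:
    """Write a bucket table such that :func:`read_bucket_table` inverts it.

    Floats are written with :func:`repr` precision, so a write/read
    roundtrip is the identity to full double precision.
    """
    path = Path(path)
    if table.n_samples == 0:  # pragma: no cover - unconstructible, guarded anyway
        raise ValueError("refusing to write an empty table")
    df = table.to_dataframe(label_column=label_column)
    df.to_csv(path, sep=delimiter, index=False, float_format=None, encoding="utf-8")
    return path


# ----------------------------------------------------------------------
# bucket -> metabolite annotations


@dataclass
class AnnotationMap:
    """Mapping bucket label -> set of (metabolite, signal id).

    A signal id groups the buckets carrying the same multiplet; a bucket
    may map to several metabolites when signals are superimposed.
    """

    entries: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, bucket_label: str, metabolite: str, signal_id: str) -> None:
        self.entries.setdefault(bucket_label, set()).add((metabolite, signal_id))

    def metabolites(self, bucket_label: str) -> set[str]:
        return {m for m, _ in self.entries.get(bucket_label, set())}

    def signal_groups(self) -> dict[str, list[str]]:
        """Signal id -> bucket labels carrying that signal (sorted)."""
        groups: dict[str, set[str]] = {}
        for label, pairs in self.entries.items():
            for _, sid in pairs:
                groups.setdefault(sid, set()).add(label)
        return {sid: sorted(labels) for sid, labels in sorted(groups.items())}

    def metabolite_buckets(self) -> dict[str, list[str]]:
        """Metabolite -> bucket labels assigned to it (sorted)."""
        out: dict[str, set[str]] = {}
        for label, pairs in self.entries.items():
            for met, _ in pairs:
                out.setdefault(met, set()).add(label)
        return {m: sorted(v) for m, v in sorted(out.items())}

    def validate_against(self, table: BucketTable) -> None:
        known = set(table.labels)
        unknown = sorted(set(self.entries) - known)
        if unknown:
            raise ValueError(f"annotated buckets absent from table: {unknown}")


def read_annotation_map(path: str | Path) -> AnnotationMap:
    amap = AnnotationMap()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"bucket_label", "metabolite", "signal_id"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"annotation table must have columns {sorted(required)}")
        for row in reader:
            amap.add(row["bucket_label"], row["metabolite"], row["signal_id"])
    return amap


def write_annotation_map(amap: AnnotationMap, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bucket_label", "metabolite", "signal_id"])
        for label in sorted(amap.entries):
            for met, sid in sorted(amap.entries[label]):
                writer.writerow([label, met, sid])
    return path
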
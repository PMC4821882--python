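"""Sequence→TIR tables and ranked-library results.

A :class:`TirDataset` maps every explicit sequence of a randomized RBS
window (length L, alphabet ACGT) to a positive predicted translation
initiation rate in arbitrary units, as exported by an external RBS
prediction tool.  A complete window has 4^L entries (65,536 for L=8).
TIRs are kept in input units throughout; target distributions carry the
range instead.
"""

from __future__ import annotations

import hashlib
import io
import json
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .iupac import BASE_INDEX, degeneracy, expand, validate

__all__ = [
    "TirDataset",
    "RankedLibrary",
    "MissingMembersError",
    "TableFormatError",
    "read_tir_table",
    "tirs_for",
    "write_results",
    "read_results",
]

_ACGT_RE = re.compile(r"^[ACGTacgt]+$")


class TableFormatError(ValueError):
    """Malformed sequence→TIR table."""


class MissingMembersError(KeyError):
    """A degenerate candidate expands to sequences absent from the dataset."""

    def __init__(self, sequence: str, missing: list[str]):
        self.sequence = sequence
        self.missing = missing
        shown = ", ".join(missing[:5]) + ("..." if len(missing) > 5 else "")
        super().__init__(
            f"candidate {sequence!r}: {len(missing)} expansion member(s) "
            f"absent from dataset: {shown}"
        )


@dataclass
class TirDataset:
    """Explicit sequence → TIR map for one randomized window.

    entries keys are length-L ACGT strings; values are finite positive
    floats (arbitrary units).  ``is_complete`` records whether all 4^L
    sequences are present; completeness is a flag, not a requirement.
    """

    entries: dict[str, float]
    label: str = ""
    window_length: int = field(init=False)

    def __post_init__(self):
        if not self.entries:
            raise ValueError("empty dataset")
        lengths = {len(s) for s in self.entries}
        if len(lengths) != 1:
            raise TableFormatError(f"inconsistent sequence lengths: {sorted(lengths)}")
        self.window_length = lengths.pop()
        for s, v in self.entries.items():
            if not _ACGT_RE.match(s):
                raise TableFormatError(f"non-ACGT sequence {s!r}")
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"TIR for {s!r} must be finite and > 0, got {v}")
        self._vector = None

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    @property
    def is_complete(self) -> bool:
        return len(self.entries) == 4**self.window_length

    @property
    def tir_min(self) -> float:
        return min(self.entries.values())

    @property
    def tir_max(self) -> float:
        return max(self.entries.values())

    @property
    def tir_range(self) -> tuple[float, float]:
        return self.tir_min, self.tir_max

    def encode(self, seq: str) -> int:
        """Base-4 index of an explicit sequence (A=0, C=1, G=2, T=3)."""
        i = 0
        for b in seq.upper():
            i = i * 4 + BASE_INDEX[b]
        return i

    def tir_vector(self) -> np.ndarray:
        """TIRs as a dense array indexed by :meth:`encode`; NaN = absent.

        Cached; this is the lookup table the vectorized search gathers from.
        """
        if self._vector is None:
            v = np.full(4**self.window_length, np.nan)
            for s, t in self.entries.items():
                v[self.encode(s)] = t
            self._vector = v
        return self._vector

    def all_tirs(self) -> np.ndarray:
        return np.fromiter(self.entries.values(), dtype=float, count=len(self.entries))

    def digest(self) -> str:
        """Order-independent sha256 digest of the (sequence, TIR) pairs."""
        h = hashlib.sha256()
        for s in sorted(self.entries):
            h.update(f"{s}\t{self.entries[s]!r}\n".encode())
        return h.hexdigest()[:16]


@dataclass
class RankedLibrary:
    """One scored candidate: a degenerate sequence, its member TIR multiset
    (sorted ascending, size == degeneracy) and its KS distance to the target."""

    sequence: str
    tirs: np.ndarray
    dks: float
    rank: int

    def __post_init__(self):
        self.tirs = np.sort(np.asarray(self.tirs, dtype=float))
        if len(self.tirs) != degeneracy(self.sequence):
            raise ValueError(
                f"{self.sequence!r}: {len(self.tirs)} TIRs for degeneracy "
                f"{degeneracy(self.sequence)}"
            )
        if not 0.0 <= self.dks <= 1.0:
            raise ValueError(f"dks out of [0,1]: {self.dks}")

    @property
    def degeneracy(self) -> int:
        return len(self.tirs)


def _sniff(path_or_buf, delimiter):
    if delimiter is not None:
        return delimiter
    if hasattr(path_or_buf, "read"):
        head = path_or_buf.readline()
        path_or_buf.seek(0)
    else:
        with open(path_or_buf) as fh:
            head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_tir_table(
    path,
    sequence_column: str | int | None = None,
    tir_column: str | int | None = None,
    delimiter: str | None = None,
    label: str = "",
) -> TirDataset:
    """Read a TSV/CSV sequence→TIR table (external predictor export style).

    The header row is auto-detected (a first row whose fields are neither an
    ACGT word nor a number is treated as a header).  Columns are picked by
    name patterns /seq/i and /tir|rate/i unless given explicitly (by name or
    0-based position).  Duplicate rows with identical TIR collapse; a
    duplicate sequence with a conflicting TIR is an error.
    """
    sep = _sniff(path, delimiter)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.empty:
        raise TableFormatError(f"empty table: {path}")

    first = [str(v) for v in df.iloc[0]]

    def _headerish(v):
        if _ACGT_RE.match(v):
            return False
        try:
            float(v)
            return False
        except ValueError:
            return True

    has_header = any(_headerish(v) for v in first)
    if has_header:
        df.columns = first
        df = df.iloc[1:].reset_index(drop=True)

    def _resolve(col, pattern, default_pos, what):
        if isinstance(col, int):
            return df.columns[col]
        if col is not None:
            if col not in df.columns:
                raise TableFormatError(f"{what} column {col!r} not in {list(df.columns)}")
            return col
        if has_header:
            for c in df.columns:
                if re.search(pattern, str(c), re.I):
                    return c
            raise TableFormatError(
                f"no column matching /{pattern}/i for {what} in {list(df.columns)}"
            )
        return df.columns[default_pos]

    seq_col = _resolve(sequence_column, r"seq", 0, "sequence")
    rate_col = _resolve(tir_column, r"tir|rate", 1, "TIR")

    entries: dict[str, float] = {}
    offset = 2 if has_header else 1  # 1-based data line numbers in the file
    for i, (s, t) in enumerate(zip(df[seq_col], df[rate_col])):
        line = i + offset
        s = str(s).strip().upper()
        if not _ACGT_RE.match(s):
            raise TableFormatError(f"line {line}: non-ACGT sequence {s!r}")
        try:
            tir = float(t)
        except (TypeError, ValueError):
            raise TableFormatError(f"line {line}: non-numeric TIR {t!r}") from None
        if not np.isfinite(tir) or tir <= 0:
            raise ValueError(f"line {line}: TIR must be finite and > 0, got {tir}")
        if s in entries and entries[s] != tir:
            raise TableFormatError(
                f"line {line}: duplicate sequence {s!r} with conflicting TIRs "
                f"{entries[s]} vs {tir}"
            )
        entries[s] = tir
    return TirDataset(entries=entries, label=label)


def write_tir_table(dataset: TirDataset, path, delimiter: str = "\t") -> None:
    """Write a dataset back out as a two-column sequence/TIR table."""
    with open(path, "w") as fh:
        fh.write(f"sequence{delimiter}tir\n")
        for s in sorted(dataset.entries):
            fh.write(f"{s}{delimiter}{dataset.entries[s]!r}\n")


def tirs_for(seq: str, data: TirDataset) -> np.ndarray:
    """Member TIR multiset of a degenerate candidate on a dataset.

    Returns the TIRs of all expansion members (in expansion order, size ==
    degeneracy; ties preserved).  Raises :class:`MissingMembersError` if any
    member is absent.
    """
    seq = validate(seq)
    if len(seq) != data.window_length:
        raise ValueError(
            f"candidate length {len(seq)} != window length {data.window_length}"
        )
    members = expand(seq)
    missing = [m for m in members if m not in data.entries]
    if missing:
        raise MissingMembersError(seq, missing)
    return np.array([data.entries[m] for m in members], dtype=float)


_TSV_COLUMNS = ["rank", "degenerate_sequence", "degeneracy", "dks", "member_tirs"]


def write_results(
    libraries: list[RankedLibrary],
    path,
    format: str = "tsv",
    config: dict | None = None,
    dataset_digest: str | None = None,
) -> None:
    """Write a ranked-library list as TSV or JSON (bit-stable).

    TSV columns: rank, degenerate_sequence, degeneracy, dks, member TIRs
    (semicolon-joined, ascending).  The JSON variant carries the same fields
    plus the run configuration and dataset digest.
    """
    if not libraries:
        raise ValueError("refusing to write an empty result list")
    ranks = [lib.rank for lib in libraries]
    if ranks != list(range(1, len(libraries) + 1)):
        raise ValueError(f"inconsistent ranks: {ranks}")
    if any(a.dks > b.dks for a, b in zip(libraries, libraries[1:])):
        raise ValueError("dks must be non-decreasing with rank")

    if format == "tsv":
        buf = io.StringIO()
        buf.write("\t".join(_TSV_COLUMNS) + "\n")
        for lib in libraries:
            tirs = ";".join(repr(float(t)) for t in lib.tirs)
            buf.write(
                f"{lib.rank}\t{lib.sequence}\t{lib.degeneracy}\t{lib.dks!r}\t{tirs}\n"
            )
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    elif format == "json":
        doc = {
            "config": config or {},
            "dataset_digest": dataset_digest,
            "libraries": [
                {
                    "rank": lib.rank,
                    "degenerate_sequence": lib.sequence,
                    "degeneracy": lib.degeneracy,
                    "dks": lib.dks,
                    "member_tirs": [float(t) for t in lib.tirs],
                }
                for lib in libraries
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path, format: str = "tsv") -> list[RankedLibrary]:
    """Read back a result file written by :func:`write_results`."""
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns) != _TSV_COLUMNS:
            raise TableFormatError(f"unexpected result columns {list(df.columns)}")
        return [
            RankedLibrary(
                sequence=row.degenerate_sequence,
                tirs=np.array([float(v) for v in row.member_tirs.split(";")]),
                dks=float(row.dks),
                rank=int(row.rank),
            )
            for row in df.itertuples()
        ]
    if format == "json":
        with open(path) as fh:
            doc = json.load(fh)
        return [
            RankedLibrary(
                sequence=d["degenerate_sequence"],
                tirs=np.array(d["member_tirs"], dtype=float),
                dks=d["dks"],
                rank=d["rank"],
            )
            for d in doc["libraries"]
        ]
    raise ValueError(f"unknown format {format!r}")
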
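"""Restriction-fragment coordinate system and on-disk formats.

Everything downstream (bias factors, contact profiles, DIR calls) is indexed
against a :class:`FragmentMap`: the ordered, contiguous tiling of a chromosome
by restriction fragments.  Coordinates are 0-based half-open (BED convention)
throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FragmentMap",
    "Viewpoint",
    "CaptureTable",
    "digest_sequence",
    "read_capture_table",
    "write_track",
    "read_track",
]

_VALID_DNA = re.compile(r"^[ACGTNacgtn]+$")


class InputError(ValueError):
    """Malformed user input (sequences, tables, intervals)."""


@dataclass(frozen=True)
class FragmentMap:
    """Ordered restriction fragments tiling one chromosome.

    Fragments are sorted, non-overlapping and contiguous over the digested
    span; every fragment has positive length, so midpoints are strictly
    increasing.
    """

    chromosome: str
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=np.int64)
        ends = np.asarray(self.ends, dtype=np.int64)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "ends", ends)
        if starts.shape != ends.shape or starts.ndim != 1 or starts.size == 0:
            raise InputError("fragment map needs matching 1-D start/end arrays")
        if np.any(ends <= starts):
            raise InputError("every fragment must have positive length")
        if np.any(starts[1:] != ends[:-1]):
            raise InputError("fragments must be sorted and contiguous")

    @property
    def n_fragments(self) -> int:
        return int(self.starts.size)

    def __len__(self) -> int:
        return self.n_fragments

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    @property
    def span(self) -> tuple[int, int]:
        return int(self.starts[0]), int(self.ends[-1])

    def locate(self, start: int, end: int) -> int | None:
        """Index of the fragment exactly equal to ``[start, end)``, else None."""
        i = int(np.searchsorted(self.starts, start))
        if i < self.n_fragments and self.starts[i] == start and self.ends[i] == end:
            return i
        return None

    def locate_midpoint(self, position: float) -> int | None:
        """Index of the fragment containing ``position``, else None."""
        lo, hi = self.span
        if not (lo <= position < hi):
            return None
        return int(np.searchsorted(self.ends, position, side="right"))

    def overlapping(self, start: int, end: int) -> np.ndarray:
        """Indices of fragments overlapping ``[start, end)``."""
        first = int(np.searchsorted(self.ends, start, side="right"))
        last = int(np.searchsorted(self.starts, end, side="left"))
        return np.arange(first, last)

    @classmethod
    def uniform(cls, chromosome: str, n_fragments: int, fragment_bp: int,
                origin: int = 0) -> "FragmentMap":
        edges = origin + fragment_bp * np.arange(n_fragments + 1, dtype=np.int64)
        return cls(chromosome, edges[:-1], edges[1:])

    def to_bed(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "chrom": self.chromosome,
            "start": self.starts,
            "end": self.ends,
            "name": [f"frag_{i}" for i in range(self.n_fragments)],
        })
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "FragmentMap":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"])
        if df.empty:
            raise InputError(f"{path}: empty fragment BED")
        chroms = df["chrom"].unique()
        if len(chroms) != 1:
            raise InputError("fragment map must cover a single chromosome")
        df = df.sort_values("start")
        return cls(str(chroms[0]), df["start"].to_numpy(), df["end"].to_numpy())


@dataclass(frozen=True)
class Viewpoint:
    """One 4C anchor: the restriction fragment(s) whose contacts an
    experiment measures.  ``length`` is the viewpoint length used for BCP
    normalization (defaults to the interval length)."""

    id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise InputError(f"viewpoint {self.id}: empty interval")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def fragment_indices(self, frags: FragmentMap) -> np.ndarray:
        idx = frags.overlapping(self.start, self.end)
        if idx.size == 0:
            raise InputError(f"viewpoint {self.id} maps to no fragment")
        return idx


def viewpoints_to_bed(viewpoints: Sequence[Viewpoint], path: str | Path) -> None:
    pd.DataFrame({
        "chrom": [v.chromosome for v in viewpoints],
        "start": [v.start for v in viewpoints],
        "end": [v.end for v in viewpoints],
        "name": [v.id for v in viewpoints],
    }).to_csv(path, sep="\t", header=False, index=False)


def viewpoints_from_bed(path: str | Path) -> list[Viewpoint]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"])
    return [Viewpoint(str(r["name"]), str(r["chrom"]), int(r["start"]), int(r["end"]))
            for _, r in df.iterrows()]


class CaptureTable:
    """Raw capture read counts per (viewpoint, fragment, replicate, condition).

    Internally a dense int64 vector over the fragment map per experiment key
    ``(viewpoint_id, replicate, condition)``.
    """

    def __init__(self, frags: FragmentMap):
        self.frags = frags
        self._data: dict[tuple[str, str, str], np.ndarray] = {}

    @property
    def keys(self) -> list[tuple[str, str, str]]:
        return sorted(self._data)

    def __len__(self) -> int:
        return sum(int(np.count_nonzero(v)) for v in self._data.values())

    def set_counts(self, viewpoint: str, replicate: str, condition: str,
                   counts: np.ndarray) -> None:
        counts = np.asarray(counts)
        if counts.shape != (self.frags.n_fragments,):
            raise InputError("counts must be dense over the fragment map")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)) or np.any(counts < 0):
                raise InputError("counts must be non-negative integers")
        self._data[(viewpoint, replicate, condition)] = counts.astype(np.int64)

    def add(self, viewpoint: str, fragment: int, replicate: str, condition: str,
            count: int) -> None:
        key = (viewpoint, replicate, condition)
        if key not in self._data:
            self._data[key] = np.zeros(self.frags.n_fragments, dtype=np.int64)
        if count < 0:
            raise InputError("counts must be non-negative")
        self._data[key][fragment] += int(count)

    def counts(self, viewpoint: str, replicate: str, condition: str) -> np.ndarray:
        key = (viewpoint, replicate, condition)
        if key not in self._data:
            return np.zeros(self.frags.n_fragments, dtype=np.int64)
        return self._data[key]

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for (vp, rep, cond), counts in sorted(self._data.items()):
            nz = np.nonzero(counts)[0]
            for i in nz:
                rows.append((self.frags.chromosome, int(self.frags.starts[i]),
                             int(self.frags.ends[i]), int(counts[i]), vp, rep, cond))
        pd.DataFrame(rows, columns=["chrom", "start", "end", "count",
                                    "viewpoint", "replicate", "condition"]) \
          .to_csv(path, sep="\t", index=False)


def digest_sequence(sequence: str, recognition_site: str) -> FragmentMap:
    """In-silico digestion: cut at every (left-to-right non-overlapping)
    occurrence of ``recognition_site``, at the site start.

    The resulting fragments tile ``[0, len(sequence))``; each internal fragment
    carries the recognition site at its 5' end.
    """
    if not sequence or not recognition_site:
        raise InputError("sequence and recognition site must be non-empty")
    if len(recognition_site) >= len(sequence):
        raise InputError("recognition site must be shorter than the sequence")
    if not _VALID_DNA.match(sequence) or not _VALID_DNA.match(recognition_site):
        raise InputError("sequences may contain only ACGTN characters")
    seq = sequence.upper()
    site = recognition_site.upper()
    cuts = [0]
    pos = seq.find(site)
    while pos != -1:
        if pos > 0:
            cuts.append(pos)
        pos = seq.find(site, pos + len(site))
    cuts.append(len(seq))
    cuts = sorted(set(cuts))
    starts = np.asarray(cuts[:-1], dtype=np.int64)
    ends = np.asarray(cuts[1:], dtype=np.int64)
    return FragmentMap("seq", starts, ends)


def digest_fasta(path: str | Path, recognition_site: str) -> dict[str, FragmentMap]:
    """Digest every record of a FASTA file; returns {record name: FragmentMap}."""
    maps: dict[str, FragmentMap] = {}
    name, chunks = None, []

    def _flush():
        if name is not None:
            fm = digest_sequence("".join(chunks), recognition_site)
            maps[name] = FragmentMap(name, fm.starts, fm.ends)

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
    _flush()
    if not maps:
        raise InputError(f"{path}: no FASTA records")
    return maps


def read_capture_table(path: str | Path, frags: FragmentMap,
                       midpoint_fallback: bool = False
                       ) -> tuple[CaptureTable, pd.DataFrame]:
    """Read a TSV of per-fragment capture counts.

    Expected columns: chrom, start, end, count, viewpoint, replicate,
    condition (header row).  Rows are matched to fragments by exact interval;
    with ``midpoint_fallback`` a row whose interval is not an exact fragment is
    assigned to the fragment containing its midpoint.  Unmatched rows are
    returned in a rejects frame, never silently dropped.
    """
    table = CaptureTable(frags)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return table, pd.DataFrame(columns=["chrom", "start", "end", "count",
                                            "viewpoint", "replicate", "condition",
                                            "reason"])
    required = {"chrom", "start", "end", "count", "viewpoint", "replicate",
                "condition"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    rejects = []
    for _, row in df.iterrows():
        if str(row["chrom"]) != frags.chromosome:
            rejects.append((*row[["chrom", "start", "end", "count", "viewpoint",
                                  "replicate", "condition"]], "wrong chromosome"))
            continue
        idx = frags.locate(int(row["start"]), int(row["end"]))
        if idx is None and midpoint_fallback:
            idx = frags.locate_midpoint((row["start"] + row["end"]) / 2.0)
        if idx is None:
            rejects.append((*row[["chrom", "start", "end", "count", "viewpoint",
                                  "replicate", "condition"]], "no matching fragment"))
            continue
        table.add(str(row["viewpoint"]), idx, str(row["replicate"]),
                  str(row["condition"]), int(row["count"]))
    rejects_df = pd.DataFrame(rejects, columns=["chrom", "start", "end", "count",
                                                "viewpoint", "replicate",
                                                "condition", "reason"])
    return table, rejects_df


def write_track(chromosome: str, starts: Iterable[int], ends: Iterable[int],
                values: Iterable[float], path: str | Path,
                fmt: str = "bedGraph", precision: int = 10) -> None:
    """Write per-interval values as bedGraph or TSV (0-based half-open).

    NaN values are written as omitted intervals (standard bedGraph practice
    for missing data); re-reading reproduces the finite values at the declared
    precision.
    """
    starts = np.asarray(list(starts), dtype=np.int64)
    ends = np.asarray(list(ends), dtype=np.int64)
    values = np.asarray(list(values), dtype=float)
    keep = np.isfinite(values)
    df = pd.DataFrame({"chrom": chromosome, "start": starts[keep],
                       "end": ends[keep], "value": values[keep]})
    if fmt == "bedGraph":
        df.to_csv(path, sep="\t", header=False, index=False,
                  float_format=f"%.{precision}g")
    elif fmt == "TSV":
        df.to_csv(path, sep="\t", header=True, index=False,
                  float_format=f"%.{precision}g")
    else:
        raise InputError(f"unknown track format {fmt!r}")


def read_track(path: str | Path, fmt: str = "bedGraph") -> pd.DataFrame:
    """Read a track written by :func:`write_track`."""
    if fmt == "bedGraph":
        return pd.read_csv(path, sep="\t", header=None,
                           names=["chrom", "start", "end", "value"])
    elif fmt == "TSV":
        return pd.read_csv(path, sep="\t")
    raise InputError(f"unknown track format {fmt!r}")
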
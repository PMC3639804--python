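"""Core domain objects shared across the pipeline.

All genomic coordinates are 0-based, half-open ``[start, end)`` (the BED
convention).  Formats that use 1-based closed coordinates (GFF3) are
converted at the I/O boundary; nothing downstream ever sees them.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Interval",
    "Probe",
    "ProbeTrack",
    "GeneModel",
    "FeatureSet",
    "AssayRecord",
    "GenomeSequence",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally named/stranded."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        """Half-open overlap test: shared span must be >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, order=True)
class Probe:
    """One tiling-array probe carrying a normalized log ratio (NLR).

    NLR is the log ratio of ChIP signal over input after array
    normalization; negative values indicate histone depletion.
    """

    chrom: str
    start: int
    end: int
    nlr: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"probe end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        import math

        if not math.isfinite(self.nlr):
            raise ValueError(
                f"probe NLR must be finite at {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)


class ProbeTrack:
    """Ordered probe intervals with NLR signal for a single antibody.

    Probes are kept sorted by (chrom, start); within a chromosome, starts
    are strictly increasing.  Identical duplicate coordinates are rejected
    (they indicate corrupt input and averaging would silently change the
    caller's behaviour).
    """

    def __init__(self, probes: Iterable[Probe], antibody: str = "panH3") -> None:
        probes = sorted(probes, key=lambda p: (p.chrom, p.start, p.end))
        for a, b in zip(probes, probes[1:]):
            if a.chrom == b.chrom and a.start >= b.start:
                raise ValueError(
                    f"duplicate or non-increasing probe start at "
                    f"{b.chrom}:{b.start} (previous start {a.start})"
                )
        self.antibody = antibody
        self.probes: tuple[Probe, ...] = tuple(probes)
        self._starts: dict[str, list[int]] = {}
        self._by_chrom: dict[str, list[Probe]] = {}
        for p in self.probes:
            self._by_chrom.setdefault(p.chrom, []).append(p)
        for chrom, ps in self._by_chrom.items():
            self._starts[chrom] = [p.start for p in ps]

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ProbeTrack)
            and self.antibody == other.antibody
            and self.probes == other.probes
        )

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(sorted(self._by_chrom))

    def probes_on(self, chrom: str) -> list[Probe]:
        return list(self._by_chrom.get(chrom, ()))

    def probes_in(self, chrom: str, start: int, end: int) -> list[Probe]:
        """Probes sharing >= 1 bp with [start, end) on *chrom*."""
        ps = self._by_chrom.get(chrom)
        if not ps:
            return []
        # first probe that could overlap: any with probe.end > start; probe
        # lengths are near-constant so scan left from the bisect point
        i = bisect.bisect_left(self._starts[chrom], start)
        while i > 0 and ps[i - 1].end > start:
            i -= 1
        out = []
        for p in ps[i:]:
            if p.start >= end:
                break
            if p.end > start:
                out.append(p)
        return out

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.probes],
                "start": [p.start for p in self.probes],
                "end": [p.end for p in self.probes],
                "nlr": [p.nlr for p in self.probes],
            }
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body with cluster letter and paralog ordinal used in naming.

    ``tss``/``tes`` are strand-resolved: on '+' the transcription start is
    ``start`` and the end is ``end``; on '-' they swap.
    """

    name: str
    cluster: str
    ordinal: int
    strand: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: strand must be '+' or '-'")
        if self.end <= self.start:
            raise ValueError(f"gene {self.name}: end must exceed start")

    @property
    def body(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, name=self.name, strand=self.strand)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


class FeatureSet:
    """A sorted set of genomic intervals of one kind (NCT, CpG, HS, CTCF...)."""

    KINDS = ("NCT", "CpG", "HS", "CTCF", "custom")

    def __init__(
        self,
        intervals: Iterable[Interval],
        kind: str = "custom",
        cell_type: str | None = None,
    ) -> None:
        self.kind = kind
        self.cell_type = cell_type
        self.intervals: tuple[Interval, ...] = tuple(
            sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def label(self) -> str:
        return f"{self.kind}:{self.cell_type}" if self.cell_type else self.kind


@dataclass(frozen=True)
class AssayRecord:
    """One colony count from an enhancer-blocking assay.

    ``batch`` identifies the biological replicate experiment and
    ``replicate`` the technical replicate within it.
    """

    construct: str
    batch: str
    replicate: int
    colonies: int

    def __post_init__(self) -> None:
        if self.colonies < 0:
            raise ValueError(
                f"negative colony count for {self.construct}/{self.batch}/{self.replicate}"
            )


class GenomeSequence:
    """Uniform sequence accessor over a dict of strings or a FASTA file.

    FASTA files are read through :mod:`pyfaidx` so only the requested
    windows are loaded.
    """

    def __init__(self, source: Mapping[str, str] | str | Path) -> None:
        if isinstance(source, (str, Path)):
            from pyfaidx import Fasta

            self._fasta = Fasta(str(source))
            self._dict: Mapping[str, str] | None = None
        else:
            self._fasta = None
            self._dict = source

    def __contains__(self, chrom: str) -> bool:
        if self._dict is not None:
            return chrom in self._dict
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end) on *chrom*; raises on out-of-bounds."""
        if chrom not in self:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        n = self.length(chrom)
        if start < 0 or end > n:
            raise ValueError(
                f"requested {chrom}:{start}-{end} outside sequence of length {n}"
            )
        if self._dict is not None:
            return self._dict[chrom][start:end].upper()
        return str(self._fasta[chrom][start:end]).upper()
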
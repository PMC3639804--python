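"""Segmentation of probe NLR tracks into histone-free regions (HFRs).

The algorithm walks each chromosome's ordered probes, partitions them into
groups of five contiguous probes, classifies each group as low or high
enrichment (low = at least three probes with strictly negative NLR), and
extends continuous blocks of low groups until two or more consecutive high
groups are met or the genomic distance between successive probes exceeds
200 bp.  Surviving blocks become HFRs.  All constants live in
:class:`CallerParams` and are recorded in the catalog for provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

from .core import Interval, Probe, ProbeTrack

logger = logging.getLogger(__name__)

__all__ = [
    "CallerParams",
    "ProbeGroup",
    "Block",
    "HFR",
    "HFRCatalog",
    "partition_groups",
    "classify_group",
    "call_blocks",
    "blocks_to_hfrs",
    "call_hfrs",
    "cross_array_consistency",
]

LOW = "low"
HIGH = "high"


@dataclass(frozen=True)
class CallerParams:
    """Constants of the HFR-calling algorithm.

    group_size
        Probes per group (5).
    low_neg_count
        Minimum probes with NLR < 0 for a group to be "low enrichment" (3).
        NLR exactly 0 is non-negative: the rule is strict.
    max_gap
        Maximum genomic distance in bp between successive probes, measured
        end-to-start; larger gaps break both grouping and blocks (200).
    stop_high_run
        Number of consecutive high groups that terminates a block (2); a
        shorter interior run is absorbed.
    min_groups
        Minimum low groups per HFR (2).
    min_span
        Minimum HFR length in bp (500); the smallest catalogued HFR is
        510 bp, the span of ten contiguous probes at the array geometry.
    """

    group_size: int = 5
    low_neg_count: int = 3
    max_gap: int = 200
    stop_high_run: int = 2
    min_groups: int = 2
    min_span: int = 500

    def __post_init__(self) -> None:
        if not (1 <= self.low_neg_count <= self.group_size):
            raise ValueError("low_neg_count must lie in [1, group_size]")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.stop_high_run < 1:
            raise ValueError("stop_high_run must be >= 1")
        if self.min_groups < 1:
            raise ValueError("min_groups must be >= 1")
        if self.min_span < 0:
            raise ValueError("min_span must be >= 0")


@dataclass
class ProbeGroup:
    """A run of <= group_size contiguous probes, labelled low or high.

    ``segment`` indexes the gap-free stretch the group came from; blocks
    never join groups across segment boundaries.
    """

    probes: tuple[Probe, ...]
    segment: int
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.probes:
            raise ValueError("probe group cannot be empty")

    @property
    def chrom(self) -> str:
        return self.probes[0].chrom

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.probes[0].start, self.probes[-1].end)

    @property
    def n_negative(self) -> int:
        return sum(1 for p in self.probes if p.nlr < 0)


@dataclass
class Block:
    """A continuous stretch of low-enrichment groups (with absorbed highs)."""

    groups: tuple[ProbeGroup, ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("block cannot be empty")
        if self.groups[0].label != LOW or self.groups[-1].label != LOW:
            raise ValueError("block must start and end with a low group")

    @property
    def chrom(self) -> str:
        return self.groups[0].chrom

    @property
    def n_low(self) -> int:
        return sum(1 for g in self.groups if g.label == LOW)

    @property
    def probes(self) -> tuple[Probe, ...]:
        return tuple(p for g in self.groups for p in g.probes)

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.groups[0].probes[0].start, self.groups[-1].probes[-1].end)


@dataclass
class HFR:
    """A called histone-free region."""

    chrom: str
    start: int
    end: int
    n_probes: int
    n_low_groups: int
    mean_nlr: float
    name: str | None = None
    context: str | None = None
    cross_array_flags: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, name=self.name)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class HFRCatalog:
    """Sorted, non-overlapping HFRs with the parameters that produced them."""

    def __init__(
        self,
        hfrs: Iterable[HFR],
        params: CallerParams | None = None,
        source_track: str | None = None,
    ) -> None:
        hfrs = sorted(hfrs, key=lambda h: (h.chrom, h.start, h.end))
        for a, b in zip(hfrs, hfrs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise ValueError(
                    f"overlapping HFRs {a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
                )
        self.hfrs: tuple[HFR, ...] = tuple(hfrs)
        self.params = params
        self.source_track = source_track

    def __len__(self) -> int:
        return len(self.hfrs)

    def __iter__(self):
        return iter(self.hfrs)

    def __getitem__(self, i):
        return self.hfrs[i]

    def intervals(self) -> list[Interval]:
        return [h.interval for h in self.hfrs]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "name": [h.name for h in self.hfrs],
                "chrom": [h.chrom for h in self.hfrs],
                "start": [h.start for h in self.hfrs],
                "end": [h.end for h in self.hfrs],
                "size": [h.size for h in self.hfrs],
                "context": [h.context for h in self.hfrs],
                "n_probes": [h.n_probes for h in self.hfrs],
                "n_low_groups": [h.n_low_groups for h in self.hfrs],
                "mean_nlr": [h.mean_nlr for h in self.hfrs],
            }
        )

    def provenance(self) -> dict:
        return {
            "source_track": self.source_track,
            "params": asdict(self.params) if self.params else None,
            "n_hfrs": len(self),
        }


def partition_groups(
    probes: Sequence[Probe], params: CallerParams | None = None
) -> list[ProbeGroup]:
    """Partition one chromosome's sorted probes into consecutive groups.

    The partition restarts (and the segment index increments) whenever the
    gap between consecutive probes, ``next.start - prev.end``, exceeds
    ``max_gap``; groups never span such a gap.  Trailing partial groups are
    retained.  Overlapping tiling (probe step < probe length) yields
    negative gaps and never triggers the gap rule.
    """
    params = params or CallerParams()
    if not probes:
        return []
    chroms = {p.chrom for p in probes}
    if len(chroms) > 1:
        raise ValueError(f"partition_groups expects one chromosome, got {sorted(chroms)}")
    groups: list[ProbeGroup] = []
    segment = 0
    current: list[Probe] = []

    def flush() -> None:
        if current:
            groups.append(ProbeGroup(tuple(current), segment))
            current.clear()

    prev: Probe | None = None
    for p in probes:
        if prev is not None and p.start - prev.end > params.max_gap:
            flush()
            segment += 1
        current.append(p)
        if len(current) == params.group_size:
            flush()
        prev = p
    flush()
    return groups


def classify_group(group: ProbeGroup, params: CallerParams | None = None) -> str:
    """Label a group low iff >= low_neg_count probes have NLR strictly < 0."""
    params = params or CallerParams()
    return LOW if group.n_negative >= params.low_neg_count else HIGH


def call_blocks(
    groups: Sequence[ProbeGroup], params: CallerParams | None = None
) -> list[Block]:
    """Extend continuous blocks of low groups into maximal valid stretches.

    A block opens at a low group and absorbs interior high runs shorter
    than ``stop_high_run``; a run of >= stop_high_run consecutive high
    groups (or a segment boundary, i.e. a > max_gap inter-probe distance)
    terminates it.  The terminating high run is excluded: blocks are
    right-trimmed to their last low group.  Groups must already be
    labelled.
    """
    params = params or CallerParams()
    for g in groups:
        if g.label not in (LOW, HIGH):
            raise ValueError("call_blocks requires labelled groups; run classify_group first")
    blocks: list[Block] = []
    current: list[ProbeGroup] = []
    pending_high: list[ProbeGroup] = []
    current_segment: int | None = None

    def close() -> None:
        nonlocal current, pending_high
        if current:
            blocks.append(Block(tuple(current)))
        current = []
        pending_high = []

    for g in groups:
        if current and g.segment != current_segment:
            close()
        current_segment = g.segment
        if g.label == LOW:
            if current:
                current.extend(pending_high)
                pending_high = []
            current.append(g)
        else:
            if current:
                pending_high.append(g)
                if len(pending_high) >= params.stop_high_run:
                    close()
    close()
    return blocks


def blocks_to_hfrs(blocks: Sequence[Block], params: CallerParams | None = None) -> list[HFR]:
    """Convert blocks to HFRs, dropping those below the minimum extent.

    The HFR spans the first probe's start to the last probe's end of the
    block; its size is the genomic span, including any interior masked
    stretch of <= max_gap, not just probe-covered bases.
    """
    params = params or CallerParams()
    out: list[HFR] = []
    for b in blocks:
        span = b.span
        if b.n_low < params.min_groups or len(span) < params.min_span:
            continue
        probes = b.probes
        out.append(
            HFR(
                chrom=b.chrom,
                start=span.start,
                end=span.end,
                n_probes=len(probes),
                n_low_groups=b.n_low,
                mean_nlr=sum(p.nlr for p in probes) / len(probes),
            )
        )
    return out


def call_hfrs(track: ProbeTrack, params: CallerParams | None = None) -> HFRCatalog:
    """Run the full caller on a validated probe track, per chromosome."""
    params = params or CallerParams()
    hfrs: list[HFR] = []
    for chrom in track.chromosomes:
        groups = partition_groups(track.probes_on(chrom), params)
        for g in groups:
            g.label = classify_group(g, params)
        blocks = call_blocks(groups, params)
        hfrs.extend(blocks_to_hfrs(blocks, params))
    return HFRCatalog(hfrs, params=params, source_track=track.antibody)


def cross_array_consistency(
    catalog: HFRCatalog,
    other_tracks: Sequence[ProbeTrack],
    mean_threshold: float = 0.0,
    neg_fraction: float = 0.5,
) -> tuple["object", float]:
    """Flag each HFR unenriched in each additional antibody track.

    An HFR is unenriched in a track iff the mean NLR of the track's probes
    overlapping it is below ``mean_threshold`` AND at least ``neg_fraction``
    of those probes have NLR < 0.  Returns a per-HFR/per-track boolean
    DataFrame (NaN where a track has no overlapping probes) and the
    fraction of HFRs unenriched in every track simultaneously, computed
    over HFRs whose flags are all determined.
    """
    import numpy as np
    import pandas as pd

    rows = {}
    for track in other_tracks:
        flags = []
        for h in catalog:
            probes = track.probes_in(h.chrom, h.start, h.end)
            if not probes:
                logger.warning(
                    "HFR %s has no overlapping probes in track %r; flag undetermined",
                    h.name or f"{h.chrom}:{h.start}-{h.end}",
                    track.antibody,
                )
                flags.append(np.nan)
                continue
            nlrs = np.array([p.nlr for p in probes])
            flags.append(
                bool(nlrs.mean() < mean_threshold and (nlrs < 0).mean() >= neg_fraction)
            )
        rows[track.antibody] = flags
    index = [h.name or f"{h.chrom}:{h.start}-{h.end}" for h in catalog]
    df = pd.DataFrame(rows, index=index)
    for h, (_, row) in zip(catalog, df.iterrows()):
        h.cross_array_flags = {k: (None if pd.isna(v) else bool(v)) for k, v in row.items()}
    determined = df.dropna()
    if len(determined) == 0:
        return df, float("nan")
    fraction = float(determined.all(axis=1).mean())
    return df, fraction
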
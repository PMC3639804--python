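"""GAGAG (GAGA-factor) motif scanning over HFR sequences.

The GAGA factor binds GAGAG runs; its vertebrate homolog is Th-POK.  The
scanner reports exact string matches of the motif on the plus strand and
of its reverse complement on the minus strand.  For tandem runs like
GAGAGAG the counting policy matters: the default counts matches greedily
left-to-right without overlap on each strand; an overlapping policy is
available and the choice is recorded in provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .caller import HFRCatalog
from .core import GenomeSequence, Interval, reverse_complement

__all__ = [
    "ScanParams",
    "MotifHit",
    "MotifLocus",
    "scan_gaga",
    "per_hfr_motif_stats",
    "merge_hits",
]

_DNA = set("ACGT")


@dataclass(frozen=True)
class ScanParams:
    """Motif, strandedness and counting policy for the scanner."""

    pattern: str = "GAGAG"
    both_strands: bool = True
    overlap_policy: str = "non_overlapping"
    merge_dist: int = 20

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        if set(self.pattern.upper()) - _DNA:
            raise ValueError(f"pattern {self.pattern!r} must be uppercase DNA (ACGT)")
        if self.overlap_policy not in ("non_overlapping", "overlapping"):
            raise ValueError(f"unknown overlap policy {self.overlap_policy!r}")


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence: genomic span, strand, and containing HFR."""

    chrom: str
    start: int
    end: int
    strand: str
    hfr_name: str | None = None

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, strand=self.strand)


def _find_matches(seq: str, pattern: str, overlapping: bool) -> list[int]:
    """Start offsets of exact matches, greedy left-to-right.

    N (or any non-matching base) never matches.  Under the
    non-overlapping policy the cursor jumps past each match; under the
    overlapping policy it advances one base.
    """
    step = 1 if overlapping else len(pattern)
    positions = []
    i = seq.find(pattern)
    while i != -1:
        positions.append(i)
        i = seq.find(pattern, i + step)
    return positions


def scan_gaga(
    sequence: str,
    params: ScanParams | None = None,
    offset: int = 0,
    chrom: str = ".",
    hfr_name: str | None = None,
) -> list[MotifHit]:
    """Scan one sequence for the motif; returns hits sorted by position.

    Minus-strand hits are matches of the reverse complement of the
    pattern within the given sequence, reported with strand '-' at their
    coordinates on the given (plus) strand.  ``offset`` shifts reported
    coordinates so callers can pass sub-sequences of a chromosome.
    """
    params = params or ScanParams()
    seq = sequence.upper()
    k = len(params.pattern)
    overlapping = params.overlap_policy == "overlapping"
    hits = [
        MotifHit(chrom, offset + i, offset + i + k, "+", hfr_name)
        for i in _find_matches(seq, params.pattern, overlapping)
    ]
    if params.both_strands:
        rc = reverse_complement(params.pattern)
        if rc != params.pattern:
            hits += [
                MotifHit(chrom, offset + i, offset + i + k, "-", hfr_name)
                for i in _find_matches(seq, rc, overlapping)
            ]
    return sorted(hits)


def per_hfr_motif_stats(
    catalog: HFRCatalog,
    genome: GenomeSequence | dict,
    params: ScanParams | None = None,
):
    """Per-HFR motif counts and catalog totals.

    Counts are taken after strand-deduplication: plus and minus hits at
    identical coordinates count once (impossible for GAGAG itself, which
    is not its own reverse complement, but enforced for any pattern).
    Returns ``(per_hfr DataFrame, totals dict, hits list)``.
    """
    import pandas as pd

    params = params or ScanParams()
    if not isinstance(genome, GenomeSequence):
        genome = GenomeSequence(genome)
    rows = []
    all_hits: list[MotifHit] = []
    for h in catalog:
        label = h.name or f"{h.chrom}:{h.start}-{h.end}"
        try:
            seq = genome.fetch(h.chrom, h.start, h.end)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"HFR {label} outside genome bounds: {exc}") from exc
        hits = scan_gaga(seq, params, offset=h.start, chrom=h.chrom, hfr_name=label)
        all_hits.extend(hits)
        n = len({(hit.start, hit.end) for hit in hits})
        rows.append({"hfr": label, "n_hits": n, "has_motif": n > 0})
        h.flags["n_motifs"] = n
    per_hfr = pd.DataFrame(rows, columns=["hfr", "n_hits", "has_motif"])
    totals = {
        "total_hits": int(per_hfr["n_hits"].sum()) if len(per_hfr) else 0,
        "n_hfrs_with_motif": int(per_hfr["has_motif"].sum()) if len(per_hfr) else 0,
    }
    return per_hfr, totals, all_hits


@dataclass(frozen=True)
class MotifLocus:
    """A display-level cluster of nearby motif hits."""

    chrom: str
    start: int
    end: int
    n_members: int


def merge_hits(hits: Sequence[MotifHit], merge_dist: int = 20) -> list[MotifLocus]:
    """Collapse hits within ``merge_dist`` bp (end-to-start, either strand).

    This mirrors map rendering where motifs appearing close together are
    drawn as one locus; it affects display only, never the counts from
    :func:`per_hfr_motif_stats`.
    """
    ordered = sorted(hits, key=lambda h: (h.chrom, h.start, h.end))
    if list(hits) != ordered:
        raise ValueError("merge_hits requires hits sorted by (chrom, start)")
    loci: list[MotifLocus] = []
    cur: list[MotifHit] = []
    for h in ordered:
        if cur and h.chrom == cur[-1].chrom and h.start - max(x.end for x in cur) <= merge_dist:
            cur.append(h)
        else:
            if cur:
                loci.append(_to_locus(cur))
            cur = [h]
    if cur:
        loci.append(_to_locus(cur))
    return loci


def _to_locus(members: list[MotifHit]) -> MotifLocus:
    return MotifLocus(
        chrom=members[0].chrom,
        start=min(m.start for m in members),
        end=max(m.end for m in members),
        n_members=len(members),
    )
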
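"""Interval-overlap statistics between the HFR catalog and peak sets.

Open-chromatin (DNaseI-hypersensitive) peaks are a standard orthogonal
readout of histone depletion: an HFR overlapping an HS peak in a cell
type carries independent evidence of accessibility there.  Overlap is
half-open and requires >= 1 shared bp by default (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .caller import HFRCatalog
from .core import FeatureSet, Interval

logger = logging.getLogger(__name__)

__all__ = ["OverlapSummary", "intersect", "hs_overlap_summary"]


def _check_sorted(intervals: Sequence[Interval], what: str) -> None:
    keys = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    if keys != sorted(keys):
        raise ValueError(f"{what} intervals must be sorted by (chrom, start, end)")


def intersect(
    a: Sequence[Interval],
    b: Sequence[Interval],
    min_overlap: int = 1,
) -> tuple[list[bool], list[int], list[tuple[int, int, int]]]:
    """Overlap flags and shared base pairs of each ``a`` interval against ``b``.

    Both lists must be sorted.  Returns, per ``a`` interval, whether it
    shares >= ``min_overlap`` bp with any ``b`` interval and its total
    shared bp, plus the list of overlapping pairs ``(i, j, shared_bp)``.
    Half-open semantics: [0,10) and [10,20) do not overlap.
    """
    _check_sorted(a, "a")
    _check_sorted(b, "b")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    flags = [False] * len(a)
    shared = [0] * len(a)
    pairs: list[tuple[int, int, int]] = []
    # sweep per chromosome with a lagging pointer into b
    from collections import defaultdict

    b_by_chrom: dict[str, list[tuple[int, Interval]]] = defaultdict(list)
    for j, iv in enumerate(b):
        b_by_chrom[iv.chrom].append((j, iv))
    cursor: dict[str, int] = defaultdict(int)
    for i, iv in enumerate(a):
        cand = b_by_chrom.get(iv.chrom)
        if not cand:
            continue
        k = cursor[iv.chrom]
        # advance past b intervals that can no longer overlap anything at or
        # beyond iv (a is sorted, but b intervals can be long, so only move
        # the cursor past intervals ending before iv.start)
        while k < len(cand) and cand[k][1].end <= iv.start:
            k += 1
        cursor[iv.chrom] = k
        for j, bv in cand[k:]:
            if bv.start >= iv.end:
                break
            ov = iv.overlap_bp(bv)
            if ov >= min_overlap:
                flags[i] = True
                shared[i] += ov
                pairs.append((i, j, ov))
    return flags, shared, pairs


@dataclass
class OverlapSummary:
    """Per-HFR overlap matrix against labelled peak sets plus headline stats.

    ``frac_any`` is the fraction of HFRs overlapping at least one set;
    ``n_all`` counts HFRs overlapping every set simultaneously.
    """

    per_hfr: "object"  # DataFrame: HFR x set booleans
    frac_any: float
    n_all: int

    def to_dataframe(self):
        return self.per_hfr


def hs_overlap_summary(
    catalog: HFRCatalog,
    sets: Sequence[FeatureSet],
    min_overlap: int = 1,
) -> OverlapSummary:
    """Overlap of every HFR against each peak set (e.g. HS per cell type).

    Peak sets with no data on an HFR's chromosome count as
    non-overlapping, with a warning.  An empty catalog yields NaN
    ``frac_any`` and zero ``n_all``.
    """
    import numpy as np
    import pandas as pd

    if not sets:
        raise ValueError("at least one feature set is required")
    hfr_ivs = catalog.intervals()
    index = [h.name or f"{h.chrom}:{h.start}-{h.end}" for h in catalog]
    data = {}
    for fs in sets:
        covered_chroms = {iv.chrom for iv in fs}
        for h in catalog:
            if h.chrom not in covered_chroms:
                logger.warning(
                    "peak set %s has no data on %s; HFRs there count as non-overlapping",
                    fs.label,
                    h.chrom,
                )
                break
        flags, _, _ = intersect(hfr_ivs, list(fs.intervals), min_overlap=min_overlap)
        data[fs.label] = flags
    per_hfr = pd.DataFrame(data, index=index, dtype=bool)
    if len(per_hfr) == 0:
        logger.warning("empty catalog: overlap fractions undefined")
        return OverlapSummary(per_hfr, float("nan"), 0)
    frac_any = float(per_hfr.any(axis=1).mean())
    n_all = int(per_hfr.all(axis=1).sum())
    for h, any_flag in zip(catalog, per_hfr.any(axis=1)):
        h.flags["hs_any"] = bool(any_flag)
    return OverlapSummary(per_hfr, frac_any, n_all)
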
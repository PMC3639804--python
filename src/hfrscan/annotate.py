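"""Genomic-context classification, catalog naming, and summary tallies.

Each HFR receives exactly one context label, resolved in a fixed
precedence order (Genic > TSS > 3' end > NCT > Intergenic), and a
catalog name that encodes its position relative to the cluster's genes:
``A_3-4.2`` is the second HFR between genes 3 and 4 of cluster A,
``A_5.1`` the first HFR inside gene 5, and ``A_UP.1``/``A_DOWN.1`` lie
beyond the outermost genes (UP on the side of the highest paralog
ordinal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

from .caller import HFR, HFRCatalog
from .core import FeatureSet, GeneModel, Interval

logger = logging.getLogger(__name__)

GENIC = "Genic"
TSS = "TSS"
THREE_PRIME = "3' end"
NCT = "NCT"
INTERGENIC = "Intergenic"
CONTEXTS = (GENIC, TSS, THREE_PRIME, NCT, INTERGENIC)

__all__ = [
    "AnnotatorParams",
    "CONTEXTS",
    "GENIC",
    "TSS",
    "THREE_PRIME",
    "NCT",
    "INTERGENIC",
    "classify_context",
    "annotate_catalog",
    "assign_names",
    "summarize_catalog",
    "load_reference_catalog",
]


@dataclass(frozen=True)
class AnnotatorParams:
    """Windows (bp) and precedence for context classification.

    ``tss_window`` is the half-width of the promoter-proximal window
    around a gene's transcription start (1 kb); ``tes_window`` mirrors it
    at the 3' end.  Precedence must be a permutation of the five labels.
    """

    tss_window: int = 1000
    tes_window: int = 1000
    precedence: tuple[str, ...] = CONTEXTS

    def __post_init__(self) -> None:
        if self.tss_window < 0 or self.tes_window < 0:
            raise ValueError("context windows must be >= 0")
        if sorted(self.precedence) != sorted(CONTEXTS):
            raise ValueError(f"precedence must be a permutation of {CONTEXTS}")


def _window(chrom: str, center: int, half_width: int) -> Interval | None:
    start = center - half_width
    end = center + half_width
    if end <= start:
        return None
    return Interval(chrom, max(0, start), end)


def classify_context(
    hfr: HFR,
    genes: Sequence[GeneModel],
    ncts: FeatureSet | None = None,
    params: AnnotatorParams | None = None,
) -> str:
    """Assign the single genomic-context label for an HFR.

    Genic requires the HFR *midpoint* inside a gene body (so edge-touching
    HFRs fall to the TSS / 3'-end classes, keeping the labels mutually
    exclusive near gene edges); TSS and 3' end require overlap with the
    strand-resolved +/- window around the transcription start or end; NCT
    requires overlap with a noncoding-transcript interval; anything else
    is Intergenic.
    """
    params = params or AnnotatorParams()
    if not genes:
        logger.warning("no gene models supplied; contexts restricted to NCT/Intergenic")
    iv = hfr.interval

    def test(label: str) -> bool:
        if label == GENIC:
            return any(
                g.chrom == hfr.chrom and g.start <= hfr.midpoint < g.end for g in genes
            )
        if label == TSS:
            for g in genes:
                w = _window(g.chrom, g.tss, params.tss_window)
                if w is not None and iv.overlaps(w):
                    return True
            return False
        if label == THREE_PRIME:
            for g in genes:
                w = _window(g.chrom, g.tes, params.tes_window)
                if w is not None and iv.overlaps(w):
                    return True
            return False
        if label == NCT:
            return ncts is not None and any(iv.overlaps(n) for n in ncts)
        return True  # Intergenic: the fall-through class

    for label in params.precedence:
        if test(label):
            return label
    return INTERGENIC


def assign_names(
    catalog: HFRCatalog,
    genes: Sequence[GeneModel],
    cluster: str,
) -> HFRCatalog:
    """Name every HFR from its position relative to the cluster's genes.

    Intergenic-position HFRs between consecutive genes are named
    ``{cluster}_{left}-{right}.{k}`` with k counting left to right within
    the pair; HFRs whose midpoint lies in a gene body get
    ``{cluster}_{ordinal}.{k}``; HFRs beyond the outermost genes get the
    UP affix on the side flanking the highest gene ordinal and DOWN on the
    side flanking the lowest.  Names are guaranteed unique.
    """
    if not genes:
        raise ValueError("assign_names requires gene models with ordinals")
    genes = sorted(genes, key=lambda g: (g.chrom, g.start))
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    counters: dict[str, int] = {}

    def serial(stem: str) -> str:
        counters[stem] = counters.get(stem, 0) + 1
        return f"{stem}.{counters[stem]}"

    for h in catalog:  # catalog iterates in genomic order
        chrom_genes = by_chrom.get(h.chrom, [])
        if not chrom_genes:
            h.name = serial(f"{cluster}_UNPLACED")
            continue
        mid = h.midpoint
        inside = [g for g in chrom_genes if g.start <= mid < g.end]
        if inside:
            h.name = serial(f"{cluster}_{inside[0].ordinal}")
            continue
        left = None
        right = None
        for g in chrom_genes:
            if g.end <= mid:
                left = g
            elif g.start > mid and right is None:
                right = g
        ascending = chrom_genes[0].ordinal < chrom_genes[-1].ordinal
        if left is None:
            affix = "DOWN" if ascending else "UP"
            h.name = serial(f"{cluster}_{affix}")
        elif right is None:
            affix = "UP" if ascending else "DOWN"
            h.name = serial(f"{cluster}_{affix}")
        else:
            h.name = serial(f"{cluster}_{left.ordinal}-{right.ordinal}")
    names = [h.name for h in catalog]
    if len(set(names)) != len(names):
        raise RuntimeError("HFR naming produced duplicates")  # pragma: no cover
    return catalog


def annotate_catalog(
    catalog: HFRCatalog,
    genes: Sequence[GeneModel],
    cluster: str,
    ncts: FeatureSet | None = None,
    cpg: FeatureSet | None = None,
    params: AnnotatorParams | None = None,
) -> HFRCatalog:
    """Classify contexts, assign names, and flag CpG-island overlap.

    CpG overlap is an extra boolean flag, not a context class.
    """
    params = params or AnnotatorParams()
    for h in catalog:
        h.context = classify_context(h, genes, ncts, params)
        if cpg is not None:
            h.flags["cpg"] = any(h.interval.overlaps(c) for c in cpg)
    assign_names(catalog, genes, cluster)
    return catalog


def summarize_catalog(catalog) -> dict:
    """Tallies over a named, classified catalog (or a catalog DataFrame).

    Accepts an :class:`HFRCatalog` or a DataFrame with columns
    ``name`` (or ``cluster``), ``size`` and ``context``.  Returns total
    count, per-cluster counts, per-context counts, and min/max/mean size.
    """
    import pandas as pd

    if isinstance(catalog, HFRCatalog):
        df = catalog.to_dataframe()
    else:
        df = catalog.copy()
    if len(df) == 0:
        return {
            "total": 0,
            "per_cluster": {},
            "per_context": {},
            "min_size": 0,
            "max_size": 0,
            "mean_size": 0.0,
        }
    if "cluster" not in df.columns:
        df["cluster"] = df["name"].astype(str).str.split("_", n=1).str[0]
    per_cluster = df["cluster"].value_counts().sort_index().to_dict()
    per_context = df["context"].value_counts().sort_index().to_dict()
    return {
        "total": int(len(df)),
        "per_cluster": {str(k): int(v) for k, v in per_cluster.items()},
        "per_context": {str(k): int(v) for k, v in per_context.items()},
        "min_size": int(df["size"].min()),
        "max_size": int(df["size"].max()),
        "mean_size": float(df["size"].mean()),
    }


def load_reference_catalog():
    """The packaged reference HFR catalog of the murine Hox clusters.

    A machine-readable transcription of the published pan-H3 ChIP-chip
    catalog (93 HFRs across HoxA-D) with name, size and context per HFR;
    genomic coordinates are not part of the published table.
    """
    import pandas as pd

    ref = resources.files("hfrscan.data").joinpath("hox_hfr_catalog.tsv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
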
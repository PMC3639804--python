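"""Matplotlib views of probe tracks, HFR maps, and assay results."""

from __future__ import annotations

from typing import Sequence

from .caller import HFRCatalog
from .core import GeneModel, ProbeTrack


def plot_track(
    track: ProbeTrack,
    catalog: HFRCatalog | None = None,
    genes: Sequence[GeneModel] | None = None,
    chrom: str | None = None,
    ax=None,
):
    """Probe NLR profile with called HFRs (boxes) and gene bodies below.

    Mirrors the browser view the arrays are usually inspected in: NLR on
    the y axis, depleted stretches standing out as runs of negative
    probes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    chrom = chrom or track.chromosomes[0]
    probes = track.probes_on(chrom)
    mids = [(p.start + p.end) / 2 for p in probes]
    nlrs = [p.nlr for p in probes]
    ax.vlines(mids, 0, nlrs, color="steelblue", linewidth=0.6)
    ax.axhline(0, color="black", linewidth=0.8)
    ymin = min(nlrs, default=-1)
    if catalog is not None:
        for h in catalog:
            if h.chrom != chrom:
                continue
            ax.axvspan(h.start, h.end, color="green", alpha=0.15)
    if genes:
        for g in genes:
            if g.chrom != chrom:
                continue
            ax.annotate(
                g.name,
                xy=((g.start + g.end) / 2, ymin * 1.15),
                ha="center",
                fontsize=7,
            )
            ax.plot([g.start, g.end], [ymin * 1.1] * 2, color="navy", linewidth=4)
    ax.set_xlabel(f"{chrom} position (bp)")
    ax.set_ylabel("NLR")
    ax.set_title(f"{track.antibody} probe signal")
    return ax


def plot_survival(results, ax=None):
    """Bar chart of percent survival per construct with SE and tier lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    df = results.to_dataframe().sort_values("survival_pct")
    colors = {
        "strong": "#1f4e9c",
        "control-level": "#4a7fd4",
        "weak": "#9ab6e8",
        "none": "#c44e52",
    }
    ax.bar(
        df["construct"],
        df["survival_pct"],
        yerr=df["se_pct"],
        color=[colors.get(t, "grey") for t in df["tier"]],
        capsize=3,
    )
    tp = results.model.tier_params
    for bound, label in (
        (tp.strong_max, "strong"),
        (tp.control_max, "control-level"),
        (tp.weak_max, "weak"),
    ):
        ax.axhline(bound, linestyle=":", color="grey", linewidth=0.8)
        ax.annotate(label, xy=(0.99, bound), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=7, color="grey")
    ax.set_ylabel("colony survival (% of vector)")
    ax.tick_params(axis="x", rotation=60)
    return ax
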
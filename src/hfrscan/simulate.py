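"""Self-contained synthetic datasets emulating the tiling-array study design.

The generator lays out a Hox-like cluster over a ~150-kb region: 60-mer
probes tiled at a 50-bp step (10-bp overlap), repeat-masked holes whose
probes are omitted, a same-strand gene cluster with regular intergenic
spacing, and planted histone-depleted regions whose probes draw NLR from
a depleted Gaussian while the background draws from an enriched one.
Sequences carry planted GAGAG motifs at configured densities, and gene /
noncoding-transcript / CpG / DNaseI-HS feature tracks are emitted
consistent with each planted region's intended genomic context.  Every
output is reproducible from the seed, and a machine-readable truth
bundle records what was planted where.

Planted depleted intervals are snapped to the probe-step grid and a probe
counts as depleted only when fully contained in one, so the recoverable
boundary of a planted region is well defined at probe resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import annotate as _ann
from .caller import HFR
from .core import AssayRecord, FeatureSet, GeneModel, Interval, Probe, ProbeTrack, reverse_complement

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "simulate_cluster",
    "simulate_colony_counts",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cluster.

    Geometry (150-kb region, 60-mer probes, 50-bp step) matches the
    array design so size arithmetic — e.g. the 510-bp span of ten
    contiguous probes — is exercised natively.  NLR noise is Gaussian
    around ``mu_enriched`` outside planted regions and ``mu_depleted``
    inside.  Motif densities are per kb of sequence.
    """

    region_length: int = 150_000
    probe_length: int = 60
    probe_step: int = 50
    masked_fraction: float = 0.05
    n_planted_hfrs: int = 8
    planted_length_range: tuple[int, int] = (600, 1500)
    mu_enriched: float = 1.0
    mu_depleted: float = -1.0
    sigma: float = 0.4
    n_genes: int = 9
    gene_length_range: tuple[int, int] = (3500, 4500)
    gene_strand: str = "+"
    gc_content: float = 0.45
    motif_rate_inside: float = 2.0
    motif_rate_outside: float = 0.1
    antibodies: tuple[str, ...] = ("panH3", "H3K4me3", "H3K27me3")
    cell_types: tuple[str, ...] = ("skeletal", "mesoderm", "esc")
    hs_coverage: float = 0.85
    chrom: str = "chrS"
    cluster: str = "S"
    context_cycle: tuple[str, ...] = (
        _ann.INTERGENIC,
        _ann.INTERGENIC,
        _ann.NCT,
        _ann.TSS,
        _ann.INTERGENIC,
        _ann.THREE_PRIME,
        _ann.GENIC,
        _ann.INTERGENIC,
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probe_step > self.probe_length:
            raise ValueError("probe_step must be <= probe_length (overlapping tiling)")
        if not (0 <= self.masked_fraction < 0.5):
            raise ValueError("masked_fraction must lie in [0, 0.5)")
        if self.planted_length_range[0] > self.planted_length_range[1]:
            raise ValueError("planted_length_range must be (lo, hi) with lo <= hi")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must lie in (0, 1)")
        if self.gene_strand not in ("+", "-"):
            raise ValueError("gene_strand must be '+' or '-'")


@dataclass
class PlantedMotif:
    start: int
    end: int
    strand: str
    inside_hfr: bool


@dataclass
class SyntheticTruth:
    """Ground truth for a simulated cluster."""

    planted_hfrs: list[Interval]
    planted_contexts: list[str]
    planted_motifs: list[PlantedMotif]
    masked: list[Interval]
    hs_cover: dict[str, list[bool]]

    def to_json(self) -> str:
        payload = {
            "planted_hfrs": [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "context": ctx}
                for iv, ctx in zip(self.planted_hfrs, self.planted_contexts)
            ],
            "planted_motifs": [asdict(m) for m in self.planted_motifs],
            "masked": [
                {"chrom": iv.chrom, "start": iv.start, "end": iv.end} for iv in self.masked
            ],
            "hs_cover": self.hs_cover,
        }
        return json.dumps(payload, indent=2)


@dataclass
class SyntheticDataset:
    """Everything one simulated cluster emits, as in-memory objects."""

    config: SimConfig
    tracks: dict[str, ProbeTrack]
    sequence: str
    genes: list[GeneModel]
    ncts: FeatureSet
    cpg: FeatureSet
    hs: dict[str, FeatureSet]
    truth: SyntheticTruth

    def genome(self) -> dict[str, str]:
        return {self.config.chrom: self.sequence}

    def write(self, outdir) -> None:
        from . import io as _io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for antibody, track in self.tracks.items():
            _io.write_probe_track(track, outdir / f"{antibody}.bedgraph")
        _io.write_fasta(self.genome(), outdir / "genome.fa")
        _io.write_gene_models_gff3(self.genes, outdir / "genes.gff3")
        _io.write_intervals_bed(list(self.ncts.intervals), outdir / "nct.bed")
        _io.write_intervals_bed(list(self.cpg.intervals), outdir / "cpg.bed")
        for cell, fs in self.hs.items():
            _io.write_intervals_bed(list(fs.intervals), outdir / f"hs_{cell}.bed")
        (outdir / "truth.json").write_text(self.truth.to_json())


def _snap(value: int, step: int, up: bool) -> int:
    if up:
        return int(-(-value // step) * step)
    return int(value // step * step)


def _lay_out_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    flank = 10_000
    usable = config.region_length - 2 * flank
    slot = usable / config.n_genes
    lo, hi = config.gene_length_range
    if slot < hi + 3000:
        raise ValueError("region too short for the requested gene layout")
    genes = []
    for i in range(config.n_genes):
        glen = int(rng.integers(lo, hi + 1))
        centre = flank + int((i + 0.5) * slot) + int(rng.integers(-300, 301))
        start = centre - glen // 2
        genes.append(
            GeneModel(
                name=f"hox{config.cluster.lower()}{i + 1}",
                cluster=config.cluster,
                ordinal=i + 1,
                strand=config.gene_strand,
                chrom=config.chrom,
                start=start,
                end=start + glen,
            )
        )
    return genes


def _plant_hfrs(
    config: SimConfig, genes: list[GeneModel], rng: np.random.Generator
) -> tuple[list[Interval], list[str]]:
    """Place planted depleted intervals so each realizes its intended context."""
    lo, hi = config.planted_length_range
    contexts = [
        config.context_cycle[k % len(config.context_cycle)]
        for k in range(config.n_planted_hfrs)
    ]
    # free gaps between consecutive gene bodies (plus both flanks)
    gaps = []
    prev_end = 2000
    for g in genes:
        gaps.append((prev_end, g.start))
        prev_end = g.end
    gaps.append((prev_end, config.region_length - 2000))
    gap_cursor = 0
    gene_cursor = 0
    placed: list[Interval] = []
    out_contexts: list[str] = []

    def collides(start: int, end: int) -> bool:
        return any(start < p.end + 1000 and p.start - 1000 < end for p in placed)

    for ctx in contexts:
        length = int(rng.integers(lo, hi + 1))
        start = None
        if ctx == _ann.GENIC:
            for _ in range(len(genes)):
                g = genes[gene_cursor % len(genes)]
                gene_cursor += 1
                if g.end - g.start >= length + 1200:
                    cand = g.start + ((g.end - g.start) - length) // 2
                    if not collides(cand, cand + length):
                        start = cand
                        break
        elif ctx == _ann.TSS:
            for _ in range(len(genes)):
                g = genes[gene_cursor % len(genes)]
                gene_cursor += 1
                cand = g.tss - 150 - length if g.strand == "+" else g.tss + 150
                if cand > 0 and not collides(cand, cand + length):
                    start = cand
                    break
        elif ctx == _ann.THREE_PRIME:
            for _ in range(len(genes)):
                g = genes[gene_cursor % len(genes)]
                gene_cursor += 1
                cand = g.tes + 150 if g.strand == "+" else g.tes - 150 - length
                if cand > 0 and not collides(cand, cand + length):
                    start = cand
                    break
        else:  # Intergenic or NCT: centre of a free gap, away from gene windows
            for _ in range(len(gaps)):
                gs, ge = gaps[gap_cursor % len(gaps)]
                gap_cursor += 1
                inner_s, inner_e = gs + 1800, ge - 1800
                if inner_e - inner_s < length + 200:
                    continue
                cand = (inner_s + inner_e - length) // 2
                if not collides(cand, cand + length):
                    start = cand
                    break
        if start is None:
            raise ValueError(
                f"cannot place a planted region with context {ctx!r} without overlap; "
                "reduce n_planted_hfrs or planted lengths"
            )
        # snap to the probe lattice: starts on the step grid, ends on the
        # step grid shifted by probe_length % probe_step, so a planted
        # region is exactly the union of the probes it contains and its
        # size takes the array's natural values (probe_length + k * step)
        residue = config.probe_length % config.probe_step
        s = _snap(start, config.probe_step, up=False)
        e = _snap(start + length - residue, config.probe_step, up=True) + residue
        placed.append(Interval(config.chrom, s, e))
        out_contexts.append(ctx)
    return placed, out_contexts


def _draw_masked(
    config: SimConfig, planted: list[Interval], rng: np.random.Generator
) -> list[Interval]:
    target = config.masked_fraction * config.region_length
    holes: list[Interval] = []
    total = 0
    tries = 0
    buffer = 300
    while total < target and tries < 10_000:
        tries += 1
        length = int(rng.integers(300, 1501))
        start = int(rng.integers(0, config.region_length - length))
        end = start + length
        clash = any(
            start < iv.end + buffer and iv.start - buffer < end
            for iv in list(planted) + holes
        )
        if clash:
            continue
        holes.append(Interval(config.chrom, start, end))
        total += length
    return sorted(holes, key=lambda iv: iv.start)


def _make_tracks(
    config: SimConfig,
    planted: list[Interval],
    holes: list[Interval],
    rng: np.random.Generator,
) -> dict[str, ProbeTrack]:
    starts = np.arange(
        0, config.region_length - config.probe_length + 1, config.probe_step
    )
    keep = np.ones(len(starts), dtype=bool)
    for hole in holes:
        keep &= ~(
            (starts < hole.end) & (starts + config.probe_length > hole.start)
        )
    starts = starts[keep]
    depleted = np.zeros(len(starts), dtype=bool)
    for iv in planted:
        depleted |= (starts >= iv.start) & (starts + config.probe_length <= iv.end)
    mu = np.where(depleted, config.mu_depleted, config.mu_enriched)
    tracks = {}
    for antibody in config.antibodies:
        nlrs = rng.normal(mu, config.sigma)
        probes = [
            Probe(config.chrom, int(s), int(s) + config.probe_length, float(v))
            for s, v in zip(starts, nlrs)
        ]
        tracks[antibody] = ProbeTrack(probes, antibody=antibody)
    return tracks


def _scrub_pattern(
    seq: np.ndarray,
    pattern: str,
    rng: np.random.Generator,
    protected: list[tuple[int, int]] | None = None,
) -> None:
    """Mutate bases in-place until neither the pattern nor its reverse
    complement occurs anywhere except at the protected (planted) spans.

    Chance occurrences in the random background — expected every ~4^k bp —
    would otherwise make the planted-motif truth inexact.  Any offending
    occurrence must contain at least one base outside every protected
    span (planted motifs are kept >= 1 bp apart), so mutating such a base
    removes it without touching the planted motifs; mutations can create
    new occurrences, hence the fixed-point loop.
    """
    protected_spans = set(protected or [])
    k = len(pattern)
    rc = reverse_complement(pattern)

    def protected_at(pos: int) -> bool:
        return any(s <= pos < e for s, e in protected_spans)

    for _ in range(200):
        text = "".join(seq.tolist())
        offenders = []
        for pat in {pattern, rc}:
            i = text.find(pat)
            while i != -1:
                if (i, i + k) not in protected_spans:
                    offenders.append(i)
                i = text.find(pat, i + 1)
        if not offenders:
            return
        for i in offenders:
            for j in range(i, i + k):
                if not protected_at(j):
                    current = seq[j]
                    choices = [b for b in "ACGT" if b != current]
                    seq[j] = choices[int(rng.integers(0, len(choices)))]
                    break
    raise RuntimeError("could not scrub chance motif occurrences")  # pragma: no cover


def _make_sequence(
    config: SimConfig,
    planted: list[Interval],
    rng: np.random.Generator,
    pattern: str = "GAGAG",
) -> tuple[str, list[PlantedMotif]]:
    gc = config.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = rng.choice(_BASES, size=config.region_length, p=probs)
    k = len(pattern)
    rc = reverse_complement(pattern)

    occupied: list[tuple[int, int]] = []

    def free(pos: int) -> bool:
        return all(pos + k + 1 <= s or pos >= e + 1 for s, e in occupied)

    motifs: list[PlantedMotif] = []

    def plant(lo: int, hi: int, inside: bool) -> bool:
        if hi - lo < k:
            return False
        for _ in range(50):
            pos = int(rng.integers(lo, hi - k + 1))
            if free(pos):
                strand = "+" if rng.random() < 0.5 else "-"
                word = pattern if strand == "+" else rc
                seq[pos : pos + k] = list(word)
                occupied.append((pos, pos + k))
                motifs.append(PlantedMotif(pos, pos + k, strand, inside))
                return True
        return False

    for iv in planted:
        n = rng.poisson(config.motif_rate_inside * len(iv) / 1000.0)
        for _ in range(int(n)):
            plant(iv.start, iv.end, inside=True)
    outside_bp = config.region_length - sum(len(iv) for iv in planted)
    n_out = rng.poisson(config.motif_rate_outside * outside_bp / 1000.0)
    planted_sorted = sorted(planted, key=lambda iv: iv.start)
    for _ in range(int(n_out)):
        for _ in range(50):
            pos = int(rng.integers(0, config.region_length - k))
            in_hfr = any(iv.start - k < pos < iv.end for iv in planted_sorted)
            if not in_hfr and free(pos):
                strand = "+" if rng.random() < 0.5 else "-"
                word = pattern if strand == "+" else rc
                seq[pos : pos + k] = list(word)
                occupied.append((pos, pos + k))
                motifs.append(PlantedMotif(pos, pos + k, strand, False))
                break
    _scrub_pattern(seq, pattern, rng, protected=occupied)
    return "".join(seq.tolist()), sorted(motifs, key=lambda m: m.start)


def _make_features(
    config: SimConfig,
    planted: list[Interval],
    contexts: list[str],
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> tuple[FeatureSet, FeatureSet, dict[str, FeatureSet], dict[str, list[bool]]]:
    ncts = [
        Interval(config.chrom, iv.start - 100, iv.end + 100, name=f"nct{i + 1}")
        for i, (iv, ctx) in enumerate(zip(planted, contexts))
        if ctx == _ann.NCT
    ]
    cpg = [
        Interval(config.chrom, g.tss - 400, g.tss + 400, name=f"cpg_{g.name}")
        for g in genes
    ]
    hs: dict[str, FeatureSet] = {}
    cover: dict[str, list[bool]] = {}
    for cell in config.cell_types:
        flags = [bool(rng.random() < config.hs_coverage) for _ in planted]
        peaks = [
            Interval(config.chrom, iv.start - 100, iv.end + 100, name=f"hs_{cell}_{i + 1}")
            for i, (iv, f) in enumerate(zip(planted, flags))
            if f
        ]
        hs[cell] = FeatureSet(peaks, kind="HS", cell_type=cell)
        cover[cell] = flags
    return (
        FeatureSet(ncts, kind="NCT"),
        FeatureSet(cpg, kind="CpG"),
        hs,
        cover,
    )


def simulate_cluster(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate one synthetic cluster dataset with full ground truth.

    The same seed yields byte-identical outputs.  Planted-context
    consistency is verified at generation time: classifying each planted
    interval against the emitted gene/NCT tracks reproduces its intended
    label.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    genes = _lay_out_genes(config, rng)
    planted, contexts = _plant_hfrs(config, genes, rng)
    order = np.argsort([iv.start for iv in planted])
    planted = [planted[i] for i in order]
    contexts = [contexts[i] for i in order]
    holes = _draw_masked(config, planted, rng)
    tracks = _make_tracks(config, planted, holes, rng)
    sequence, motifs = _make_sequence(config, planted, rng)
    ncts, cpg, hs, cover = _make_features(config, planted, contexts, genes, rng)
    for iv, ctx in zip(planted, contexts):
        got = _ann.classify_context(
            HFR(iv.chrom, iv.start, iv.end, 0, 0, 0.0), genes, ncts
        )
        if got != ctx:  # pragma: no cover - layout guarantees agreement
            raise RuntimeError(
                f"planted region {iv.start}-{iv.end} intended {ctx!r} classifies as {got!r}"
            )
    truth = SyntheticTruth(
        planted_hfrs=planted,
        planted_contexts=contexts,
        planted_motifs=motifs,
        masked=holes,
        hs_cover=cover,
    )
    return SyntheticDataset(
        config=config,
        tracks=tracks,
        sequence=sequence,
        genes=genes,
        ncts=ncts,
        cpg=cpg,
        hs=hs,
        truth=truth,
    )


def simulate_colony_counts(
    design: dict[str, float],
    batches: int = 2,
    replicates: int = 3,
    base_rate: float = 200.0,
    batch_sigma: float = 0.15,
    vector_label: str = "vector",
    seed: int = 0,
) -> list[AssayRecord]:
    """Poisson colony counts for an enhancer-blocking experiment.

    ``design`` maps construct label to true survival fraction.  Vector
    counts draw from Poisson(base_rate x batch_effect); construct counts
    scale that rate by the survival fraction.  A log-normal batch effect
    (sigma = ``batch_sigma``) emulates transfection-scale differences
    between biological replicate experiments.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if any(s < 0 for s in design.values()):
        raise ValueError("survival fractions must be >= 0")
    design = dict(design)
    design.setdefault(vector_label, 1.0)
    rng = np.random.default_rng(seed)
    records: list[AssayRecord] = []
    for b in range(1, batches + 1):
        effect = float(rng.lognormal(0.0, batch_sigma))
        for construct in sorted(design):
            s = design[construct]
            lam = base_rate * effect * s
            for r in range(1, replicates + 1):
                records.append(
                    AssayRecord(construct, f"batch{b}", r, int(rng.poisson(lam)))
                )
    return records
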
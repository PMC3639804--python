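"""Readers and writers for the pipeline's plain-text interchange formats.

Probe tracks travel as bedGraph or 4-column TSV, features as BED or GFF3,
genes as GFF3, sequence as FASTA, and colony counts as TSV.  Everything is
validated on the way in; all coordinates are converted to the internal
0-based half-open convention (GFF3 starts shift by exactly 1).
"""

from __future__ import annotations

import io as _stdio
import logging
from pathlib import Path
from typing import IO, Iterable, Sequence

from .core import AssayRecord, FeatureSet, GeneModel, Interval, Probe, ProbeTrack

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_probe_track",
    "write_probe_track",
    "read_features",
    "read_gene_models",
    "write_intervals_bed",
    "write_gene_models_gff3",
    "read_assay_table",
    "write_assay_table",
    "write_fasta",
]


class ParseError(ValueError):
    """Malformed input line; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _open_text(source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode), True
    return source, False


def read_probe_track(
    source,
    format: str = "bedgraph",
    antibody: str = "panH3",
    one_based: bool = False,
) -> ProbeTrack:
    """Read a probe NLR track from bedGraph or 4-column TSV.

    Columns are chrom, start, end, NLR.  ``one_based=True`` accepts TSVs
    whose starts are 1-based inclusive (shifted down by 1 on read); the
    deposited-array convention varies, so both are accepted.  Unsorted
    input is sorted with a logged notice.
    """
    if format not in ("bedgraph", "tsv"):
        raise ValueError(f"unknown probe-track format {format!r}")
    handle, should_close = _open_text(source)
    probes: list[Probe] = []
    was_sorted = True
    prev_key: tuple[str, int] | None = None
    try:
        for ln, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if format == "tsv" else line.split()
            if len(fields) < 4:
                raise ParseError(
                    f"expected 4 columns (chrom, start, end, nlr), got {len(fields)}", ln
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"non-integer coordinates {fields[1]!r}/{fields[2]!r}", ln)
            try:
                nlr = float(fields[3])
            except ValueError:
                raise ParseError(f"non-numeric NLR {fields[3]!r}", ln)
            if one_based:
                start -= 1
            try:
                probes.append(Probe(chrom, start, end, nlr))
            except ValueError as exc:
                raise ParseError(str(exc), ln)
            key = (chrom, start)
            if prev_key is not None and key < prev_key:
                was_sorted = False
            prev_key = key
    finally:
        if should_close:
            handle.close()
    if not probes:
        logger.warning("probe track %r is empty", antibody)
    if not was_sorted:
        logger.info("probe track %r was unsorted; sorting on read", antibody)
    return ProbeTrack(probes, antibody=antibody)


def write_probe_track(track: ProbeTrack, sink, format: str = "bedgraph") -> None:
    handle, should_close = _open_text(sink, "w")
    sep = "\t"
    try:
        for p in track:
            handle.write(f"{p.chrom}{sep}{p.start}{sep}{p.end}{sep}{p.nlr:.6f}\n")
    finally:
        if should_close:
            handle.close()


def read_features(
    source,
    format: str = "bed",
    kind: str = "custom",
    cell_type: str | None = None,
) -> FeatureSet:
    """Read a feature track (BED 0-based half-open, or GFF3 1-based closed).

    GFF3 starts are shifted down by 1 so internal intervals are half-open.
    Overlapping records are kept as-is (no auto-merge).
    """
    if format not in ("bed", "gff3"):
        raise ValueError(f"unknown feature format {format!r}")
    handle, should_close = _open_text(source)
    intervals: list[Interval] = []
    try:
        for ln, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "bed":
                    if len(fields) < 3:
                        raise ValueError(f"BED needs >= 3 columns, got {len(fields)}")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else None
                    score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
                    strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
                else:
                    if len(fields) < 5:
                        raise ValueError(f"GFF3 needs >= 5 columns, got {len(fields)}")
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    name = None
                    if len(fields) > 8:
                        attrs = _parse_gff3_attributes(fields[8])
                        name = attrs.get("Name") or attrs.get("ID")
                    score = None
                    strand = fields[6] if len(fields) > 6 and fields[6] in "+-" else None
                intervals.append(Interval(chrom, start, end, name=name, score=score, strand=strand))
            except ValueError as exc:
                raise ParseError(f"{exc} [{line!r}]", ln)
    finally:
        if should_close:
            handle.close()
    return FeatureSet(intervals, kind=kind, cell_type=cell_type)


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(source) -> list[GeneModel]:
    """Read gene models from GFF3 ``gene`` records.

    Attributes must carry ``Name``; ``cluster`` and ``ordinal`` attributes
    drive the naming scheme downstream.
    """
    handle, should_close = _open_text(source)
    genes: list[GeneModel] = []
    try:
        for ln, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"GFF3 needs 9 columns, got {len(fields)}", ln)
            if fields[2] != "gene":
                continue
            attrs = _parse_gff3_attributes(fields[8])
            name = attrs.get("Name") or attrs.get("ID")
            if name is None:
                raise ParseError("gene record lacks Name/ID attribute", ln)
            try:
                ordinal = int(attrs["ordinal"])
            except (KeyError, ValueError):
                raise ParseError(f"gene {name}: missing/invalid 'ordinal' attribute", ln)
            genes.append(
                GeneModel(
                    name=name,
                    cluster=attrs.get("cluster", "?"),
                    ordinal=ordinal,
                    strand=fields[6],
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                )
            )
    finally:
        if should_close:
            handle.close()
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def write_gene_models_gff3(genes: Sequence[GeneModel], sink) -> None:
    handle, should_close = _open_text(sink, "w")
    try:
        handle.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.name};Name={g.name};cluster={g.cluster};ordinal={g.ordinal}"
            handle.write(
                f"{g.chrom}\thfrscan\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    finally:
        if should_close:
            handle.close()


def write_intervals_bed(intervals: Sequence[Interval], sink) -> None:
    """Write sorted intervals as BED6 (name/score/strand default to '.')."""
    keys = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    if keys != sorted(keys):
        raise ValueError("intervals must be sorted before writing BED")
    handle, should_close = _open_text(sink, "w")
    try:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            score = f"{iv.score:g}" if iv.score is not None else "."
            strand = iv.strand if iv.strand is not None else "."
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n")
    finally:
        if should_close:
            handle.close()


def read_assay_table(source, vector_label: str = "vector") -> list[AssayRecord]:
    """Read a colony-count TSV with columns construct, batch, replicate, colonies.

    Every batch must contain the vector-control construct (normalization is
    impossible without it) and (construct, batch, replicate) must be unique.
    """
    import pandas as pd

    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, sep="\t")
    else:
        df = pd.read_csv(source, sep="\t")
    required = ["construct", "batch", "replicate", "colonies"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"assay table missing column(s): {', '.join(missing)}")
    records = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (str(row.construct), str(row.batch), int(row.replicate))
        if key in seen:
            raise ValueError(f"duplicate assay record {key}")
        seen.add(key)
        records.append(AssayRecord(key[0], key[1], key[2], int(row.colonies)))
    by_batch: dict[str, set[str]] = {}
    for r in records:
        by_batch.setdefault(r.batch, set()).add(r.construct)
    for batch, constructs in sorted(by_batch.items()):
        if vector_label not in constructs:
            raise ValueError(
                f"batch {batch!r} lacks the vector control {vector_label!r}; "
                "normalization impossible"
            )
    return records


def write_assay_table(records: Iterable[AssayRecord], sink) -> None:
    handle, should_close = _open_text(sink, "w")
    try:
        handle.write("construct\tbatch\treplicate\tcolonies\n")
        for r in records:
            handle.write(f"{r.construct}\t{r.batch}\t{r.replicate}\t{r.colonies}\n")
    finally:
        if should_close:
            handle.close()


def write_fasta(sequences: dict[str, str], sink, width: int = 70) -> None:
    handle, should_close = _open_text(sink, "w")
    try:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if should_close:
            handle.close()
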
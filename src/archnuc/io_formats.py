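"""Readers and writers for the formats the pipeline touches.

FASTA (genome), BED3/BED6 (reads, called centers), bedGraph
(occupancy), GFF3 or 4-column TSV (gene start codons) and 2-column TSV
(single-end tag counts).  All coordinates become 0-based half-open on
the way in; GFF3's 1-based inclusive convention is converted here and
only here.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .types import (
    FormatError,
    GeneAnnotation,
    GenomeSequence,
    MappedRead,
    NucleosomeCenter,
    OccupancyTrack,
    TagTrack,
)


def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Load a FASTA file into a :class:`GenomeSequence` (uppercased)."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"duplicate contig id {record.id!r} in {path}")
        contigs[record.id] = str(record.seq).upper()
    if not contigs:
        raise FormatError(f"no FASTA records found in {path}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_reads_bed(path: str | os.PathLike) -> list[MappedRead]:
    """Parse BED3+ fragment intervals; column 6 (strand) is optional.

    Missing or '.' strand defaults to '+': every fragment-level
    statistic downstream is strand-symmetric, so the default is inert.
    """
    reads: list[MappedRead] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            contig = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
            reads.append(MappedRead(contig, start, end, strand))
    return reads


def write_reads_bed(reads: Iterable[MappedRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t.\t0\t{r.strand}\n")


def write_bedgraph(tracks: dict[str, OccupancyTrack] | OccupancyTrack, path: str | os.PathLike) -> None:
    """Write occupancy as bedGraph, merging runs of equal value.

    Zero runs are written too so that a round trip restores the full
    vector; values are printed to 6 decimals.
    """
    if isinstance(tracks, OccupancyTrack):
        tracks = {tracks.contig: tracks}
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="occupancy"\n')
        for contig, track in tracks.items():
            v = track.values
            if len(v) == 0:
                continue
            # run-length boundaries of equal consecutive values
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{v[s]:.6f}\n")


def read_bedgraph(path: str | os.PathLike, lengths: dict[str, int] | None = None) -> dict[str, OccupancyTrack]:
    """Inverse of :func:`write_bedgraph`.

    If ``lengths`` is omitted, each contig's length is taken as the
    rightmost interval end seen.
    """
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            contig, s, e, val = line.split("\t")
            spans.setdefault(contig, []).append((int(s), int(e), float(val)))
    out: dict[str, OccupancyTrack] = {}
    for contig, runs in spans.items():
        n = lengths[contig] if lengths else max(e for _, e, _ in runs)
        v = np.zeros(n)
        for s, e, val in runs:
            v[s:e] = val
        out[contig] = OccupancyTrack(contig, v)
    return out


def write_centers_bed(centers: Iterable[NucleosomeCenter], path: str | os.PathLike) -> None:
    """Called dyads as 1-bp BED intervals, height in the score column."""
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tsource\theight\n")
        for c in centers:
            fh.write(f"{c.contig}\t{c.position}\t{c.position + 1}\t{c.source}\t{c.height:.6f}\n")


def read_centers_bed(path: str | os.PathLike) -> list[NucleosomeCenter]:
    centers: list[NucleosomeCenter] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            contig, start, _end, source, height = line.split("\t")
            centers.append(NucleosomeCenter(contig, int(start), float(height), source))
    return centers


_GFF_FEATURES = {"gene", "CDS"}


def read_annotations(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Read gene start-codon anchors from GFF3 or 4-column TSV.

    GFF3 rows (1-based, inclusive) yield the leftmost base minus one
    for '+' features and the rightmost base minus one for '-'
    features, i.e. the first base of the start codon in 0-based
    coordinates either way.  The TSV form is ``id  contig  position
    strand`` with the position already 0-based.
    """
    annotations: list[GeneAnnotation] = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        is_gff = first.startswith("##gff") or len(first.split("\t")) == 9
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if is_gff:
                if len(fields) != 9:
                    raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
                contig, _src, ftype, start, end, _score, strand, _frame, attrs = fields
                if ftype not in _GFF_FEATURES:
                    continue
                gene_id = _gff_attr(attrs, ("ID", "gene_id", "Name")) or f"feature{lineno}"
            else:
                if len(fields) != 4:
                    raise FormatError(f"{path}:{lineno}: expected 4 TSV columns")
                gene_id, contig, pos, strand = fields
                if strand not in ("+", "-"):
                    raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
                annotations.append(GeneAnnotation(gene_id, contig, int(pos), strand))
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            start0, end0 = int(start) - 1, int(end)  # to 0-based half-open
            position = start0 if strand == "+" else end0 - 1
            annotations.append(GeneAnnotation(gene_id, contig, position, strand))
    return annotations


def _gff_attr(attrs: str, keys: Sequence[str]) -> str | None:
    pairs = dict(
        kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
    )
    for key in keys:
        if key in pairs:
            return pairs[key]
    return None


def write_annotations_tsv(annotations: Iterable[GeneAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.contig}\t{a.position}\t{a.strand}\n")


def write_annotations_gff3(
    genes: Iterable[tuple[str, str, int, int, str]], path: str | os.PathLike
) -> None:
    """Write full gene spans as GFF3 ``gene`` features.

    ``genes`` holds (id, contig, start, end, strand) in 0-based
    half-open coordinates; converted to GFF3's 1-based inclusive.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, contig, start, end, strand in genes:
            fh.write(
                f"{contig}\tarchnuc\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={gene_id}\n"
            )


def read_tags_tsv(path: str | os.PathLike, length: int, contig: str = "chr") -> np.ndarray:
    """Read ``position<TAB>count`` rows into a dense count vector."""
    counts = np.zeros(length)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            pos, count = line.split("\t")
            counts[int(pos)] += float(count)
    return counts


def write_tags_tsv(counts: np.ndarray, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for pos in np.flatnonzero(counts):
            fh.write(f"{pos}\t{counts[pos]:.6f}\n")
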
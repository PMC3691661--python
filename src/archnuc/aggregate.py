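"""Positional averages of occupancy: metagene, NDR depth, locus export.

The metagene profile averages the occupancy track across genes in a
window around each start codon, oriented so positive offsets point
into the ORF, and normalizes by the genome-wide mean occupancy so a
uniform track reads exactly 1.0 everywhere.  The nucleosome-depleted
region (NDR) upstream of start codons then shows up as a dip below 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr

from .types import GeneAnnotation, OccupancyTrack


def genome_mean(tracks: dict[str, OccupancyTrack]) -> float:
    """Mean occupancy over every base of every contig."""
    total = sum(float(t.values.sum()) for t in tracks.values())
    n = sum(len(t) for t in tracks.values())
    if n == 0:
        raise ValueError("no track data")
    return total / n


@dataclass
class MetageneProfile:
    """Gene-averaged relative occupancy around start codons.

    ``offsets`` run -F..+F in gene orientation (negative = upstream of
    the ATG); ``values`` are occupancy relative to the genome-wide
    mean; ``n_genes_at_offset`` counts how many genes contributed at
    each offset (genes near contig edges contribute only their
    in-bounds offsets).
    """

    offsets: np.ndarray
    values: np.ndarray
    n_genes: int
    n_genes_at_offset: np.ndarray


def metagene_start_codons(
    tracks: dict[str, OccupancyTrack],
    annotations: Sequence[GeneAnnotation],
    flank: int = 500,
) -> MetageneProfile:
    """Average relative occupancy in a +/- ``flank`` bp window around ATGs.

    For a '+' gene the window is track[start-F .. start+F]; for a '-'
    gene the same window is read right-to-left so that positive
    offsets always point into the ORF.  Out-of-bounds positions are
    simply ignored (ragged averaging), and the per-offset means are
    divided by the genome-wide mean occupancy.
    """
    if not annotations:
        raise ValueError("no annotations given")
    width = 2 * flank + 1
    acc = np.zeros(width)
    cnt = np.zeros(width, dtype=np.int64)
    offsets = np.arange(-flank, flank + 1)
    for gene in annotations:
        if gene.contig not in tracks:
            raise ValueError(f"gene {gene.gene_id} on contig without a track")
        v = tracks[gene.contig].values
        sign = 1 if gene.strand == "+" else -1
        pos = gene.position + sign * offsets
        ok = (pos >= 0) & (pos < len(v))
        acc[ok] += v[pos[ok]]
        cnt[ok] += 1
    mean = genome_mean(tracks)
    if mean == 0:
        raise ValueError("track is identically zero; cannot normalize")
    with np.errstate(invalid="ignore"):
        values = np.where(cnt > 0, acc / np.maximum(cnt, 1) / mean, np.nan)
    return MetageneProfile(offsets, values, len(annotations), cnt)


def ndr_depth(
    profile: MetageneProfile,
    upstream: tuple[int, int] = (-150, 0),
    gene_body: tuple[int, int] = (50, 250),
) -> float:
    """mean(gene-body window) - mean(upstream window), half-open in bp.

    Positive values indicate depletion upstream of the start codon
    relative to the gene body.
    """
    def window_mean(lo: int, hi: int) -> float:
        sel = (profile.offsets >= lo) & (profile.offsets < hi)
        vals = profile.values[sel]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"window [{lo}, {hi}) has no data")
        return float(vals.mean())

    return window_mean(*gene_body) - window_mean(*upstream)


@dataclass
class RegionProfile:
    """A raw occupancy slice plus its genome-relative summary."""

    contig: str
    start: int
    end: int
    values: np.ndarray
    mean: float
    relative_mean: float


def region_profile(
    tracks: dict[str, OccupancyTrack],
    contig: str,
    start: int,
    end: int,
) -> RegionProfile:
    """Occupancy over [start, end) and its mean relative to the genome.

    Nucleosome-refractory regions (e.g. rDNA operons) score a
    relative mean far below 1.
    """
    if contig not in tracks:
        raise ValueError(f"no track for contig {contig!r}")
    v = tracks[contig].values
    if start < 0 or end > len(v) or start >= end:
        raise ValueError(f"interval [{start}, {end}) out of bounds for {contig}")
    values = v[start:end]
    mean = float(values.mean())
    return RegionProfile(contig, start, end, values, mean, mean / genome_mean(tracks))


@dataclass
class ProfileComparison:
    log2_ratio: np.ndarray
    rank_correlation: float


def compare_profiles(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    pseudocount: float = 1e-6,
) -> ProfileComparison:
    """Per-offset log2(a/b) with a pseudocount, plus Spearman correlation."""
    a = np.asarray(profile_a, float)
    b = np.asarray(profile_b, float)
    if a.shape != b.shape:
        raise ValueError("profiles must have matching offsets")
    log2 = np.log2((a + pseudocount) / (b + pseudocount))
    rho = spearmanr(a, b).statistic
    return ProfileComparison(log2, float(rho))
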
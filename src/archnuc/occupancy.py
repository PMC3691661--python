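"""Center-weighted occupancy, dyad calling, and single-end conversion.

The occupancy score spreads each protected fragment's evidence over a
truncated Gaussian kernel around its center: a fragment of odd length
has one central base and contributes ``exp(-0.5*(d/sigma)^2)`` at
distance ``d <= dmax`` from it; an even-length fragment has two
equally plausible central bases and contributes half a kernel at each,
so every fragment carries the same total mass regardless of parity.
Dyads are then called as prominent local maxima of the summed track,
and each called peak is snapped to the center of a nearby fragment of
preferred length when one exists.

Single-end libraries only observe fragment 5' ends.  ``convert_single_end``
reconstructs fractional fragments by pairing each Watson tag with the
opposite-strand tag field inside a plausible insert-length window
[a, b] = [51, 68] bp, splitting the tag's count proportionally to the
Crick counts at each candidate end (and symmetrically for Crick tags).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .types import (
    PEAK_FALLBACK,
    GenomeSequence,
    MappedRead,
    NucleosomeCenter,
    OccupancyTrack,
    PseudoPairedRead,
)

#: read lengths tried in order when snapping a peak to a fragment center
DEFAULT_LENGTH_PRIORITY = (60, 61, 59, 62, 58)


def select_reads_by_length(
    reads: list[MappedRead], min_len: int, max_len: int
) -> list[MappedRead]:
    """Keep reads with ``min_len <= length <= max_len`` (order preserved)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= r.length <= max_len]


def center_weight(d, sigma: float = 10.0, dmax: int = 25):
    """Truncated Gaussian kernel weight at distance ``d`` from a center.

    Returns ``exp(-0.5*(d/sigma)**2)`` for ``0 <= d <= dmax`` and 0
    beyond the truncation radius.  Accepts scalars or arrays.
    """
    d = np.asarray(d)
    if (d < 0).any():
        raise ValueError("distance d must be non-negative")
    w = np.exp(-0.5 * (d / sigma) ** 2)
    w = np.where(d <= dmax, w, 0.0)
    return float(w) if w.ndim == 0 else w


def _kernel(sigma: float, dmax: int) -> np.ndarray:
    d = np.abs(np.arange(-dmax, dmax + 1))
    return np.exp(-0.5 * (d / sigma) ** 2)


def build_occupancy(
    reads: list[MappedRead] | list[PseudoPairedRead],
    genome: GenomeSequence,
    sigma: float = 10.0,
    dmax: int = 25,
    even_read_literal_halving: bool = False,
) -> dict[str, OccupancyTrack]:
    """Sum center-weighted kernels from all reads into per-contig tracks.

    Each odd-length read deposits mass 1 at its unique center before
    kernel spreading; each even-length read deposits 0.5 at each of
    its two candidate centers, so parity does not change a read's
    total evidentiary weight.  ``even_read_literal_halving`` instead
    deposits 0.25 per candidate center (total mass 0.5 per even read),
    the alternative reading of the even-read weighting rule.
    Contributions are truncated at contig edges.  Accepts weighted
    pseudo-paired reads; their ``weight`` scales the deposited mass.
    """
    lengths = genome.lengths
    mass = {contig: np.zeros(n) for contig, n in lengths.items()}
    even_share = 0.25 if even_read_literal_halving else 0.5
    for read in reads:
        if read.contig not in mass:
            raise ValueError(f"read {read} on unknown contig {read.contig!r}")
        n = lengths[read.contig]
        if read.start < 0 or read.end > n:
            raise ValueError(f"read {read} out of bounds for contig of length {n}")
        weight = getattr(read, "weight", 1.0)
        length = read.end - read.start
        mid = read.start + (length - 1) // 2
        if length % 2 == 1:
            mass[read.contig][mid] += weight
        else:
            mass[read.contig][mid] += even_share * weight
            mass[read.contig][mid + 1] += even_share * weight
    kernel = _kernel(sigma, dmax)
    out = {}
    for contig, m in mass.items():
        values = np.convolve(m, kernel, mode="same") if len(m) else m
        # clip float noise that can dip infinitesimally below zero
        out[contig] = OccupancyTrack(contig, np.maximum(values, 0.0))
    return out


def call_peaks(
    track: OccupancyTrack,
    min_height_quantile: float = 0.60,
    min_prominence: float = 0.25,
    min_separation: int = 50,
) -> list[NucleosomeCenter]:
    """Call putative dyads as prominent local maxima of the track.

    "Well-defined" is made concrete as three simultaneous conditions:
    height at or above the ``min_height_quantile`` quantile of the
    track, topographic prominence at least ``min_prominence``, and
    greedy thinning (highest peak first) so that no two surviving
    peaks are closer than ``min_separation`` bp.  A plateau maximum is
    reported at its leftmost index.
    """
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    v = track.values
    if len(v) == 0 or not v.any():
        return []
    idx, props = find_peaks(v, prominence=min_prominence, plateau_size=(1, None))
    positions = props["left_edges"]
    threshold = float(np.quantile(v, min_height_quantile))
    keep = v[positions] >= threshold
    positions = positions[keep]
    if len(positions) == 0:
        return []
    heights = v[positions]
    # greedy thinning: tallest first, ties broken leftmost for determinism
    order = np.lexsort((positions, -heights))
    accepted: list[int] = []
    taken = np.zeros(len(v), dtype=bool)
    for i in order:
        p = positions[i]
        if not taken[p]:
            accepted.append(i)
            lo = max(0, p - min_separation + 1)
            taken[lo : p + min_separation] = True
    accepted.sort(key=lambda i: positions[i])
    return [
        NucleosomeCenter(track.contig, int(positions[i]), float(heights[i]))
        for i in accepted
    ]


def assign_center_read(
    peak: NucleosomeCenter,
    reads: list[MappedRead],
    window: int = 5,
    length_priority: tuple[int, ...] = DEFAULT_LENGTH_PRIORITY,
) -> NucleosomeCenter:
    """Snap a called peak to the center of a nearby preferred-length read.

    Read lengths are tried in ``length_priority`` order; within a
    length class the candidate center nearest the peak wins (distance
    ties break leftmost).  Even-length reads offer both of their
    candidate centers.  When no candidate lies within ``+/- window``
    bp for any priority length, the peak position itself is kept with
    source "peak-fallback".
    """
    by_length: dict[int, list[int]] = {}
    for r in reads:
        if r.contig != peak.contig:
            continue
        by_length.setdefault(r.length, []).extend(r.centers)
    for length in length_priority:
        candidates = by_length.get(length)
        if not candidates:
            continue
        best = None
        for c in sorted(candidates):
            d = abs(c - peak.position)
            if d <= window and (best is None or d < abs(best - peak.position)):
                best = c
        if best is not None:
            return NucleosomeCenter(peak.contig, best, peak.height, str(length))
    return NucleosomeCenter(peak.contig, peak.position, peak.height, PEAK_FALLBACK)


def assign_centers(
    peaks: list[NucleosomeCenter],
    reads: list[MappedRead],
    window: int = 5,
    length_priority: tuple[int, ...] = DEFAULT_LENGTH_PRIORITY,
) -> list[NucleosomeCenter]:
    """Vectorized :func:`assign_center_read` over many peaks.

    Builds one sorted candidate-center index per (contig, length) so a
    genome-scale peak list resolves in O(n log n).
    """
    index: dict[tuple[str, int], np.ndarray] = {}
    for r in reads:
        key = (r.contig, r.length)
        index.setdefault(key, [])  # type: ignore[arg-type]
        index[key].extend(r.centers)  # type: ignore[union-attr]
    index = {k: np.array(sorted(v)) for k, v in index.items()}

    out: list[NucleosomeCenter] = []
    for peak in peaks:
        assigned = None
        for length in length_priority:
            centers = index.get((peak.contig, length))
            if centers is None or len(centers) == 0:
                continue
            j = np.searchsorted(centers, peak.position)
            best = None
            for c in centers[max(0, j - 1) : j + 1]:
                d = abs(int(c) - peak.position)
                if d <= window and (best is None or d < abs(best - peak.position)):
                    best = int(c)
            if best is not None:
                assigned = NucleosomeCenter(peak.contig, best, peak.height, str(length))
                break
        out.append(assigned or NucleosomeCenter(peak.contig, peak.position, peak.height, PEAK_FALLBACK))
    return out


@dataclass
class ConversionReport:
    """Bookkeeping for single-end to pseudo-paired conversion."""

    emitted_weight: float = 0.0
    dropped_weight: float = 0.0
    dropped_tags: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def total_weight(self) -> float:
        return self.emitted_weight + self.dropped_weight


def convert_single_end(
    watson: np.ndarray,
    crick: np.ndarray,
    contig: str = "chr",
    a: int = 51,
    b: int = 68,
) -> tuple[list[PseudoPairedRead], ConversionReport]:
    """Fan stranded 5'-tag counts out into fractional fragments.

    A Watson tag of count w at position i becomes pseudo fragments
    [i, i+k) for k = a..b, each weighted ``w * c[i+k] / sum_j c[i+j]``
    where c is the Crick tag vector (Crick tags are stored at the
    half-open end coordinate of their fragment).  Crick tags fan out
    mirror-symmetrically to [i-k, i).  Total emitted weight plus
    dropped weight equals the total tag count exactly; a tag whose
    opposite-strand window sums to zero is undefined under the
    formula, so it is dropped and counted rather than imputed.
    """
    if a > b:
        raise ValueError(f"a={a} > b={b}")
    watson = np.asarray(watson, dtype=float)
    crick = np.asarray(crick, dtype=float)
    n = len(watson)
    report = ConversionReport()
    pseudo: list[PseudoPairedRead] = []

    for i in np.flatnonzero(watson):
        w = watson[i]
        lo, hi = i + a, min(i + b + 1, n)
        window = crick[lo:hi] if lo < n else np.empty(0)
        denom = window.sum()
        if denom <= 0:
            report.dropped_weight += w
            report.dropped_tags += 1
            continue
        for off in np.flatnonzero(window):
            end = lo + int(off)
            weight = w * window[off] / denom
            pseudo.append(PseudoPairedRead(contig, int(i), end, float(weight)))
            report.emitted_weight += weight
    for j in np.flatnonzero(crick):
        c = crick[j]
        lo, hi = max(j - b, 0), j - a + 1
        window = watson[lo:hi] if hi > 0 else np.empty(0)
        denom = window.sum()
        if denom <= 0:
            report.dropped_weight += c
            report.dropped_tags += 1
            continue
        for off in np.flatnonzero(window):
            start = lo + int(off)
            weight = c * window[off] / denom
            pseudo.append(PseudoPairedRead(contig, start, int(j), float(weight)))
            report.emitted_weight += weight
    return pseudo, report
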
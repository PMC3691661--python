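"""Sequence statistics around called dyads.

Two families of statistics characterise the nucleosome positioning
code.  Dinucleotide-group frequency profiles measure, at each offset
relative to the dyad, how often the dinucleotide starting there
belongs to the AT group {AA, AT, TA, TT} or the GC group
{CC, CG, GC, GG}; in positioned nucleosomes both profiles oscillate
with the ~10-bp helical repeat, half a turn out of phase.  Pentamer
enrichment compares the relative frequency of each of the 4^5 = 1024
pentamers in nucleosomal DNA against non-nucleosomal background DNA;
poly(dA:dT)-excluding genomes deplete every A/T-only pentamer from
nucleosomal sequence.

Both dinucleotide groups and the double-strand pentamer counts are
closed under reverse complement, so no separate strand pass is
needed and ratio(p) == ratio(revcomp(p)) holds by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import GenomeSequence, MappedRead, NucleosomeCenter

AT_GROUP = ("AA", "AT", "TA", "TT")
GC_GROUP = ("CC", "CG", "GC", "GG")

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Bases to codes A=0 C=1 G=2 T=3; anything else (N) becomes -1."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def extract_centered_windows(
    genome: GenomeSequence,
    centers: Sequence[NucleosomeCenter],
    halfwidth: int,
) -> tuple[list[str], int]:
    """Genomic windows [center - H, center + H) around each dyad.

    Returns the window sequences and the number of dyads skipped
    because their window would leave the contig.
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    windows: list[str] = []
    skipped = 0
    for c in centers:
        seq = genome[c.contig]
        lo, hi = c.position - halfwidth, c.position + halfwidth
        if lo < 0 or hi > len(seq):
            skipped += 1
            continue
        windows.append(seq[lo:hi])
    return windows, skipped


@dataclass
class DinucProfile:
    """Per-offset dinucleotide-group frequency around the dyad.

    Offsets run -H .. H-2: the dinucleotide starting at the last
    window position would need a base outside the window, so a 2H-bp
    window supports 2H-1 dinucleotide start offsets.
    """

    group: str
    offsets: np.ndarray
    frequency: np.ndarray
    n_sequences: int


def dinuc_group_profile(
    windows: Sequence[str],
    group: str = "AT",
    smooth: int = 3,
    symmetrize: bool = True,
) -> DinucProfile:
    """Frequency of AT-group or GC-group dinucleotides at each offset.

    At each start offset the frequency is the fraction of windows
    whose dinucleotide there belongs to the group, among windows
    where both bases are unambiguous (no N).  ``smooth`` applies a
    centered moving average of that width (0 or 1 disables);
    ``symmetrize`` averages the profile with its mirror image about
    the dyad, the reverse-complement symmetry the statistic should
    have in expectation.
    """
    if not windows:
        raise ValueError("need at least one window")
    length = len(windows[0])
    if any(len(w) != length for w in windows):
        raise ValueError("all windows must have the same length")
    if length % 2 != 0 or length < 4:
        raise ValueError("window length must be even and >= 4 (2*halfwidth)")
    if group not in ("AT", "GC"):
        raise ValueError("group must be 'AT' or 'GC'")
    halfwidth = length // 2

    codes = np.vstack([_encode(w) for w in windows])
    left, right = codes[:, :-1], codes[:, 1:]
    valid = (left >= 0) & (right >= 0)
    if group == "AT":
        in_group = ((left == 0) | (left == 3)) & ((right == 0) | (right == 3))
    else:
        in_group = ((left == 1) | (left == 2)) & ((right == 1) | (right == 2))
    in_group &= valid
    denom = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(denom > 0, in_group.sum(axis=0) / np.maximum(denom, 1), np.nan)

    if smooth and smooth > 1:
        kernel = np.ones(smooth)
        counts = np.convolve(np.ones_like(freq), kernel, mode="same")
        freq = np.convolve(freq, kernel, mode="same") / counts
    if symmetrize:
        # a dinucleotide starting at offset o maps to offset -o-2 under
        # reverse complement of the window, i.e. the reversed array
        freq = 0.5 * (freq + freq[::-1])

    offsets = np.arange(-halfwidth, halfwidth - 1)
    return DinucProfile(group, offsets, freq, len(windows))


@dataclass
class PeriodEstimate:
    """Result of autocorrelation period estimation.

    ``period`` is None when the profile shows no usable oscillation,
    in which case the diagnostics say why: a sub-threshold peak
    autocorrelation, or a detrended amplitude that is negligible
    relative to the profile's mean level.
    """

    period: int | None
    peak_autocorr: float
    relative_amplitude: float


def estimate_period(
    profile: DinucProfile | np.ndarray,
    min_lag: int = 2,
    max_lag: int = 20,
    min_autocorr: float = 0.2,
    min_relative_amplitude: float = 0.05,
) -> PeriodEstimate:
    """Dominant oscillation period of a profile, in bp.

    Subtracts the mean, computes the normalized autocorrelation over
    lags ``min_lag..max_lag``, takes the lag of the maximum and
    refines it by parabolic interpolation before rounding to integer
    bp.  The normalized autocorrelation is scale-free, so a flatness
    guard is applied first: when the detrended RMS amplitude is below
    ``min_relative_amplitude`` of the mean level, or the peak
    autocorrelation is below ``min_autocorr``, no period is reported.
    """
    x = profile.frequency if isinstance(profile, DinucProfile) else np.asarray(profile, float)
    x = x[np.isfinite(x)]
    n = len(x)
    max_lag = min(max_lag, n // 3)
    if max_lag < min_lag:
        raise ValueError(f"profile too short ({n} offsets) for period search")
    mean_level = float(np.mean(x))
    d = x - mean_level
    denom = float(np.dot(d, d))
    rel_amp = float(np.sqrt(denom / n) / abs(mean_level)) if mean_level != 0 else np.inf
    if denom == 0 or rel_amp < min_relative_amplitude:
        return PeriodEstimate(None, 0.0, rel_amp)

    lags = np.arange(1, max_lag + 2)
    r = np.array([np.dot(d[:-l], d[l:]) / denom for l in lags])
    search = slice(min_lag - 1, max_lag)  # indices of lags min_lag..max_lag
    best = int(np.argmax(r[search])) + (min_lag - 1)
    peak = float(r[best])
    if peak < min_autocorr:
        return PeriodEstimate(None, peak, rel_amp)
    # parabolic sub-bp refinement using the two neighboring lags
    if 0 < best < len(r) - 1:
        y0, y1, y2 = r[best - 1], r[best], r[best + 1]
        denom2 = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom2 if denom2 != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return PeriodEstimate(int(round(lags[best] + delta)), peak, rel_amp)


def estimate_phase_offset(
    profile_at: DinucProfile | np.ndarray,
    profile_gc: DinucProfile | np.ndarray,
    period: int | None = None,
) -> int | None:
    """Circular lag (bp) that aligns the GC profile onto the AT profile.

    Returns the shift s in [0, period) maximizing the circular
    cross-correlation of the detrended profiles, or None when either
    profile carries no oscillation.  Antiphase helical repeats yield
    period/2 (5 bp for the canonical 10-bp repeat).
    """
    a = profile_at.frequency if isinstance(profile_at, DinucProfile) else np.asarray(profile_at, float)
    g = profile_gc.frequency if isinstance(profile_gc, DinucProfile) else np.asarray(profile_gc, float)
    if len(a) != len(g):
        raise ValueError("profiles must share offsets")
    if period is None:
        est = estimate_period(profile_at)
        if est.period is None:
            return None
        period = est.period
    if estimate_period(profile_gc).period is None:
        return None
    a = a - a.mean()
    g = g - g.mean()
    n = len(a)
    scores = [float(np.dot(a, np.roll(g, s))) for s in range(period)]
    return int(np.argmax(scores)) if n else None


ALPHABET = "ACGT"
PENTAMERS = ["".join(p) for p in itertools.product(ALPHABET, repeat=5)]


def _pentamer_index(p: str) -> int:
    i = 0
    for ch in p:
        i = i * 4 + ALPHABET.index(ch)
    return i


_RC_PERM = np.array([_pentamer_index(reverse_complement(p)) for p in PENTAMERS])


def count_pentamers(sequences: Sequence[str]) -> np.ndarray:
    """Occurrences of each of the 1024 pentamers on both strands.

    Sliding 5-bp windows containing N are skipped.  Counting the
    reverse complement of every occurrence makes the vector exactly
    reverse-complement symmetric.
    """
    counts = np.zeros(1024, dtype=np.int64)
    powers = 4 ** np.arange(4, -1, -1)
    for seq in sequences:
        if len(seq) < 5:
            continue
        codes = _encode(seq)
        win = np.lib.stride_tricks.sliding_window_view(codes, 5)
        ok = (win >= 0).all(axis=1)
        if not ok.any():
            continue
        ids = win[ok] @ powers
        counts += np.bincount(ids, minlength=1024)
    return counts + counts[_RC_PERM]


def classify_pentamer(p: str) -> str:
    bases = set(p)
    if bases <= {"A", "T"}:
        return "AT-only"
    if bases <= {"G", "C"}:
        return "GC-only"
    return "mixed"


@dataclass
class PentamerTable:
    """1024-row nucleosomal-vs-background pentamer enrichment table."""

    df: pd.DataFrame
    pseudocount: float

    def ratio(self, pentamer: str) -> float:
        return float(self.df.loc[pentamer, "ratio"])


def pentamer_enrichment(
    nucleosomal_windows: Sequence[str],
    background_sequences: Sequence[str],
    pseudocount: float = 1.0,
) -> PentamerTable:
    """Enrichment ratio P_nucleosome / P for every pentamer.

    Both sets are counted double-stranded; counts get ``pseudocount``
    added before normalizing to relative frequencies, so every ratio
    is finite and positive even for absent pentamers.
    """
    if not nucleosomal_windows or not background_sequences:
        raise ValueError("both sequence sets must be non-empty")
    nuc = count_pentamers(nucleosomal_windows).astype(float) + pseudocount
    bg = count_pentamers(background_sequences).astype(float) + pseudocount
    p_nuc = nuc / nuc.sum()
    p_bg = bg / bg.sum()
    ratio = p_nuc / p_bg
    df = pd.DataFrame(
        {
            "pentamer": PENTAMERS,
            "count_nucleosomal": (nuc - pseudocount).astype(np.int64),
            "count_background": (bg - pseudocount).astype(np.int64),
            "p_nucleosome": p_nuc,
            "p_background": p_bg,
            "ratio": ratio,
            "log2_ratio": np.log2(ratio),
            "kmer_class": [classify_pentamer(p) for p in PENTAMERS],
        }
    ).set_index("pentamer")
    return PentamerTable(df, pseudocount)


def pentamer_class_summary(table: PentamerTable) -> dict:
    """Headline counts for the A/T-only and G/C-only pentamer classes.

    Reports how many of the 32 A/T-only pentamers are depleted
    (ratio < 1), how many of the 32 G/C-only pentamers are enriched
    (ratio > 1), and the single most disfavored pentamer overall
    (minimum ratio; ties broken lexicographically).
    """
    df = table.df
    at_only = df[df["kmer_class"] == "AT-only"]
    gc_only = df[df["kmer_class"] == "GC-only"]
    # index is lexicographically sorted by construction, so idxmin's
    # first-occurrence rule is the lexicographic tie-break
    return {
        "n_AT_only": int(len(at_only)),
        "n_GC_only": int(len(gc_only)),
        "n_AT_only_depleted": int((at_only["ratio"] < 1).sum()),
        "n_GC_only_enriched": int((gc_only["ratio"] > 1).sum()),
        "most_disfavored": str(df["ratio"].idxmin()),
    }


def nonnucleosomal_sequences(
    genome: GenomeSequence, reads: Sequence[MappedRead]
) -> list[str]:
    """Genomic complement of the merged read footprint, per contig.

    The literal reading of "non-nucleosomal DNA": every stretch not
    covered by any protected fragment.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.contigs}
    for r in reads:
        by_contig[r.contig].append((r.start, r.end))
    out: list[str] = []
    for contig, intervals in by_contig.items():
        seq = genome[contig]
        pos = 0
        for start, end in sorted(intervals):
            if start > pos:
                out.append(seq[pos:start])
            pos = max(pos, end)
        if pos < len(seq):
            out.append(seq[pos:])
    return [s for s in out if s]
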
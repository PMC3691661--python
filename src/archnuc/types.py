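"""Core value types shared across the pipeline.

Coordinate convention: everything internal is 0-based, half-open
(BED-style).  GFF3 input is converted at the boundary in
:mod:`archnuc.io_formats` and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A malformed input file (bad FASTA/BED/GFF record)."""


@dataclass
class GenomeSequence:
    """Named contigs over the alphabet {A, C, G, T, N}, uppercased.

    Attributes
    ----------
    contigs : dict of str -> str
        Contig id to base string.
    """

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains illegal characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]


class MappedRead(NamedTuple):
    """A nucleosome-protected fragment mapped to the genome."""

    contig: str
    start: int
    end: int  # exclusive
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def centers(self) -> tuple[int, ...]:
        """Candidate dyad positions: one for odd lengths, two for even.

        A fragment of odd length has a unique central base; an
        even-length fragment has two equally plausible central bases
        (e.g. offsets 29 and 30 of a 60-bp fragment).
        """
        n = self.length
        mid = self.start + (n - 1) // 2
        if n % 2 == 1:
            return (mid,)
        return (mid, mid + 1)


class GeneAnnotation(NamedTuple):
    """A gene reduced to its start-codon anchor.

    ``position`` is the first transcribed/translated base of the ATG in
    0-based coordinates: the leftmost base of the codon for ``+`` genes
    and the rightmost base for ``-`` genes.
    """

    gene_id: str
    contig: str
    position: int
    strand: str


@dataclass
class TagTrack:
    """Stranded single-end 5'-tag counts along one contig.

    ``watson[i]`` counts tags whose fragment starts at i (forward
    strand).  ``crick[j]`` counts tags stored at the half-open *end*
    coordinate j of their fragment, i.e. one past the rightmost base;
    with that convention a Watson tag at i and a Crick tag at i + k
    bound a fragment [i, i + k).
    """

    contig: str
    watson: np.ndarray
    crick: np.ndarray

    def __post_init__(self) -> None:
        self.watson = np.asarray(self.watson, dtype=float)
        self.crick = np.asarray(self.crick, dtype=float)
        if self.watson.shape != self.crick.shape:
            raise ValueError("watson and crick vectors must be the same length")
        if (self.watson < 0).any() or (self.crick < 0).any():
            raise ValueError("tag counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.watson.sum() + self.crick.sum())


class PseudoPairedRead(NamedTuple):
    """A fractional fragment reconstructed from single-end tags."""

    contig: str
    start: int
    end: int
    weight: float


@dataclass
class OccupancyTrack:
    """Per-base center-weighted occupancy along one contig."""

    contig: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("occupancy values must be a 1-D vector")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("occupancy values must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.values)


PEAK_FALLBACK = "peak-fallback"


class NucleosomeCenter(NamedTuple):
    """A called dyad.

    ``source`` records provenance: the length of the representative
    read ("60", "61", ...) or ``"peak-fallback"`` when no read of a
    preferred length lay within the search window of the peak.
    """

    contig: str
    position: int
    height: float
    source: str = PEAK_FALLBACK


class PlantedNucleosome(NamedTuple):
    """Ground-truth dyad emitted by the simulator."""

    contig: str
    position: int
    score: float
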
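"""Synthetic genomes with a planted nucleosome positioning code.

The generator builds everything the pipeline consumes — genome,
gene annotations, ground-truth dyads, and reads — with the sequence
features that position real nucleosomes planted at known strength:

* gene bodies carry a cosine-modulated dinucleotide preference of
  period ``helical_period``: AT-group dinucleotides {AA,AT,TA,TT} are
  favored at phase maxima and GC-group dinucleotides {CC,CG,GC,GG} at
  phase minima, producing the 10-bp helical repeat with the two groups
  half a turn apart;
* intergenic spacers are A/T-rich and seeded with poly(dA:dT)-like
  tracts (alternating (AT)n tracts and A/T homopolymers), the
  sequences nucleosomes exclude;
* an optional "rDNA-like" zone is filled with maximal-penalty sequence
  and is fully refractory to placement.

Nucleosome dyads are drawn by sequential Boltzmann sampling from a
per-base positioning energy (cosine phasing reward minus a
poly(dA:dT)-run penalty), with a hard minimum spacing; reads are then
sampled around dyads with Gaussian center jitter and uniform fragment
lengths.  Every stage is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .types import GeneAnnotation, GenomeSequence, MappedRead, PlantedNucleosome, TagTrack

# fixed per-stage seed offsets so stages can be rerun independently
_STAGE = {"genome": 1, "placement": 2, "reads": 3}


class GeneSpan(NamedTuple):
    gene_id: str
    contig: str
    start: int
    end: int
    strand: str


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults describe a compact archaeal-like chromosome: a 200-kb
    contig that is mostly coding, short A/T-rich intergenic spacers,
    a 5-kb nucleosome-refractory zone, ~60-bp nucleosome footprints
    and 55-65 bp protected fragments at ~60x coverage.
    """

    genome_length: int = 200_000
    n_genes: int = 150
    intergenic_length: int = 120
    intergenic_at_fraction: float = 0.85
    rdna_zone: tuple[int, int] | None | str = "auto"  # "auto": 45-47.5% of the genome
    helical_period: int = 10
    code_modulation: float = 0.8  # dinucleotide-class probability modulation in gene bodies
    phase_amplitude: float = 1.0  # alpha: weight of the cosine phasing term in the energy
    polyat_penalty: float = 0.25  # gamma: per-base penalty for A/T runs under the footprint
    polyat_min_run: int = 5
    footprint: int = 60
    min_spacing: int = 60
    beta: float = 4.0  # inverse temperature of Boltzmann placement
    read_beta: float = 0.05  # gentler inverse temperature for per-dyad read depth
    n_nucleosomes: int = 3000
    n_reads: int = 200_000
    read_length_window: tuple[int, int] = (55, 65)
    jitter_sd: float = 2.0
    jitter_max: int = 4
    contig: str = "sim1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.intergenic_at_fraction <= 1:
            raise ValueError("intergenic_at_fraction must be in [0, 1]")
        if self.rdna_zone == "auto":
            self.rdna_zone = (
                int(0.45 * self.genome_length),
                int(0.475 * self.genome_length),
            )
        if self.rdna_zone is not None:
            zs, ze = self.rdna_zone
            if not (0 <= zs < ze <= self.genome_length):
                raise ValueError("rdna_zone must lie within the genome")
        minimum = (self.n_genes + 1) * self.intergenic_length
        if minimum >= self.genome_length:
            raise ValueError("genes do not fit: spacers alone exceed the genome")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STAGE[stage],))
        )


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AT_DINUCS = [b"AA", b"AT", b"TA", b"TT"]
_GC_DINUCS = [b"CC", b"CG", b"GC", b"GG"]
_MIXED_DINUCS = [
    bytes([x, y])
    for x in _BASES
    for y in _BASES
    if (chr(x) in "AT") != (chr(y) in "AT")
]


def _gene_body(start: int, length: int, config: SimConfig, rng: np.random.Generator) -> bytes:
    """Gene-body sequence with phase-modulated dinucleotide classes.

    Dinucleotides are laid down two bases at a time; at genomic
    position i the AT-group probability is 0.25*(1 + m*cos(2*pi*i/P))
    and the GC-group probability its mirror image, with mixed
    dinucleotides taking the remaining half.  The cosine phase runs in
    absolute genomic coordinates so planted nucleosomes share one
    rotational frame genome-wide.
    """
    m = config.code_modulation
    n_dinuc = length // 2
    pos = start + 2 * np.arange(n_dinuc)
    phase = np.cos(2 * np.pi * pos / config.helical_period)
    p_at = 0.25 * (1 + m * phase)
    p_gc = 0.25 * (1 - m * phase)
    u = rng.random(n_dinuc)
    member = rng.integers(0, 8, n_dinuc)  # enough entropy for any class
    out = bytearray()
    for k in range(n_dinuc):
        if u[k] < p_at[k]:
            out += _AT_DINUCS[member[k] % 4]
        elif u[k] < p_at[k] + p_gc[k]:
            out += _GC_DINUCS[member[k] % 4]
        else:
            out += _MIXED_DINUCS[member[k]]
    if length % 2:
        out.append(_BASES[rng.integers(0, 4)])
    return bytes(out)


def _spacer(length: int, config: SimConfig, rng: np.random.Generator) -> bytes:
    """A/T-rich intergenic spacer with embedded A/T tracts.

    Background bases are i.i.d. with total A+T probability
    ``intergenic_at_fraction``; on top, short tracts (alternating
    (AT)n, poly-A or poly-T, length >= polyat_min_run) are stamped in.
    Alternating tracts are made twice as common as either homopolymer
    so that ATATA/TATAT dominate the A/T-only pentamer spectrum of
    linker DNA.
    """
    at = config.intergenic_at_fraction
    probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    seq = bytearray(_BASES[rng.choice(4, size=length, p=probs)].tobytes())
    n_tracts = max(1, length // 25)
    for _ in range(n_tracts):
        run = int(rng.integers(config.polyat_min_run, config.polyat_min_run + 8))
        if run >= length:
            run = length
        start = int(rng.integers(0, length - run + 1))
        kind = rng.random()
        if kind < 0.5:
            first = b"AT" if rng.random() < 0.5 else b"TA"
            tract = (first * (run // 2 + 1))[:run]
        elif kind < 0.75:
            tract = b"A" * run
        else:
            tract = b"T" * run
        seq[start : start + run] = tract
    return bytes(seq)


def generate_genome(
    config: SimConfig,
) -> tuple[GenomeSequence, list[GeneAnnotation], list[GeneSpan]]:
    """Deterministically build the genome, start-codon anchors, and spans.

    Layout: spacer, gene, spacer, gene, ..., spacer, with gene strands
    alternating +,-,+,... so every start codon abuts an intergenic
    spacer.  The optional rdna_zone is overwritten last with
    alternating-AT maximal-penalty sequence, and genes overlapping it
    are dropped from the annotation.
    """
    rng = config.rng("genome")
    n_spacers = config.n_genes + 1
    coding_total = config.genome_length - n_spacers * config.intergenic_length
    gene_len = coding_total // config.n_genes
    parts: list[bytes] = []
    annotations: list[GeneAnnotation] = []
    spans: list[GeneSpan] = []
    pos = 0
    for g in range(config.n_genes):
        parts.append(_spacer(config.intergenic_length, config, rng))
        pos += config.intergenic_length
        length = gene_len if g < config.n_genes - 1 else coding_total - gene_len * (config.n_genes - 1)
        parts.append(_gene_body(pos, length, config, rng))
        strand = "+" if g % 2 == 0 else "-"
        start_codon = pos if strand == "+" else pos + length - 1
        gene_id = f"g{g + 1:04d}"
        annotations.append(GeneAnnotation(gene_id, config.contig, start_codon, strand))
        spans.append(GeneSpan(gene_id, config.contig, pos, pos + length, strand))
        pos += length
    parts.append(_spacer(config.intergenic_length, config, rng))
    seq = bytearray(b"".join(parts))
    assert len(seq) == config.genome_length
    if config.rdna_zone is not None:
        zs, ze = config.rdna_zone
        seq[zs:ze] = (b"AT" * ((ze - zs) // 2 + 1))[: ze - zs]
        keep = [
            (a, s)
            for a, s in zip(annotations, spans)
            if s.end <= zs or s.start >= ze
        ]
        annotations = [a for a, _ in keep]
        spans = [s for _, s in keep]
    genome = GenomeSequence({config.contig: seq.decode("ascii")})
    return genome, annotations, spans


def positioning_energy(genome: GenomeSequence, config: SimConfig) -> dict[str, np.ndarray]:
    """Per-base placement score: cosine phasing reward minus A/T-run penalty.

    score(i) = alpha * sum_{j=-W..W-1} cos(2*pi*j/P) *
               (1[dinuc at i+j in AT-group] - 1[in GC-group])
             - gamma * #bases in [i-W, i+W) lying in A/T runs >= polyat_min_run,
    with W = footprint/2.  Positions whose footprint window leaves the
    contig score -inf and are never placed.
    """
    W = config.footprint // 2
    out: dict[str, np.ndarray] = {}
    for contig, seq in genome.contigs.items():
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_at = (codes == ord("A")) | (codes == ord("T"))
        is_gc = (codes == ord("C")) | (codes == ord("G"))
        n = len(codes)
        score = np.full(n, -np.inf)
        if n < 2 * W + 1:
            out[contig] = score
            continue
        at_dinuc = (is_at[:-1] & is_at[1:]).astype(float)
        gc_dinuc = (is_gc[:-1] & is_gc[1:]).astype(float)
        signal = at_dinuc - gc_dinuc
        j = np.arange(-W, W)
        kernel = np.cos(2 * np.pi * j / config.helical_period)
        # correlation: cos_term[i] = sum_j kernel[j] * signal[i + j - W_offset]
        corr = np.convolve(signal, kernel[::-1], mode="valid")
        # corr[i0] covers dinuc starts i0 .. i0+2W-1, i.e. dyad i = i0 + W
        run_mask = _in_long_at_run(is_at, config.polyat_min_run)
        cs = np.concatenate(([0], np.cumsum(run_mask)))
        # interior dyads: window [i-W, i+W) inside the contig and every
        # dinucleotide start i+j (j = -W..W-1) has both bases available
        interior = np.arange(W, n - W)
        polyat = cs[interior + W] - cs[interior - W]
        score[interior] = (
            config.phase_amplitude * corr[interior - W]
            - config.polyat_penalty * polyat
        )
        out[contig] = score
    return out


def _in_long_at_run(is_at: np.ndarray, min_run: int) -> np.ndarray:
    """Boolean per base: inside a maximal A/T run of length >= min_run."""
    n = len(is_at)
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask
    padded = np.concatenate(([False], is_at, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            mask[s:e] = True
    return mask


def place_nucleosomes(
    energy: dict[str, np.ndarray], config: SimConfig
) -> list[PlantedNucleosome]:
    """Sequential Boltzmann sampling of dyads with hard minimum spacing.

    Equivalent to repeatedly drawing a dyad with probability
    proportional to exp(beta * score) over still-admissible positions
    and removing everything within ``min_spacing``; implemented as an
    exponential-clock race (E_i ~ Exp(1)/w_i, accept in increasing E
    order while admissible), which has the identical distribution by
    the memorylessness of the exponential.  Dyads whose footprint
    would overlap the rdna_zone are inadmissible outright.
    """
    rng = config.rng("placement")
    planted: list[PlantedNucleosome] = []
    W = config.footprint // 2
    for contig, score in energy.items():
        admissible = np.isfinite(score)
        if config.rdna_zone is not None:
            zs, ze = config.rdna_zone
            lo, hi = max(0, zs - W), min(len(score), ze + W)
            admissible[lo:hi] = False
        if not admissible.any():
            continue
        finite = score[admissible]
        w = np.zeros(len(score))
        w[admissible] = np.exp(config.beta * (finite - finite.max()))
        with np.errstate(divide="ignore"):
            clocks = np.where(w > 0, rng.exponential(size=len(score)) / np.maximum(w, 1e-300), np.inf)
        order = np.argsort(clocks, kind="stable")
        blocked = ~admissible
        n_accepted = 0
        for i in order:
            if n_accepted >= config.n_nucleosomes or not np.isfinite(clocks[i]):
                break
            if blocked[i]:
                continue
            planted.append(PlantedNucleosome(contig, int(i), float(score[i])))
            lo = max(0, i - config.min_spacing + 1)
            blocked[lo : i + config.min_spacing] = True
            n_accepted += 1
    planted.sort(key=lambda p: (p.contig, p.position))
    return planted


def simulate_reads(
    planted: list[PlantedNucleosome],
    genome: GenomeSequence,
    config: SimConfig,
) -> list[MappedRead]:
    """Protected fragments around planted dyads.

    Each read picks a dyad with probability proportional to
    exp(read_beta * placement score), a length uniform on
    ``read_length_window``, and a center equal to the dyad plus
    discretized Gaussian jitter (sd ``jitter_sd``, truncated at
    +/- ``jitter_max``).  Fragments that would touch the contig edge
    are discarded.  ``read_beta`` is deliberately much smaller than
    the placement ``beta``: placement decides *where* nucleosomes sit
    (sharp), read depth varies only a few-fold between sites, as in
    real MNase libraries.
    """
    if not planted:
        return []
    rng = config.rng("reads")
    lengths_map = genome.lengths
    scores = np.array([p.score for p in planted])
    weights = np.exp(config.read_beta * (scores - scores.max()))
    weights /= weights.sum()
    idx = rng.choice(len(planted), size=config.n_reads, p=weights)
    lo, hi = config.read_length_window
    frag_len = rng.integers(lo, hi + 1, size=config.n_reads)
    jit_vals = np.arange(-config.jitter_max, config.jitter_max + 1)
    jit_p = np.exp(-0.5 * (jit_vals / config.jitter_sd) ** 2)
    jit_p /= jit_p.sum()
    jitter = rng.choice(jit_vals, size=config.n_reads, p=jit_p)
    # for even lengths the center may be either candidate base
    even_side = rng.integers(0, 2, size=config.n_reads)
    reads: list[MappedRead] = []
    for k in range(config.n_reads):
        p = planted[idx[k]]
        L = int(frag_len[k])
        center = p.position + int(jitter[k])
        if L % 2 == 1:
            start = center - (L - 1) // 2
        else:
            start = center - (L // 2 - 1) - int(even_side[k])
        end = start + L
        if start < 0 or end >= lengths_map[p.contig]:
            continue
        reads.append(MappedRead(p.contig, start, end, "+"))
    return reads


def tags_from_reads(reads: list[MappedRead], genome: GenomeSequence) -> dict[str, TagTrack]:
    """Collapse fragments to stranded 5'-tag counts (single-end mode).

    Watson tags at fragment starts; Crick tags at the half-open end
    coordinate (the pairing convention of
    :func:`archnuc.occupancy.convert_single_end`).  The fragment
    records themselves are withheld, as in a real single-end library.
    """
    tracks = {
        contig: TagTrack(contig, np.zeros(n), np.zeros(n))
        for contig, n in genome.lengths.items()
    }
    for r in reads:
        tracks[r.contig].watson[r.start] += 1
        tracks[r.contig].crick[r.end] += 1
    return tracks


@dataclass
class SimResult:
    """Everything one simulation run produced."""

    config: SimConfig
    genome: GenomeSequence
    annotations: list[GeneAnnotation]
    spans: list[GeneSpan]
    energy: dict[str, np.ndarray]
    planted: list[PlantedNucleosome]
    reads: list[MappedRead]
    tags: dict[str, TagTrack] | None = None


def simulate(config: SimConfig, single_end: bool = False) -> SimResult:
    """Run genome generation, energy, placement, and read simulation."""
    genome, annotations, spans = generate_genome(config)
    energy = positioning_energy(genome, config)
    planted = place_nucleosomes(energy, config)
    reads = simulate_reads(planted, genome, config)
    tags = tags_from_reads(reads, genome) if single_end else None
    return SimResult(config, genome, annotations, spans, energy, planted, reads, tags)


def negative_control_config(seed: int = 0, **overrides) -> SimConfig:
    """A no-code control: uniform genome statistics, flat energy.

    With ``code_modulation = phase_amplitude = polyat_penalty = 0``
    and no A/T-biased spacers, placement is uniform over admissible
    positions and reads carry no positioning signal.  Read depth is
    kept low so that uncovered background sequence remains for the
    enrichment denominator.
    """
    base = dict(
        code_modulation=0.0,
        phase_amplitude=0.0,
        polyat_penalty=0.0,
        intergenic_at_fraction=0.5,
        rdna_zone=None,
        genome_length=100_000,
        n_genes=75,
        n_nucleosomes=1500,
        n_reads=3000,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)
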
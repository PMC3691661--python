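import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from archnuc.occupancy import (
    assign_center_read,
    assign_centers,
    build_occupancy,
    call_peaks,
    center_weight,
    convert_single_end,
    select_reads_by_length,
)
from archnuc.types import GenomeSequence, MappedRead, NucleosomeCenter, OccupancyTrack

from conftest import random_reads


def flat_genome(n: int, contig: str = "c1") -> GenomeSequence:
    return GenomeSequence({contig: "A" * n})


class TestSelectReads:
    def test_window_boundaries_inclusive(self):
        reads = [MappedRead("c1", 0, n) for n in (54, 55, 60, 65, 66)]
        kept = select_reads_by_length(reads, 55, 65)
        assert [r.length for r in kept] == [55, 60, 65]

    def test_eukaryotic_window_on_short_reads_is_empty(self):
        reads = [MappedRead("c1", 0, 60)]
        assert select_reads_by_length(reads, 137, 157) == []

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(1)
        reads = [MappedRead("c1", 0, int(n)) for n in rng.integers(40, 200, 300)]
        kept = select_reads_by_length(reads, 55, 65)
        assert len(kept) == sum(1 for r in reads if 55 <= r.length <= 65)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            select_reads_by_length([], 65, 55)


class TestCenterWeight:
    def test_zero_distance_is_one(self):
        assert center_weight(0) == 1.0

    def test_beyond_truncation_is_zero(self):
        assert center_weight(26) == 0.0
        assert center_weight(25) > 0.0

    def test_closed_form_value(self):
        assert center_weight(10) == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            center_weight(-1)


def brute_force_occupancy(reads, n, sigma=10.0, dmax=25, even_share=0.5):
    """Independent oracle: per-position, per-read, per-candidate-center loop."""
    track = np.zeros(n)
    for read in reads:
        centers = read.centers
        share = 1.0 if len(centers) == 1 else even_share
        for p in range(n):
            for c in centers:
                d = abs(p - c)
                if d <= dmax:
                    track[p] += share * math.exp(-0.5 * (d / sigma) ** 2)
    return track


class TestBuildOccupancy:
    def test_odd_read_kernel_values(self):
        genome = flat_genome(200)
        track = build_occupancy([MappedRead("c1", 70, 131)], genome)["c1"]
        c = 100  # center of [70, 131)
        assert track.values[c] == pytest.approx(1.0)
        assert track.values[c - 10] == pytest.approx(math.exp(-0.5))
        assert track.values[c + 10] == pytest.approx(math.exp(-0.5))
        bump = track.values[c - 25 : c + 26]
        np.testing.assert_allclose(bump, bump[::-1], atol=1e-12)

    def test_even_read_split_centers(self):
        genome = flat_genome(100)
        track = build_occupancy([MappedRead("c1", 0, 60)], genome)["c1"]
        expected = 0.5 + 0.5 * math.exp(-0.5 * (1 / 10) ** 2)
        assert track.values[29] == pytest.approx(expected, abs=1e-6)
        assert track.values[30] == pytest.approx(expected, abs=1e-6)

    def test_literal_halving_flag_halves_even_read_mass(self):
        genome = flat_genome(200)
        reads = [MappedRead("c1", 40, 100)]
        full = build_occupancy(reads, genome)["c1"].values
        literal = build_occupancy(reads, genome, even_read_literal_halving=True)["c1"].values
        np.testing.assert_allclose(literal, full / 2)

    def test_empty_read_set_gives_zero_track(self):
        track = build_occupancy([], flat_genome(50))["c1"]
        assert not track.values.any()

    def test_out_of_bounds_read_named_in_error(self):
        with pytest.raises(ValueError, match="out of bounds"):
            build_occupancy([MappedRead("c1", 10, 80)], flat_genome(60))

    def test_unknown_contig_rejected(self):
        with pytest.raises(ValueError, match="unknown contig"):
            build_occupancy([MappedRead("cX", 0, 61)], flat_genome(100))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(100, 2000))
            reads = random_reads(rng, "c1", n, int(rng.integers(1, 40)))
            track = build_occupancy(reads, flat_genome(n))["c1"].values
            np.testing.assert_allclose(track, brute_force_occupancy(reads, n), atol=1e-9)

    def test_mass_conservation_away_from_edges(self):
        # every interior read contributes the same total mass regardless of parity
        genome = flat_genome(500)
        kernel_mass = sum(math.exp(-0.5 * (d / 10) ** 2) for d in range(-25, 26))
        for length in (59, 60):
            track = build_occupancy([MappedRead("c1", 200, 200 + length)], genome)["c1"]
            assert track.values.sum() == pytest.approx(kernel_mass, rel=1e-12)


def brute_force_peaks(values, q, prom_min, min_sep):
    """Enumeration oracle: strict/plateau maxima, prominence, greedy thinning."""
    from scipy.signal import peak_prominences

    n = len(values)
    maxima = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and values[j + 1] == values[j]:
            j += 1
        if values[i] > values[i - 1] and j + 1 < n and values[j] > values[j + 1]:
            maxima.append(i)  # leftmost plateau index
        i = j + 1
    if not maxima:
        return []
    prom = peak_prominences(values, maxima)[0]
    thr = np.quantile(values, q)
    cands = [(values[p], -p, p) for p, pr in zip(maxima, prom)
             if pr >= prom_min and values[p] >= thr]
    cands.sort(reverse=True)
    accepted = []
    for _, _, p in cands:
        if all(abs(p - a) >= min_sep for a in accepted):
            accepted.append(p)
    return sorted(accepted)


class TestCallPeaks:
    def test_flat_track_has_no_peaks(self):
        assert call_peaks(OccupancyTrack("c1", np.full(100, 2.0))) == []

    def test_all_zero_track_is_empty_not_error(self):
        assert call_peaks(OccupancyTrack("c1", np.zeros(100))) == []

    def test_single_kernel_bump_peaks_at_apex(self):
        genome = flat_genome(200)
        track = build_occupancy([MappedRead("c1", 70, 131)], genome)["c1"]
        (peak,) = call_peaks(track)
        assert peak.position == 100
        assert peak.height == pytest.approx(1.0)

    def test_greedy_thinning_keeps_taller_of_close_pair(self):
        v = np.zeros(200)
        v[80], v[120] = 3.0, 2.0  # 40 bp apart
        v[81], v[119] = 0.1, 0.1  # make both strict maxima
        peaks = call_peaks(OccupancyTrack("c1", v), min_height_quantile=0.0,
                           min_separation=50)
        assert [p.position for p in peaks] == [80]

    def test_plateau_reports_leftmost_index(self):
        v = np.zeros(50)
        v[20:23] = 1.0
        (peak,) = call_peaks(OccupancyTrack("c1", v), min_height_quantile=0.0)
        assert peak.position == 20

    def test_positions_invariant_under_constant_shift(self):
        rng = np.random.default_rng(3)
        reads = random_reads(rng, "c1", 3000, 200)
        v = build_occupancy(reads, flat_genome(3000))["c1"].values
        base = [p.position for p in call_peaks(OccupancyTrack("c1", v),
                                               min_height_quantile=0.0)]
        shifted = [p.position for p in call_peaks(OccupancyTrack("c1", v + 5.0),
                                                  min_height_quantile=0.0)]
        assert base == shifted

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(15):
            n = int(rng.integers(200, 1500))
            reads = random_reads(rng, "c1", n, int(rng.integers(5, 60)))
            v = build_occupancy(reads, flat_genome(n))["c1"].values
            got = [p.position for p in call_peaks(OccupancyTrack("c1", v),
                                                  min_height_quantile=0.3,
                                                  min_prominence=0.25,
                                                  min_separation=50)]
            assert got == brute_force_peaks(v, 0.3, 0.25, 50)


class TestAssignCenterRead:
    peak = NucleosomeCenter("c1", 1000, 5.0)

    @staticmethod
    def read_with_center(center, length, contig="c1"):
        # build a read whose (leftmost) candidate center is `center`
        start = center - (length - 1) // 2
        return MappedRead(contig, start, start + length)

    def test_sixty_bp_read_nearby_wins(self):
        reads = [self.read_with_center(1003, 60)]
        got = assign_center_read(self.peak, reads)
        assert (got.position, got.source) == (1003, "60")

    def test_priority_order_prefers_61_over_closer_59(self):
        reads = [self.read_with_center(1002, 59), self.read_with_center(1004, 61)]
        got = assign_center_read(self.peak, reads)
        assert (got.position, got.source) == (1004, "61")

    def test_fallback_to_peak_position(self):
        reads = [self.read_with_center(1020, 60)]  # outside +/-5
        got = assign_center_read(self.peak, reads)
        assert (got.position, got.source) == (1000, "peak-fallback")

    def test_distance_tie_breaks_leftmost(self):
        reads = [self.read_with_center(997, 61), self.read_with_center(1003, 61)]
        got = assign_center_read(self.peak, reads)
        assert got.position == 997

    def test_other_contig_reads_ignored(self):
        reads = [self.read_with_center(1000, 60, contig="c2")]
        got = assign_center_read(self.peak, reads)
        assert got.source == "peak-fallback"

    def test_batch_assignment_matches_single(self):
        rng = np.random.default_rng(9)
        reads = random_reads(rng, "c1", 5000, 300)
        peaks = [NucleosomeCenter("c1", int(p), 1.0)
                 for p in rng.integers(30, 4970, 50)]
        batch = assign_centers(peaks, reads)
        single = [assign_center_read(p, reads) for p in peaks]
        assert batch == single


class TestConvertSingleEnd:
    def test_unique_pairing_recovers_fragment(self):
        n = 200
        watson, crick = np.zeros(n), np.zeros(n)
        watson[50] = 1.0
        crick[110] = 1.0  # insert length 60, inside [51, 68]
        pseudo, report = convert_single_end(watson, crick)
        frags = {(r.start, r.end): r.weight for r in pseudo}
        assert frags == {(50, 110): pytest.approx(1.0)}  # from both tags
        # Watson fan-out and Crick fan-out each contribute the full tag count
        assert report.emitted_weight == pytest.approx(2.0)
        assert report.dropped_weight == 0.0

    def test_weights_follow_opposite_strand_frequencies(self):
        n = 300
        watson, crick = np.zeros(n), np.zeros(n)
        watson[100] = 2.0
        crick[100 + 55] = 1.0
        crick[100 + 60] = 3.0
        pseudo, _ = convert_single_end(watson, crick)
        w: dict = {}
        for r in pseudo:
            w[(r.start, r.end)] = w.get((r.start, r.end), 0.0) + r.weight
        # Watson fan-out splits 2.0 as 1/4 : 3/4; each Crick tag maps its
        # full count back onto the lone Watson position
        assert w[(100, 155)] == pytest.approx(2.0 * 1 / 4 + 1.0)
        assert w[(100, 160)] == pytest.approx(2.0 * 3 / 4 + 3.0)

    def test_zero_denominator_drops_tag(self):
        n = 100
        watson, crick = np.zeros(n), np.zeros(n)
        watson[10] = 2.5
        pseudo, report = convert_single_end(watson, crick)
        assert pseudo == []
        assert report.dropped_tags == 1
        assert report.dropped_weight == pytest.approx(2.5)

    def test_insert_lengths_confined_to_window(self):
        rng = np.random.default_rng(2)
        watson = rng.poisson(0.2, 500).astype(float)
        crick = rng.poisson(0.2, 500).astype(float)
        pseudo, _ = convert_single_end(watson, crick)
        assert pseudo, "expected some pairings"
        assert all(51 <= r.end - r.start <= 68 for r in pseudo)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_total_tag_count_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(80, 400))
        watson = rng.poisson(0.3, n).astype(float)
        crick = rng.poisson(0.3, n).astype(float)
        pseudo, report = convert_single_end(watson, crick)
        total = watson.sum() + crick.sum()
        assert report.emitted_weight + report.dropped_weight == pytest.approx(total, rel=1e-9)
        assert sum(r.weight for r in pseudo) == pytest.approx(report.emitted_weight, rel=1e-9)
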
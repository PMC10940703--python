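"""Demultiplexing: merging, length filtering, barcode identification, counting."""

import numpy as np
import pytest

from aavbench import (AMBIGUOUS, UNMATCHED, BarcodeLibrary, DemuxParams,
                      MergedRead, ReadPair, SimulationConfig, count_barcodes,
                      identify_barcode, length_filter, merge_read_pair,
                      simulate_reads)
from aavbench.demux import MalformedReadError, hamming, reverse_complement


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_merge(s1, s2, min_overlap, max_mismatch_frac):
    """Brute-force merge: enumerate every overlap length, score matches."""
    rc2 = reverse_complement(s2)
    n1, n2 = len(s1), len(rc2)
    best = None  # (matches, L)
    for L in range(min_overlap, min(n1, n2) + 1):
        matches = sum(a == b for a, b in zip(s1[n1 - L:], rc2[:L]))
        if (L - matches) / L > max_mismatch_frac:
            continue
        if best is None or (matches, L) > best:
            best = (matches, L)
    return best  # None or (matches, overlap_len)


def oracle_identify(seq, lib, max_hamming):
    """Exhaustive scan: anchor by python find / full <=1-mismatch search,
    then Hamming distance to every barcode."""
    seq = seq.upper()
    up, down = lib.upstream_anchor, lib.downstream_anchor
    pos = seq.find(up)
    if pos < 0:
        cands = [(sum(a != b for a, b in zip(seq[i:i + len(up)], up)), i)
                 for i in range(len(seq) - len(up) + 1)]
        d, pos = min(cands)
        if d > 1:
            return UNMATCHED
    start = pos + len(up)
    end = start + lib.barcode_length
    if end + len(down) > len(seq):
        return UNMATCHED
    if sum(a != b for a, b in zip(seq[end:end + len(down)], down)) > 1:
        return UNMATCHED
    window = seq[start:end]
    dists = sorted((hamming(window, bc), name)
                   for name, bc in lib.entries.items())
    d0, name0 = dists[0]
    if d0 > max_hamming:
        return UNMATCHED
    if len(dists) > 1 and dists[1][0] == d0:
        return AMBIGUOUS
    return name0


def _pair(s1, s2, q1=None, q2=None):
    return ReadPair(id="r", seq1=s1, seq2=s2,
                    qual1=q1 or "I" * len(s1), qual2=q2 or "I" * len(s2))


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

class TestMerge:
    def test_perfect_overlap(self):
        merged = merge_read_pair(_pair("ATGCATTT", "TGCCAAAT"), min_overlap=4)
        assert merged.seq == "ATGCATTTGGCA"
        assert merged.overlap_len == 4

    def test_no_admissible_overlap_fails(self):
        assert merge_read_pair(_pair("AAAA", "TTTT"), min_overlap=5) is None

    def test_disagreement_resolved_by_higher_quality_mate(self):
        # overlap of 6 with one disagreement; mate 2 has the higher quality
        s1 = "AACCGGTTAA"
        rc2 = "GGTTTACCCC"  # disagrees with s1 suffix "GGTTAA" at position 4
        s2 = reverse_complement(rc2)
        q1 = "I" * 4 + "#" * 6          # low quality in the overlap
        q2 = ("J" * 6 + "I" * 4)[::-1]  # higher quality, as-sequenced order
        merged = merge_read_pair(_pair(s1, s2, q1, q2), min_overlap=6,
                                 max_mismatch_frac=0.2)
        assert merged.overlap_len == 6
        assert merged.seq[4:10] == rc2[:6]  # mate-2 base won the disagreement
        # quality tie goes to mate 1
        q2_low = ("#" * 6 + "I" * 4)[::-1]
        merged_tie = merge_read_pair(_pair(s1, s2, q1, q2_low), min_overlap=6,
                                     max_mismatch_frac=0.2)
        assert merged_tie.seq[4:10] == s1[4:]

    def test_malformed_read_raises(self):
        with pytest.raises(MalformedReadError):
            ReadPair(id="x", seq1="ACGT", seq2="ACGT", qual1="III", qual2="IIII")

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        """Seed-free offset scan agrees with exhaustive offset scoring."""
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for _ in range(300):
            n1 = int(rng.integers(20, 60))
            n2 = int(rng.integers(20, 60))
            s1 = rng.choice(bases, size=n1).tobytes().decode()
            s2 = rng.choice(bases, size=n2).tobytes().decode()
            # half the time, plant a real overlap
            if rng.random() < 0.5:
                L = int(rng.integers(8, min(n1, n2) + 1))
                rc2 = s1[-L:] + rng.choice(bases, size=n2 - L).tobytes().decode()
                s2 = reverse_complement(rc2)
            expected = oracle_merge(s1, s2, 8, 0.1)
            merged = merge_read_pair(_pair(s1, s2), min_overlap=8,
                                     max_mismatch_frac=0.1)
            if expected is None:
                assert merged is None
            else:
                assert merged is not None
                assert merged.overlap_len == expected[1]
                assert len(merged.seq) == n1 + n2 - expected[1]


# ---------------------------------------------------------------------------
# length filter
# ---------------------------------------------------------------------------

class TestLengthFilter:
    @pytest.mark.parametrize("delta,tol,expected", [
        (0, 0, True), (1, 0, False), (2, 1, False), (1, 1, True), (-1, 0, False),
    ])
    def test_boundaries(self, library, delta, tol, expected):
        lib = BarcodeLibrary(entries=library.entries,
                             expected_merged_length=220, length_tolerance=tol)
        read = MergedRead(id="r", seq="A" * (220 + delta),
                          qual="I" * (220 + delta), overlap_len=20)
        assert length_filter(read, lib) is expected

    def test_indel_corrupted_reads_fail_exactly(self, library):
        """With a 10% indel rate, the length-filter fail count equals the
        generator's corrupted-read count."""
        sim = simulate_reads(library, SimulationConfig(
            seed=33, n_reads=500, base_error_rate=0.0, indel_rate=0.1))
        table = count_barcodes(sim.pairs, library)
        assert table.n_length_filtered == sim.n_indel_corrupted
        assert sum(table.counts.values()) == 500 - sim.n_indel_corrupted


# ---------------------------------------------------------------------------
# identification
# ---------------------------------------------------------------------------

class TestIdentify:
    def test_exact_barcode(self, library):
        for name, bc in list(library.entries.items())[:3]:
            seq = library.upstream_anchor + bc + library.downstream_anchor
            assert identify_barcode(seq, library, max_hamming=0) == name

    def test_single_substitution_recovered(self, library):
        name, bc = next(iter(library.entries.items()))
        mutated = ("C" if bc[10] != "C" else "G").join([bc[:10], bc[11:]])
        seq = library.upstream_anchor + mutated + library.downstream_anchor
        assert identify_barcode(seq, library, max_hamming=2) == name
        assert oracle_identify(seq, library, 2) == name

    def test_equidistant_window_is_ambiguous(self):
        lib = BarcodeLibrary(entries={"a": "AAAA", "b": "AATT"},
                             expected_merged_length=60)
        # window "AAAT" is at distance 1 from both barcodes
        seq = lib.upstream_anchor + "AAAT" + lib.downstream_anchor
        assert identify_barcode(seq, lib, max_hamming=2) == AMBIGUOUS

    def test_distance_beyond_radius_unmatched(self, library):
        seq = library.upstream_anchor + "A" * 44 + library.downstream_anchor
        name = identify_barcode(seq, library, max_hamming=3)
        assert name in (UNMATCHED, AMBIGUOUS) or \
            min(hamming("A" * 44, bc) for bc in library.entries.values()) <= 3

    def test_agrees_with_exhaustive_oracle_on_noisy_batch(self, library,
                                                          noisy_reads):
        merged = [merge_read_pair(p) for p in noisy_reads.pairs]
        checked = 0
        for m in merged:
            if m is None or not length_filter(m, library):
                continue
            assert identify_barcode(m, library, 3) == \
                oracle_identify(m.seq, library, 3)
            checked += 1
        assert checked > 1500


# ---------------------------------------------------------------------------
# counting pipeline
# ---------------------------------------------------------------------------

class TestCountBarcodes:
    def test_empty_input_is_zero_table(self, library):
        table = count_barcodes([], library)
        assert table.total_input_pairs == 0
        assert sum(table.counts.values()) == 0
        table.check_conservation()

    def test_error_free_recovery_is_exact(self, library, clean_reads):
        table = count_barcodes(clean_reads.pairs, library)
        assert table.counts == dict(clean_reads.truth_counts)
        assert table.n_unmatched == table.n_ambiguous == 0
        assert table.n_unmerged == table.n_length_filtered == 0

    def test_read_accounting_conserved_under_noise(self, library, noisy_reads):
        table = count_barcodes(noisy_reads.pairs, library)
        table.check_conservation()
        assert table.total_input_pairs == len(noisy_reads.pairs)

    def test_counts_within_multinomial_error(self, library):
        frac = np.array([2.0] * 4 + [1.0] * 10)
        frac /= frac.sum()
        sim = simulate_reads(library, SimulationConfig(
            seed=44, n_reads=20000, base_error_rate=0.0,
            mix_fractions=tuple(frac)))
        table = count_barcodes(sim.pairs, library)
        n = 20000
        for i, name in enumerate(library.variants):
            expected = n * frac[i]
            sigma = np.sqrt(n * frac[i] * (1 - frac[i]))
            assert abs(table.counts[name] - expected) <= 3 * sigma

    def test_permutation_invariance_of_labels(self, small_library, rng):
        """Relabeling library entries permutes counts identically."""
        sim = simulate_reads(small_library, SimulationConfig(
            seed=5, n_variants=3, n_reads=300, base_error_rate=0.003))
        table = count_barcodes(sim.pairs, small_library)
        names = small_library.variants
        renamed = {f"Z_{name}": small_library.entries[name] for name in names}
        relabeled = BarcodeLibrary(
            entries=renamed,
            upstream_anchor=small_library.upstream_anchor,
            downstream_anchor=small_library.downstream_anchor,
            expected_merged_length=small_library.expected_merged_length,
            length_tolerance=small_library.length_tolerance)
        table2 = count_barcodes(sim.pairs, relabeled)
        assert {f"Z_{k}": v for k, v in table.counts.items()} == table2.counts
        assert table.n_unmatched == table2.n_unmatched
        assert table.n_ambiguous == table2.n_ambiguous
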
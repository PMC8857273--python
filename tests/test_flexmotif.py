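"""Flexible-pattern scanner vs exhaustive enumeration, and positional stats."""

import itertools

import numpy as np
import pytest

from silencerscope.flexmotif import (
    FlexPatternSpec,
    count_in_regions,
    motif_gene_distances,
    positional_density,
    scan_flexible,
)
from silencerscope.genome_io import GeneModel, reverse_complement

CANONICAL = "TTAAAGAAATAAAAAAAAAATT"


def brute_force_scan(seq, spec):
    """Independent oracle: at every position try every gap combination."""
    hits = {}
    ranges = [
        range(g - t, g + t + 1)
        for g, t in zip(spec.gap_lengths, spec.gap_tolerances)
    ]
    for start in range(len(seq)):
        for gaps in itertools.product(*ranges):
            pos = start
            ok = True
            for i, blk in enumerate(spec.literal_blocks):
                if seq[pos : pos + len(blk)] != blk:
                    ok = False
                    break
                pos += len(blk)
                if i < len(gaps):
                    pos += gaps[i]
            if ok:
                hits.setdefault(start, gaps)
                break
    return hits


def fwd_starts(matches):
    return {m.start - 1: m.gap_realization for m in matches if m.strand == "+"}


class TestScanner:
    def test_canonical_pattern_single_match(self):
        m = scan_flexible(CANONICAL, strand_mode="forward")
        assert len(m) == 1
        assert (m[0].start, m[0].end) == (1, 22)
        assert m[0].gap_realization == (3, 3, 10)

    def test_poly_a_no_match(self):
        assert scan_flexible("A" * 500, strand_mode="both") == []

    def test_non_acgt_literal_rejected(self):
        with pytest.raises(ValueError):
            FlexPatternSpec(literal_blocks=["TT", "N", "T", "TT"])

    def test_span_range(self):
        assert FlexPatternSpec().span_range() == (18, 26)

    def test_matches_oracle_on_random_sequences(self):
        spec = FlexPatternSpec()
        rng = np.random.default_rng(0)
        for _ in range(20):
            # T/G-rich alphabet so matches actually occur
            seq = "".join(rng.choice(list("TTGA"), size=300))
            assert fwd_starts(
                scan_flexible(seq, spec, "forward")
            ) == brute_force_scan(seq, spec)

    def test_matches_oracle_on_edge_fixtures(self):
        spec = FlexPatternSpec()
        fixtures = [
            CANONICAL,
            CANONICAL[:-1],  # truncated final literal
            "TT" + "A" * 2 + "G" + "A" * 2 + "T" + "A" * 8 + "TT",  # min gaps
            "TT" + "A" * 4 + "G" + "A" * 4 + "T" + "A" * 12 + "TT",  # max gaps
            "TT" + "A" * 5 + "G" + "A" * 4 + "T" + "A" * 12 + "TT",  # gap1 over
            CANONICAL + CANONICAL,  # tandem
            "T" + CANONICAL,  # shifted, extra feasible start
            "TT" * 30,  # T-saturated
            "TTTTTGTTTTTTTTTTTTTTTTTTTT",
        ]
        for seq in fixtures:
            assert fwd_starts(
                scan_flexible(seq, spec, "forward")
            ) == brute_force_scan(seq, spec)

    def test_smallest_gap_realization_recorded(self):
        # embed so that both (3,3,10) and (2,3,11) spell the pattern:
        # T at position covering both → oracle picks lexicographic min too
        seq = "TTAAAGAAATAAAAAAAAAATT"
        got = scan_flexible(seq, strand_mode="forward")[0].gap_realization
        assert got == min(
            g for s, g in brute_force_scan(seq, FlexPatternSpec()).items() if s == 0
        )

    def test_monotone_in_tolerance(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("TTGAC"), size=2000))
        tight = FlexPatternSpec(gap_tolerances=[0, 0, 0])
        mid = FlexPatternSpec(gap_tolerances=[1, 1, 1])
        wide = FlexPatternSpec(gap_tolerances=[1, 1, 2])
        s_tight = {(m.start, m.strand) for m in scan_flexible(seq, tight)}
        s_mid = {(m.start, m.strand) for m in scan_flexible(seq, mid)}
        s_wide = {(m.start, m.strand) for m in scan_flexible(seq, wide)}
        assert s_tight <= s_mid <= s_wide

    def test_strand_symmetry(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("TTGAC"), size=3000))
        rc = reverse_complement(seq)
        fwd_on_rc = {m.start for m in scan_flexible(rc, strand_mode="forward")}
        minus = {
            len(seq) - m.end + 1
            for m in scan_flexible(seq, strand_mode="both")
            if m.strand == "-"
        }
        assert fwd_on_rc == minus

    def test_planted_motifs_all_recovered(self, small_dataset):
        # the pattern start on the scanned strand is the stable anchor:
        # forward-axis start for '+' matches, forward-axis end for '-'
        spec = FlexPatternSpec()
        for rid, rep in small_dataset.genome.items():
            matches = scan_flexible(rep.sequence, spec, "both", rid)
            plus_starts = {m.start for m in matches if m.strand == "+"}
            minus_ends = {m.end for m in matches if m.strand == "-"}
            planted = small_dataset.ledger.motifs
            for r in planted[planted.replicon_id == rid].itertuples(index=False):
                if r.strand == "+":
                    assert r.start in plus_starts
                else:
                    assert r.end in minus_ends


class TestRegionCounts:
    def test_midpoint_membership(self):
        m = scan_flexible(CANONICAL, strand_mode="forward")  # midpoint 11.5
        assert count_in_regions(m, [(1, 22)]) == [1]
        assert count_in_regions(m, [(12, 22)]) == [0]
        assert count_in_regions(m, [(11.5, 22)]) == [1]

    def test_planted_counts_match_ledger(self, small_dataset):
        spec = FlexPatternSpec()
        led = small_dataset.ledger.motifs
        for rid, rep in small_dataset.genome.items():
            matches = scan_flexible(rep.sequence, spec, "both", rid)
            sub = led[led.replicon_id == rid]
            regions = [(int(r.start), int(r.end)) for r in sub.itertuples(index=False)]
            counts = count_in_regions(matches, regions)
            assert all(c >= 1 for c in counts)  # every plant found in place


class TestGeneDistances:
    def test_upstream_retained(self):
        g = GeneModel("g", "chr", 1000, 3500, "+")
        m = scan_flexible(CANONICAL, strand_mode="forward", replicon_id="chr")[0]
        m.start, m.end = 789, 810  # midpoint 799.5 -> distance -200.5
        out = motif_gene_distances([m], [g])
        assert len(out) == 1 and out[0][1] == pytest.approx(-200.5)

    def test_short_gene_downstream_dropped(self):
        g = GeneModel("g", "chr", 1000, 1899, "+")  # 900 bp long
        m = scan_flexible(CANONICAL, strand_mode="forward", replicon_id="chr")[0]
        m.start, m.end = 2489, 2510  # distance ~ +1500, past stop codon
        assert motif_gene_distances([m], [g]) == []

    def test_matches_naive_filter(self, small_dataset):
        spec = FlexPatternSpec()
        rid, rep = next(iter(small_dataset.genome.items()))
        matches = scan_flexible(rep.sequence, spec, "both", rid)
        genes = [g for g in small_dataset.genes if g.replicon_id == rid]
        out = motif_gene_distances(matches, genes)
        naive = []
        for g in genes:
            for m in matches:
                d = m.midpoint - g.start if g.strand == "+" else g.end - m.midpoint
                if -500 <= d <= 2000 and not (d > 0 and d > g.length - 1):
                    naive.append((g.gene_id, d))
        assert sorted(out) == sorted(naive)


class TestDensity:
    def test_peaked_at_zero(self):
        grid, dens = positional_density([0.0] * 50 + [0.1], bandwidth=5.0)
        assert abs(grid[np.argmax(dens)]) < 10

    def test_uniform_is_flat(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(-500, 2000, size=10_000)
        grid, dens = positional_density(x, bandwidth=100.0)
        inner = dens[(grid > -300) & (grid < 1800)]
        assert inner.max() / inner.min() < 1.5

    def test_normalised_on_any_input(self):
        rng = np.random.default_rng(9)
        for x in (rng.normal(0, 30, 100), rng.uniform(-500, 2000, 37),
                  np.array([-499.0, 1999.0])):
            grid, dens = positional_density(x)
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            positional_density([1.0])
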
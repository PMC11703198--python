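"""Spacing-core: primary matching, centering, secondary scanning,
the binomial spacing test, and the end-to-end pair analysis."""

from fractions import Fraction

import numpy as np
import pytest

from spice.motif_io import motif_from_consensus, reverse_complement
from spice.peaks_io import SequenceWindow
from spice.spacing_core import (
    QUADRANTS,
    SpacingBin,
    SpacingConfig,
    SpacingHistogram,
    analyze_library,
    analyze_pair,
    available_bins,
    binomial_spacing_test,
    binomial_tail,
    center_and_orient,
    center_windows,
    find_best_primary,
    pair_evalue,
    revcomp_str,
    scan_secondary_best,
)
from spice.synthetic import PlantSpec, generate, generate_gas_tetramer
from spice.motif_io import MotifDatabase

from conftest import plant, random_seq, random_motif, windows_from_seqs

AP1 = motif_from_consensus("AP1", "TGACTCAG")  # even width: symmetric centering
IRF = motif_from_consensus("IRF", "TGAAAC")


def _window_with_site(rng, width, motif_consensus, pos, strand="+"):
    s = random_seq(rng, width)
    site = motif_consensus if strand == "+" else revcomp_str(motif_consensus)
    return SequenceWindow(id="w", seq=plant(s, site, pos))


class TestFindBestPrimary:
    def test_finds_planted_site(self, rng):
        for _ in range(10):
            pos = int(rng.integers(0, 492))
            w = _window_with_site(rng, 500, "TGACTCAG", pos)
            m = find_best_primary(w, AP1)
            assert m is not None
            assert (m.position, m.strand) == (pos, "+")

    def test_minus_strand_plant_reported_on_minus(self, rng):
        pos = 123
        w = _window_with_site(rng, 500, "TGACTCAG", pos, strand="-")
        m = find_best_primary(w, AP1)
        assert (m.position, m.strand) == (pos, "-")

    def test_unreachable_threshold_gives_none(self, rng):
        w = _window_with_site(rng, 500, "TGACTCAG", 100)
        assert find_best_primary(w, AP1, min_score=AP1.max_score + 1) is None

    def test_score_is_the_maximum_over_positions_and_strands(self, rng):
        w = _window_with_site(rng, 300, "TGACTCAG", 50)
        m = find_best_primary(w, AP1)
        assert m.score == pytest.approx(AP1.max_score, abs=1e-9)


class TestCenterAndOrient:
    def test_centered_plus_match_is_identity(self, rng):
        # width 500, motif width 8, site at 246 -> equal 246-bp flanks
        w = _window_with_site(rng, 500, "TGACTCAG", 246)
        m = find_best_primary(w, AP1)
        cw = center_and_orient(w, m, AP1.width)
        assert cw.seq == w.seq
        assert cw.primary_span == (246, 254)

    def test_minus_strand_match_reads_forward_after_orientation(self, rng):
        w = _window_with_site(rng, 500, "TGACTCAG", 100, strand="-")
        m = find_best_primary(w, AP1)
        cw = center_and_orient(w, m, AP1.width)
        p0, p1 = cw.primary_span
        assert cw.seq[p0:p1] == "TGACTCAG"

    def test_primary_midpoint_is_window_midpoint(self, rng):
        for pos in (12, 100, 400):
            w = _window_with_site(rng, 500, "TGACTCAG", pos)
            m = find_best_primary(w, AP1)
            cw = center_and_orient(w, m, AP1.width)
            p0, p1 = cw.primary_span
            assert abs((p0 + p1) / 2 - len(cw.seq) / 2) <= 1
            assert len(cw.seq) <= 500

    def test_rescanning_centered_window_finds_primary_at_center(self, rng):
        w = _window_with_site(rng, 500, "TGACTCAG", 77)
        m = find_best_primary(w, AP1)
        cw = center_and_orient(w, m, AP1.width)
        again = find_best_primary(SequenceWindow(id="c", seq=cw.seq), AP1)
        assert (again.position, again.strand) == (cw.primary_span[0], "+")
        assert again.score == pytest.approx(m.score, abs=1e-9)


def _centered(rng, flank=100, primary="TGACTCAG"):
    """A centered window with the primary consensus in the middle.

    Flanks use an A/C-only filler so no spurious site can tie with a
    planted consensus and the expected best hit is unambiguous.
    """
    filler = ("ACCAC" * (flank // 5 + 1))[:flank]
    seq = filler + primary + filler
    w = len(primary)
    from spice.spacing_core import CenteredWindow

    return CenteredWindow(id="c", seq=seq, primary_span=(flank, flank + w))


class TestScanSecondaryBest:
    @pytest.mark.parametrize("quadrant", QUADRANTS)
    @pytest.mark.parametrize("gap", [0, 4, 17])
    def test_planted_quadrant_and_gap_recovered(self, rng, quadrant, gap):
        cw = _centered(rng)
        p0, p1 = cw.primary_span
        site = "TGAAAC"
        side, strand = quadrant.split("-")
        placed = site if strand == "same" else revcomp_str(site)
        if side == "downstream":
            pos = p1 + gap
        else:
            pos = p0 - gap - len(site)
        seq = plant(cw.seq, placed, pos)
        cw2 = type(cw)(id="c", seq=seq, primary_span=cw.primary_span)
        got = scan_secondary_best(cw2, IRF)
        assert got is not None
        b, score = got
        assert (b.quadrant, b.gap) == (quadrant, gap)
        assert score == pytest.approx(IRF.max_score, abs=1e-9)

    def test_self_pair_excludes_central_site(self, rng):
        cw = _centered(rng)
        got = scan_secondary_best(cw, AP1)
        assert got is not None
        b, score = got
        # the perfect central site is excluded, so the best legal hit is weaker
        assert score < AP1.max_score - 1e-6
        assert b.gap >= 0

    def test_no_legal_position_gives_none(self, rng):
        from spice.spacing_core import CenteredWindow

        cw = CenteredWindow(id="c", seq="TGACTCAG", primary_span=(0, 8))
        assert scan_secondary_best(cw, IRF) is None

    def test_margin_caps_the_gap(self, rng):
        cw = _centered(rng, flank=100)
        p1 = cw.primary_span[1]
        seq = plant(cw.seq, "TGAAAC", p1 + 50)  # perfect site at gap 50
        cw2 = type(cw)(id="c", seq=seq, primary_span=cw.primary_span)
        b, _ = scan_secondary_best(cw2, IRF, margin=20)
        assert b.gap <= 20


def fraction_binomial_tail(k: int, n: int, B: int) -> Fraction:
    """Exact rational upper-tail binomial probability with p = 1/B."""
    from math import comb

    p = Fraction(1, B)
    return sum(
        Fraction(comb(n, j)) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


class TestBinomialSpacingTest:
    def test_tail_from_zero_is_one(self):
        assert binomial_tail(0, 100, 0.01) == 1.0

    @pytest.mark.parametrize("n,B,k", [(100, 200, 20), (50, 40, 3), (500, 1000, 9)])
    def test_matches_exact_rational_oracle(self, n, B, k):
        got = binomial_tail(k, n, 1.0 / B)
        exact = float(fraction_binomial_tail(k, n, B))
        assert got == pytest.approx(exact, rel=1e-9)

    def test_exactness_at_large_n(self):
        for n, B, k in [(5000, 1000, 10), (5000, 1000, 40), (3000, 500, 25)]:
            got = binomial_tail(k, n, 1.0 / B)
            exact = float(fraction_binomial_tail(k, n, B))
            assert got == pytest.approx(exact, rel=1e-9)

    def test_single_bin_forces_p_one(self):
        hist = SpacingHistogram(counts={SpacingBin("upstream-same", 0): 10}, n=10, B=1)
        (res,) = binomial_spacing_test(hist)
        assert res.p_raw == pytest.approx(1.0)
        assert res.p_adj == 1.0

    def test_bonferroni_adjustment_and_ordering(self):
        hist = SpacingHistogram(
            counts={
                SpacingBin("downstream-same", 4): 30,
                SpacingBin("upstream-opposite", 9): 2,
            },
            n=32,
            B=100,
        )
        results = binomial_spacing_test(hist)
        assert results[0].bin.gap == 4
        for r in results:
            assert 0 < r.p_raw <= r.p_adj <= 1
            assert r.p_adj == pytest.approx(min(1.0, 100 * r.p_raw))

    def test_zero_bins_rejected(self):
        hist = SpacingHistogram(counts={}, n=0, B=0)
        with pytest.raises(ValueError):
            binomial_spacing_test(hist)


class TestPairEvalue:
    def test_identity_for_single_motif_database(self):
        assert pair_evalue(0.003, 1) == 0.003

    def test_scales_by_database_size(self):
        assert pair_evalue(1e-12, 401) == pytest.approx(4.01e-10)

    def test_monotone_in_database_size_and_uncapped(self):
        values = [pair_evalue(0.02, n) for n in (1, 10, 100, 1000)]
        assert values == sorted(values)
        assert values[-1] > 1.0


def _aice_windows(n, gap, seed, fraction=0.6):
    spec = PlantSpec(
        n_windows=n,
        primary=AP1,
        secondary=IRF,
        gap=gap,
        quadrant="downstream-same",
        plant_fraction=fraction,
        rng_seed=seed,
    )
    return generate(spec)[0]


class TestAnalyzePair:
    def test_recovers_planted_gap(self):
        windows = _aice_windows(400, 4, seed=11)
        r = analyze_pair(windows, AP1, IRF)
        assert r.best.bin == SpacingBin("downstream-same", 4)
        assert r.best.p_adj < 1e-10
        assert r.evalue == pytest.approx(r.best.p_adj)  # database of size 1

    def test_self_pair_recovers_tandem_gap(self):
        windows, _, gas = generate_gas_tetramer(400, 11, seed=5)
        r = analyze_pair(windows, gas, gas)
        assert r.best.bin.gap == 11

    def test_null_is_not_significant_across_seeds(self):
        hits = 0
        for seed in range(20):
            windows = _aice_windows(300, 4, seed=seed, fraction=0.0)
            r = analyze_pair(windows, AP1, IRF)
            if r.best.p_adj < 0.01:
                hits += 1
        assert hits == 0

    def test_histogram_counts_conserve_contributing_windows(self):
        windows = _aice_windows(300, 4, seed=2)
        r = analyze_pair(windows, AP1, IRF)
        assert sum(r.histogram.counts.values()) == r.n
        for b in r.histogram.counts:
            assert 0 <= b.gap <= r.histogram.B  # every counted bin available

    def test_strand_invariance(self):
        windows = _aice_windows(200, 4, seed=3)
        flipped = [
            SequenceWindow(id=w.id, seq=revcomp_str(w.seq)) for w in windows
        ]
        a = analyze_pair(windows, AP1, IRF)
        b = analyze_pair(flipped, AP1, IRF)
        assert a.best.bin == b.best.bin
        assert a.best.p_adj == pytest.approx(b.best.p_adj)
        assert a.evalue == pytest.approx(b.evalue)

    def test_shift_equivariance(self):
        for g in (3, 7):
            wa = _aice_windows(300, g, seed=9)
            wb = _aice_windows(300, g + 1, seed=9)
            ra = analyze_pair(wa, AP1, IRF)
            rb = analyze_pair(wb, AP1, IRF)
            assert ra.best.bin.gap == g
            assert rb.best.bin.gap == g + 1

    def test_no_retained_windows_sets_empty_flag(self, rng):
        windows = windows_from_seqs([random_seq(rng, 100) for _ in range(10)])
        strict = SpacingConfig(min_score_frac=2.0)  # unreachable threshold
        r = analyze_pair(windows, AP1, IRF, config=strict)
        assert r.empty and r.n == 0


class TestAnalyzeLibrary:
    @pytest.fixture
    def planted_db(self, rng):
        decoys = [random_motif(rng, f"D{i}", 8) for i in range(9)]
        return MotifDatabase(motifs=decoys + [IRF])

    def test_planted_partner_ranks_first(self, planted_db):
        windows = _aice_windows(400, 4, seed=21)
        results = analyze_library(windows, AP1, planted_db, alpha=0.01)
        assert results
        assert results[0].secondary_name == "IRF"
        assert results[0].best.bin.gap == 4
        # E-value uses the full database size
        assert results[0].evalue == pytest.approx(results[0].best.p_adj * planted_db.size)

    def test_alpha_zero_gives_empty_result(self, planted_db):
        windows = _aice_windows(200, 4, seed=22)
        assert analyze_library(windows, AP1, planted_db, alpha=0.0) == []

    def test_ordering_invariant_to_database_permutation(self, planted_db, rng):
        windows = _aice_windows(300, 4, seed=23)
        base = analyze_library(windows, AP1, planted_db, alpha=0.5)
        shuffled_motifs = list(planted_db.motifs)
        rng.shuffle(shuffled_motifs)
        shuffled = analyze_library(
            windows, AP1, MotifDatabase(motifs=shuffled_motifs), alpha=0.5
        )
        assert [r.secondary_name for r in base] == [r.secondary_name for r in shuffled]
        assert [r.best.p_adj for r in base] == [r.best.p_adj for r in shuffled]


def test_available_bins_geometry():
    # flank F, secondary width ws: gaps 0..F-ws in each of 4 quadrants
    assert available_bins(flank=100, secondary_width=6) == 4 * 95
    assert available_bins(flank=5, secondary_width=6) == 0
    assert available_bins(flank=100, secondary_width=6, margin=10) == 4 * 11
    assert available_bins(flank=100, secondary_width=6, pool_quadrants=True) == 95


def test_center_windows_drops_unmatched(rng):
    good = _window_with_site(rng, 300, "TGACTCAG", 50)
    bad = SequenceWindow(id="b", seq=random_seq(rng, 300))
    centered = center_windows([good, bad], AP1, min_score=0.9 * AP1.max_score)
    assert len(centered) == 1
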
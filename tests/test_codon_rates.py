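"""NG86 site counting, pathway averaging, JC correction and sliding windows."""

import math
from itertools import permutations

import pytest
from hypothesis import given, settings, strategies as st

from regsplice.codon_rates import (
    STOPS,
    CodonAlignment,
    _translate,
    codon_align,
    ng86_pair,
    ng86_sites,
    sliding_kaks,
)
from regsplice.synthetic_data import evolve_codon_pair

BASES = "ACGT"


def brute_sites(codon: str) -> tuple[float, float]:
    """Independent enumeration of all nine single-nt neighbours."""
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        neighbours = [
            codon[:pos] + b + codon[pos + 1 :] for b in BASES if b != codon[pos]
        ]
        valid = [n for n in neighbours if n not in STOPS]
        if valid:
            s += sum(_translate(n) == aa for n in valid) / len(valid)
    return s, 3.0 - s


class TestSites:
    @pytest.mark.parametrize(
        "codon, s_expected",
        [("TTT", 1 / 3), ("ATG", 0.0), ("GGG", 1.0)],
    )
    def test_known_codons(self, codon, s_expected):
        s, n = ng86_sites(codon)
        assert s == pytest.approx(s_expected)
        assert s + n == pytest.approx(3.0)

    def test_all_codons_match_enumeration(self):
        for a in BASES:
            for b in BASES:
                for c in BASES:
                    codon = a + b + c
                    if codon in STOPS:
                        continue
                    assert ng86_sites(codon) == pytest.approx(brute_sites(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")


class TestPairwiseRates:
    def test_identical_sequences(self):
        cols = [("GGG", "GGG")] * 5
        r = ng86_pair(cols)
        assert r.Ka == 0.0 and r.Ks == 0.0 and r.ratio is None

    def test_single_synonymous_difference(self):
        cols = [("GGG", "GGG")] * 9 + [("TTT", "TTC")]
        r = ng86_pair(cols)
        assert r.Sd == pytest.approx(1.0)
        assert r.Nd == pytest.approx(0.0)
        assert r.S_sites == pytest.approx(28 / 3)
        assert r.Ka == 0.0
        expected_ks = -0.75 * math.log(1 - 4 * (3 / 28) / 3)
        assert r.Ks == pytest.approx(expected_ks)
        assert r.Ks == pytest.approx(0.116, abs=1e-3)

    def test_two_difference_codon_pathway_average(self):
        """TGT<->AGA: enumerate both pathways by hand; the one crossing the
        TGA stop is excluded."""
        paths = []
        for order in permutations([0, 2]):
            cur, steps, blocked = "TGT", [], False
            for pos in order:
                nxt = cur[:pos] + "AGA"[pos] + cur[pos + 1 :]
                blocked = blocked or nxt in STOPS
                steps.append((cur, nxt))
                cur = nxt
            paths.append((blocked, steps))
        valid = [s for blocked, s in paths if not blocked]
        sd = sum(_translate(a) == _translate(b) for s in valid for a, b in s) / len(valid)
        nd = sum(_translate(a) != _translate(b) for s in valid for a, b in s) / len(valid)
        r = ng86_pair([("TGT", "AGA")] + [("GGG", "GGG")] * 9)
        assert r.Sd == pytest.approx(sd)
        assert r.Nd == pytest.approx(nd)

    @given(
        codons=st.lists(
            st.tuples(
                st.sampled_from([c for c in
                                 (a + b + c for a in BASES for b in BASES for c in BASES)
                                 if c not in STOPS][:60]),
                st.sampled_from(["GGG", "GGA", "TTT", "TTC", "ATG", "CGC", "AAA"]),
            ),
            min_size=1,
            max_size=20,
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_symmetric_under_swap(self, codons):
        fwd = ng86_pair(codons)
        rev = ng86_pair([(b, a) for a, b in codons])
        assert fwd.Sd == pytest.approx(rev.Sd)
        assert fwd.Nd == pytest.approx(rev.Nd)
        assert fwd.S_sites == pytest.approx(rev.S_sites)

    def test_additive_over_concatenation(self):
        part1 = [("TTT", "TTC"), ("GGG", "GGG")]
        part2 = [("ATG", "ATA"), ("CGC", "CGC")]
        whole = ng86_pair(part1 + part2)
        a, b = ng86_pair(part1), ng86_pair(part2)
        assert whole.Sd == pytest.approx(a.Sd + b.Sd)
        assert whole.Nd == pytest.approx(a.Nd + b.Nd)
        assert whole.S_sites == pytest.approx(a.S_sites + b.S_sites)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            ng86_pair([])


class TestCodonAlign:
    def test_identical_cds(self):
        cds = "ATGGGATTTCGC"
        aln = codon_align(cds, cds)
        assert all(a == b for a, b in aln.columns)
        assert aln.aligned_nt == len(cds)

    def test_terminal_stop_trimmed(self):
        aln = codon_align("ATGTAA", "ATGTAA")
        assert aln.columns == (("ATG", "ATG"),)

    def test_single_codon_deletion_gives_one_gap_column(self):
        cds_a = "ATGGGATGGTTTCGCAAA"
        cds_b = "ATGGGATTTCGCAAA"  # TGG (Trp) deleted
        aln = codon_align(cds_a, cds_b)
        gap_cols = [(a, b) for a, b in aln.columns if "---" in (a, b)]
        assert gap_cols == [("TGG", "---")]
        assert len(aln.columns) == 6

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            codon_align("ATGG", "ATG")

    def test_internal_stop_named(self):
        with pytest.raises(ValueError, match="codon index 1"):
            codon_align("ATGTAACGC", "ATGAAACGC")


class TestSlidingWindows:
    def _uniform_alignment(self, n_codons, a="GGG", b="GGG"):
        return CodonAlignment("x", "y", tuple((a, b) for _ in range(n_codons)))

    def test_window_count_for_300_nt(self):
        aln = self._uniform_alignment(100)
        assert len(sliding_kaks(aln)) == 91

    def test_identical_sequences_all_zero(self):
        windows = sliding_kaks(self._uniform_alignment(20))
        assert all(w.Ka == 0.0 and w.Ks == 0.0 for w in windows)
        assert all(w.display_ratio == 0.0 for w in windows)

    def test_center_coordinates(self):
        windows = sliding_kaks(self._uniform_alignment(12))
        assert [w.center_nt for w in windows] == [16, 19, 22]

    def test_synonymous_only_pair_has_zero_ka_everywhere(self):
        cds_a, cds_b, _ = evolve_codon_pair(60, omega=0.0, subs_per_codon=0.3, seed=2)
        aln = codon_align(cds_a, cds_b)
        windows = sliding_kaks(aln)
        assert all(w.Ka == 0.0 for w in windows)
        assert any(w.Ks > 0 for w in windows)

    def test_ks_zero_ka_positive_display_capped(self):
        cols = tuple([("ATG", "TGG")] + [("GGG", "GGG")] * 9)
        [w] = sliding_kaks(CodonAlignment("x", "y", cols))
        assert w.Ka > 0 and w.Ks == 0.0
        assert w.ratio is None and w.display_ratio == 6.0

    def test_sparse_window_undefined(self):
        cols = tuple([("GGG", "---")] * 6 + [("GGG", "GGG")] * 4)
        [w] = sliding_kaks(CodonAlignment("x", "y", cols))
        assert w.comparable_codons == 4
        assert w.Ka is None and w.display_ratio is None

    def test_window_larger_than_alignment_rejected(self):
        with pytest.raises(ValueError):
            sliding_kaks(self._uniform_alignment(5))

    def test_non_codon_window_rejected(self):
        with pytest.raises(ValueError):
            sliding_kaks(self._uniform_alignment(20), window_nt=20)


class TestParameterRecovery:
    def test_omega_one_recovered_roughly(self):
        """Smoke check at 10 replicates; the full 50-replicate recovery
        experiment across the omega grid runs in the acceptance suite."""
        ratios = []
        for seed in range(10):
            a, b, _ = evolve_codon_pair(200, omega=1.0, subs_per_codon=0.3, seed=seed)
            r = ng86_pair(codon_align(a, b))
            assert r.ratio is not None
            ratios.append(r.ratio)
        ratios.sort()
        median = ratios[len(ratios) // 2]
        assert 0.5 <= median <= 2.0

    def test_window_ratio_variance_shrinks_with_length(self):
        """Sliding-window ratios over a uniform-divergence pair spread less
        as the alignment grows."""
        import statistics

        def window_sd(n_codons, seed):
            a, b, _ = evolve_codon_pair(n_codons, omega=1.0, subs_per_codon=0.5, seed=seed)
            windows = sliding_kaks(codon_align(a, b), window_nt=3 * n_codons // 2)
            vals = [w.ratio for w in windows if w.ratio is not None]
            return statistics.pstdev(vals) if len(vals) > 1 else 0.0

        short = statistics.mean(window_sd(40, s) for s in range(5))
        long = statistics.mean(window_sd(400, s) for s in range(5))
        assert long < short
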
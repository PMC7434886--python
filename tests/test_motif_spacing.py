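import re

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from nucpioneer.io_tracks import Genome, GenomicInterval, Peak
from nucpioneer.dyad_profile import revcomp
from nucpioneer.motif_spacing import (
    ExpectationModel,
    SamplingError,
    chisq_2x2,
    chisq_class_compare,
    count_pairs_in_window,
    expected_pair_probability,
    find_tandem_pairs,
    monte_carlo_enrichment,
    sample_random_windows,
    site_masks,
    spacer_enrichment,
    spacing_table,
)


def brute_force_pairs(seq, max_spacer=10):
    """Independent oracle: regex-with-lookahead over every (start, spacer)."""
    out = []
    for x in range(max_spacer + 1):
        for pat, ori in [
            (f"GAT.{{{x}}}GAT", "GG"),
            (f"ATC.{{{x}}}ATC", "GG"),
            (f"GAT.{{{x}}}ATC", "GA"),
        ]:
            for m in re.finditer(f"(?=({pat}))", seq):
                if "N" not in m.group(1):
                    out.append((m.start(), x, ori))
    return sorted(out)


class TestFindTandemPairs:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GATAAAGAT", [(0, 3, "GG")]),
            ("GATATC", [(0, 0, "GA")]),
            ("GATGATGAT", [(0, 0, "GG"), (0, 3, "GG"), (3, 0, "GG")]),
            ("ATCAATC", [(0, 1, "GG")]),
            ("GATNNNGAT", []),  # N never matches
            ("ATCGAT", []),  # divergent arrangement not counted by default
        ],
    )
    def test_examples(self, seq, expected):
        pairs = find_tandem_pairs(seq)
        assert sorted((p.first_start, p.spacer, p.orientation) for p in pairs) == expected

    def test_divergent_flag_enables_atc_gat(self):
        pairs = find_tandem_pairs("ATCGAT", include_divergent=True)
        assert [(p.first_start, p.spacer, p.orientation) for p in pairs] == [
            (0, 0, "GA")
        ]

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            seq = "".join(rng.choice(list("ACGT"), size=200))
            pairs = find_tandem_pairs(seq)
            assert sorted((p.first_start, p.spacer, p.orientation) for p in pairs) == (
                brute_force_pairs(seq)
            )

    def test_fast_counting_path_agrees(self, rng):
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            gat, atc = site_masks(seq)
            s, e = 37, 287
            sub = seq[s:e]
            for ori in (None, "GG", "GA"):
                expect = [
                    p for p in find_tandem_pairs(sub)
                    if ori is None or p.orientation == ori
                ]
                assert count_pairs_in_window(gat, atc, s, e, orientation=ori) == len(expect)

    def test_reverse_complement_leaves_counts_invariant(self, rng):
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=120))
            def counts(s):
                pairs = find_tandem_pairs(s)
                return (
                    sum(p.orientation == "GG" for p in pairs),
                    sum(p.orientation == "GA" for p in pairs),
                )
            assert counts(seq) == counts(revcomp(seq))


class TestSpacingTable:
    def _genome_with_windows(self, windows):
        g = Genome()
        seq = "C" * 50
        peaks = []
        for i, w in enumerate(windows):
            start = len(seq)
            pad = 200 - len(w)
            seq += w + "C" * pad + "C" * 100
            iv = GenomicInterval("c1", start, start + 200)
            peaks.append(Peak(f"p{i}", iv, start + 100, "G1"))
        g.add("c1", seq)
        return g, peaks

    def test_single_planted_pair(self):
        g, peaks = self._genome_with_windows(["GATAAAGAT"])
        t = spacing_table(peaks, g)
        assert t.count("G1", "GG", 3) == 1
        assert t.loci("G1", "GG", 3) == 1
        assert t.n_peaks["G1"] == 1

    def test_multiple_pairs_single_locus(self):
        g, peaks = self._genome_with_windows(["GATGATGAT"])
        t = spacing_table(peaks, g)
        assert t.count("G1", "GG", 0) == 2
        assert t.loci("G1", "GG", 0) == 1
        # counts always >= loci_with_pair
        for key, n_loci in t.loci_with_pair.items():
            assert t.counts[key] >= n_loci

    def test_zero_peaks_gives_empty_table(self, random_genome):
        t = spacing_table([], random_genome)
        assert t.counts == {} and t.n_peaks == {}


class TestExpectationModel:
    def test_uniform_closed_forms(self):
        m = ExpectationModel.uniform()
        for x in range(11):
            assert expected_pair_probability(m, "GA", x) == pytest.approx(1 / 4096)
            assert expected_pair_probability(m, "GG", x) == pytest.approx(2 / 4096)

    def test_same_strand_twice_opposite_under_uniform(self):
        m = ExpectationModel.uniform()
        for x in range(11):
            ratio = expected_pair_probability(m, "GG", x) / expected_pair_probability(m, "GA", x)
            assert ratio == 2.0

    def test_skewed_model(self):
        m = ExpectationModel({"A": 0.4, "C": 0.1, "G": 0.2, "T": 0.3})
        p_gat, p_atc = 0.2 * 0.4 * 0.3, 0.4 * 0.3 * 0.1
        assert expected_pair_probability(m, "GA", 5) == pytest.approx(p_gat * p_atc)
        assert expected_pair_probability(m, "GG", 5) == pytest.approx(p_gat**2 + p_atc**2)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            ExpectationModel({"A": 0.5, "C": 0.5, "G": 0.5, "T": 0.5})

    def test_empirical_rates_match_analytic_on_iid_genome(self, rng):
        # 300 kb iid-uniform sequence: per-spacer GG and GA counts within
        # 4 binomial sigma of the closed form, and the pooled same-strand /
        # opposite-strand ratio near its analytic value of 2
        n = 300_000
        seq = "".join(rng.choice(list("ACGT"), size=n))
        gat, atc = site_masks(seq)
        m = ExpectationModel.uniform()
        totals = {"GG": 0, "GA": 0}
        for ori in ("GG", "GA"):
            for x in range(11):
                c = count_pairs_in_window(gat, atc, 0, n, spacers=[x], orientation=ori)
                p = expected_pair_probability(m, ori, x)
                trials = n - 5 - x
                sigma = np.sqrt(trials * p * (1 - p))
                assert abs(c - trials * p) < 4 * sigma
                totals[ori] += c
        assert 1.8 <= totals["GG"] / totals["GA"] <= 2.2


class TestRandomWindows:
    def test_within_bounds_and_deterministic(self, random_genome):
        a = sample_random_windows(random_genome, 25, 200, seed=5)
        b = sample_random_windows(random_genome, 25, 200, seed=5)
        assert a == b
        for iv in a:
            assert 0 <= iv.start and iv.end <= random_genome.length("c1")
            assert len(iv) == 200

    def test_exclusion_forces_placement(self):
        g = Genome()
        g.add("c1", "A" * 1000)
        exclude = [GenomicInterval("c1", 0, 400), GenomicInterval("c1", 600, 1000)]
        wins = sample_random_windows(g, 8, 200, exclude, seed=1)
        assert all((iv.start, iv.end) == (400, 600) for iv in wins)

    def test_n_runs_block_placement(self):
        g = Genome()
        g.add("c1", "N" * 500)
        with pytest.raises(SamplingError):
            sample_random_windows(g, 1, 100, seed=0)


class TestMonteCarlo:
    def _make(self, peak_seq, bg_char="C", n_peaks=3, genome_len=6000):
        g = Genome()
        seq = list(bg_char * genome_len)
        peaks = []
        for i in range(n_peaks):
            start = 500 + i * 1500
            seq[start : start + len(peak_seq)] = list(peak_seq)
            peaks.append(
                Peak(f"p{i}", GenomicInterval("c1", start, start + 200), start + 100, "G1")
            )
        g.add("c1", "".join(seq))
        return g, peaks

    def test_zero_observed_gives_p_one(self):
        g, peaks = self._make("C" * 10)
        null = monte_carlo_enrichment(peaks, g, R=99, seed=3)
        assert null.observed == 0
        assert null.empirical_p == 1.0

    def test_observed_above_all_replicates(self):
        g, peaks = self._make("GATGATGATGATGAT")
        null = monte_carlo_enrichment(peaks, g, R=999, seed=3)
        assert null.observed > max(null.replicate_counts)
        assert null.empirical_p == pytest.approx(1 / 1000)

    def test_replicate_determinism(self, random_genome):
        peaks = [
            Peak("p0", GenomicInterval("c1", 1000, 1200), 1100, "G1"),
            Peak("p1", GenomicInterval("c1", 5000, 5200), 5100, "G2"),
        ]
        a = monte_carlo_enrichment(peaks, random_genome, R=99, seed=9)
        b = monte_carlo_enrichment(peaks, random_genome, R=99, seed=9)
        assert a.replicate_counts == b.replicate_counts
        assert a.empirical_p == b.empirical_p

    def test_small_r_rejected(self, random_genome):
        with pytest.raises(ValueError):
            monte_carlo_enrichment([], random_genome, R=10)


class TestChiSquared:
    @pytest.mark.parametrize(
        "table,stat",
        [([[25, 75], [25, 75]], 0.0), ([[10, 10], [10, 10]], 0.0)],
    )
    def test_identical_proportions_give_zero(self, table, stat):
        s, p = chisq_2x2(np.array(table))
        assert s == pytest.approx(stat)
        assert p == pytest.approx(1.0)

    def test_hand_computed_contrast(self):
        s, p = chisq_class_compare(30, 100, 10, 100)
        assert s == pytest.approx(12.5)
        assert p == pytest.approx(4.07e-4, rel=2e-3)

    def test_agrees_with_scipy_uncorrected(self, rng):
        for _ in range(25):
            t = rng.integers(1, 200, size=(2, 2))
            s, p = chisq_2x2(t)
            ref = chi2_contingency(t, correction=False)
            assert s == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_2x2(np.array([[0, 0], [5, 5]]))


class TestSpacerEnrichment:
    def _table(self, counts_by_spacer, cls="G3", ori="GG"):
        from nucpioneer.motif_spacing import SpacingTable

        t = SpacingTable()
        t.n_peaks[cls] = 100
        for x, c in counts_by_spacer.items():
            t.counts[(cls, ori, x)] = c
        return t

    def test_uniform_counts_give_unit_folds(self):
        t = self._table({x: 50 for x in range(11)})
        bkg = {x: 500 for x in range(11)}
        enr = spacer_enrichment(t, "G3", "GG", bkg)
        assert np.allclose(enr["fold"], 1.0, atol=0.01)
        assert (enr["p"] > 0.5).all()

    def test_planted_spacer_six_dominates(self):
        t = self._table({x: (200 if x == 6 else 2) for x in range(11)})
        bkg = {x: 100 for x in range(11)}
        enr = spacer_enrichment(t, "G3", "GG", bkg)
        best = enr.loc[enr["fold"].idxmax()]
        assert best["spacer"] == 6
        assert best["p"] < 1e-10

    def test_degenerate_background_reports_p_one(self):
        t = self._table({x: 0 for x in range(11)})
        with pytest.warns(UserWarning):
            enr = spacer_enrichment(t, "G3", "GG", {x: 0 for x in range(11)})
        assert (enr["p"] == 1.0).all()
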
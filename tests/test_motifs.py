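"""Sequence analyses: k-mer enrichment, distances, windows, PWM scanning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cckit import motifs, simdata
from cckit.ccparse import revcomp


@pytest.fixture(scope="module")
def peak_regions(scenario):
    """±50 bp regions centred on the planted motifs of the standard study."""
    rows = [
        (s.chrom, s.start - 47, s.start + 54) for s in scenario.genome.planted_motif_sites
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestKmerEnrichment:
    def test_whole_genome_self_background(self, small_genome):
        L = len(small_genome.sequences["chr1"])
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": range(50, L - 50, 100), "end": range(150, L + 50, 100)}
        )
        table = motifs.kmer_enrichment(regions, small_genome, k=7)
        # regions tile the genome, so every 7-mer is ~1.0-enriched
        assert table["enrichment"].between(0.3, 3.0).mean() > 0.95

    def test_planted_consensus_ranks_top5(self, scenario, peak_regions):
        table = motifs.kmer_enrichment(peak_regions, scenario.genome, k=7)
        top5 = table.head(5)["kmer"].tolist()
        assert any("TGAAAC" in k or "TGAAAC" in revcomp(k) for k in top5)

    def test_empty_regions(self, small_genome):
        table = motifs.kmer_enrichment(pd.DataFrame(columns=["chrom", "start", "end"]), small_genome)
        assert table.empty

    def test_observed_total_equals_window_count(self, small_genome):
        regions = pd.DataFrame({"chrom": ["chr1"] * 3, "start": [500, 2000, 4000], "end": [504, 2004, 4004]})
        table = motifs.kmer_enrichment(regions, small_genome, k=7)
        assert table["observed"].sum() == 3 * (100 - 7 + 1) * 2

    def test_strand_symmetry(self, small_genome):
        regions = pd.DataFrame({"chrom": ["chr1"] * 2, "start": [1000, 3000], "end": [1004, 3004]})
        table = motifs.kmer_enrichment(regions, small_genome, k=5)
        by_kmer = table.set_index("kmer")["observed"]
        for kmer in by_kmer.index[:50]:
            assert by_kmer[kmer] == by_kmer.get(revcomp(kmer), 0)


class TestNearestMotifDistance:
    def test_peaks_on_consensus_have_zero_distance(self, scenario):
        sites = scenario.genome.planted_motif_sites
        peaks = pd.DataFrame(
            [(s.chrom, s.start, s.start + 7) for s in sites], columns=["chrom", "start", "end"]
        )
        dist, fraction = motifs.nearest_motif_distance(peaks, scenario.genome)
        assert fraction == 1.0
        assert (dist <= 0.5).all()

    def test_no_consensus_all_capped(self):
        genome = {"c": "ACACACACAC" * 200}
        peaks = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [110]})
        dist, fraction = motifs.nearest_motif_distance(peaks, genome, cap=1000)
        assert fraction == 0.0 and (dist == 1000).all()

    def test_fraction_tracks_simulated_near_rate(self, scenario):
        # estimator vs the realised event-level fraction, via the event list
        events = simdata.simulate_insertions(scenario.genome, scenario.model, "s", seed=33)
        ev_iv = pd.DataFrame(
            [(e.chrom, e.pos, e.pos + 4) for e in events], columns=["chrom", "start", "end"]
        )
        dist, fraction = motifs.nearest_motif_distance(ev_iv, scenario.genome)
        # brute-force realised fraction from consensus occurrence scan
        occ = motifs.consensus_occurrences(scenario.genome)
        centers = np.array([p + 3.5 for _, p in occ])
        realised = np.mean(
            [np.min(np.abs(centers - (e.pos + 2))) <= 200 for e in events]
        )
        assert fraction == pytest.approx(realised, abs=1e-9)


class TestConsensusFrequencyEnrichment:
    def test_whole_genome_is_one(self, small_genome):
        L = len(small_genome.sequences["chr1"])
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [L]})
        assert motifs.consensus_frequency_enrichment(regions, small_genome) == pytest.approx(1.0)

    def test_planted_regions_strongly_enriched(self, scenario, peak_regions):
        enr = motifs.consensus_frequency_enrichment(peak_regions, scenario.genome)
        # ~1 match / 100 bp in regions vs ~1 per 5 kb genome-wide
        assert enr > 10

    def test_zero_match_regions_below_one(self, small_genome):
        # find a 200 bp stretch with no consensus match
        seq = small_genome.sequences["chr1"]
        for start in range(0, len(seq) - 200, 200):
            window = seq[start : start + 200]
            if "TGAAACA" not in window and revcomp("TGAAACA") not in window:
                break
        regions = pd.DataFrame({"chrom": ["chr1"], "start": [start], "end": [start + 200]})
        assert motifs.consensus_frequency_enrichment(regions, small_genome) < 1.0


class TestHighCountWindows:
    def test_all_equal_counts_all_qualify(self):
        sites = pd.DataFrame({"sample": "s", "chrom": "chr1", "pos": [100, 200, 5000], "umis": 1})
        win = motifs.high_count_windows(sites)
        # 100 and 200 are within 300 bp so their windows merge
        assert len(win) == 2
        merged = motifs.merge_intervals([("chr1", max(0, p + 2 - 150), p + 2 + 150) for p in [100, 200, 5000]])
        assert list(win.itertuples(index=False, name=None)) == merged

    def test_threshold_matches_quantile_oracle(self):
        counts = list(range(1, 101))
        sites = pd.DataFrame({"sample": "s", "chrom": "chr1", "pos": np.arange(100) * 1000, "umis": counts})
        win = motifs.high_count_windows(sites, percentile=85)
        thr = np.percentile(counts, 85)
        expected = (np.array(counts) >= thr).sum()
        assert len(win) == expected  # sites are 1 kb apart: no merging

    def test_disjoint_windows(self):
        sites = pd.DataFrame({"sample": "s", "chrom": "chr1", "pos": [1000, 1400], "umis": [5, 5]})
        win = motifs.high_count_windows(sites)
        assert len(win) == 2
        assert (win["start"].iloc[1] >= win["end"].iloc[0])

    def test_merged_disjoint_sorted(self, sites):
        win = motifs.high_count_windows(sites[sites["sample"] == "wt_rep1"])
        assert (win["start"] < win["end"]).all()
        assert (win["start"].iloc[1:].to_numpy() > win["end"].iloc[:-1].to_numpy()).all()

    def test_bad_percentile(self, sites):
        with pytest.raises(ValueError):
            motifs.high_count_windows(sites, percentile=0)


class TestMemeIO:
    def test_roundtrip(self, tmp_path):
        lib = motifs.toy_motif_library()
        motifs.write_meme(lib, tmp_path / "lib.meme")
        back = motifs.parse_meme(tmp_path / "lib.meme")
        assert [p.name for p in back] == [p.name for p in lib]
        for a, b in zip(lib, back):
            np.testing.assert_allclose(a.probs, b.probs, atol=1e-4)

    def test_malformed_matrix_reports_line(self, tmp_path):
        lib = motifs.toy_motif_library()[:1]
        motifs.write_meme(lib, tmp_path / "bad.meme")
        text = (tmp_path / "bad.meme").read_text().splitlines()
        assert text[10].startswith("letter-probability")
        text[11] = "0.9 0.5 0.1 0.1"  # first matrix row now sums to 1.6
        (tmp_path / "bad.meme").write_text("\n".join(text))
        with pytest.raises(motifs.MemeParseError, match="line 12"):
            motifs.parse_meme(tmp_path / "bad.meme")


class TestScanPwms:
    def test_point_mass_pwm_single_hit(self):
        pwm = motifs.consensus_pwm("S", "TGAAACA", match_prob=1.0)
        genome = {"c": "ACGTACG" + "TGAAACA" + "CGTACGTACGTAGCTAGC"}
        windows = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [len(genome["c"])]})
        hits = motifs.scan_pwms(windows, genome, [pwm], background=np.array([0.25] * 4))
        assert len(hits) == 1
        assert hits.loc[0, "position"] == 7 and hits.loc[0, "strand"] == "+"

    def test_uniform_pwm_no_hits(self):
        pwm = motifs.PWM("U", np.full((7, 4), 0.25))
        genome = {"c": "ACGT" * 50}
        windows = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [200]})
        hits = motifs.scan_pwms(windows, genome, [pwm], background=np.array([0.25] * 4))
        assert hits.empty

    def test_pvalues_match_enumeration_oracle(self):
        # exhaustive oracle over all 4^5 words with the same integer scores
        rng = np.random.default_rng(5)
        probs = rng.dirichlet([1.0] * 4, size=5)
        pwm = motifs.PWM("R", probs)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        scored = motifs.ScoredPWM.build(pwm, bg)
        words = list(itertools.product(range(4), repeat=5))
        word_scores = np.array([scored.score_word(np.array(w)) for w in words])
        word_probs = np.array([np.prod([bg[b] for b in w]) for w in words])
        for s in np.unique(word_scores)[::5]:
            oracle = word_probs[word_scores >= s].sum()
            assert scored.pvalue(int(s)) == pytest.approx(oracle, abs=1e-12)

    def test_hit_set_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        genome = {"c": "".join(rng.choice(list("ACGT"), 3000))}
        windows = pd.DataFrame({"chrom": ["c"] * 10, "start": np.arange(10) * 300, "end": np.arange(1, 11) * 300})
        pwms = motifs.toy_motif_library()[:3]
        bg = motifs.genome_background(genome)
        hits = motifs.scan_pwms(windows, genome, pwms, p_threshold=1e-3, dedup=False)
        # brute-force: enumerate every offset of every window and strand
        expected = 0
        for pwm in pwms:
            scored = motifs.ScoredPWM.build(pwm, bg)
            rc = motifs.ScoredPWM.build(pwm.reverse_complement(), bg)
            for _, r in windows.iterrows():
                text = genome["c"][r["start"] : r["end"]]
                enc = motifs._encode(text)
                for sp in (scored, rc):
                    for off in range(len(text) - pwm.width + 1):
                        s = sp.score_word(enc[off : off + pwm.width])
                        if scored.pvalue(s) <= 1e-3:
                            expected += 1
        assert len(hits) == expected

    def test_order_invariance(self, small_genome):
        windows = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [100, 2000, 5000], "end": [400, 2300, 5300]}
        )
        pwms = motifs.toy_motif_library()[:2]
        a = motifs.scan_pwms(windows, small_genome, pwms)
        b = motifs.scan_pwms(windows.iloc[::-1].reset_index(drop=True), small_genome, pwms)
        key = ["window_id", "motif_id", "position", "strand"]
        pd.testing.assert_frame_equal(
            a.sort_values(key, ignore_index=True), b.sort_values(key, ignore_index=True)
        )


class TestMotifPairs:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["window_id", "motif_id", "position", "strand", "score", "p_value"])

    def test_two_motifs_one_pair(self):
        hits = self._hits([("w1", "STE12", 5, "+", 10, 1e-5), ("w1", "MCM1", 40, "+", 9, 1e-5)])
        table = motifs.motif_pair_counts(hits, n_windows=4)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row["motif_a"], row["motif_b"]) == ("MCM1", "STE12")
        assert row["raw"] == 1 and row["normalized"] == 0.25

    def test_single_motif_no_pairs(self):
        hits = self._hits([("w1", "STE12", 5, "+", 10, 1e-5)])
        assert motifs.motif_pair_counts(hits, 4).empty

    def test_self_pair_needs_two_positions(self):
        hits = self._hits([("w1", "STE12", 5, "+", 10, 1e-5), ("w1", "STE12", 50, "-", 8, 1e-5)])
        table = motifs.motif_pair_counts(hits, 4)
        assert table.iloc[0]["raw"] == 1 and table.iloc[0]["motif_a"] == table.iloc[0]["motif_b"]

    def test_matches_bruteforce_enumeration(self, rng):
        names = ["A", "B", "C", "D"]
        rows = []
        for w in range(100):
            for m in names:
                for j in range(rng.integers(0, 3)):
                    rows.append((f"w{w}", m, int(rng.integers(0, 200)), "+", 5.0, 1e-5))
        hits = self._hits(rows)
        table = motifs.motif_pair_counts(hits, 100).set_index(["motif_a", "motif_b"])
        # oracle
        expected: dict = {}
        for w, grp in hits.groupby("window_id"):
            present = sorted(grp["motif_id"].unique())
            for i, a in enumerate(present):
                for b in present[i + 1 :]:
                    expected[(a, b)] = expected.get((a, b), 0) + 1
                if grp[grp["motif_id"] == a]["position"].nunique() >= 2:
                    expected[(a, a)] = expected.get((a, a), 0) + 1
        assert dict(table["raw"]) == expected

    def test_zero_windows_with_hits_raises(self):
        hits = self._hits([("w1", "STE12", 5, "+", 10, 1e-5)])
        with pytest.raises(ValueError):
            motifs.motif_pair_counts(hits, 0)


class TestDiffMotifPairs:
    def _table(self, data, cols):
        df = pd.DataFrame(data, columns=cols)
        df.insert(0, "motif_a", [f"m{i}" for i in range(len(df))])
        df.insert(1, "motif_b", [f"n{i}" for i in range(len(df))])
        return df

    def test_identical_counts_nothing_passes(self):
        cols = ["a_1", "a_2", "b_1", "b_2"]
        sample_of = {c: c[0] for c in cols}
        df = self._table(np.full((20, 4), 30.0), cols)
        res = motifs.diff_motif_pairs(df, sample_of)
        assert not res["passes_filter"].any()

    def test_low_mean_pairs_filtered(self, rng):
        cols = ["a_1", "a_2", "b_1", "b_2"]
        sample_of = {c: c[0] for c in cols}
        df = self._table(rng.poisson(4.0, (30, 4)).astype(float), cols)
        res = motifs.diff_motif_pairs(df, sample_of)
        assert not res["passes_filter"].any()  # log10(mean) <= 1 everywhere

    def test_planted_fivefold_pair_detected(self, rng):
        cols = ["a_1", "a_2", "b_1", "b_2", "c_1", "c_2"]
        sample_of = {c: c[0] for c in cols}
        base = rng.integers(12, 60, 40)
        data = rng.poisson(base[:, None], (40, 6)).astype(float)
        data[0, :2] *= 5.0
        df = self._table(data, cols)
        res = motifs.diff_motif_pairs(df, sample_of)
        top = res.iloc[0]
        assert top["motif_a"] == "m0" and top["passes_filter"]

    def test_filter_monotone_in_mean_threshold(self, rng):
        cols = ["a_1", "a_2", "b_1", "b_2"]
        sample_of = {c: c[0] for c in cols}
        df = self._table(rng.poisson(30, (30, 4)).astype(float) * rng.integers(1, 4, (30, 1)), cols)
        lo = motifs.diff_motif_pairs(df, sample_of, mean_log10_threshold=1.0)
        hi = motifs.diff_motif_pairs(df, sample_of, mean_log10_threshold=1.5)
        passing = lambda r: set(zip(r[r["passes_filter"]]["motif_a"], r[r["passes_filter"]]["motif_b"]))
        assert passing(hi) <= passing(lo)
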
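"""Moving-average scanning: profiles, probe scores, site calls, PWM scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_profile, random_dna, random_symmetric_table, uniform_table
from pbmscan import (
    PBMScanner,
    PwmMatrix,
    ScanConfig,
    SeqRecord,
    build_dense_array,
    call_sites,
    pwm_log_odds_score,
    reverse_complement,
    scan_regions,
    score_probe,
    score_profile,
)
from pbmscan.errors import ScanError
from pbmscan.kmers import RC_CODES, encode_octamer
from pbmscan.scanner import promoter_regions

dna = st.text(alphabet="ACGT", min_size=14, max_size=70)

_RNG = np.random.default_rng(100)
_TABLE = random_symmetric_table(_RNG)
_ARRAY = build_dense_array(_TABLE)


class TestScoreProfile:
    def test_minimum_length_single_window_constant_table(self):
        arr = build_dense_array(uniform_table(0.2))
        prof = score_profile("A" * 14, arr, ScanConfig(window_w=7))
        assert prof.n_windows == 1
        assert prof.scores[0] == pytest.approx(0.2, abs=1e-15)

    @pytest.mark.parametrize("length,window", [(15, 7), (14, 7), (40, 6), (21, 1)])
    def test_matches_naive_recomputation(self, length, window):
        seq = random_dna(np.random.default_rng(length * window), length)
        prof = score_profile(seq, _ARRAY, ScanConfig(window_w=window))
        expected = naive_profile(seq, _TABLE, window)
        assert prof.n_windows == length - window - 6
        np.testing.assert_allclose(prof.scores, expected, atol=1e-12)

    def test_too_short_sequence_names_minimum_length(self):
        with pytest.raises(ScanError, match="minimum 14"):
            score_profile("ACGTACGTACGTA", _ARRAY, ScanConfig(window_w=7))

    def test_windows_touching_ambiguity_are_masked(self):
        seq = random_dna(np.random.default_rng(0), 30)
        seq = seq[:15] + "N" + seq[16:]
        prof = score_profile(seq, _ARRAY, ScanConfig(window_w=7))
        expected = naive_profile(seq, _TABLE, 7)
        assert np.isnan(prof.scores[~prof.mask]).all()
        np.testing.assert_allclose(prof.scores, expected, atol=1e-12)

    def test_soft_mask_policy(self):
        seq = random_dna(np.random.default_rng(1), 40)
        mask = np.zeros(40, dtype=bool)
        mask[18:22] = True
        default = score_profile(seq, _ARRAY, ScanConfig(window_w=7), mask=mask)
        skipping = score_profile(seq, _ARRAY, ScanConfig(window_w=7, skip_masked=True), mask=mask)
        assert default.mask.all()  # masked sequence scanned by default
        assert not skipping.mask.all()
        assert np.isnan(skipping.scores[~skipping.mask]).all()

    @given(dna)
    @settings(max_examples=150, derandomize=True)
    def test_reverse_complement_invariance(self, seq):
        fwd = score_profile(seq, _ARRAY, ScanConfig(window_w=7))
        rev = score_profile(reverse_complement(seq), _ARRAY, ScanConfig(window_w=7))
        np.testing.assert_allclose(rev.scores, fwd.scores[::-1], atol=1e-12)

    def test_monotone_in_table_scores(self):
        seq = random_dna(np.random.default_rng(2), 60)
        before = score_profile(seq, _ARRAY, ScanConfig(window_w=7)).scores
        bumped = _TABLE.values.copy()
        c = encode_octamer(seq[20:28])
        bump = min(0.05, 0.5 - bumped[c])
        bumped[c] += bump
        bumped[RC_CODES[c]] = bumped[c]
        from pbmscan.kmers import DenseScoreArray

        after = score_profile(seq, DenseScoreArray(bumped), ScanConfig(window_w=7)).scores
        assert (after - before >= -1e-15).all()


class TestScoreProbe:
    def test_uniform_table_probe(self):
        arr = build_dense_array(uniform_table(0.3))
        ps = score_probe("ACGT" * 6, arr, ScanConfig(window_w=7))
        assert ps.max_escore == pytest.approx(0.3)
        assert ps.pbm_mapping_score == pytest.approx(0.3)

    def test_equals_brute_force_max(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = random_dna(rng, 30)
            ps = score_probe(seq, _ARRAY, ScanConfig(window_w=7))
            octs = [_TABLE.score(seq[i : i + 8]) for i in range(len(seq) - 7)]
            assert ps.max_escore == pytest.approx(max(octs), abs=1e-15)
            assert ps.pbm_mapping_score == pytest.approx(
                max(naive_profile(seq, _TABLE, 7)), abs=1e-12
            )

    @given(dna)
    @settings(max_examples=100, derandomize=True)
    def test_window_average_never_exceeds_max_escore(self, seq):
        ps = score_probe(seq, _ARRAY, ScanConfig(window_w=7))
        assert ps.pbm_mapping_score <= ps.max_escore + 1e-12

    def test_short_probe_flagged_not_scored(self):
        ps = score_probe("ACGTACGTAC", _ARRAY, ScanConfig(window_w=7))
        assert ps.pbm_mapping_score is None and not ps.has_window
        with pytest.raises(ScanError):
            score_probe("ACGTACG", _ARRAY, ScanConfig())


class TestCallSites:
    def test_all_below_threshold_gives_no_calls(self):
        arr = build_dense_array(uniform_table(0.0))
        seq = SeqRecord("chr1", "ACGT" * 50)
        assert call_sites([seq], arr, ScanConfig(threshold=0.37)) == []

    def test_degenerate_threshold_spans_every_window(self):
        arr = build_dense_array(uniform_table(0.2))
        rec = SeqRecord("chr1", "A" * 100)
        sites = call_sites([rec], arr, ScanConfig(window_w=7, threshold=-0.5))
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end) == (0, 100)

    def test_planted_site_recovered_exactly(self, clean_table, clean_array):
        from pbmscan import PlantedGenomeSpec, evaluate_calls, make_genome

        table, _ = clean_table
        rec, manifest = make_genome(PlantedGenomeSpec(seed=21, site_scores=(0.42,)), table)
        sites = call_sites([rec], clean_array, ScanConfig(threshold=0.37))
        assert len(sites) == 1
        planted = manifest.sites[0]
        assert sites[0].start <= planted.start and sites[0].end >= planted.end
        assert sites[0].peak_score == pytest.approx(planted.peak_score, abs=1e-12)
        res = evaluate_calls(sites, manifest)
        assert res["precision"] == 1.0 and res["recall"] == 1.0

    def test_chunked_scan_equals_whole_scan(self):
        rng = np.random.default_rng(4)
        rec = SeqRecord("chr1", random_dna(rng, 5000))
        whole = call_sites([rec], _ARRAY, ScanConfig(threshold=0.15))
        chunked = call_sites([rec], _ARRAY, ScanConfig(threshold=0.15, chunk_size=64))
        assert [(s.start, s.end, s.peak_score, s.peak_octamer) for s in whole] == [
            (s.start, s.end, s.peak_score, s.peak_octamer) for s in chunked
        ]
        assert whole  # the low threshold must actually exercise merging

    def test_revcomp_genome_mirrors_calls(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 2000)
        fwd = call_sites([SeqRecord("c", seq)], _ARRAY, ScanConfig(threshold=0.2))
        rev = call_sites([SeqRecord("c", reverse_complement(seq))], _ARRAY, ScanConfig(threshold=0.2))
        L = len(seq)
        mirrored = sorted((L - s.end, L - s.start, round(s.peak_score, 12)) for s in rev)
        assert mirrored == sorted((s.start, s.end, round(s.peak_score, 12)) for s in fwd)


class TestScanRegions:
    def test_region_containing_site_vs_disjoint(self, clean_table, clean_array):
        from pbmscan import PlantedGenomeSpec, make_genome

        table, _ = clean_table
        rec, manifest = make_genome(PlantedGenomeSpec(seed=22, site_scores=(0.43,)), table)
        site = manifest.sites[0]
        regions = [
            ("chrSyn", max(site.start - 30, 0), site.end + 30, "hit"),
            ("chrSyn", 0, 60, "miss"),
        ]
        per = scan_regions([rec], regions, clean_array, ScanConfig(threshold=0.37))
        assert len(per["hit"]) == 1
        assert per["miss"] == []
        # coordinates are lifted back to the genome
        called = per["hit"][0]
        assert called.start <= site.start and called.end >= site.end

    def test_shared_site_flagged_in_both_regions(self, clean_table, clean_array):
        from pbmscan import PlantedGenomeSpec, make_genome

        table, _ = clean_table
        rec, manifest = make_genome(PlantedGenomeSpec(seed=23, site_scores=(0.44,)), table)
        site = manifest.sites[0]
        a = ("chrSyn", site.start - 40, site.end + 5, "A")
        b = ("chrSyn", site.start - 5, site.end + 40, "B")
        per = scan_regions([rec], [a, b], clean_array, ScanConfig(threshold=0.37))
        assert len(per["A"]) == len(per["B"]) == 1
        assert per["A"][0].shared and per["B"][0].shared

    def test_out_of_bounds_region_is_reported(self):
        rec = SeqRecord("chr1", "ACGT" * 10)
        with pytest.raises(ScanError, match="out of bounds"):
            scan_regions([rec], [("chr1", 0, 9999, "r")], _ARRAY, ScanConfig())

    def test_promoter_regions_are_strand_aware(self):
        tss = [("g1", "chr1", 10000, "+"), ("g2", "chr1", 10000, "-")]
        regions = promoter_regions(tss, upstream=2500, downstream=1000)
        assert regions[0] == ("chr1", 7500, 11000, "g1")
        assert regions[1] == ("chr1", 9000, 12500, "g2")


class TestPwmScanner:
    def test_consensus_scores_matrix_maximum(self):
        pwm = PwmMatrix(np.array([[10, 0, 0, 0]] * 4, dtype=float), name="A4")
        score = pwm_log_odds_score("AAAA", pwm)
        assert score == pytest.approx(4 * np.log(4.0))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        pwm = PwmMatrix(rng.integers(1, 20, size=(2, 4)).astype(float), pseudocount=0.1)
        seq = "ACGTTGCAAGTCT"  # 13-mer: 12 dinucleotide windows
        freqs = pwm.frequencies
        lods = np.log((freqs + 0.1 * 0.25) / (0.25 * 1.1))
        idx = {b: i for i, b in enumerate("ACGT")}

        def windows(s):
            return (
                lods[0, idx[s[i]]] + lods[1, idx[s[i + 1]]] for i in range(len(s) - 1)
            )

        expected = max(max(windows(seq)), max(windows(reverse_complement(seq))))
        assert pwm_log_odds_score(seq, pwm) == pytest.approx(expected, abs=1e-12)

    @given(dna)
    @settings(max_examples=100, derandomize=True)
    def test_strand_symmetry(self, seq):
        rng = np.random.default_rng(8)
        pwm = PwmMatrix(rng.integers(1, 9, size=(5, 4)).astype(float), pseudocount=0.05)
        fwd = pwm_log_odds_score(seq, pwm)
        assert pwm_log_odds_score(reverse_complement(seq), pwm) == pytest.approx(fwd, abs=1e-12)

    def test_zero_frequency_without_pseudocount_advises(self):
        pwm = PwmMatrix(np.array([[10, 0, 0, 0]] * 3, dtype=float))
        with pytest.raises(ScanError, match="pseudocount"):
            pwm_log_odds_score("CCCCCC", pwm)  # no window can score finitely


class TestPBMScannerEstimator:
    def test_sklearn_contract(self, clean_table):
        table, _ = clean_table
        sc = PBMScanner(window=6, threshold=0.3)
        assert sc.get_params()["window"] == 6
        sc.set_params(threshold=0.26)
        assert sc.config.threshold == 0.26
        with pytest.raises(ScanError, match="not fitted"):
            sc.score_probe("ACGTACGTACGTAC")
        sc.fit(table)
        assert sc.array_.values.shape == (65536,)

    def test_transform_returns_probe_features(self, clean_table):
        table, _ = clean_table
        X = ["GGTAAGTAAGTAAGTAACC", "CACACACACACACACACA"]
        feats = PBMScanner().fit(table).transform(X)
        assert feats.shape == (2, 2)
        assert feats[0, 0] >= feats[0, 1]  # max E-score bounds the window mean
        assert feats[0, 1] > feats[1, 1]

    def test_pipeline_composability(self, clean_table):
        pytest.importorskip("sklearn")
        from sklearn.pipeline import Pipeline

        table, _ = clean_table
        scanner_step = PBMScanner().fit(table)
        pipe = Pipeline([("scan", scanner_step)])
        out = pipe.transform(["GGTAAGTAAGTAAGTAACC"])
        assert out.shape == (1, 2)
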
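"""Conservation analytics: entropy scans, bootstrap profiles, identity, metagenes."""

import math

import numpy as np
import pytest

from microx.conservation import (
    ConservedKmer,
    MsaBlock,
    ScoreTrack,
    bootstrap_profile,
    conserved_kmer_enrichment,
    conserved_kmer_scan,
    coverage_metagene,
    entropy_window,
    mean_score_classify,
    merge_tracks,
    percent_identity,
    read_msa_blocks,
)
from microx.genome import Exon


def brute_force_entropy(rows):
    """Independent oracle: explicit per-column base counting."""
    if any("-" in r for r in rows):
        return None
    total = 0.0
    for j in range(len(rows[0])):
        column = [r[j].upper() for r in rows]
        for base in set(column):
            f = column.count(base) / len(column)
            total -= f * math.log(f)
    return total


class TestEntropyWindow:
    def test_identical_rows_zero(self):
        assert entropy_window(["ACGTAC"] * 5) == 0.0

    def test_hand_computed_split_column(self):
        # five rows, one column split 3/2, others invariant
        rows = ["AAAAAA", "AAAAAA", "AAAAAA", "ACAAAA", "ACAAAA"]
        expected = -(0.6 * math.log(0.6) + 0.4 * math.log(0.4))
        assert entropy_window(rows) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.6730116670092565, abs=1e-12)

    def test_gapped_window_excluded(self):
        assert entropy_window(["ACG-AC", "ACGTAC"]) is None

    def test_matches_brute_force_oracle_on_random_windows(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            n_rows = int(rng.integers(2, 7))
            rows = [
                "".join(rng.choice(list("ACGT"), size=6)) for _ in range(n_rows)
            ]
            assert entropy_window(rows) == pytest.approx(
                brute_force_entropy(rows), abs=1e-12
            )

    def test_bounds_and_permutation_invariance(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            rows = ["".join(rng.choice(list("ACGT"), size=6)) for _ in range(5)]
            e = entropy_window(rows)
            assert 0.0 <= e <= 6 * math.log(4) + 1e-12
            perm = [rows[i] for i in rng.permutation(5)]
            assert entropy_window(perm) == pytest.approx(e, abs=1e-12)


class TestConservedKmerScan:
    def _block(self, rows, flank5, exon_len, flank3):
        return MsaBlock(
            region_id="r",
            rows=dict(zip(["human", "mouse", "dog"], rows)),
            flank5=flank5,
            exon_len=exon_len,
            flank3=flank3,
        )

    def test_fully_conserved_single_region_window_count(self):
        seq = "ACGTACGTACGTACGTACGT"  # length 20 -> 15 windows of 6
        block = self._block([seq] * 3, 0, 20, 0)
        hits = conserved_kmer_scan(block)
        assert len(hits) == 15
        assert all(h.entropy == 0.0 for h in hits)
        assert hits[0].kmer == "ACGTAC"

    def test_divergent_windows_excluded(self):
        human = "A" * 30
        other = "A" * 10 + "CGTCGTCGTC" + "A" * 10
        block = self._block([human, other, human], 0, 30, 0)
        hits = conserved_kmer_scan(block)
        positions = {h.position for h in hits}
        # one divergent column (2/3 vs 1/3 split) adds ~0.64 entropy, so any
        # window overlapping >= 2 of the divergent columns (10..19) exceeds 1.0
        assert positions == set(range(0, 6)) | set(range(19, 25))

    def test_region_partition_and_positions(self):
        human = "AAAAAAAAAA" + "CCCCCC" + "GGGGGGGGGG"
        block = self._block([human] * 3, 10, 6, 10)
        hits = conserved_kmer_scan(block)
        by_region = {}
        for h in hits:
            by_region.setdefault(h.region, []).append(h)
        assert {r for r in by_region} == {"5p", "exon", "3p"}
        assert len(by_region["5p"]) == 5
        assert len(by_region["exon"]) == 1
        assert by_region["exon"][0].kmer == "CCCCCC"
        assert by_region["exon"][0].position == 0

    def test_missing_reference_row_raises(self):
        block = MsaBlock(
            region_id="r", rows={"mouse": "ACGTACGT", "dog": "ACGTACGT"},
            flank5=0, exon_len=8, flank3=0,
        )
        with pytest.raises(ValueError, match="reference"):
            conserved_kmer_scan(block)

    def test_planted_rbfox_motif_tops_downstream_enrichment(self, sim_default):
        from microx.simulate import make_msa_blocks

        sim, _ = sim_default
        blocks = {b.region_id: b for b in make_msa_blocks(sim, seed=33)}
        kinds = sim.exons.set_index("exon_id")["kind"]
        scans = {"AS": [], "CS": []}
        for exon_id, kind in kinds.items():
            scan = conserved_kmer_scan(blocks[exon_id])
            scans["CS" if kind == "CS" else "AS"].append(scan)
        table = conserved_kmer_enrichment(scans)
        down_as = table[(table["class"] == "AS") & (table["region"] == "3p")]
        assert not down_as.empty
        assert down_as.iloc[0]["kmer"] == "TGCATG"  # sorted by mean occurrence

    def test_enrichment_mean_invariance_under_duplication(self):
        scan = [ConservedKmer("3p", "TGCATG", 4, 0.2)]
        once = conserved_kmer_enrichment({"AS": [scan]})
        twice = conserved_kmer_enrichment({"AS": [scan, scan]})
        assert once.iloc[0]["mean_per_exon"] == twice.iloc[0]["mean_per_exon"] == 1.0

    def test_empty_class_gives_no_rows(self):
        assert conserved_kmer_enrichment({"AS": []}).empty


class TestMsaIO:
    def test_round_trip_blocks(self, tmp_path):
        text = (
            ">human|ex1:2:6:2\nAACCCCCCGG\n"
            ">mouse|ex1:2:6:2\nAACCCCCCGG\n"
            ">human|ex2:0:8:0\nACGTACGT\n"
            ">mouse|ex2:0:8:0\nACGTACGT\n"
        )
        p = tmp_path / "msa.fa"
        p.write_text(text)
        blocks = {b.region_id: b for b in read_msa_blocks(str(p))}
        assert set(blocks) == {"ex1", "ex2"}
        assert blocks["ex1"].flank5 == 2 and blocks["ex1"].exon_len == 6
        assert blocks["ex1"].rows["mouse"] == "AACCCCCCGG"

    def test_unequal_rows_raise(self):
        with pytest.raises(ValueError):
            MsaBlock("r", {"human": "ACGT", "mouse": "ACG"}, 0, 4, 0)


class TestPercentIdentity:
    def test_identical_is_hundred(self):
        assert percent_identity("A" * 100, "A" * 100) == 100.0

    def test_single_substitution(self):
        a = "A" * 100
        b = "A" * 50 + "C" + "A" * 49
        assert percent_identity(a, b) == 99.0

    def test_region_slice_with_mismatches(self):
        a = "ACGTACGTACGT"
        b = "ACGTTTTTACGT"
        assert percent_identity(a, b, slice(0, 12)) == 75.0

    def test_gap_columns_count_as_mismatch(self):
        assert percent_identity("AC-T", "ACGT") == 75.0

    def test_self_identity_any_region(self):
        seq = "ACGT-ACGTTT"
        # gap-gap columns also count as mismatch under the gap rule
        assert percent_identity(seq.replace("-", "A"), seq.replace("-", "A")) == 100.0


class TestBootstrapProfile:
    def test_identical_vectors_collapse_interval(self):
        vectors = np.tile(np.linspace(0, 1, 10), (8, 1))
        prof = bootstrap_profile(vectors, B=200, seed=0)
        np.testing.assert_allclose(prof.lo, prof.mean)
        np.testing.assert_allclose(prof.hi, prof.mean)

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        vectors = rng.random((30, 20))
        p1 = bootstrap_profile(vectors, B=300, seed=7)
        p2 = bootstrap_profile(vectors, B=300, seed=7)
        np.testing.assert_array_equal(p1.lo, p2.lo)
        np.testing.assert_array_equal(p1.hi, p2.hi)
        np.testing.assert_array_equal(p1.mean, p2.mean)

    def test_binary_mixture_matches_independent_resampler(self):
        n = 20
        vectors = np.vstack([np.zeros((n // 2, 4)), np.ones((n // 2, 4))])
        prof = bootstrap_profile(vectors, B=4000, seed=1)
        # independent oracle: resample row indices with a different generator
        rng = np.random.default_rng(999)
        means = np.array(
            [vectors[rng.integers(0, n, n)].mean(axis=0) for _ in range(4000)]
        )
        lo_oracle = np.percentile(means, 5, axis=0)
        hi_oracle = np.percentile(means, 95, axis=0)
        np.testing.assert_allclose(prof.mean, 0.5)
        np.testing.assert_allclose(prof.lo, lo_oracle, atol=0.05)
        np.testing.assert_allclose(prof.hi, hi_oracle, atol=0.05)

    def test_interval_brackets_mean(self):
        rng = np.random.default_rng(3)
        vectors = rng.random((50, 10))
        prof = bootstrap_profile(vectors, B=500, seed=3)
        assert (prof.lo <= prof.mean + 1e-9).all()
        assert (prof.hi >= prof.mean - 1e-9).all()

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            bootstrap_profile(np.empty((0, 10)))


class TestScoreTrack:
    def test_wig_round_trip(self, tmp_path):
        wig = "fixedStep chrom=chr1 start=3 step=1\n0.1\n0.2\n0.3\n"
        p = tmp_path / "t.wig"
        p.write_text(wig)
        track = ScoreTrack.from_wig(str(p), {"chr1": 6})
        got = track.get("chr1", 0, 6)
        np.testing.assert_allclose(got[2:5], [0.1, 0.2, 0.3])
        assert np.isnan(got[0]) and np.isnan(got[5])

    def test_bedgraph_and_strand_flip(self, tmp_path):
        p = tmp_path / "t.bg"
        p.write_text("chr1\t0\t3\t1.0\nchr1\t3\t6\t2.0\n")
        track = ScoreTrack.from_bedgraph(str(p), {"chr1": 6})
        np.testing.assert_allclose(track.get("chr1", 0, 6), [1, 1, 1, 2, 2, 2])
        np.testing.assert_allclose(track.get("chr1", 0, 6, "-"), [2, 2, 2, 1, 1, 1])

    def test_merge_tracks_averages(self):
        t1 = ScoreTrack({"c": np.array([1.0, 2.0])})
        t2 = ScoreTrack({"c": np.array([3.0, 4.0])})
        merged = merge_tracks([t1, t2])
        np.testing.assert_allclose(merged.data["c"], [2.0, 3.0])


class TestMeanScoreClassify:
    def _exon(self, start, end):
        return Exon("c", start, end, "+", frozenset(), "internal")

    def test_tail_fractions(self):
        track = ScoreTrack({"c": np.concatenate([np.ones(10), np.zeros(10)])})
        exons = [self._exon(0, 10), self._exon(10, 20), self._exon(5, 15)]
        df, fractions = mean_score_classify(exons, track)
        means = dict(zip(df["exon_id"], df["mean_score"]))
        assert means["c:0-10:+"] == 1.0
        assert means["c:10-20:+"] == 0.0
        assert means["c:5-15:+"] == 0.5
        assert fractions["high"] == pytest.approx(1 / 3)
        assert fractions["low"] == pytest.approx(1 / 3)

    def test_mostly_missing_exon_dropped(self):
        arr = np.full(20, np.nan)
        arr[:4] = 1.0
        track = ScoreTrack({"c": arr})
        df, _ = mean_score_classify([self._exon(0, 20)], track)
        assert df.empty


class TestCoverageMetagene:
    def test_uniform_coverage_flat_profile(self):
        track = ScoreTrack({"c": np.full(1000, 3.0)})
        exons = [Exon("c", 400, 430, "+", frozenset(), "internal")]
        prof = coverage_metagene(track, {"x": exons}, window=100, B=50, seed=0)["x"]
        np.testing.assert_allclose(prof.mean, 3.0)
        assert len(prof.positions) == 100

    def test_linearity_in_track_scale(self):
        rng = np.random.default_rng(5)
        arr = rng.random(1000)
        exons = [
            Exon("c", s, s + 20, "+", frozenset(), "internal")
            for s in (100, 300, 500)
        ]
        p1 = coverage_metagene(
            ScoreTrack({"c": arr}), {"x": exons}, window=60, B=50, seed=4
        )["x"]
        p2 = coverage_metagene(
            ScoreTrack({"c": arr * 2.5}), {"x": exons}, window=60, B=50, seed=4
        )["x"]
        np.testing.assert_allclose(p2.mean, 2.5 * p1.mean)
        np.testing.assert_allclose(p2.lo, 2.5 * p1.lo)

    def test_minus_strand_profile_is_flipped(self):
        arr = np.arange(1000, dtype=float)
        fwd = [Exon("c", 400, 430, "+", frozenset(), "internal")]
        rev = [Exon("c", 400, 430, "-", frozenset(), "internal")]
        track = ScoreTrack({"c": arr})
        pf = coverage_metagene(track, {"x": fwd}, window=50, B=10, seed=0)["x"]
        pr = coverage_metagene(track, {"x": rev}, window=50, B=10, seed=0)["x"]
        np.testing.assert_allclose(pr.mean, pf.mean[::-1])

    def test_empty_set_yields_none(self):
        track = ScoreTrack({"c": np.zeros(10)})
        assert coverage_metagene(track, {"x": []}, B=10)["x"] is None

    def test_planted_clip_peaks_downstream_of_as_exons(self, sim_default):
        from microx.simulate import make_clip_track

        sim, _ = sim_default
        track = make_clip_track(sim, seed=44)
        kinds = sim.exons.set_index("exon_id")
        sets = {"AS": [], "CS": []}
        from microx.genome import identify_micro_exons

        mes = {m.id: m for m in identify_micro_exons(sim.model)}
        for exon_id, row in kinds.iterrows():
            sets["CS" if row["kind"] == "CS" else "AS"].append(mes[exon_id])
        profs = coverage_metagene(track, sets, window=300, B=100, seed=1)
        down = slice(200, 300)  # 3' flank side of the centered window
        assert profs["AS"].mean[down].mean() > profs["CS"].mean[down].mean()
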
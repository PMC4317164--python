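"""Splicing features: ESE density, PWM scans, profiles, overlap statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microx._seq import random_seq
from microx.features import (
    LogOddsPwmScorer,
    Pwm,
    TableScorer,
    class_feature_table,
    ese_density,
    flank_density,
    kmer_flank_profile,
    mann_whitney_p,
    motif_occurrence_window,
    nt_content_profile,
    overlap_test,
    pwm_scan,
    read_hexamers,
    region_central,
    splice_site_score,
)
from microx.genome import Gene, GenomeModel, Transcript, identify_micro_exons

DNA = st.text(alphabet="ACGT", min_size=6, max_size=60)
HEXAMERS = st.sets(st.text(alphabet="ACGT", min_size=6, max_size=6), max_size=8)


def _single_me_model(up_intron, down_intron, me_seq):
    """Plus-strand gene: exon (0,100), micro-exon, exon; introns as given."""
    contig = "A" * 100 + up_intron + me_seq + down_intron + "G" * 100
    s = 100 + len(up_intron)
    e = s + len(me_seq)
    t = Transcript("t", "g", "c", "+", [(0, 100), (s, e), (len(contig) - 100, len(contig))])
    model = GenomeModel(contigs={"c": contig}, genes=[Gene("g", "c", "+", [t])])
    return model, identify_micro_exons(model)[0]


class TestEseDensity:
    def test_overlapping_matches_counted(self):
        assert ese_density("GAAGAAGAAGAA", {"GAAGAA"}) == pytest.approx(3 / 7)

    def test_empty_set_and_single_window(self):
        assert ese_density("ACGTACGTACGT", set()) == 0.0
        assert ese_density("GAAGAA", {"GAAGAA"}) == 1.0

    def test_short_sequence_undefined(self):
        assert ese_density("ACGTA", {"GAAGAA"}) is None

    @settings(max_examples=50, deadline=None)
    @given(seq=DNA, hexamers=HEXAMERS, extra=st.text(alphabet="ACGT", min_size=6, max_size=6))
    def test_bounded_and_monotone(self, seq, hexamers, extra):
        d = ese_density(seq, hexamers)
        assert 0.0 <= d <= 1.0
        assert ese_density(seq, hexamers | {extra}) >= d

    def test_read_hexamers_validates(self, tmp_path):
        p = tmp_path / "hex.txt"
        p.write_text("GAAGAA\nUCAAGA\n")
        assert read_hexamers(str(p)) == {"GAAGAA", "TCAAGA"}
        p.write_text("TOOLONGG\n")
        with pytest.raises(ValueError):
            read_hexamers(str(p))


class TestSpliceSiteScorers:
    def test_perfect_pwm_scores_two_bits_per_position(self):
        seq = "CAGGTAAGT"
        probs = np.full((9, 4), 1e-12)
        for i, c in enumerate(seq):
            probs[i, "ACGT".index(c)] = 1.0
        probs /= probs.sum(axis=1, keepdims=True)
        scorer = LogOddsPwmScorer(Pwm("perfect", probs))
        assert splice_site_score(seq, scorer) == pytest.approx(18.0, abs=1e-6)

    def test_uniform_pwm_scores_zero(self):
        scorer = LogOddsPwmScorer(Pwm("uniform", np.full((9, 4), 0.25)))
        assert splice_site_score("CAGGTAAGT", scorer) == pytest.approx(0.0)

    def test_table_scorer_lookup(self):
        scorer = TableScorer({"CAGGTAAGT": 10.86})
        assert splice_site_score("CAGGTAAGT", scorer) == 10.86
        with pytest.raises(ValueError):
            scorer("AAAAAAAAA")

    def test_window_length_mismatch_raises(self):
        scorer = LogOddsPwmScorer(Pwm("uniform", np.full((9, 4), 0.25)))
        with pytest.raises(ValueError):
            scorer("ACGT")

    def test_pwm_tsv_round_trip(self, tmp_path):
        pwm = Pwm("u", np.full((7, 4), 0.25))
        p = tmp_path / "u.pwm"
        p.write_text(pwm.to_tsv())
        again = Pwm.from_tsv(str(p))
        np.testing.assert_allclose(again.probs, pwm.probs)


class TestPwmScan:
    def _perfect(self, motif="TTTTTTT"):
        probs = np.full((len(motif), 4), 1e-12)
        for i, c in enumerate(motif):
            probs[i, "ACGT".index(c)] = 1.0
        probs /= probs.sum(axis=1, keepdims=True)
        return Pwm("m", probs)

    def test_perfect_match_is_hit(self):
        hits = pwm_scan("TTTTTTT", self._perfect())
        assert len(hits) == 1
        assert hits[0][0] == 0
        assert hits[0][1] == pytest.approx(0.0, abs=1e-6)
        assert hits[0][1] >= 7 * math.log(0.6)

    def test_uniform_pwm_never_hits(self):
        pwm = Pwm("u", np.full((7, 4), 0.25))
        assert pwm_scan("ACGTACGTACGTACGT", pwm) == []
        # closed form: every window scores 7*ln(0.25)
        hits = pwm_scan("ACGTACGT", pwm, threshold=7 * math.log(0.25) - 1e-9)
        assert [h[0] for h in hits] == [0, 1]

    def test_sequence_shorter_than_width(self):
        assert pwm_scan("ACGT", self._perfect()) == []

    def test_hit_set_invariant_under_base_change_with_rescaled_threshold(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(4), size=7)
        pwm = Pwm("r", probs)
        seq = random_seq(rng, 200)
        t_nat = 7 * math.log(0.6)
        hits_nat = {h[0] for h in pwm_scan(seq, pwm, threshold=t_nat)}
        # recompute all scores, convert to log2 and compare against t/ln(2)
        all_scores = {
            h[0]: h[1] for h in pwm_scan(seq, pwm, threshold=-math.inf)
        }
        hits_log2 = {
            i for i, s in all_scores.items() if s / math.log(2) >= t_nat / math.log(2)
        }
        assert hits_nat == hits_log2


class TestMotifWindow:
    def _pwm_t7(self):
        probs = np.full((7, 4), 0.01)
        probs[:, 3] = 0.97
        return Pwm("t7", probs / probs.sum(axis=1, keepdims=True))

    def _intron(self, tract_end_offset=10):
        # 60-nt canonical intron with TTTTTTT ending `tract_end_offset` before the exon
        fill = "C"
        n = 60
        seq = list(fill * n)
        seq[0:2] = "GT"
        seq[-2:] = "AG"
        start = n - tract_end_offset - 7
        seq[start : start + 7] = "TTTTTTT"
        return "".join(seq)

    def test_planted_tract_in_window_fraction_one(self):
        model, me = _single_me_model(self._intron(), "GT" + "C" * 56 + "AG", "ACGTAC")
        mean_hits, frac = motif_occurrence_window([me], model, self._pwm_t7())
        assert frac == 1.0
        assert mean_hits >= 1.0

    def test_tract_outside_window_not_counted(self):
        model, me = _single_me_model(
            self._intron(tract_end_offset=35), "GT" + "C" * 56 + "AG", "ACGTAC"
        )
        mean_hits, frac = motif_occurrence_window([me], model, self._pwm_t7())
        assert (mean_hits, frac) == (0.0, 0.0)

    def test_mixed_exons_mean_and_fraction(self):
        model1, me1 = _single_me_model(self._intron(), "GT" + "C" * 56 + "AG", "ACGTAC")
        model2, me2 = _single_me_model(
            self._intron(tract_end_offset=35), "GT" + "C" * 56 + "AG", "ACGTAC"
        )
        # evaluate each exon against its own model, then combine
        m1 = motif_occurrence_window([me1], model1, self._pwm_t7())
        m2 = motif_occurrence_window([me2], model2, self._pwm_t7())
        assert (m1[1] + m2[1]) / 2 == 0.5


class TestNtContentProfile:
    def test_all_t_upstream(self):
        up = "GT" + "T" * 56 + "AG"
        down = "GT" + "C" * 56 + "AG"
        model, me = _single_me_model(up, down, "ACGTAC")
        prof = nt_content_profile([me], model, flank=30, min_exons=1)
        upstream = prof[(prof["position"] < -2)]
        assert (upstream["fraction"] == 1.0).all()

    def test_positions_beyond_intron_masked(self):
        up = "GT" + "T" * 26 + "AG"  # 30-nt intron
        down = "GT" + "C" * 26 + "AG"
        model, me = _single_me_model(up, down, "ACGTAC")
        prof = nt_content_profile([me], model, flank=50, min_exons=1)
        beyond = prof[prof["position"] < -30]
        assert beyond["fraction"].isna().all()

    def test_random_sequence_near_background(self, sim_default):
        sim, _ = sim_default
        mes = identify_micro_exons(sim.model)
        prof = nt_content_profile(mes, model=sim.model, flank=40, min_exons=5)
        # background is uniform: T fraction near 0.25 outside planted tracts
        downstream = prof[prof["position"] > 10]["fraction"].dropna()
        n = len(mes)
        bound = 4 * math.sqrt(0.25 * 0.75 / n)
        assert (downstream - 0.25).abs().mean() < bound


class TestKmerFlankProfile:
    def test_single_planted_site_position(self):
        down = list("GT" + "C" * 66 + "AG")
        down[29:35] = "TGCATG"  # k-mer start at downstream offset 29 -> +30
        model, me = _single_me_model("GT" + "C" * 56 + "AG", "".join(down), "ACGTAC")
        prof = kmer_flank_profile([me], model, flank=60)
        hit_rows = prof[prof["count"] > 0]
        assert list(hit_rows["position"]) == [30]

    def test_absent_kmer_zero_profile(self):
        model, me = _single_me_model(
            "GT" + "C" * 56 + "AG", "GT" + "C" * 56 + "AG", "ACGTAC"
        )
        prof = kmer_flank_profile([me], model, flank=60)
        assert (prof["count"] == 0).all()

    def test_downstream_density_ratio_tracks_planting_rate(self, sim_default):
        sim, _ = sim_default
        mes = {m.id: m for m in identify_micro_exons(sim.model)}
        kinds = sim.exons.set_index("exon_id")["kind"]
        as_exons = [mes[e] for e, k in kinds.items() if k in ("AS", "BS")]
        cs_exons = [mes[e] for e, k in kinds.items() if k == "CS"]
        p_as = kmer_flank_profile(as_exons, sim.model)
        p_cs = kmer_flank_profile(cs_exons, sim.model)
        ratio = flank_density(p_as, "downstream") / flank_density(p_cs, "downstream")
        assert ratio > 1.2  # AS flanks planted at twice the background rate


class TestClassFeatureTable:
    def test_simulated_cs_introns_shorter_than_as(self, sim_default):
        sim, _ = sim_default
        mes = {m.id: m for m in identify_micro_exons(sim.model)}
        kinds = sim.exons.set_index("exon_id")["kind"]
        by_class = {
            "CS": [mes[e] for e, k in kinds.items() if k == "CS"],
            "AS": [mes[e] for e, k in kinds.items() if k != "CS"],
        }
        hexamers = frozenset(sim.config.ese_hexamers)
        per_exon, summary = class_feature_table(by_class, sim.model, hexamers)
        med = summary.set_index(["class", "feature"])["median"]
        assert med["CS", "intron_3_len"] < med["AS", "intron_3_len"]
        assert med["CS", "ese_density"] > med["AS", "ese_density"]
        # medians in the summary match the per-exon export
        direct = per_exon[per_exon["class"] == "CS"]["intron_3_len"].median()
        assert med["CS", "intron_3_len"] == direct

    def test_identical_distributions_p_one(self):
        assert mann_whitney_p([1.0, 1.0, 1.0], [1.0, 1.0]) == 1.0

    def test_u_statistic_matches_naive_rank_comparison(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(3)
        x = rng.normal(size=120)
        y = rng.normal(0.3, size=80)
        u_scipy = mannwhitneyu(x, y, alternative="two-sided").statistic
        u_naive = sum(
            (xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y
        )
        assert u_scipy == pytest.approx(u_naive)


class TestOverlapTest:
    def test_complete_overlap_small_universe(self):
        # P(overlap = 5 | N=10, A=B=5) = 1 / C(10,5)
        assert overlap_test(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_zero_overlap_probability_one(self):
        assert overlap_test(100, 10, 10, 0) == 1.0

    def test_rbfox_ptbp1_overlap_is_significant(self):
        # 25 of 159 RBFOX-enhanced and 113 PTBP1-repressed among 1480 AS
        # exons; the reference 6.7e-5 bound corresponds to the
        # strictly-greater tail convention
        assert overlap_test(1480, 159, 113, 25, inclusive=False) <= 6.7e-5
        # tail conventions agree up to a one-count shift
        assert overlap_test(1480, 159, 113, 25) == pytest.approx(
            overlap_test(1480, 159, 113, 24, inclusive=False), rel=1e-9
        )

    def test_matches_enumeration_oracle(self):
        from math import comb

        def oracle(N, A, B, k):
            total = sum(
                comb(B, i) * comb(N - B, A - i)
                for i in range(k, min(A, B) + 1)
            )
            return total / comb(N, A)

        rng = np.random.default_rng(4)
        for _ in range(50):
            N = int(rng.integers(2, 25))
            A = int(rng.integers(0, N + 1))
            B = int(rng.integers(0, N + 1))
            lo = max(0, A + B - N)
            k = int(rng.integers(lo, min(A, B) + 1))
            assert overlap_test(N, A, B, k) == pytest.approx(
                oracle(N, A, B, k), rel=1e-10
            )

    def test_monotone_in_overlap(self):
        ps = [overlap_test(100, 30, 40, k) for k in range(0, 31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            overlap_test(10, 5, 5, 6)
        with pytest.raises(ValueError):
            overlap_test(10, 11, 5, 2)
        with pytest.raises(ValueError):
            overlap_test(10, 9, 9, 2)  # overlap below forced minimum (8)


def test_region_central_left_shift_on_ties():
    assert region_central("ABCDEFGH", 4) == "CDEF"
    assert region_central("ABCDEFG", 4) == "BCDE"  # floor(7/2)=3 -> start 1
    assert region_central("ACGT", 24) == "ACGT"
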
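"""Motif scoring, scanning, region decomposition, sampling and testing."""

import itertools
import math

import numpy as np
import pytest

from titrseq.io_formats import PWMRecord
from titrseq.motif_analysis import (
    BackgroundModel,
    decompose_regions,
    estimate_background,
    group_by_rbp,
    group_hit_count,
    mann_whitney,
    motif_enrichment_test,
    positional_density,
    region_windows,
    reverse_complement,
    sample_background,
    scan_hits,
    score_motif,
)
from titrseq.synthetic_data import (
    SimulationConfig,
    gen_events,
    gen_pwms,
    gen_sequences_with_motifs,
)
from conftest import make_se_event

RNA = "ACGU"
UNIFORM = BackgroundModel(freqs=(0.25, 0.25, 0.25, 0.25))


def brute_force_hits(pwm_probs, background, pseudocount, sequence, hit_fraction=0.8):
    """Independent per-window log-odds enumeration."""
    L = len(pwm_probs)
    w = [[math.log2((pwm_probs[i][b] + pseudocount) / background[b]) for b in range(4)]
         for i in range(L)]
    max_score = sum(max(row) for row in w)
    hits = []
    for off in range(len(sequence) - L + 1):
        s = sum(w[i][RNA.index(sequence[off + i])] for i in range(L))
        if s > hit_fraction * max_score:
            hits.append(off)
    return hits


def mw_permutation_oracle(x, y):
    """Two-sided exact Mann–Whitney p by full enumeration of splits."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    observed = u_stat(x, y)
    n2 = len(y)
    mu = n1 * n2 / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


class TestBackground:
    def test_add_one_smoothing_closed_form(self):
        bg = estimate_background(["AAAA"])
        assert bg.freqs == pytest.approx((5 / 8, 1 / 8, 1 / 8, 1 / 8))

    def test_uniform_sequence_near_quarter(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list(RNA), size=40000))
        bg = estimate_background([seq])
        sd = math.sqrt(0.25 * 0.75 / 40000)
        for q in bg.freqs:
            assert abs(q - 0.25) < 3 * sd

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_background([])


class TestScoreMotif:
    def test_background_equal_pwm_scores_zero(self):
        probs = np.full((5, 4), 0.25)
        pwm = PWMRecord(motif_id="m", rbp_names=("r",), probs=probs)
        scored = score_motif(pwm, UNIFORM, pseudocount=1e-12)
        assert scored.max_score == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(scored.log_odds, 0.0, atol=1e-9)

    def test_max_score_equals_hand_summation(self, uniform_pwm):
        scored = score_motif(uniform_pwm, UNIFORM, pseudocount=0.001)
        expected = 4 * math.log2(0.851 / 0.25)
        assert scored.max_score == pytest.approx(expected)
        assert scored.hit_threshold == pytest.approx(0.8 * expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_is_always_80pct_of_max(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(4), size=rng.integers(2, 12))
        pwm = PWMRecord(motif_id="m", rbp_names=("r",), probs=probs)
        scored = score_motif(pwm, UNIFORM)
        assert scored.hit_threshold == pytest.approx(0.8 * scored.max_score)


class TestScanHits:
    def test_consensus_hits_single_mismatch_does_not(self, uniform_pwm):
        scored = score_motif(uniform_pwm, UNIFORM)
        assert scan_hits(scored, "ACGU") == [0]
        # one mismatch: 3·log2(.851/.25) + log2(.051/.25) ≈ 3.0 bits < 0.8·7.06
        assert scan_hits(scored, "ACGA") == []

    def test_zero_threshold_boundary_is_strict(self):
        from titrseq.motif_analysis import ScoredMotif

        scored = ScoredMotif(motif_id="m", rbp_names=("r",),
                             log_odds=np.zeros((3, 4)), max_score=0.0, hit_threshold=0.0)
        assert scan_hits(scored, "ACGUACGU") == []  # 0 > 0 is false

    def test_sequence_shorter_than_motif(self, uniform_pwm):
        scored = score_motif(uniform_pwm, UNIFORM)
        assert scan_hits(scored, "AC") == []

    def test_non_alphabet_character_rejected_with_position(self, uniform_pwm):
        scored = score_motif(uniform_pwm, UNIFORM)
        with pytest.raises(ValueError, match="position 2"):
            scan_hits(scored, "ACTGU")

    @pytest.mark.parametrize("seed", range(50))
    def test_scanner_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(3, 11))
        probs = rng.dirichlet(np.ones(4) * rng.uniform(0.2, 2.0), size=L)
        pwm = PWMRecord(motif_id="m", rbp_names=("r",), probs=probs)
        q = rng.dirichlet(np.ones(4) + 1)
        bg = BackgroundModel(freqs=tuple(float(v) for v in q))
        seq = "".join(rng.choice(list(RNA), size=int(rng.integers(L, 201))))
        scored = score_motif(pwm, bg)
        assert scan_hits(scored, seq) == brute_force_hits(
            probs.tolist(), q.tolist(), 1e-3, seq
        )


class TestGrouping:
    def test_disjoint_hit_counts_sum(self):
        m1 = PWMRecord(motif_id="a", rbp_names=("R",), probs=np.array(
            [[0.97, 0.01, 0.01, 0.01]] * 3))
        m2 = PWMRecord(motif_id="b", rbp_names=("R",), probs=np.array(
            [[0.01, 0.97, 0.01, 0.01]] * 3))
        scored = [score_motif(m, UNIFORM) for m in (m1, m2)]
        groups = group_by_rbp(scored)
        assert list(groups) == ["R"]
        # two AAA hits and three CCC hits, disjoint
        assert group_hit_count(groups["R"], "AAAAGCCCCC") == 2 + 3

    def test_motif_with_two_rbps_joins_both_groups(self):
        m = PWMRecord(motif_id="a", rbp_names=("R1", "R2"),
                      probs=np.array([[0.97, 0.01, 0.01, 0.01]] * 3))
        groups = group_by_rbp([score_motif(m, UNIFORM)])
        assert set(groups) == {"R1", "R2"}

    def test_no_shared_rbps_groups_equal_motifs(self):
        ms = [PWMRecord(motif_id=f"m{i}", rbp_names=(f"R{i}",),
                        probs=np.full((2, 4), 0.25)) for i in range(3)]
        groups = group_by_rbp([score_motif(m, UNIFORM) for m in ms])
        assert len(groups) == 3


class TestRegions:
    def test_plus_strand_se_has_seven_300nt_windows(self):
        ev = make_se_event("e", "+", intron_len=1000)
        windows = region_windows(ev)
        assert len(windows) == 7
        for name in ("intron5p_start", "intron5p_end", "intron3p_start", "intron3p_end"):
            s, e = windows[name]
            assert e - s == 300

    def test_short_intron_midpoint_rule(self):
        ev = make_se_event("e", "+", intron_len=400)
        windows = region_windows(ev)
        s1, e1 = windows["intron5p_start"]
        s2, e2 = windows["intron5p_end"]
        assert e1 - s1 == 200 and e2 - s2 == 200
        assert e1 <= s2  # never overlap

    def test_minus_strand_regions_are_revcomp_mirror(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list(RNA), size=6000))
        plus = make_se_event("p", "+", origin=500)
        minus = make_se_event("m", "-", origin=500)
        store = {"chrS": seq}
        rp = decompose_regions(plus, store).regions
        rm = decompose_regions(minus, store).regions
        # same genomic intervals, mirrored roles: the minus 5' exon is the
        # plus 3' exon reverse-complemented
        assert rm["exon_5p"] == reverse_complement(rp["exon_3p"])
        assert rm["alt_exon"] == reverse_complement(rp["alt_exon"])
        assert rm["intron5p_start"] == reverse_complement(rp["intron3p_end"])
        assert rm["intron3p_start"] == reverse_complement(rp["intron5p_end"])

    def test_out_of_bounds_region_rejected(self):
        ev = make_se_event("e", "+", origin=100)
        with pytest.raises(ValueError, match="outside chromosome"):
            decompose_regions(ev, {"chrS": "ACGU" * 100})


class TestSampling:
    def test_ten_negatives_per_positive(self):
        pos = {f"p{i}": 100.0 + i for i in range(5)}
        pool = {f"n{i}": 100.0 + i % 7 for i in range(200)}
        neg = sample_background(pos, pool, seed=0)
        assert len(neg) == 50

    def test_without_replacement_when_pool_suffices(self):
        pos = {"p1": 100.0}
        pool = {f"n{i}": 100.0 for i in range(50)}
        neg = sample_background(pos, pool, n_per_pos=10, n_bins=1, seed=0)
        assert len(set(neg)) == 10

    def test_deterministic_given_seed(self):
        pos = {f"p{i}": float(i * 10) for i in range(8)}
        pool = {f"n{i}": float(i % 80) for i in range(300)}
        assert sample_background(pos, pool, seed=5) == sample_background(pos, pool, seed=5)
        assert sample_background(pos, pool, seed=5) != sample_background(pos, pool, seed=6)

    def test_negatives_come_from_matching_length_bin(self):
        pos = {"short": 10.0, "long": 1000.0}
        pool = {f"s{i}": 10.0 + i * 0.01 for i in range(100)}
        pool.update({f"l{i}": 1000.0 + i * 0.01 for i in range(100)})
        neg = sample_background(pos, pool, n_per_pos=10, n_bins=2, seed=1)
        short_negs = [n for n in neg if n.startswith("s")]
        long_negs = [n for n in neg if n.startswith("l")]
        assert len(short_negs) == 10 and len(long_negs) == 10


class TestEnrichmentTest:
    def test_identical_rates_null(self):
        rates = {("R", "region", "increasing"): ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])}
        res = motif_enrichment_test(rates)[0]
        assert res.u_statistic == pytest.approx(4.5)
        assert res.p_value > 0.9
        assert res.effect == "none"

    def test_separated_samples_exact_p(self):
        rates = {("R", "region", "increasing"): ([10.0, 11.0, 12.0], [1.0, 2.0, 3.0])}
        res = motif_enrichment_test(rates)[0]
        assert res.u_statistic == 9
        assert res.p_value == pytest.approx(2 / math.comb(6, 3))
        assert res.effect == "enriched"

    @pytest.mark.parametrize("seed", range(8))
    def test_mann_whitney_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 8), rng.integers(2, 8)
        # distinct values so the exact method applies cleanly
        vals = rng.permutation(np.arange(n1 + n2, dtype=float) * 1.7)
        x, y = vals[:n1].tolist(), vals[n1:].tolist()
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(mw_permutation_oracle(x, y), rel=1e-9)

    def test_all_zero_rates_give_p1_effect_none(self):
        rates = {("R", "region", "increasing"): ([0.0, 0.0], [0.0, 0.0, 0.0])}
        res = motif_enrichment_test(rates)[0]
        assert res.p_value == 1.0
        assert res.effect == "none"

    def test_effect_requires_25pct_rate_difference(self):
        rates = {
            ("R", "a", "increasing"): ([1.2] * 30, [1.0] * 30),  # +20% → none
            ("R", "b", "increasing"): ([1.3] * 30, [1.0] * 30),  # +30% → enriched
            ("R", "c", "increasing"): ([0.7] * 30, [1.0] * 30),  # −30% → depleted
        }
        by_region = {r.region: r.effect for r in motif_enrichment_test(rates)}
        assert by_region == {"a": "none", "b": "enriched", "c": "depleted"}


class TestPlantedRecovery:
    def test_planted_group_flagged_in_planted_region(self):
        cfg = SimulationConfig(seed=3, n_events=400, event_mix={"SE": 1.0},
                               frac_increasing=0.25, frac_decreasing=0.0,
                               motif_plant_density_pos=3.0, motif_plant_density_bg=1.0)
        events, truth = gen_events(cfg)
        pwms = gen_pwms(cfg)
        seqs, truth = gen_sequences_with_motifs(cfg, events, truth, pwms)
        bg = estimate_background(seqs)
        scored = [score_motif(p, bg) for p in pwms]
        groups = group_by_rbp(scored)
        pos = [e for e in events if truth.labels[e.event_id] == "increasing"]
        pool = {e.event_id: e for e in events if truth.labels[e.event_id] == "null"}
        neg_ids = sample_background(
            {e.event_id: e.alt_length for e in pos},
            {eid: e.alt_length for eid, e in pool.items()}, seed=cfg.seed)
        from titrseq.motif_analysis import region_hit_rates

        pos_r = [decompose_regions(e, seqs) for e in pos]
        neg_r = [decompose_regions(pool[i], seqs) for i in neg_ids]
        results = motif_enrichment_test(region_hit_rates(groups, pos_r, neg_r, "increasing"))
        planted = [r for r in results
                   if r.rbp_group == "RBP1" and r.region == "intron5p_start"][0]
        assert planted.q_value < 0.05
        assert planted.effect == "enriched"


class TestPositionalDensity:
    def test_planted_offset_spike(self, uniform_pwm):
        # every positive event gets the consensus ACGU planted at offset −50
        # from the skipped-exon start junction
        events = [make_se_event(f"e{i}", "+", origin=500 + 6000 * i) for i in range(20)]
        rng = np.random.default_rng(0)
        length = events[-1].coords.segments[-1][2] + 1000
        chrom = list(rng.choice(list("ACG"), size=length))  # no U: no spurious hits
        for ev in events[:10]:
            j = ev.coords.segment("alt")[0]
            chrom[j - 50 : j - 46] = list("ACGU")
        seqs = {"chrS": "".join(chrom)}
        scored = score_motif(uniform_pwm, UNIFORM)
        dens = positional_density("R", [scored], events[:10], events[10:], seqs,
                                  junction="alt_start", window=200)
        spike = int(np.argmax(dens.rate_positive))
        assert dens.offsets[spike] == -50
        assert dens.rate_positive[spike] == 1.0
        assert dens.rate_background.max() == 0.0

    def test_no_hits_all_zero(self, uniform_pwm):
        events = [make_se_event("e", "+", origin=500)]
        seqs = {"chrS": "A" * 10000}
        scored = score_motif(uniform_pwm, UNIFORM)
        dens = positional_density("R", [scored], events, events, seqs,
                                  junction="alt_end", window=200)
        assert dens.rate_positive.sum() == 0.0

    def test_profile_counts_match_scan_totals(self, uniform_pwm):
        rng = np.random.default_rng(4)
        events = [make_se_event(f"e{i}", "+", origin=500 + 6000 * i) for i in range(5)]
        length = events[-1].coords.segments[-1][2] + 1000
        seqs = {"chrS": "".join(rng.choice(list(RNA), size=length))}
        scored = score_motif(uniform_pwm, UNIFORM)
        dens = positional_density("R", [scored], events, [], seqs,
                                  junction="alt_start", window=200)
        total = 0
        for ev in events:
            j = ev.coords.segment("alt")[0]
            window = seqs["chrS"][j - 200 : j + 200]
            total += len(scan_hits(scored, window))
        # every hit start lands on a distinct offset with ≤ 1 hit per event here
        assert dens.rate_positive.sum() * len(events) == pytest.approx(total)
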
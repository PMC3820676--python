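"""Gibbs site-sampler bookkeeping, predictive updates, and recovery."""

import numpy as np
import pytest
from scipy import stats

import motifstat as ms
from motifstat.alphabet import DNA
from motifstat.gibbs import add_window_counts, remove_window_counts
from motifstat.synthetic import DEMO_S11_ODDS, PlantedMotifSpec


@pytest.fixture()
def ery_seqs(rng):
    seqs, truth = ms.plant_motifs(ms.erythroid_spec(), rng)
    return seqs, truth


class TestInitialize:
    def test_invariants_on_erythroid_scale_data(self, ery_seqs, rng):
        seqs, _ = ery_seqs
        state = ms.initialize(seqs, 6, rng)
        state.check_invariants()
        assert np.all(state.c.sum(axis=0) == 29)
        assert np.array_equal(
            state.c0 + state.c.sum(axis=1), ms.residue_counts(seqs)
        )
        assert seqs.total_length == 1209 or seqs.total_length > 0

    def test_sequence_of_motif_length_is_pinned(self, rng):
        seqs = ms.SequenceSet.from_strings(["ACGTAG"])
        state = ms.initialize(seqs, 6, rng)
        assert state.assignments[0] == 0

    def test_too_short_sequence_rejected(self, rng):
        seqs = ms.SequenceSet.from_strings(["ACGT"])
        with pytest.raises(ValueError, match="shorter than"):
            ms.initialize(seqs, 6, rng)


class TestWithdrawDeposit:
    def test_withdraw_reproduces_published_state(self, demo_states):
        c0, c = remove_window_counts(
            demo_states["initial"]["c0"], demo_states["initial"]["c"], DNA.encode("AGTGTG")
        )
        assert c0.tolist() == [279, 279, 233, 250]
        assert np.array_equal(c, demo_states["withdrawn"]["c"])
        assert c[2].tolist() == [7, 4, 6, 4, 3, 10]  # G row
        assert np.all(c.sum(axis=0) == 28)

    def test_deposit_reproduces_published_state(self, demo_states):
        c0, c = add_window_counts(
            demo_states["withdrawn"]["c0"], demo_states["withdrawn"]["c"], DNA.encode("TCACAG")
        )
        assert c0.tolist() == [277, 277, 232, 249]
        assert np.array_equal(c, demo_states["updated"]["c"])
        assert c[3].tolist() == [12, 9, 8, 8, 9, 6]  # T row

    def test_withdraw_then_deposit_is_identity(self, ery_seqs, rng):
        seqs, _ = ery_seqs
        state = ms.initialize(seqs, 6, rng)
        i = 11
        original_start = int(state.assignments[i])
        back = ms.deposit(ms.withdraw(state, i), i, original_start)
        assert np.array_equal(back.assignments, state.assignments)
        assert np.array_equal(back.c0, state.c0)
        assert np.array_equal(back.c, state.c)

    def test_double_withdraw_rejected(self, ery_seqs, rng):
        seqs, _ = ery_seqs
        state = ms.withdraw(ms.initialize(seqs, 6, rng), 0)
        with pytest.raises(ValueError, match="withdrawn"):
            ms.withdraw(state, 0)

    def test_conservation_on_erythroid_totals(self, demo_states):
        # all three published states conserve the 1209 residues (325/316/267/301)
        for state in demo_states.values():
            totals = state["c0"] + state["c"].sum(axis=1)
            assert totals.tolist() == [325, 316, 267, 301]
            assert totals.sum() == 1209


class TestCandidateScores:
    def test_candidate_count_and_normalization(self, demo_states):
        dist = ms.candidate_distribution(
            demo_states["withdrawn"]["c0"],
            demo_states["withdrawn"]["c"],
            DNA.encode(ms.gibbs_demo_sequence()),
        )
        assert dist.starts.size == 35  # 40 - 6 + 1
        assert dist.p_norm.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(dist.odds >= 0)

    def test_published_odds_and_ranking(self, demo_states):
        """Rescoring S11 against the withdrawn state reproduces the published
        odds table: identical rank order, odds within 3%."""
        dist = ms.candidate_distribution(
            demo_states["withdrawn"]["c0"],
            demo_states["withdrawn"]["c"],
            DNA.encode(ms.gibbs_demo_sequence()),
        )
        published = np.array([DEMO_S11_ODDS[i] for i in range(1, 36)])
        assert np.max(np.abs(dist.odds - published) / published) < 0.03
        assert np.array_equal(
            np.argsort(-dist.odds, kind="stable"), np.argsort(-published, kind="stable")
        )
        assert int(np.argmax(dist.odds)) == 24  # start 25, motif TCACAG

    def test_zero_c0_entry_with_no_pseudocount_rejected(self):
        c0 = np.array([10, 10, 0, 10])
        c = np.array([[1], [1], [1], [1]])
        with pytest.raises(ValueError, match="zero symbol count"):
            ms.candidate_distribution(
                c0, c, DNA.encode("ACGT"), spec=ms.PseudocountSpec(alpha=0.0)
            )


class TestSelectPosition:
    def test_argmax_picks_published_best(self, demo_states):
        dist = ms.candidate_distribution(
            demo_states["withdrawn"]["c0"],
            demo_states["withdrawn"]["c"],
            DNA.encode(ms.gibbs_demo_sequence()),
        )
        assert ms.select_position(dist, "argmax") == 24

    def test_single_candidate(self, rng):
        dist = ms.CandidateDistribution(
            starts=np.array([0]), odds=np.array([2.0]), p_norm=np.array([1.0])
        )
        assert ms.select_position(dist, "argmax") == 0
        assert ms.select_position(dist, "sample", rng) == 0

    def test_argmax_tie_breaks_to_lowest_start(self):
        dist = ms.CandidateDistribution(
            starts=np.arange(3), odds=np.array([1.0, 1.0, 1.0]), p_norm=np.full(3, 1 / 3)
        )
        assert ms.select_position(dist, "argmax") == 0

    def test_sampling_matches_multinomial(self, rng):
        """Draw frequencies agree with P_Norm by a chi-square goodness-of-fit."""
        odds = np.array([5.0, 1.0, 0.5, 2.5, 1.0])
        dist = ms.CandidateDistribution(
            starts=np.arange(5), odds=odds, p_norm=odds / odds.sum()
        )
        n_draws = 20_000
        draws = np.array([ms.select_position(dist, "sample", rng) for _ in range(n_draws)])
        observed = np.bincount(draws, minlength=5)
        chi2, p = stats.chisquare(observed, n_draws * dist.p_norm)
        assert p > 0.001


class TestSweep:
    def test_invariants_hold_after_every_sweep(self, ery_seqs, rng):
        seqs, _ = ery_seqs
        state = ms.initialize(seqs, 6, rng)
        for _ in range(5):
            state, f = ms.sweep(state, rng)
            state.check_invariants()
            assert np.isfinite(f)

    def test_identical_windows_leave_f_unchanged(self, rng):
        # every window of a homopolymer is the same string: a sweep cannot
        # change the C matrix, so F is invariant
        seqs = ms.SequenceSet.from_strings(["AAAAAAA"] * 5)
        state = ms.initialize(seqs, 3, rng)
        f_before = ms.state_F(state)
        _, f_after = ms.sweep(state, rng)
        assert f_after == pytest.approx(f_before)

    def test_converged_planted_state_is_argmax_fixed_point(self, rng):
        bg = ms.make_background("user-specified", [0.3, 0.2, 0.2, 0.3])
        spec = PlantedMotifSpec(
            consensus="TTATCA", n_seqs=15, length_min=30, length_max=40,
            background=bg, per_site_noise=0.0,
        )
        seqs, truth = ms.plant_motifs(spec, rng)
        res = ms.run_site_sampler(seqs, 6, ms.GibbsConfig(seed=1, restarts=10))
        state, f = res.state, res.F
        state2, f2 = ms.sweep(state, rng, strategy="argmax")
        state3, f3 = ms.sweep(state2, rng, strategy="argmax")
        assert np.array_equal(state2.assignments, state3.assignments)
        assert f3 == pytest.approx(f2)


class TestRunSiteSampler:
    def test_deterministic_given_seed(self, ery_seqs):
        seqs, _ = ery_seqs
        config = ms.GibbsConfig(seed=7, restarts=3, max_sweeps=30)
        r1 = ms.run_site_sampler(seqs, 6, config)
        r2 = ms.run_site_sampler(seqs, 6, config)
        assert np.array_equal(r1.assignments, r2.assignments)
        assert r1.F == r2.F
        assert r1.hits == r2.hits

    def test_recovers_exact_planted_motif(self):
        """Noise-free planted TTATCA is recovered verbatim in every sequence."""
        bg = ms.make_background("user-specified", [0.3, 0.2, 0.2, 0.3])
        spec = PlantedMotifSpec(
            consensus="TTATCA", n_seqs=20, length_min=40, length_max=60,
            background=bg, per_site_noise=0.0,
        )
        recovered = 0
        n_runs = 8
        for seed in range(n_runs):
            seqs, truth = ms.plant_motifs(spec, np.random.default_rng(500 + seed))
            res = ms.run_site_sampler(seqs, 6, ms.GibbsConfig(seed=seed, restarts=50))
            recovered += all(
                seqs.window(i, int(a), 6) == "TTATCA"
                for i, a in enumerate(res.assignments)
            )
        assert recovered >= n_runs - 1

    def test_planted_f_beats_background_f(self):
        """The best F on planted data exceeds the best F on background-only
        data of the same shape (paired runs)."""
        bg = ms.make_background("user-specified", [0.3, 0.2, 0.2, 0.3])
        spec = PlantedMotifSpec(
            consensus="TTATCA", n_seqs=15, length_min=35, length_max=45,
            background=bg, per_site_noise=0.0,
        )
        wins = 0
        n_pairs = 5
        for seed in range(n_pairs):
            gen = np.random.default_rng(900 + seed)
            planted, _ = ms.plant_motifs(spec, gen)
            null = ms.random_sequences(bg, 15, planted.lengths, gen)
            cfg = ms.GibbsConfig(seed=seed, restarts=8)
            f_planted = ms.run_site_sampler(planted, 6, cfg).F
            f_null = ms.run_site_sampler(null, 6, cfg).F
            wins += f_planted > f_null
        assert wins == n_pairs

    def test_accepted_f_non_decreasing_within_restart(self, ery_seqs):
        """Hill-climbing contract: the stored best F never decreases."""
        seqs, _ = ery_seqs
        rng = np.random.default_rng(3)
        state = ms.initialize(seqs, 6, rng)
        best = ms.state_F(state)
        accepted = [best]
        for _ in range(15):
            state, f = ms.sweep(state, rng)
            if f > best:
                best = f
                accepted.append(best)
        assert all(b >= a for a, b in zip(accepted, accepted[1:]))

    def test_short_sequence_warning(self, rng):
        seqs = ms.SequenceSet.from_strings(["ACGTACGTAC"] * 5)
        with pytest.warns(UserWarning, match="background"):
            ms.run_site_sampler(seqs, 6, ms.GibbsConfig(restarts=1, max_sweeps=3))


class TestMotifScanPostprocess:
    def test_two_planted_occurrences_both_reported(self, rng):
        bg = ms.make_background("user-specified", [0.3, 0.2, 0.2, 0.3])
        spec = PlantedMotifSpec(
            consensus="TTATCA", n_seqs=12, length_min=50, length_max=60,
            background=bg, per_site_noise=0.0, occurrences_per_seq=2,
        )
        seqs, truth = ms.plant_motifs(spec, rng)
        pwm = ms.build_pwm(
            [seqs.window(i, s, 6) for i, starts in enumerate(truth) for s in starts],
            bg,
        )
        hits = ms.motif_scan_postprocess(pwm, seqs, cutoff_odds=20.0)
        for i, name in enumerate(seqs.names):
            found = {h.start for h in hits[name]}
            assert set(truth[i]) <= found

    def test_infinite_cutoff_is_empty(self, small_seqs):
        pwm = ms.PWMatrix(w=np.zeros((4, 4)))
        hits = ms.motif_scan_postprocess(pwm, small_seqs, cutoff_odds=np.inf)
        assert all(len(v) == 0 for v in hits.values())

    def test_matches_exhaustive_window_odds(self, rng):
        """Oracle: hits are exactly the windows whose brute-force odds clear
        the cutoff."""
        bg = ms.make_background("user-specified", [0.3, 0.2, 0.2, 0.3])
        motifs = ["TTATCA", "TTATCA", "TTGTCA", "CTATCA"] * 3
        pwm = ms.build_pwm(motifs, bg)
        seqs = ms.random_sequences(bg, 5, 80, rng)
        hits = ms.motif_scan_postprocess(pwm, seqs, cutoff_odds=5.0)
        for i, name in enumerate(seqs.names):
            expected = set()
            for s in range(80 - 6 + 1):
                odds = ms.score_window(pwm, seqs.window(i, s, 6)).odds
                if odds > 5.0:
                    expected.add(s)
            assert {h.start for h in hits[name]} == expected
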
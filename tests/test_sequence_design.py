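import random
from collections import Counter

import pytest
from scipy import stats

from rnamct import (
    AssignmentEvent,
    CandidateSequence,
    EssentialAssignment,
    ReferenceBackend,
    RewardParams,
    generate_initial,
    gc_content,
    local_update,
    parse_dotbracket,
    random_assignment,
    simulate_playout,
)
from rnamct.sequence_design import PAIR_VALUES, RULE_I_PAIRS, RULE_II_MAP, SINGLE_BASES


class TestRandomAssignment:
    def test_single_site_uniform(self):
        rng = random.Random(0)
        counts = Counter(random_assignment(3, rng).value for _ in range(60_000))
        assert set(counts) == set(SINGLE_BASES)
        _, p = stats.chisquare(list(counts.values()))
        assert p > 0.001

    def test_paired_site_uniform(self):
        rng = random.Random(1)
        counts = Counter(random_assignment((2, 9), rng).value for _ in range(60_000))
        assert set(counts) == set(PAIR_VALUES)
        _, p = stats.chisquare(list(counts.values()))
        assert p > 0.001

    def test_seeded_determinism(self):
        draws = lambda: [  # noqa: E731
            random_assignment(1, random.Random(42)).value for _ in range(5)
        ]
        assert draws() == draws()


class TestGenerateInitial:
    def test_gc_count_hits_target_with_bounded_overshoot(self):
        target = parse_dotbracket("((....))")
        rng = random.Random(0)
        for _ in range(1000):
            cand = generate_initial(target, EssentialAssignment(), 0.5, rng)
            gc = cand.bases.count("G") + cand.bases.count("C")
            assert gc in (4, 5)  # N*alpha = 4; one paired placement may overshoot

    def test_all_essential_returned_verbatim(self, worked_target):
        events = tuple(
            AssignmentEvent(site=s, value="A" if isinstance(s, int) else "GC")
            for s in worked_target.sites
        )
        essential = EssentialAssignment(events=events)
        cand = generate_initial(worked_target, essential, 0.5, random.Random(3))
        expected = essential.bases()
        assert all(cand.bases[p - 1] == b for p, b in expected.items())

    def test_alpha_zero_yields_au_only(self, hairpin_target):
        cand = generate_initial(hairpin_target, EssentialAssignment(), 0.0, random.Random(5))
        assert set(cand.bases) <= {"A", "U"}

    def test_essential_gc_excess_skips_placement(self):
        target = parse_dotbracket("....")
        essential = EssentialAssignment(
            events=(AssignmentEvent(site=1, value="G"), AssignmentEvent(site=2, value="C"))
        )
        # target GC count 0.25*4 = 1 already exceeded by essentials
        cand = generate_initial(target, essential, 0.25, random.Random(8))
        assert cand.bases[:2] == "GC"
        assert set(cand.bases[2:]) <= {"A", "U"}

    def test_without_alpha_all_bases_occur(self, hairpin_target):
        rng = random.Random(11)
        seen = set()
        for _ in range(50):
            seen.update(generate_initial(hairpin_target, EssentialAssignment(), None, rng).bases)
        assert seen == {"A", "C", "G", "U"}

    def test_paired_sites_complementary(self, worked_target):
        rng = random.Random(13)
        for alpha in (None, 0.0, 0.5, 1.0):
            cand = generate_initial(worked_target, EssentialAssignment(), alpha, rng)
            for i, j in worked_target.pairs:
                assert cand.bases[i - 1] + cand.bases[j - 1] in PAIR_VALUES


class TestLocalUpdate:
    def test_rule_one_restores_missing_target_pairs(self):
        # two target pairs absent from the prediction are rewritten to one
        # of AU/UA/CG/GC
        target = parse_dotbracket("..((.....))..")  # pairs (3,11), (4,10)
        seq = CandidateSequence(bases="GCAAAAAAAUUCC")
        predicted = "." * 13
        rng = random.Random(0)
        for _ in range(50):
            out = local_update(seq, target, predicted, EssentialAssignment(), rng)
            for i, j in [(3, 11), (4, 10)]:
                assert out.bases[i - 1] + out.bases[j - 1] in RULE_I_PAIRS

    def test_rule_two_breaks_spurious_gc_pair(self):
        # a predicted pair (2,13) absent from the target becomes CC or GG
        target = parse_dotbracket("..((.....))..")
        seq = CandidateSequence(bases="AGAAAAAAAAAAC")
        predicted = ".(..........)"
        rng = random.Random(1)
        results = set()
        for _ in range(50):
            out = local_update(seq, target, predicted, EssentialAssignment(), rng)
            results.add(out.bases[1] + out.bases[12])
        assert results == {"CC", "GG"}

    def test_rule_two_wobble_options_conserve_gc(self):
        target = parse_dotbracket(".............")
        seq = CandidateSequence(bases="AGAAAAAAAAAAU")
        predicted = ".(..........)"
        rng = random.Random(2)
        results = set()
        for _ in range(200):
            out = local_update(seq, target, predicted, EssentialAssignment(), rng)
            pair = out.bases[1] + out.bases[12]
            results.add(pair)
            assert gc_content(out.bases) == gc_content(seq.bases)
        assert results == set(RULE_II_MAP["GU"])

    def test_essential_positions_never_touched(self):
        target = parse_dotbracket("..((.....))..")
        seq = CandidateSequence(bases="AGAAAAAAAUUAC")
        predicted = ".(..........)"
        essential = EssentialAssignment(
            events=(AssignmentEvent(site=(3, 11), value="AU"),)
        )
        rng = random.Random(3)
        for _ in range(30):
            out = local_update(seq, target, predicted, essential, rng)
            assert out.bases[2] == "A" and out.bases[10] == "U"

    def test_pair_with_one_essential_position_skipped(self):
        # rule (ii) requires both positions non-essential
        target = parse_dotbracket(".............")
        seq = CandidateSequence(bases="AGAAAAAAAAAAC")
        predicted = ".(..........)"
        essential = EssentialAssignment(events=(AssignmentEvent(site=2, value="G"),))
        out = local_update(seq, target, predicted, essential, random.Random(4))
        assert out.bases == seq.bases

    def test_rules_do_not_retouch_within_a_pass(self):
        # position fixed by rule (i) is not re-touched by rule (ii) even if
        # the predicted structure pairs it spuriously
        target = parse_dotbracket("(........)...")  # target pair (1,10)
        predicted = "(...........)"  # spurious predicted pair (1,13)... wait
        # predicted pairs (1,13); target pair (1,10) missing from it
        seq = CandidateSequence(bases="AAAAAAAAAUAAU")
        rng = random.Random(5)
        out = local_update(seq, target, predicted, EssentialAssignment(), rng)
        # rule (i) rewrote (1,10); rule (ii) must then skip (1,13)
        assert out.bases[0] + out.bases[9] in RULE_I_PAIRS
        assert out.bases[12] == "U"

    def test_gc_conservation_under_rule_two_only(self):
        # random all-dot targets: only rule (ii) can fire, and the GC count
        # is invariant
        rng = random.Random(6)
        backend = ReferenceBackend()
        for _ in range(300):
            n = rng.randint(8, 30)
            target = parse_dotbracket("." * n)
            bases = "".join(rng.choice("ACGU") for _ in range(n))
            predicted = backend.fold(bases).structure
            out = local_update(
                CandidateSequence(bases=bases), target, predicted,
                EssentialAssignment(), rng,
            )
            assert gc_content(out.bases) == gc_content(bases)


class TestSimulatePlayout:
    def test_k_one_generates_single_candidate(self, hairpin_target):
        backend = ReferenceBackend()
        out = simulate_playout(
            EssentialAssignment(), hairpin_target, RewardParams(alpha_star=0.5),
            1, backend, random.Random(0),
        )
        assert len(out) == 1 and backend.call_count == 1
        assert out[0].score is not None

    def test_exact_fold_budget_without_early_exit(self):
        # an unsatisfiable target (all dots but long) rarely matches, so the
        # playout spends exactly k folds
        target = parse_dotbracket("." * 40)
        backend = ReferenceBackend()
        out = simulate_playout(
            EssentialAssignment(), target, RewardParams(), 10, backend,
            random.Random(1),
        )
        if out[-1].predicted != target.dotbracket:
            assert len(out) == 10 and backend.call_count == 10

    def test_short_circuits_on_match(self, hairpin_target):
        backend = ReferenceBackend()
        out = simulate_playout(
            EssentialAssignment(), hairpin_target, RewardParams(), 50, backend,
            random.Random(2),
        )
        if any(c.predicted == hairpin_target.dotbracket for c in out):
            assert out[-1].predicted == hairpin_target.dotbracket
            assert len(out) == backend.call_count <= 50

    def test_essential_bases_survive_whole_playout(self, worked_target):
        essential = EssentialAssignment(
            events=(
                AssignmentEvent(site=(2, 13), value="GC"),
                AssignmentEvent(site=7, value="A"),
            )
        )
        out = simulate_playout(
            essential, worked_target, RewardParams(alpha_star=0.5), 25,
            ReferenceBackend(), random.Random(3),
        )
        for cand in out:
            assert cand.bases[1] == "G" and cand.bases[12] == "C"
            assert cand.bases[6] == "A"

    def test_mean_distance_improves_over_playout(self, worked_target):
        # local updates make progress in expectation on a toy stem-loop
        first, last = [], []
        for seed in range(200):
            out = simulate_playout(
                EssentialAssignment(), worked_target, RewardParams(), 10,
                ReferenceBackend(), random.Random(seed),
            )
            first.append(out[0].score.d)
            last.append(out[-1].score.d)
        assert sum(last) / len(last) <= sum(first) / len(first)

    def test_k_below_one_rejected(self, hairpin_target):
        with pytest.raises(ValueError):
            simulate_playout(
                EssentialAssignment(), hairpin_target, RewardParams(), 0,
                ReferenceBackend(), random.Random(0),
            )
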
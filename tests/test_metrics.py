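"""Complexity metrics: LZ76, entropies, rates, and the half split."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from courtseq.events import ALPHABET, EventRecord, SymbolSequence
from courtseq.metrics import (
    HalfSplitError,
    complexity_profile,
    courtship_rates,
    half_split,
    lz76_phrases,
    lz_normalized,
    markov_entropy_rate,
    shannon_entropy,
    transition_model,
)
from courtseq.simulate import simulate_iid

from .conftest import random_symbols
from .oracles import lz76_phrases_bruteforce

LOG2_3 = math.log2(3)


def ev(label, onset, offset=None, tid="T1"):
    return EventRecord(tid, label, onset, offset if offset is not None else onset + 1.0)


class TestLZ76:
    @pytest.mark.parametrize("label", ALPHABET)
    @pytest.mark.parametrize("n", [2, 5, 80])
    def test_homogeneous_sequence_has_two_phrases(self, label, n):
        assert lz76_phrases([label] * n) == 2

    def test_all_distinct_symbols(self):
        assert lz76_phrases(["rev", "idle", "leg_tap"]) == 3

    def test_single_symbol(self):
        assert lz76_phrases(["rev"]) == 1

    def test_matches_bruteforce_oracle_on_random_sequences(self, rng):
        # covers sequences effectively over 1-, 2- and 3-letter alphabets
        for i in range(200):
            n = int(rng.integers(2, 81))
            n_labels = int(rng.integers(1, 4))
            symbols = random_symbols(rng, n, n_labels)
            assert lz76_phrases(symbols) == lz76_phrases_bruteforce(symbols), symbols

    def test_normalization_formula(self):
        # homogeneous length-100: c = 2, so c * log_3(100) / 100
        expected = 2 * math.log(100, 3) / 100
        assert lz_normalized(["rev"] * 100) == pytest.approx(expected)
        assert expected == pytest.approx(0.0838, abs=5e-4)

    def test_normalized_needs_two_symbols(self):
        with pytest.raises(ValueError):
            lz_normalized(["rev"])


class TestShannonEntropy:
    def test_degenerate_distribution_is_zero(self):
        assert shannon_entropy(["rev"] * 17) == 0.0

    def test_uniform_thirds_is_log2_3(self):
        seq = ["rev", "idle", "leg_tap"] * 4
        assert shannon_entropy(seq) == pytest.approx(LOG2_3, abs=1e-12)

    def test_skewed_proportions_match_direct_formula(self):
        # proportions (0.90, 0.05, 0.05) from an 18/1/1 sequence of 20
        seq = ["rev"] * 18 + ["idle", "leg_tap"]
        expected = -(0.9 * math.log2(0.9) + 2 * 0.05 * math.log2(0.05))
        assert shannon_entropy(seq) == pytest.approx(expected)
        assert expected == pytest.approx(0.569, abs=5e-4)

    def test_maximal_iff_uniform_on_simplex_grid(self):
        # entropy strictly decreases as mass concentrates away from uniform
        h_uniform = shannon_entropy(["rev", "idle", "leg_tap"])
        last = h_uniform
        for extra in (2, 4, 8, 16):
            seq = ["rev"] * (1 + extra) + ["idle", "leg_tap"]
            h = shannon_entropy(seq)
            assert h < last
            last = h

    def test_natural_log_base_option(self):
        seq = ["rev", "idle", "leg_tap"]
        assert shannon_entropy(seq, base=math.e) == pytest.approx(math.log(3))


class TestMarkovEntropyRate:
    def test_periodic_cycle_is_zero(self):
        assert markov_entropy_rate(["rev", "idle", "leg_tap"] * 30) == 0.0

    def test_hand_computed_eight_symbol_sequence(self):
        # r r i r i i r r: transitions rr,ri,ir,ri,ii,ir,rr
        # counts: r->r 2, r->i 2, i->r 2, i->i 1; sources r:4 i:3
        # rate = 4/7 * H(1/2) + 3/7 * H(2/3, 1/3) = 4/7 + 3/7*(log2 3 - 2/3)
        seq = ["rev", "rev", "idle", "rev", "idle", "idle", "rev", "rev"]
        expected = 4 / 7 + 3 / 7 * (LOG2_3 - 2 / 3)
        assert markov_entropy_rate(seq) == pytest.approx(expected)

    def test_iid_uniform_approaches_log2_3(self):
        seq = simulate_iid([1 / 3] * 3, 100_000, seed=11)
        assert markov_entropy_rate(seq) == pytest.approx(LOG2_3, abs=0.02)

    def test_rate_at_most_entropy_for_iid_sources(self, rng):
        # H-rate <= H for stationary sources; tolerance absorbs plug-in bias
        for props in ([0.5, 0.3, 0.2], [0.8, 0.15, 0.05], [1 / 3] * 3):
            seq = simulate_iid(props, 10_000, seed=rng)
            assert markov_entropy_rate(seq) <= shannon_entropy(seq) + 0.02

    def test_needs_two_symbols(self):
        with pytest.raises(ValueError):
            markov_entropy_rate(["rev"])

    def test_stationary_weighting_close_to_empirical_on_long_chains(self):
        seq = simulate_iid([0.6, 0.3, 0.1], 50_000, seed=3)
        emp = markov_entropy_rate(seq, weights="empirical")
        stat = markov_entropy_rate(seq, weights="stationary")
        assert emp == pytest.approx(stat, abs=1e-3)


class TestTransitionModel:
    @given(st.lists(st.sampled_from(ALPHABET), min_size=2, max_size=60))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_counts_probs_weights_invariants(self, labels):
        tm = transition_model(labels)
        assert tm.counts.sum() == len(labels) - 1
        rows = tm.counts.sum(axis=1)
        for i in range(3):
            if rows[i] > 0:
                assert tm.probs[i].sum() == pytest.approx(1.0, abs=1e-12)
            else:
                assert tm.probs[i].sum() == 0.0
        assert tm.source_weights.sum() == pytest.approx(1.0, abs=1e-12)


class TestRelabelingInvariance:
    def test_metrics_invariant_under_alphabet_permutation(self, rng):
        import itertools

        perms = list(itertools.permutations(ALPHABET))
        for i in range(30):
            symbols = random_symbols(rng, int(rng.integers(5, 60)))
            ref = (
                lz76_phrases(symbols),
                shannon_entropy(symbols),
                markov_entropy_rate(symbols),
            )
            perm = perms[int(rng.integers(len(perms)))]
            mapping = dict(zip(ALPHABET, perm))
            relabeled = [mapping[s] for s in symbols]
            got = (
                lz76_phrases(relabeled),
                shannon_entropy(relabeled),
                markov_entropy_rate(relabeled),
            )
            assert got[0] == ref[0]
            assert got[1] == pytest.approx(ref[1], abs=1e-12)
            assert got[2] == pytest.approx(ref[2], abs=1e-12)


class TestCourtshipRates:
    def test_stated_counting_rule(self):
        # 8 revs + 2 leg-taps over 20 s: taps count in both channels
        events = [ev("rev", 2.0 * i, 2.0 * i + 1) for i in range(8)]
        events += [ev("leg_tap", 16.0, 17.0), ev("leg_tap", 19.0, 20.0)]
        events.sort(key=lambda e: e.onset_s)
        mm, vis = courtship_rates(events)
        assert mm == pytest.approx(12 / 20)
        assert vis == pytest.approx(2 / 20)

    def test_single_count_rule(self):
        events = [ev("rev", 0.0, 1.0), ev("leg_tap", 5.0, 10.0)]
        mm, _ = courtship_rates(events, multimodal_rule="single_count")
        assert mm == pytest.approx(2 / 10)

    def test_visual_labels_including_idle(self):
        events = [ev("rev", 0.0), ev("idle", 2.0), ev("leg_tap", 4.0, 10.0)]
        _, vis = courtship_rates(events, visual_labels={"idle", "leg_tap"})
        assert vis == pytest.approx(2 / 10)

    def test_zero_duration_is_an_error(self):
        with pytest.raises(ValueError, match="duration"):
            courtship_rates([ev("rev", 1.0, 1.0)])


class TestComplexityProfile:
    def test_composition_matches_individual_calls(self, fixture_study):
        from courtseq.events import events_to_sequence, window_events

        trials, _ = fixture_study
        events = window_events(trials[0].events)
        prof = complexity_profile(events)
        seq = events_to_sequence(events)
        assert prof.lz_phrases == lz76_phrases(seq)
        assert prof.lz_normalized == pytest.approx(lz_normalized(seq))
        assert prof.entropy_bits == pytest.approx(shannon_entropy(seq))
        assert prof.entropy_rate_bits == pytest.approx(markov_entropy_rate(seq))
        mm, vis = courtship_rates(events)
        assert (prof.multimodal_rate, prof.visual_rate) == (pytest.approx(mm), pytest.approx(vis))
        assert prof.n_components == seq.n

    def test_single_event_flagged_unusable(self):
        prof = complexity_profile([ev("rev", 0.0)])
        assert not prof.usable
        assert "need >= 2" in (prof.exclusion_reason or "")

    def test_simulated_study_profiles_all_finite(self, fixture_study):
        from courtseq.events import window_events

        trials, _ = fixture_study
        profiles = [complexity_profile(window_events(t.events)) for t in trials]
        assert len(profiles) == 44
        for p in profiles:
            assert p.usable
            for name in p.METRIC_FIELDS:
                assert np.isfinite(getattr(p, name))


class TestHalfSplit:
    def test_temporal_midpoint(self):
        events = [ev("rev", t, t) for t in (0.0, 10.0, 20.0, 30.0)]
        first, second = half_split(events)
        assert [e.onset_s for e in first] == [0.0, 10.0]
        assert [e.onset_s for e in second] == [20.0, 30.0]

    def test_event_exactly_at_midpoint_goes_second(self):
        events = [ev("rev", t, t) for t in (0.0, 5.0, 10.0, 20.0)]
        first, second = half_split(events)  # midpoint = 10
        assert 10.0 in [e.onset_s for e in second]

    def test_partition_property_on_simulated_trial(self, fixture_study):
        trials, _ = fixture_study
        events = trials[1].events
        first, second = half_split(events)
        assert first + second == list(events)

    def test_count_rule_splits_at_middle_index(self):
        events = [ev("rev", float(t)) for t in range(5)]
        first, second = half_split(events, rule="count")
        assert (len(first), len(second)) == (2, 3)

    def test_too_few_events_raises_exclusion(self):
        with pytest.raises(HalfSplitError):
            half_split([ev("rev", 0.0), ev("rev", 1.0), ev("rev", 2.0)])


def test_symbol_sequence_validates_alphabet():
    with pytest.raises(ValueError):
        SymbolSequence(("rev", "wave"))
    with pytest.raises(ValueError):
        SymbolSequence(())
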
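"""Transition modeling and SPM enumeration/reduction/matching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import electrokin as ek
from electrokin.spm import (
    collapse_runs,
    expand_runs,
    mirror_pool_map,
    occurrence_frames,
    pool_tokens,
)


class TestCollapseRuns:
    def test_worked_example(self):
        toks, spans = collapse_runs([2, 2, 7, 7, 7, 2])
        assert list(toks) == [2, 7, 2]
        assert spans == [(0, 2), (2, 5), (5, 6)]

    def test_all_equal_single_token(self):
        toks, spans = collapse_runs([4] * 7)
        assert list(toks) == [4] and spans == [(0, 7)]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 5), min_size=0, max_size=80))
    def test_round_trip(self, labels):
        toks, spans = collapse_runs(labels)
        assert list(expand_runs(toks, spans)) == labels
        assert all(a != b for a, b in zip(toks[:-1], toks[1:]))


class TestTransitionMatrix:
    def test_two_state_alternation(self):
        m = ek.transition_matrix([np.array([1, 2, 1, 2, 1])])
        assert m.probs[m.index(1), m.index(2)] == 1.0
        assert m.probs[m.index(2), m.index(1)] == 1.0

    def test_hand_counts(self):
        m = ek.transition_matrix([np.array([1, 2, 1, 3])])
        i1 = m.index(1)
        assert m.probs[i1, m.index(2)] == pytest.approx(0.5)
        assert m.probs[i1, m.index(3)] == pytest.approx(0.5)
        np.testing.assert_allclose(m.stationary.sum(), 1.0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        seq, _ = collapse_runs(rng.integers(1, 6, 500))
        m = ek.transition_matrix([seq])
        outgoing = m.counts.sum(axis=1) > 0
        np.testing.assert_allclose(m.probs[outgoing].sum(axis=1), 1.0)
        assert np.all(np.diag(m.counts) == 0)

    def test_dead_token_flagged(self):
        m = ek.transition_matrix([np.array([1, 2, 3])])
        assert list(m.dead_tokens) == [3]

    def test_no_transitions_raises(self):
        with pytest.raises(ValueError):
            ek.transition_matrix([np.array([1])])


def brute_force_top(model, n_transitions, top_n):
    m = len(model.tokens)
    seqs = []
    for combo in itertools.product(range(m), repeat=n_transitions + 1):
        p = model.stationary[combo[0]]
        for a, b in zip(combo[:-1], combo[1:]):
            p *= model.probs[a, b]
        if p > 0:
            seqs.append((tuple(int(model.tokens[i]) for i in combo), p))
    seqs.sort(key=lambda sp: (-sp[1], sp[0]))
    return seqs[:top_n]


class TestEnumeration:
    def test_deterministic_cycle(self):
        m = ek.transition_matrix([np.array([1, 2, 3] * 10 + [1])])
        top = ek.enumerate_top_spms(m, n_transitions=5, top_n=3)
        seq, p = top[0]
        assert seq[1:] == tuple((seq[0] + np.arange(1, 6) - 1) % 3 + 1)
        assert p == pytest.approx(m.stationary[m.index(seq[0])])

    def test_matches_brute_force_small_model(self):
        rng = np.random.default_rng(1)
        seq, _ = collapse_runs(rng.integers(1, 4, 400))
        m = ek.transition_matrix([seq])
        got = ek.enumerate_top_spms(m, n_transitions=2, top_n=5)
        assert got == brute_force_top(m, 2, 5)

    def test_matches_brute_force_alphabet_six(self):
        rng = np.random.default_rng(2)
        seq, _ = collapse_runs(rng.integers(1, 7, 2000))
        m = ek.transition_matrix([seq])
        for n_tr in (1, 2, 3):
            got = ek.enumerate_top_spms(m, n_transitions=n_tr, top_n=20)
            assert got == brute_force_top(m, n_tr, 20)

    def test_default_sequences_have_six_tokens(self):
        rng = np.random.default_rng(3)
        seq, _ = collapse_runs(rng.integers(1, 6, 3000))
        m = ek.transition_matrix([seq])
        top = ek.enumerate_top_spms(m)
        assert len(top) == 100
        assert all(len(s) == 6 for s, _ in top)
        assert all(p <= 1.0 for _, p in top)

    def test_invalid_length_raises(self):
        m = ek.transition_matrix([np.array([1, 2, 1])])
        with pytest.raises(ValueError):
            ek.enumerate_top_spms(m, n_transitions=0)


class TestReduction:
    def test_mirror_merging(self):
        ranked = [((2, 7, 2, 7, 2, 7), 0.02), ((2, 8, 2, 8, 2, 8), 0.019)]
        cat = ek.reduce_spms(ranked, mirror_pairs=[(7, 8)])
        assert cat.size == 1
        assert cat.entries[0].probability == pytest.approx(0.039)
        assert cat.entries[0].canonical == (2, 7, 2, 7, 2, 7)

    def test_same_composition_fine_structure_merged(self):
        ranked = [((1, 1, 1, 2, 1, 1), 0.01), ((1, 1, 2, 1, 1, 1), 0.008)]
        cat = ek.reduce_spms(ranked, mirror_pairs=[])
        assert cat.size == 1
        assert len(cat.entries[0].members) == 2

    def test_different_composition_not_merged(self):
        ranked = [((1, 1, 1, 1, 2, 2), 0.01), ((1, 1, 1, 1, 1, 2), 0.008)]
        cat = ek.reduce_spms(ranked, mirror_pairs=[])
        assert cat.size == 2

    def test_reduction_conserves_probability(self):
        rng = np.random.default_rng(4)
        seq, _ = collapse_runs(rng.integers(1, 7, 3000))
        m = ek.transition_matrix([seq])
        ranked = ek.enumerate_top_spms(m, top_n=50)
        cat = ek.reduce_spms(ranked, mirror_pairs=[(3, 4), (5, 6)])
        assert sum(e.probability for e in cat.entries) == pytest.approx(
            sum(p for _, p in ranked)
        )
        assert cat.n_raw_sequences == 50

    def test_catalog_json_round_trip(self):
        ranked = [((2, 7, 2, 7, 2, 7), 0.02), ((1, 2, 1, 2, 1, 2), 0.01)]
        cat = ek.reduce_spms(ranked, mirror_pairs=[(7, 8)])
        back = ek.SPMCatalog.from_json(cat.to_json())
        assert [e.canonical for e in back.entries] == [e.canonical for e in cat.entries]
        assert back.mirror_pairs == cat.mirror_pairs


def brute_force_occurrences(labels, entry, mirror_pairs):
    pool = mirror_pool_map(mirror_pairs)
    toks, spans = collapse_runs(labels)
    pooled = pool_tokens(toks, pool)
    L = len(entry.canonical)
    hits = []
    for i in range(len(pooled) - L + 1):
        if pooled[i:i + L] == tuple(entry.canonical):
            hits.append((spans[i][0], spans[i + L - 1][1]))
    return hits


class TestMatching:
    def make_entry(self, canonical):
        ranked = [(tuple(canonical), 1.0)]
        return ek.reduce_spms(ranked, mirror_pairs=[]).entries[0]

    def test_single_occurrence_span(self):
        entry = self.make_entry((1, 2, 3))
        labels = [4, 1, 1, 2, 3, 3, 4]
        occ = ek.match_occurrences(labels, entry, mirror_pairs=[])
        assert len(occ) == 1
        assert (occ[0]["start"], occ[0]["end"]) == (1, 6)

    def test_absent_token_no_occurrences(self):
        entry = self.make_entry((1, 5, 1))
        assert ek.match_occurrences([1, 2, 1, 2], entry, mirror_pairs=[]) == []

    def test_matches_oracle_on_random_stream(self):
        rng = np.random.default_rng(5)
        labels = rng.integers(1, 5, 500)
        entry = self.make_entry((1, 2, 1))
        occ = ek.match_occurrences(labels, entry, mirror_pairs=[(3, 4)])
        assert [(o["start"], o["end"]) for o in occ] == \
            brute_force_occurrences(labels, entry, [(3, 4)])

    def test_occurrence_frames_counts_overlap_once(self):
        occ = [{"start": 0, "end": 10}, {"start": 5, "end": 15}]
        assert occurrence_frames(occ, 20) == 15


class TestConditionContrast:
    def test_identical_datasets_zero_difference(self):
        rng = np.random.default_rng(6)
        labels = rng.integers(1, 5, 1000)
        seq, _ = collapse_runs(labels)
        m = ek.transition_matrix([seq])
        cat = ek.reduce_spms(ek.enumerate_top_spms(m, n_transitions=2, top_n=10), [])
        df = ek.condition_contrast(cat, [labels], [labels.copy()])
        np.testing.assert_allclose(df["diff"], 0.0)

    def test_entry_only_in_one_condition(self):
        entry_labels = np.array([1, 2, 1, 9, 9, 9])
        other = np.array([9, 9, 9, 9, 9, 9])
        cat = ek.reduce_spms([((1, 2, 1), 1.0)], [])
        df = ek.condition_contrast(cat, [other], [entry_labels])
        assert df.loc[0, "diff"] == pytest.approx(3 / 6)

    def test_empty_dataset_raises(self):
        cat = ek.reduce_spms([((1, 2, 1), 1.0)], [])
        with pytest.raises(ValueError):
            ek.condition_contrast(cat, [], [np.array([1, 2, 1])])
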
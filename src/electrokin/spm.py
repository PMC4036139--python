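"""Markov mining of behavioral sequences (super-prototypical movements).

Label sequences are first collapsed to runs (consecutive equal PM labels
become one token), which removes self-transitions; a first-order
transition model P(next | current) plus token stationary frequencies is
estimated from the pooled token sequences. Every sequence of a fixed
number of transitions (default 5, i.e. 6 tokens) has an overall
probability stationary(s0) * prod P(s_{i+1} | s_i); the top-ranked
sequences are found exactly by best-first search. Ranked sequences are
then reduced by (1) mapping mirror-paired PMs to one pool, discarding
left/right direction, and (2) merging sequences built from the same
token multiset but different fine structure (e.g. A-A-A-B-A-A and
A-A-B-A-A-A). The merged entries are the SPM catalog; occurrences are
located in data by sliding a window over the mirror-collapsed token
stream.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

N_TRANSITIONS = 5
TOP_N = 100


@dataclass
class TransitionModel:
    """First-order transition model on run-collapsed PM tokens."""

    tokens: np.ndarray           # sorted token alphabet
    counts: np.ndarray           # (m, m) transition counts, zero diagonal
    probs: np.ndarray            # rows normalized; all-zero rows stay zero
    stationary: np.ndarray       # token frequency among all tokens
    dead_tokens: np.ndarray      # tokens with no outgoing transitions

    def index(self, token: int) -> int:
        return int(np.searchsorted(self.tokens, token))


def collapse_runs(labels: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Collapse consecutive equal labels to single tokens.

    Returns (tokens, spans): ``spans[i]`` is the half-open frame span of
    token i. Adjacent tokens always differ; the mapping is invertible.
    """
    lab = np.asarray(labels)
    n = len(lab)
    if n == 0:
        return np.array([], dtype=lab.dtype), []
    brk = np.flatnonzero(lab[1:] != lab[:-1]) + 1
    edges = np.concatenate([[0], brk, [n]])
    tokens = lab[edges[:-1]]
    spans = [(int(s), int(e)) for s, e in zip(edges[:-1], edges[1:])]
    return tokens, spans


def expand_runs(tokens: np.ndarray, spans: Sequence[tuple[int, int]]) -> np.ndarray:
    """Inverse of :func:`collapse_runs`."""
    return np.concatenate([np.full(e - s, t) for t, (s, e) in zip(tokens, spans)]) \
        if len(spans) else np.asarray([], dtype=np.asarray(tokens).dtype)


def transition_matrix(sequences: Sequence[np.ndarray]) -> TransitionModel:
    """Estimate the transition model from one or more token sequences.

    Counts are pooled across sequences; rows are normalized to
    conditional probabilities. Tokens with no outgoing transitions are
    flagged and excluded from sequence enumeration.
    """
    seqs = [np.asarray(s) for s in sequences if len(s) > 0]
    if not seqs or sum(len(s) - 1 for s in seqs) < 1:
        raise ValueError("need at least one observed transition")
    alphabet = np.unique(np.concatenate(seqs))
    m = len(alphabet)
    pos = {int(t): i for i, t in enumerate(alphabet)}
    counts = np.zeros((m, m))
    token_counts = np.zeros(m)
    for s in seqs:
        for t in s:
            token_counts[pos[int(t)]] += 1
        for a, b in zip(s[:-1], s[1:]):
            counts[pos[int(a)], pos[int(b)]] += 1
    rowsum = counts.sum(axis=1)
    probs = np.divide(counts, rowsum[:, None], out=np.zeros_like(counts),
                      where=rowsum[:, None] > 0)
    return TransitionModel(
        tokens=alphabet,
        counts=counts,
        probs=probs,
        stationary=token_counts / token_counts.sum(),
        dead_tokens=alphabet[rowsum == 0],
    )


def enumerate_top_spms(model: TransitionModel, n_transitions: int = N_TRANSITIONS,
                       top_n: int = TOP_N) -> list[tuple[tuple, float]]:
    """Exact top-``top_n`` token sequences of ``n_transitions``
    transitions by overall probability.

    Probability of s0..sL is stationary(s0) * prod P(s_{i+1}|s_i).
    Best-first search over prefixes: since every extension multiplies by
    a factor <= 1, a prefix's probability is an admissible bound on its
    completions, so sequences pop off the frontier in exact rank order.
    Ties are broken lexicographically. Returns fewer than ``top_n``
    entries iff fewer sequences have positive probability.
    """
    if n_transitions < 1:
        raise ValueError("n_transitions must be >= 1")
    m = len(model.tokens)
    length = n_transitions + 1
    heap: list[tuple[float, tuple]] = []
    for i in range(m):
        p = model.stationary[i]
        if p > 0:
            heapq.heappush(heap, (-p, (i,)))
    out: list[tuple[tuple, float]] = []
    while heap and len(out) < top_n:
        negp, prefix = heapq.heappop(heap)
        if len(prefix) == length:
            out.append((tuple(int(model.tokens[i]) for i in prefix), -negp))
            continue
        last = prefix[-1]
        row = model.probs[last]
        for j in range(m):
            if row[j] > 0:
                heapq.heappush(heap, (negp * row[j], prefix + (j,)))
    return out


def mirror_pool_map(mirror_pairs: Sequence[tuple[int, int]]) -> dict:
    """Map each PM id to its mirror-pool id (the smaller member of the
    pair); unpaired PMs map to themselves on lookup."""
    pool = {}
    for i, j in mirror_pairs:
        lo = min(i, j)
        pool[i] = lo
        pool[j] = lo
    return pool


def pool_tokens(tokens: Sequence[int], pool_map: dict) -> tuple:
    return tuple(pool_map.get(int(t), int(t)) for t in tokens)


@dataclass
class SPMEntry:
    entry_id: int
    canonical: tuple             # mirror-collapsed sequence of the top member
    composition: tuple           # sorted multiset of pooled tokens
    members: list                # raw sequences (tuples), ranked by probability
    probability: float           # summed member probability
    rank: int = 0
    freq_by_condition: dict = field(default_factory=dict)


@dataclass
class SPMCatalog:
    entries: list
    n_transitions: int
    n_raw_sequences: int
    mirror_pairs: list

    @property
    def size(self) -> int:
        return len(self.entries)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_transitions": self.n_transitions,
                "n_raw_sequences": self.n_raw_sequences,
                "mirror_pairs": [list(map(int, p)) for p in self.mirror_pairs],
                "entries": [
                    {
                        "entry_id": e.entry_id,
                        "canonical": list(e.canonical),
                        "composition": list(e.composition),
                        "members": [list(m) for m in e.members],
                        "probability": e.probability,
                        "rank": e.rank,
                        "freq_by_condition": e.freq_by_condition,
                    }
                    for e in self.entries
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SPMCatalog":
        d = json.loads(text)
        entries = [
            SPMEntry(
                entry_id=int(e["entry_id"]),
                canonical=tuple(e["canonical"]),
                composition=tuple(e["composition"]),
                members=[tuple(m) for m in e["members"]],
                probability=float(e["probability"]),
                rank=int(e["rank"]),
                freq_by_condition=e.get("freq_by_condition", {}),
            )
            for e in d["entries"]
        ]
        return cls(entries=entries, n_transitions=int(d["n_transitions"]),
                   n_raw_sequences=int(d["n_raw_sequences"]),
                   mirror_pairs=[tuple(p) for p in d["mirror_pairs"]])


def reduce_spms(ranked: Sequence[tuple[tuple, float]],
                mirror_pairs: Sequence[tuple[int, int]],
                n_transitions: int = N_TRANSITIONS) -> SPMCatalog:
    """Merge ranked raw sequences into SPM entries.

    Step 1 maps tokens to mirror pools; step 2 merges sequences whose
    pooled token multisets (compositions) are equal. The canonical form
    of an entry is the pooled sequence of its highest-probability
    member; entry probability is the sum over members, and merging
    conserves total probability.
    """
    pool = mirror_pool_map(mirror_pairs)
    groups: dict[tuple, SPMEntry] = {}
    for seq, p in ranked:
        pooled = pool_tokens(seq, pool)
        comp = tuple(sorted(pooled))
        if comp not in groups:
            groups[comp] = SPMEntry(
                entry_id=0, canonical=pooled, composition=comp,
                members=[tuple(seq)], probability=p,
            )
        else:
            g = groups[comp]
            g.members.append(tuple(seq))
            g.probability += p
    entries = sorted(groups.values(), key=lambda e: (-e.probability, e.canonical))
    for r, e in enumerate(entries):
        e.rank = r + 1
        e.entry_id = r + 1
    return SPMCatalog(entries=entries, n_transitions=n_transitions,
                      n_raw_sequences=len(ranked),
                      mirror_pairs=[tuple(p) for p in mirror_pairs])


def match_occurrences(labels: np.ndarray, entry: SPMEntry,
                      mirror_pairs: Sequence[tuple[int, int]],
                      members_mode: bool = False) -> list[dict]:
    """Locate occurrences of a catalog entry in a labeled segment.

    The label sequence is run-collapsed, tokens are mirror-pooled, and a
    window of ``len(entry.canonical)`` tokens slides over the stream.
    By default a window matches when it equals the entry's canonical
    pooled sequence; with ``members_mode`` it matches when it equals the
    pooled form of any member. Each occurrence spans the first matched
    token's first frame to the last matched token's last frame;
    overlapping occurrences are kept and flagged.
    """
    pool = mirror_pool_map(mirror_pairs)
    tokens, spans = collapse_runs(labels)
    pooled = pool_tokens(tokens, pool)
    L = len(entry.canonical)
    targets = (
        {pool_tokens(m, pool) for m in entry.members}
        if members_mode
        else {tuple(entry.canonical)}
    )
    out = []
    prev_end = -1
    for i in range(len(pooled) - L + 1):
        window = pooled[i:i + L]
        if window in targets:
            start = spans[i][0]
            end = spans[i + L - 1][1]
            out.append({"start": start, "end": end, "token_start": i,
                        "overlap": start < prev_end})
            prev_end = max(prev_end, end)
    return out


def occurrence_frames(occurrences: Sequence[dict], n_frames: int) -> int:
    """Number of distinct frames covered by a set of occurrences
    (overlaps counted once)."""
    mask = np.zeros(n_frames, dtype=bool)
    for o in occurrences:
        mask[o["start"]:o["end"]] = True
    return int(mask.sum())


def condition_contrast(catalog: SPMCatalog,
                       labels_a: Sequence[np.ndarray],
                       labels_b: Sequence[np.ndarray],
                       name_a: str = "no_object", name_b: str = "object",
                       members_mode: bool = False):
    """Per-entry relative occurrence frequency in two datasets and their
    difference (b - a). Frequency is occurrence frames over total frames
    of the condition."""
    import pandas as pd

    if not labels_a or not labels_b:
        raise ValueError("both condition datasets must be non-empty")
    tot_a = sum(len(l) for l in labels_a)
    tot_b = sum(len(l) for l in labels_b)
    if tot_a == 0 or tot_b == 0:
        raise ValueError("both condition datasets must contain frames")
    rows = []
    for e in catalog.entries:
        fa = sum(
            occurrence_frames(match_occurrences(l, e, catalog.mirror_pairs, members_mode), len(l))
            for l in labels_a
        ) / tot_a
        fb = sum(
            occurrence_frames(match_occurrences(l, e, catalog.mirror_pairs, members_mode), len(l))
            for l in labels_b
        ) / tot_b
        e.freq_by_condition = {name_a: fa, name_b: fb}
        rows.append({"entry_id": e.entry_id, f"freq_{name_a}": fa,
                     f"freq_{name_b}": fb, "diff": fb - fa})
    return pd.DataFrame(rows)
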
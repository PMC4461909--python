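"""Null distribution of degenerate-motif occurrence counts in random sequence.

A cluster of splicing-enhancer elements is only interesting if it is unlikely
under a background model.  This module computes, for an i.i.d. (Bernoulli /
0-order Markov) background, the exact probability distribution of the number
of (overlapping) occurrences of a degenerate consensus in a random sequence of
length L.

The exact computation runs a dynamic program over a deterministic match
automaton.  Because every expansion of an IUPAC consensus has the same length
and per-position base classes, the automaton state is the *set of pattern
prefixes currently matched* (a bitmask over prefix lengths 1..m-1), not an
Aho–Corasick trie over thousands of expanded words; the two are equivalent by
construction.  The DP tracks (state, capped occurrence count) and lumps counts
at a cap, since only the tail P(count >= k) is usually wanted.

A seeded Monte Carlo estimator is provided as an independent stochastic
cross-check of the DP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import BASES
from .motif_engine import DegeneratePattern

__all__ = [
    "BackgroundModel",
    "OccurrenceDistribution",
    "MatchAutomaton",
    "UNIFORM",
    "per_position_match_prob",
    "build_automaton",
    "occurrence_distribution",
    "tail_prob",
    "mc_occurrence_prob",
]


@dataclass(frozen=True)
class BackgroundModel:
    """0-order background: independent per-position base frequencies."""

    freq_A: float
    freq_C: float
    freq_G: float
    freq_T: float

    def __post_init__(self) -> None:
        f = self.freqs
        if np.any(f < 0):
            raise ValueError("background frequencies must be non-negative")
        if abs(float(f.sum()) - 1.0) > 1e-12:
            raise ValueError(f"background frequencies must sum to 1, got {f.sum()!r}")

    @property
    def freqs(self) -> np.ndarray:
        """Frequencies in A, C, G, T order."""
        return np.array([self.freq_A, self.freq_C, self.freq_G, self.freq_T], float)

    @classmethod
    def from_sequence(cls, seq: str) -> "BackgroundModel":
        """Empirical base frequencies of a sequence (ambiguity codes ignored)."""
        seq = seq.upper()
        counts = np.array([seq.count(b) for b in BASES], float)
        if counts.sum() == 0:
            raise ValueError("sequence contains no unambiguous bases")
        f = counts / counts.sum()
        return cls(*f)


UNIFORM = BackgroundModel(0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class OccurrenceDistribution:
    """P(count = j) for j = 0..cap-1, with P(count >= cap) lumped last."""

    L: int
    cap: int
    p: np.ndarray  # length cap + 1

    def __post_init__(self) -> None:
        if self.p.shape != (self.cap + 1,):
            raise ValueError("p must have cap + 1 entries")
        if np.any(self.p < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if abs(float(self.p.sum()) - 1.0) > 1e-9:
            raise ValueError("distribution must sum to 1")

    @property
    def mean_capped(self) -> float:
        """E[min(count, cap)] — equals the true mean when P(>cap) is negligible."""
        return float(np.dot(np.arange(self.cap + 1), self.p))


@dataclass(frozen=True)
class MatchAutomaton:
    """Deterministic automaton over ACGT emitting a match count per step.

    ``transitions[s, b]`` is the successor of state ``s`` on base ``b``;
    ``emits[s, b]`` is 1 when that step completes a full-length match.
    """

    n_states: int
    transitions: np.ndarray  # (n_states, 4) intp
    emits: np.ndarray  # (n_states, 4) uint8


def per_position_match_prob(
    pattern: DegeneratePattern | str, background: BackgroundModel = UNIFORM
) -> float:
    """Probability that a fixed position starts a match: product over pattern
    positions of the summed class frequencies."""
    if isinstance(pattern, str):
        pattern = DegeneratePattern.from_iupac(pattern)
    f = background.freqs
    p = 1.0
    for cls in pattern.position_classes():
        p *= float(f[list(cls)].sum())
    return p


def build_automaton(pattern: DegeneratePattern | str) -> MatchAutomaton:
    """Build the prefix-progress automaton for a degenerate consensus.

    State = bitmask over prefix lengths 1..m-1 currently matched by a suffix
    of the text read so far; reading a base that completes the length-m prefix
    emits one occurrence.  Only reachable states are materialised.
    """
    if isinstance(pattern, str):
        pattern = DegeneratePattern.from_iupac(pattern)
    classes = [frozenset(c) for c in pattern.position_classes()]
    m = len(classes)

    index: dict[int, int] = {0: 0}
    order: list[int] = [0]
    trans_rows: list[list[int]] = []
    emit_rows: list[list[int]] = []
    i = 0
    while i < len(order):
        mask = order[i]
        trow, erow = [], []
        for b in range(4):
            new_mask = 0
            emit = 0
            if b in classes[0]:
                if m == 1:
                    emit = 1
                else:
                    new_mask |= 1  # prefix of length 1 (bit 0)
            for bit in range(m - 1):
                if mask >> bit & 1 and b in classes[bit + 1]:
                    if bit + 1 == m - 1:
                        emit = 1
                    else:
                        new_mask |= 1 << (bit + 1)
            if new_mask not in index:
                index[new_mask] = len(order)
                order.append(new_mask)
            trow.append(index[new_mask])
            erow.append(emit)
        trans_rows.append(trow)
        emit_rows.append(erow)
        i += 1
    return MatchAutomaton(
        n_states=len(order),
        transitions=np.array(trans_rows, dtype=np.intp),
        emits=np.array(emit_rows, dtype=np.uint8),
    )


def occurrence_distribution(
    pattern: DegeneratePattern | str,
    L: int,
    background: BackgroundModel = UNIFORM,
    cap: int = 8,
) -> OccurrenceDistribution:
    """Exact distribution of overlapping occurrence counts in an i.i.d.
    sequence of length L, with counts >= ``cap`` lumped."""
    if isinstance(pattern, str):
        pattern = DegeneratePattern.from_iupac(pattern)
    if L < 0:
        raise ValueError("L must be non-negative")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    p = np.zeros(cap + 1)
    if L < pattern.length:
        p[0] = 1.0
        return OccurrenceDistribution(L, cap, p)

    auto = build_automaton(pattern)
    f = background.freqs
    # P[state, c] with c = min(count, cap)
    P = np.zeros((auto.n_states, cap + 1))
    P[0, 0] = 1.0
    new = np.empty_like(P)
    for _ in range(L):
        new[:] = 0.0
        for b in range(4):
            if f[b] == 0.0:
                continue
            contrib = P * f[b]
            ns = auto.transitions[:, b]
            em = auto.emits[:, b].astype(bool)
            if (~em).any():
                np.add.at(new, ns[~em], contrib[~em])
            if em.any():
                c = contrib[em]
                shifted = np.zeros_like(c)
                shifted[:, 1:] = c[:, :-1]
                shifted[:, -1] += c[:, -1]  # counts already at cap stay lumped
                np.add.at(new, ns[em], shifted)
        P, new = new, P
    dist = P.sum(axis=0)
    dist = np.maximum(dist, 0.0)
    dist /= dist.sum()
    return OccurrenceDistribution(L, cap, dist)


def tail_prob(dist: OccurrenceDistribution, k: int) -> float:
    """P(count >= k); requires k <= cap (raise the cap otherwise)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > dist.cap:
        raise ValueError(f"k={k} exceeds cap={dist.cap}; recompute with a larger cap")
    return float(dist.p[k:].sum())


def mc_occurrence_prob(
    pattern: DegeneratePattern | str,
    L: int,
    k: int,
    background: BackgroundModel = UNIFORM,
    reps: int = 100_000,
    seed: int = 0,
    batch: int = 8192,
) -> tuple[float, float]:
    """Monte Carlo estimate of P(count >= k) with its binomial standard error.

    Simulates ``reps`` i.i.d. sequences of length L and counts overlapping
    matches with a vectorised per-position class test.  Deterministic for a
    fixed seed; serves as an independent stochastic oracle for the DP.
    """
    if isinstance(pattern, str):
        pattern = DegeneratePattern.from_iupac(pattern)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if k == 0:
        return 1.0, 0.0
    m = pattern.length
    rng = np.random.default_rng(seed)
    f = background.freqs
    table = np.zeros((m, 4), dtype=bool)
    for j, cls in enumerate(pattern.position_classes()):
        table[j, list(cls)] = True
    uniform = bool(np.allclose(f, 0.25))
    successes = 0
    done = 0
    n_pos = L - m + 1
    while done < reps:
        nb = min(batch, reps - done)
        if n_pos <= 0:
            done += nb
            continue
        if uniform:
            seqs = rng.integers(0, 4, size=(nb, L), dtype=np.uint8)
        else:
            seqs = rng.choice(4, size=(nb, L), p=f).astype(np.uint8)
        ok = np.ones((nb, n_pos), dtype=bool)
        for j in range(m):
            ok &= table[j][seqs[:, j : j + n_pos]]
        successes += int((ok.sum(axis=1) >= k).sum())
        done += nb
    phat = successes / reps
    se = float(np.sqrt(phat * (1.0 - phat) / reps))
    return phat, se
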
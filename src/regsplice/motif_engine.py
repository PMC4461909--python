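"""Degenerate (IUPAC) motif expansion, scanning, windowed clusters and
transcriptome screens.

The splicing-enhancer elements searched for here — the TRA/TRA2 repeat element
(dsxRE, NMDNCRWNCWAYM), the Nasonia-like TRA/TRA2 site (NGAAGAWN), RBP1 type A/B
motifs (DCADCTTTA, ATCYNNA) and the TRA-2-ISS silencer (CAAGR) — are degenerate
consensi.  A consensus is matched exactly and in full (every expansion is a
fixed-length word), overlapping occurrences all count, and a transcript is
"cluster-positive" when at least k occurrences fall inside one w-nt window
(e.g. 6 dsxRE copies in 224 bp, 8 RBP1b copies in 546 bp).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from ._seq import (
    BASES,
    IUPAC_CLASSES,
    class_indices,
    encode,
    normalize,
    reverse_complement,
)

__all__ = [
    "DegeneratePattern",
    "MotifHit",
    "WindowCluster",
    "ScreenRow",
    "expand_pattern",
    "scan_sequence",
    "max_window_count",
    "screen_transcripts",
]


@dataclass(frozen=True)
class DegeneratePattern:
    """An ordered IUPAC consensus, e.g. ``NMDNCRWNCWAYM``."""

    pattern_id: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 1:
            raise ValueError("pattern must have at least one position")
        for s in self.symbols:
            if s not in IUPAC_CLASSES:
                raise ValueError(f"invalid IUPAC symbol in pattern: {s!r}")

    @classmethod
    def from_iupac(cls, iupac: str, pattern_id: str | None = None) -> "DegeneratePattern":
        iupac = normalize(iupac)
        return cls(pattern_id=pattern_id or iupac, symbols=tuple(iupac))

    @property
    def length(self) -> int:
        return len(self.symbols)

    @property
    def degeneracy(self) -> int:
        """Number of distinct unambiguous words the consensus stands for."""
        d = 1
        for s in self.symbols:
            d *= len(IUPAC_CLASSES[s])
        return d

    def position_classes(self) -> list[tuple[int, ...]]:
        return [class_indices(s) for s in self.symbols]

    def __str__(self) -> str:
        return "".join(self.symbols)


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    start: int  # 0-based
    end: int  # half-open
    word: str
    pattern_id: str
    strand: str = "+"


@dataclass(frozen=True)
class WindowCluster:
    seq_id: str
    window_start: int  # 0-based
    window_len: int
    count: int
    hit_indices: tuple[int, ...] = ()


@dataclass(frozen=True)
class ScreenRow:
    seq_id: str
    total_hits: int
    best_window: WindowCluster
    retained: bool


def expand_pattern(pattern: DegeneratePattern | str) -> set[str]:
    """All unambiguous ACGT words a degenerate consensus stands for."""
    if isinstance(pattern, str):
        pattern = DegeneratePattern.from_iupac(pattern)
    return {
        "".join(word)
        for word in itertools.product(*(IUPAC_CLASSES[s] for s in pattern.symbols))
    }


def _match_positions(codes: np.ndarray, classes: list[tuple[int, ...]]) -> np.ndarray:
    """Start offsets of all (overlapping) full-length matches; vectorised."""
    m = len(classes)
    n = codes.size - m + 1
    if n <= 0:
        return np.empty(0, dtype=np.intp)
    ok = np.ones(n, dtype=bool)
    table = np.zeros((m, 5), dtype=bool)  # column 4 = ambiguity, never matches
    for j, cls in enumerate(classes):
        table[j, list(cls)] = True
    for j in range(m):
        ok &= table[j][codes[j : j + n]]
        if not ok.any():
            return np.empty(0, dtype=np.intp)
    return np.flatnonzero(ok)


def scan_sequence(
    seq: str,
    pattern: DegeneratePattern | str,
    strand_mode: str = "forward",
    seq_id: str = "seq",
) -> list[MotifHit]:
    """All exact full-length matches of a degenerate consensus in ``seq``.

    Overlapping matches are each reported.  In ``both`` mode reverse-strand
    matches carry forward-strand coordinates.  Ambiguity codes (N etc.) in the
    subject never match any pattern position.
    """
    if isinstance(pattern, str):
        pattern = DegeneratePattern.from_iupac(pattern)
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")
    seq = normalize(seq)
    if not seq:
        return []
    m = pattern.length
    classes = pattern.position_classes()
    hits: list[MotifHit] = []
    for start in _match_positions(encode(seq), classes):
        s = int(start)
        hits.append(MotifHit(seq_id, s, s + m, seq[s : s + m], pattern.pattern_id, "+"))
    if strand_mode == "both":
        rc = reverse_complement(seq)
        L = len(seq)
        for start in _match_positions(encode(rc), classes):
            s = int(start)
            hits.append(
                MotifHit(seq_id, L - s - m, L - s, rc[s : s + m], pattern.pattern_id, "-")
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def max_window_count(
    hits: Iterable[MotifHit],
    w: int,
    seq_len: int,
    seq_id: str | None = None,
    min_pattern_len: int | None = None,
) -> WindowCluster:
    """The length-``w`` window fully containing the most hits.

    Candidate windows slide by 1 nt; a hit belongs to a window iff its full
    span lies inside.  Ties are broken toward the smallest window start.
    """
    hits = list(hits)
    if hits:
        pat_len = min(h.end - h.start for h in hits)
        if w < pat_len:
            raise ValueError(f"window {w} shorter than pattern length {pat_len}")
        seq_id = seq_id or hits[0].seq_id
    elif min_pattern_len is not None and w < min_pattern_len:
        raise ValueError(f"window {w} shorter than pattern length {min_pattern_len}")
    if not hits:
        return WindowCluster(seq_id or "seq", 0, w, 0, ())

    starts = np.array([h.start for h in hits])
    ends = np.array([h.end for h in hits])
    max_start = max(0, seq_len - w)
    # count(s) changes only where a hit enters at s = end - w; evaluate those
    candidates = sorted({0} | {min(max(int(e) - w, 0), max_start) for e in ends})
    best_s, best_count, best_idx = 0, -1, ()
    for s in candidates:
        inside = (starts >= s) & (ends <= s + w)
        c = int(inside.sum())
        if c > best_count:
            best_s, best_count = s, c
            best_idx = tuple(int(i) for i in np.flatnonzero(inside))
    return WindowCluster(seq_id or "seq", best_s, w, best_count, best_idx)


def screen_transcripts(
    cds_fasta: str | Path | Mapping[str, str],
    pattern: DegeneratePattern | str,
    k: int,
    w: int,
    strand_mode: str = "forward",
) -> list[ScreenRow]:
    """Screen a transcript set for k-in-w motif clusters.

    One row per sequence; ``retained`` marks transcripts whose best window
    holds at least ``k`` occurrences (the enrichment criterion: k=6, w=224 for
    the dsxRE; k=8, w=546 for RBP1b).
    """
    if isinstance(pattern, str):
        pattern = DegeneratePattern.from_iupac(pattern)
    if k < 1:
        raise ValueError("k must be >= 1")
    if w < pattern.length:
        raise ValueError(f"window {w} shorter than pattern length {pattern.length}")
    if isinstance(cds_fasta, (str, Path)):
        from .io_utils import read_fasta

        records = read_fasta(cds_fasta)
    else:
        records = {sid: normalize(s) for sid, s in cds_fasta.items()}
    rows: list[ScreenRow] = []
    for sid, seq in records.items():
        hits = scan_sequence(seq, pattern, strand_mode=strand_mode, seq_id=sid)
        best = max_window_count(hits, w, len(seq), seq_id=sid, min_pattern_len=pattern.length)
        rows.append(ScreenRow(sid, len(hits), best, best.count >= k))
    return rows
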